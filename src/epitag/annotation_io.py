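"""Genome/annotation input and extraction of the stop-codon-centred design region.

All internal coordinates are 0-based half-open; GTF/GFF3 1-based inclusive
coordinates are converted at the parsing boundary. A transcript is usable for
C-terminal tagging only if it has CDS features, a CDS length divisible by 3, a
terminal stop codon (TAA/TAG/TGA) and a non-empty 3'UTR downstream of it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq
import gffutils

logger = logging.getLogger(__name__)

STOP_CODONS = {"TAA", "TAG", "TGA"}
#: strict alphabet kept in memory; other IUPAC ambiguity codes collapse to N
_CANONICAL = set("ACGTN")
_IUPAC_AMBIGUOUS = set("RYSWKMBDHV")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (ACGTN)."""
    return str(Seq(seq).reverse_complement())


@dataclass
class GenomeSequence:
    """In-memory genome: chromosome name -> uppercase ACGTN sequence."""

    chromosomes: dict[str, str] = field(default_factory=dict)

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Return the sequence of a 0-based half-open interval, or fail."""
        if chrom not in self.chromosomes:
            raise KeyError(f"unknown chromosome {chrom!r}")
        seq = self.chromosomes[chrom]
        if not (0 <= start <= end <= len(seq)):
            raise ValueError(
                f"interval [{start},{end}) out of bounds for {chrom} (length {len(seq)})"
            )
        return seq[start:end]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chromosomes


@dataclass
class TranscriptModel:
    """Exon/CDS structure of one transcript with its stop codon located.

    ``exons`` and ``cds`` are sorted, disjoint genomic intervals (0-based
    half-open) in genomic order regardless of strand; ``stop_codon`` is the
    genomic interval of the 3 stop bases. ``cds`` excludes the stop codon.
    """

    transcript_id: str
    chrom: str
    strand: str  # '+' or '-'
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]]
    stop_codon: tuple[int, int]

    def spliced_positions(self) -> list[int]:
        """Genomic position of every exonic base in transcript (5'->3') order."""
        pos = [p for s, e in self.exons for p in range(s, e)]
        if self.strand == "-":
            pos.reverse()
        return pos


@dataclass
class DesignRegion:
    """Stop-codon-centred window of spliced sequence, in transcript orientation.

    ``sequence`` is the coding strand; ``stop_offset`` indexes the first stop
    base; ``annotation`` labels each base CDS / UTR3 / FLANK (the stop codon
    itself carries the CDS label); ``genomic_positions[i]`` is the genomic
    coordinate of base i, enabling an exact round trip to the genome.
    """

    transcript_id: str
    sequence: str
    stop_offset: int
    annotation: list[str]
    chrom: str
    strand: str
    genomic_positions: list[int]
    warnings: list[str] = field(default_factory=list)

    @property
    def genomic_anchor(self) -> tuple[str, str, int]:
        return (self.chrom, self.strand, self.genomic_positions[0])

    @property
    def stop_codon(self) -> str:
        return self.sequence[self.stop_offset : self.stop_offset + 3]

    def __len__(self) -> int:
        return len(self.sequence)


def load_genome(path) -> GenomeSequence:
    """Load a FASTA file into memory, uppercased, validated.

    Multi-line records are concatenated. Duplicate record names and
    non-IUPAC characters are errors; IUPAC ambiguity codes other than N
    are normalised to N.
    """
    chromosomes: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in chromosomes:
            raise ValueError(f"duplicate FASTA record name {rec.id!r}")
        seq = str(rec.seq).upper()
        cleaned = []
        for i, base in enumerate(seq):
            if base in _CANONICAL:
                cleaned.append(base)
            elif base in _IUPAC_AMBIGUOUS:
                cleaned.append("N")
            else:
                raise ValueError(
                    f"non-IUPAC character {base!r} at position {i} of record {rec.id!r}"
                )
        if not cleaned:
            raise ValueError(f"empty FASTA record {rec.id!r}")
        chromosomes[rec.id] = "".join(cleaned)
    if not chromosomes:
        raise ValueError(f"no FASTA records found in {path}")
    return GenomeSequence(chromosomes)


def _transcript_sequence(tm: TranscriptModel, genome: GenomeSequence) -> str:
    parts = [genome.fetch(tm.chrom, s, e) for s, e in tm.exons]
    seq = "".join(parts)
    return revcomp(seq) if tm.strand == "-" else seq


def _locate_stop(
    tm_id: str,
    chrom: str,
    strand: str,
    exons: list[tuple[int, int]],
    cds: list[tuple[int, int]],
    genome: GenomeSequence,
) -> tuple[list[tuple[int, int]], tuple[int, int]] | None:
    """Find the stop codon from CDS extent; return (cds_without_stop, stop_iv).

    Handles both GTF dialects: a CDS that includes the stop codon (last 3
    coding bases are a stop) and one that excludes it (the 3 exonic bases
    after the CDS are the stop). Returns None when neither holds or the stop
    would be split across exons.
    """
    positions = [p for s, e in exons for p in range(s, e)]
    if strand == "-":
        positions.reverse()
    cds_set = {p for s, e in cds for p in range(s, e)}
    cds_idx = [i for i, p in enumerate(positions) if p in cds_set]
    if not cds_idx or cds_idx != list(range(cds_idx[0], cds_idx[-1] + 1)):
        return None  # CDS not contiguous on the spliced transcript

    def base_at(tx_index: int) -> str:
        p = positions[tx_index]
        b = genome.fetch(chrom, p, p + 1)
        return revcomp(b) if strand == "-" else b

    last = cds_idx[-1]
    tail = "".join(base_at(i) for i in cds_idx[-3:]) if len(cds_idx) >= 3 else ""
    if tail in STOP_CODONS:
        stop_tx = cds_idx[-3:]
    elif last + 3 < len(positions):
        after = "".join(base_at(last + k) for k in (1, 2, 3))
        if after in STOP_CODONS:
            stop_tx = [last + 1, last + 2, last + 3]
        else:
            return None
    else:
        return None
    stop_gpos = sorted(positions[i] for i in stop_tx)
    if stop_gpos[2] - stop_gpos[0] != 2:
        logger.warning("%s: stop codon split across exons; transcript rejected", tm_id)
        return None
    stop_iv = (stop_gpos[0], stop_gpos[2] + 1)
    cds_wo_stop = _subtract_interval(cds, stop_iv)
    return cds_wo_stop, stop_iv


def _subtract_interval(
    ivs: list[tuple[int, int]], cut: tuple[int, int]
) -> list[tuple[int, int]]:
    out = []
    cs, ce = cut
    for s, e in ivs:
        if e <= cs or s >= ce:
            out.append((s, e))
        else:
            if s < cs:
                out.append((s, cs))
            if e > ce:
                out.append((ce, e))
    return sorted(out)


def load_annotation(path, genome: GenomeSequence) -> dict[str, TranscriptModel]:
    """Parse a GTF or GFF3 file into a transcript catalogue.

    Only transcripts with CDS features are modelled. Transcripts whose CDS
    length is not divisible by 3, that lack a locatable stop codon, whose
    stop codon is split across exons, or that have no 3'UTR are skipped with
    a logged warning. An explicit ``stop_codon`` feature, when present, is
    authoritative.
    """
    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )

    def tx_of(feature) -> str | None:
        if "transcript_id" in feature.attributes:
            return feature.attributes["transcript_id"][0]
        if "Parent" in feature.attributes:
            return feature.attributes["Parent"][0]
        return None

    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    stops: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str]] = {}
    for ftype, store in (("exon", exons), ("CDS", cds), ("stop_codon", stops)):
        for feat in db.features_of_type(ftype):
            tid = tx_of(feat)
            if tid is None:
                continue
            # GTF/GFF 1-based inclusive -> 0-based half-open
            store.setdefault(tid, []).append((feat.start - 1, feat.end))
            meta.setdefault(tid, (feat.seqid, feat.strand))

    catalog: dict[str, TranscriptModel] = {}
    for tid, cds_ivs in cds.items():
        chrom, strand = meta[tid]
        if chrom not in genome:
            logger.warning("%s: chromosome %s not in genome; skipped", tid, chrom)
            continue
        ex = sorted(exons.get(tid, sorted(cds_ivs)))
        cd = sorted(cds_ivs)
        if tid in stops:
            sc = sorted(stops[tid])
            if sum(e - s for s, e in sc) != 3 or len(sc) > 1:
                logger.warning("%s: stop codon split or malformed; skipped", tid)
                continue
            stop_iv = sc[0]
            cd = _subtract_interval(cd, stop_iv)
        else:
            located = _locate_stop(tid, chrom, strand, ex, cd, genome)
            if located is None:
                logger.warning("%s: no locatable stop codon; skipped", tid)
                continue
            cd, stop_iv = located
        cds_len = sum(e - s for s, e in cd)
        if (cds_len + 3) % 3 != 0:
            logger.warning("%s: CDS length %d not divisible by 3; skipped", tid, cds_len + 3)
            continue
        tm = TranscriptModel(tid, chrom, strand, ex, cd, stop_iv)
        # require a non-empty 3'UTR downstream of the stop in transcript orientation
        positions = tm.spliced_positions()
        stop_last = stop_iv[0] if strand == "-" else stop_iv[1] - 1
        try:
            idx = positions.index(stop_last)
        except ValueError:
            logger.warning("%s: stop codon outside exons; skipped", tid)
            continue
        if idx + 1 >= len(positions):
            logger.warning("%s: no 3'UTR downstream of stop codon; skipped", tid)
            continue
        stop_seq = genome.fetch(chrom, *stop_iv)
        if strand == "-":
            stop_seq = revcomp(stop_seq)
        if stop_seq not in STOP_CODONS:
            logger.warning("%s: annotated stop codon %s is not a stop; skipped", tid, stop_seq)
            continue
        catalog[tid] = tm
    return catalog


def extract_design_region(
    transcript_id: str,
    catalog: dict[str, TranscriptModel],
    genome: GenomeSequence,
    window_nt: int = 200,
) -> DesignRegion:
    """Extract the ``window_nt`` spliced bases centred on the stop codon.

    ``window_nt // 2`` bases precede the stop codon and the remainder
    (including the stop codon itself) follow; the window is truncated where
    the transcript ends, with a warning. Minimum window is 46 nt (one 23-nt
    Cas9 site on either side of the stop).
    """
    if window_nt < 46:
        raise ValueError(f"window_nt must be >= 46, got {window_nt}")
    if transcript_id not in catalog:
        raise KeyError(f"unknown transcript {transcript_id!r}")
    tm = catalog[transcript_id]
    positions = tm.spliced_positions()
    tx_seq = _transcript_sequence(tm, genome)

    stop_last = tm.stop_codon[0] if tm.strand == "-" else tm.stop_codon[1] - 1
    stop_tx = positions.index(stop_last) - 2  # transcript index of first stop base

    up = window_nt // 2
    down = window_nt - up  # counted from the first stop base, includes the stop
    start = max(0, stop_tx - up)
    end = min(len(tx_seq), stop_tx + down)

    warnings_ = []
    if start > 0 and stop_tx - up < 0:
        pass  # unreachable; kept for clarity of the max() above
    if stop_tx - up < 0:
        warnings_.append("short upstream: window truncated at transcript start")
    if stop_tx + down > len(tx_seq):
        warnings_.append("short UTR: window truncated at transcript end")

    seq = tx_seq[start:end]
    gpos = positions[start:end]
    step = -1 if tm.strand == "-" else 1
    if any(b - a != step for a, b in zip(gpos, gpos[1:])):
        warnings_.append(
            "window crosses a splice junction; genomic and transcript coordinates diverge"
        )
    for w in warnings_:
        logger.warning("%s: %s", transcript_id, w)

    cds_set = {p for s, e in tm.cds for p in range(s, e)}
    stop_set = set(range(tm.stop_codon[0], tm.stop_codon[1]))
    stop_off = stop_tx - start
    labels = []
    for i, p in enumerate(gpos):
        if p in cds_set or p in stop_set:
            labels.append("CDS")
        elif i > stop_off + 2:
            labels.append("UTR3")
        else:
            labels.append("FLANK")
    region = DesignRegion(
        transcript_id=transcript_id,
        sequence=seq,
        stop_offset=stop_off,
        annotation=labels,
        chrom=tm.chrom,
        strand=tm.strand,
        genomic_positions=gpos,
        warnings=warnings_,
    )
    assert region.stop_codon in STOP_CODONS, (
        f"{transcript_id}: window does not contain a stop codon at offset {stop_off}"
    )
    return region


def region_from_sequence(
    sequence: str, stop_offset: int, transcript_id: str = "direct"
) -> DesignRegion:
    """Annotation-free entry point: a raw coding-strand sequence plus the
    0-based offset of its stop codon. Bases before the stop are labelled CDS,
    bases after it UTR3."""
    sequence = sequence.upper()
    stop = sequence[stop_offset : stop_offset + 3]
    if stop not in STOP_CODONS:
        raise ValueError(f"no stop codon at offset {stop_offset} (found {stop!r})")
    labels = [
        "CDS" if i <= stop_offset + 2 else "UTR3" for i in range(len(sequence))
    ]
    return DesignRegion(
        transcript_id=transcript_id,
        sequence=sequence,
        stop_offset=stop_offset,
        annotation=labels,
        chrom=transcript_id,
        strand="+",
        genomic_positions=list(range(len(sequence))),
    )
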