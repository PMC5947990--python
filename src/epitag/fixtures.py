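"""Synthetic genome/annotation fixtures with planted, truth-recorded features.

The generator emits a small multi-chromosome genome (FASTA), an Ensembl-style
GTF, and a truth table (TSV). Each transcript carries a protein-coding gene
whose 3'UTR contains planted Cas9 sites at exact, chosen cut-to-stop
distances; a separate decoy chromosome carries planted off-target loci at
exact Hamming distances and chosen PAM classes for the planted protospacers.

Background sequence is drawn from {A, T} only and planted protospacers from
{A, C, T} with no CC dinucleotide, so the only NGG/NAG-adjacent 20-mers in
the genome are the planted ones: every candidate site and off-target hit the
pipeline reports can be checked against the truth table. Real genomes differ
in every compositional respect (GC content, repeats, pseudogenes); the
fixtures exercise coordinate logic, filtering and scoring arithmetic, not
genomic realism.

Outputs are byte-identical for a fixed seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation_io import GenomeSequence, revcomp

_SENSE_CODONS = sorted(
    c
    for c in (a + b + d for a in "ACGT" for b in "ACGT" for d in "ACGT")
    if c not in ("TAA", "TAG", "TGA") and c != "ATG"
)


@dataclass
class PlantedOfftarget:
    """A decoy locus: ``mm`` mismatches from planted guide ``guide_index`` of
    transcript ``tx_index``, with the given PAM class."""

    tx_index: int
    guide_index: int
    mm: int
    pam_class: str = "NGG"  # or 'NAG'


@dataclass
class FixtureSpec:
    """Recipe for one deterministic fixture set."""

    seed: int = 0
    n_transcripts: int = 4
    utr_len_range: tuple[int, int] = (100, 140)
    cds_codons_range: tuple[int, int] = (40, 80)
    #: cut-to-stop distances of planted sites, one list per transcript
    #: (recycled when shorter than n_transcripts); same-transcript distances
    #: must differ by >= 23 nt or the 23-nt site spans would collide
    cut_distances: list[list[int]] = field(default_factory=lambda: [[12, 40], [5, 28]])
    strands: list[str] | None = None  # per transcript; default alternating +/-
    offtargets: list[PlantedOfftarget] = field(default_factory=list)
    flank_len: int = 60
    utr5_len: int = 12


@dataclass
class FixtureSet:
    genome: GenomeSequence
    fasta: str
    gtf: str
    truth: pd.DataFrame
    spec: FixtureSpec

    def write(self, outdir) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "genome.fa",
            "gtf": outdir / "annotation.gtf",
            "truth": outdir / "truth.tsv",
        }
        paths["fasta"].write_text(self.fasta)
        paths["gtf"].write_text(self.gtf)
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        return paths


def _background(rng: np.random.Generator, n: int) -> list[str]:
    return list(np.array(["A", "T"])[rng.integers(0, 2, n)])


def _planted_protospacer(rng: np.random.Generator, n: int = 20) -> str:
    """Random {A,C,T} 20-mer without CC (no stray minus-strand PAM)."""
    bases = list(np.array(["A", "C", "T"])[rng.integers(0, 3, n)])
    for i in range(1, n):
        if bases[i - 1] == "C" and bases[i] == "C":
            bases[i] = "A" if rng.integers(0, 2) == 0 else "T"
    return "".join(bases)


def generate_fixtures(spec: FixtureSpec, outdir=None) -> FixtureSet:
    """Build the fixture set; optionally write it to ``outdir``.

    Raises at generation time if two planted sites on one transcript would
    overlap (spans closer than 26 nt).
    """
    rng = np.random.default_rng(spec.seed)
    chroms: dict[str, str] = {}
    gtf_lines: list[str] = []
    truth_rows: list[dict] = []
    planted_protos: dict[tuple[int, int], str] = {}

    strands = spec.strands or ["+" if i % 2 == 0 else "-" for i in range(spec.n_transcripts)]
    for t in range(spec.n_transcripts):
        tid = f"TX{t + 1:03d}"
        chrom = f"chr{t + 1}"
        strand = strands[t]
        distances = spec.cut_distances[t % len(spec.cut_distances)]
        spans = sorted((d - 17, d + 6) for d in distances)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 < e1:
                raise ValueError(
                    f"{tid}: planted sites at distances {distances} overlap"
                )

        n_codons = int(rng.integers(*spec.cds_codons_range))
        cds = "ATG" + "".join(
            _SENSE_CODONS[i] for i in rng.integers(0, len(_SENSE_CODONS), n_codons - 2)
        )
        cds += "GAT"  # fixed last sense codon: no CC at the CDS/stop boundary
        utr_len = int(rng.integers(*spec.utr_len_range))
        need = max((d + 6 for d in distances), default=0)
        utr_len = max(utr_len, need + 10)
        utr = _background(rng, utr_len)

        for g, d in enumerate(distances):
            # cut bond at utr coordinate d; protospacer span [d-17, d+3), PAM [d+3, d+6)
            proto_start = d - 17
            proto = list(_planted_protospacer(rng))
            for k in range(20):
                pos = proto_start + k
                if pos >= 0:  # UTR part only; CDS/stop bases stay untouched
                    utr[pos] = proto[k]
            utr[d + 4] = "G"
            utr[d + 5] = "G"
            # truth protospacer = what actually sits at the span (may include
            # stop/CDS bases when the cut is close to the stop)
            gene_prefix = spec.flank_len + spec.utr5_len + len(cds) + 3
            planted_protos[(t, g)] = None  # filled below once cassette exists
            truth_rows.append(
                {
                    "kind": "guide_site",
                    "transcript_id": tid,
                    "chrom": chrom,
                    "tx_index": t,
                    "guide_index": g,
                    "cut_distance": d,
                    "strand": strand,
                    "mm": 0,
                    "pam_class": "NGG",
                    "protospacer": "",  # placeholder
                }
            )

        cassette = (
            "".join(_background(rng, spec.flank_len))
            + "".join(_background(rng, spec.utr5_len))
            + cds
            + "TAA"
            + "".join(utr)
            + "".join(_background(rng, spec.flank_len))
        )
        L = len(cassette)
        exon_start = spec.flank_len
        cds_start = spec.flank_len + spec.utr5_len
        stop_start = cds_start + len(cds)
        exon_end = stop_start + 3 + utr_len

        stop_end_tx = stop_start + 3
        for row in truth_rows:
            if row["transcript_id"] == tid and row["protospacer"] == "":
                d = row["cut_distance"]
                span_s = stop_end_tx + d - 17
                row["protospacer"] = cassette[span_s : span_s + 20]
                row["pam"] = cassette[span_s + 20 : span_s + 23]
                planted_protos[(t, row["guide_index"])] = row["protospacer"]
                if strand == "+":
                    row["genomic_start"] = span_s
                else:
                    row["genomic_start"] = L - (span_s + 20)

        if strand == "-":
            chroms[chrom] = revcomp(cassette)
            conv = lambda s, e: (L - e, L - s)  # noqa: E731
        else:
            chroms[chrom] = cassette
            conv = lambda s, e: (s, e)  # noqa: E731

        def gtf_line(ftype, s, e):
            gs, ge = conv(s, e)
            attrs = f'gene_id "G{tid}"; transcript_id "{tid}";'
            return f"{chrom}\tfixture\t{ftype}\t{gs + 1}\t{ge}\t.\t{strand}\t.\t{attrs}"

        gtf_lines.extend(
            [
                gtf_line("transcript", exon_start, exon_end),
                gtf_line("exon", exon_start, exon_end),
                gtf_line("CDS", cds_start, stop_start),
                gtf_line("stop_codon", stop_start, stop_start + 3),
            ]
        )

    # ---- decoy chromosome with planted off-target loci ----
    if spec.offtargets:
        gap = 40
        parts: list[str] = ["".join(_background(rng, gap))]
        offset = gap
        for ot in spec.offtargets:
            proto = planted_protos.get((ot.tx_index, ot.guide_index))
            if proto is None:
                raise ValueError(
                    f"off-target references unplanted guide {(ot.tx_index, ot.guide_index)}"
                )
            decoy = list(proto)
            positions = rng.choice(20, size=ot.mm, replace=False)
            for p in sorted(int(x) for x in positions):
                choices = [b for b in "ACT" if b != decoy[p]]
                order = rng.permutation(len(choices))
                for b in (choices[int(i)] for i in order):
                    left = decoy[p - 1] if p > 0 else "A"
                    right = decoy[p + 1] if p < 19 else "T"
                    if not (b == "C" and (left == "C" or right == "C")):
                        decoy[p] = b
                        break
                else:
                    decoy[p] = "A" if decoy[p] != "A" else "T"
            pam = "TGG" if ot.pam_class == "NGG" else "TAG"
            seq = "".join(decoy) + pam
            truth_rows.append(
                {
                    "kind": "offtarget",
                    "transcript_id": f"TX{ot.tx_index + 1:03d}",
                    "chrom": "chrOT",
                    "tx_index": ot.tx_index,
                    "guide_index": ot.guide_index,
                    "cut_distance": np.nan,
                    "strand": "+",
                    "mm": ot.mm,
                    "pam_class": ot.pam_class,
                    "protospacer": "".join(decoy),
                    "pam": pam,
                    "genomic_start": offset,
                }
            )
            parts.append(seq)
            parts.append("".join(_background(rng, gap)))
            offset += len(seq) + gap
        chroms["chrOT"] = "".join(parts)

    fasta = "".join(f">{name}\n{_wrap(seq)}\n" for name, seq in chroms.items())
    gtf = "\n".join(gtf_lines) + "\n"
    truth = pd.DataFrame(truth_rows)
    fs = FixtureSet(GenomeSequence(dict(chroms)), fasta, gtf, truth, spec)
    if outdir is not None:
        fs.write(outdir)
    return fs


def _wrap(seq: str, width: int = 60) -> str:
    return "\n".join(seq[i : i + width] for i in range(0, len(seq), width))


def spec_from_json(payload: dict) -> FixtureSpec:
    """Build a FixtureSpec from a JSON-decoded dict (CLI entry point)."""
    ots = [PlantedOfftarget(**o) for o in payload.pop("offtargets", [])]
    known = {f.name for f in dataclasses.fields(FixtureSpec)}
    unknown = set(payload) - known
    if unknown:
        raise ValueError(f"unknown fixture spec fields: {sorted(unknown)}")
    fspec = FixtureSpec(**payload)
    fspec.offtargets = ots
    if fspec.cut_distances and not isinstance(fspec.cut_distances[0], list):
        fspec.cut_distances = [list(fspec.cut_distances)]
    fspec.cut_distances = [list(d) for d in fspec.cut_distances]
    fspec.utr_len_range = tuple(fspec.utr_len_range)
    fspec.cds_codons_range = tuple(fspec.cds_codons_range)
    return fspec
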