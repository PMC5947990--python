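"""On-target efficiency and off-target specificity scoring.

On-target: the full Rule Set 2 featurization of the 30-nt context
(4 nt upstream + 20-nt protospacer + NGG PAM + 3 nt downstream) is
implemented so an externally trained linear model over those features can be
plugged in. Without a model, a documented deterministic fallback score is
used (GC balance of the protospacer plus a homopolymer-run penalty) so the
pipeline remains self-contained.

Specificity: an exhaustive scan of the genome for 20-mers within a Hamming
mismatch budget (default 3) of the protospacer, adjacent to an NGG or NAG
PAM, followed by the MIT single-hit and aggregate scores with the Hsu et al.
(2013) per-position mismatch weight vector. The scan is vectorised with
numpy but is exactly equivalent to a literal both-strand sliding-window
comparison, and is strictly at least as sensitive as a 3-mismatch short-read
aligner search.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .annotation_io import DesignRegion, GenomeSequence, revcomp
from .guide_design import GuideCandidate

# Hsu et al. 2013 experimentally derived per-position mismatch weights,
# position 1 = PAM-distal ... position 20 = PAM-proximal.
HSU_WEIGHTS = (
    0.0, 0.0, 0.014, 0.0, 0.0,
    0.395, 0.317, 0.0, 0.389, 0.079,
    0.445, 0.508, 0.613, 0.851, 0.732,
    0.828, 0.615, 0.804, 0.685, 0.583,
)

_BASES = "ACGT"
_CODE = {b: i for i, b in enumerate("ACGTN")}


@dataclass
class Context30:
    """30-nt on-target context on the protospacer strand."""

    sequence: str

    def __post_init__(self):
        if len(self.sequence) != 30:
            raise ValueError(f"context must be 30 nt, got {len(self.sequence)}")
        if any(b not in _BASES for b in self.sequence):
            raise ValueError("context contains a non-ACGT character")
        if self.sequence[25:27] != "GG":
            raise ValueError("context positions 25-26 must be the PAM GG")

    @property
    def protospacer(self) -> str:
        return self.sequence[4:24]


@dataclass
class OffTargetHit:
    """A genomic 20-mer within the mismatch budget of a protospacer."""

    chrom: str
    strand: str
    start: int  # plus-strand genomic start of the 20-mer window
    pam_class: str  # 'NGG' or 'NAG'
    mismatch_positions: tuple[int, ...]  # 1 = PAM-distal ... 20 = PAM-proximal
    is_self: bool = False

    @property
    def m(self) -> int:
        return len(self.mismatch_positions)


@dataclass
class MitConstants:
    """Parameters of the MIT specificity score."""

    weights: tuple[float, ...] = HSU_WEIGHTS
    distance_denominator: float = 19.0
    distance_scale: float = 4.0

    def __post_init__(self):
        if len(self.weights) != 20 or any(not 0 <= w <= 1 for w in self.weights):
            raise ValueError("weights must be 20 values in [0,1]")


DEFAULT_MIT = MitConstants()


def extract_context30(candidate: GuideCandidate, region: DesignRegion) -> Context30 | None:
    """The 30-nt scoring context for a candidate, or None near region edges."""
    s, e = candidate.site_span
    if candidate.strand == "+":
        lo, hi = s - 4, e + 3
        if lo < 0 or hi > len(region):
            return None
        return Context30(region.sequence[lo:hi])
    lo, hi = s - 3, e + 4
    if lo < 0 or hi > len(region):
        return None
    return Context30(revcomp(region.sequence[lo:hi]))


def ruleset2_features(ctx: Context30) -> dict[str, float]:
    """Named Rule Set 2 feature vector of a 30-nt context.

    Blocks, in stable order: position-specific single-nucleotide indicators
    (30x4), position-specific adjacent dinucleotide indicators (29x16),
    position-independent mono- and dinucleotide counts, protospacer GC count
    with low/high indicators, and the NGGN PAM-variant indicator (16 combos
    of the bases flanking the PAM GG).
    """
    seq = ctx.sequence
    feats: dict[str, float] = {}
    for i in range(30):
        for b in _BASES:
            feats[f"{b}_{i}"] = 1.0 if seq[i] == b else 0.0
    for i in range(29):
        di = seq[i : i + 2]
        for b1 in _BASES:
            for b2 in _BASES:
                feats[f"{b1}{b2}_{i}"] = 1.0 if di == b1 + b2 else 0.0
    for b in _BASES:
        feats[f"count_{b}"] = float(seq.count(b))
    for b1 in _BASES:
        for b2 in _BASES:
            di = b1 + b2
            feats[f"count_{di}"] = float(
                sum(1 for i in range(29) if seq[i : i + 2] == di)
            )
    gc = sum(1 for b in ctx.protospacer if b in "GC")
    feats["gc_count"] = float(gc)
    feats["gc_low"] = 1.0 if gc < 10 else 0.0
    feats["gc_high"] = 1.0 if gc > 10 else 0.0
    nggn = seq[24] + seq[27]
    for b1 in _BASES:
        for b2 in _BASES:
            feats[f"NGGN_{b1}GG{b2}"] = 1.0 if nggn == b1 + b2 else 0.0
    return feats


@dataclass
class LinearOnTargetModel:
    """A linear on-target model over Rule Set 2 features (external weights)."""

    weights: dict[str, float]
    intercept: float = 0.0

    def predict(self, feats: dict[str, float]) -> float:
        missing = [k for k in self.weights if k not in feats]
        if missing:
            raise ValueError(f"model features missing from featurization: {missing[:5]}")
        return self.intercept + sum(w * feats[k] for k, w in self.weights.items())


def fallback_ontarget(protospacer: str) -> float:
    """Deterministic self-contained efficiency heuristic in [0, 1].

    0.5 * gc_term + 0.5 * run_term, where gc_term = max(0, 1 - |GC20-10|/10)
    rewards balanced GC and run_term is 1 unless the protospacer contains a
    homonucleotide run of 5 or more.
    """
    gc20 = sum(1 for b in protospacer if b in "GC")
    gc_term = max(0.0, 1.0 - abs(gc20 - 10) / 10.0)
    run_term = 1.0
    run = 1
    for a, b in zip(protospacer, protospacer[1:]):
        run = run + 1 if a == b else 1
        if run >= 5:
            run_term = 0.0
            break
    return 0.5 * gc_term + 0.5 * run_term


def ontarget_score(
    candidate: GuideCandidate,
    region: DesignRegion,
    model: LinearOnTargetModel | None = None,
) -> float | None:
    """Predicted cleavage efficiency in [0,1]; None if no 30-nt context exists."""
    ctx = extract_context30(candidate, region)
    if ctx is None:
        return None
    if model is not None:
        raw = model.predict(ruleset2_features(ctx))
        return float(min(1.0, max(0.0, raw)))
    return fallback_ontarget(candidate.protospacer)


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


_LUT = np.full(256, 4, dtype=np.uint8)
for _b, _i in _CODE.items():
    _LUT[ord(_b)] = _i


def find_offtargets(
    candidate,
    genome: GenomeSequence,
    max_mm: int = 3,
    pams: tuple[str, ...] = ("NGG", "NAG"),
    self_locus: tuple[str, str, int] | None = None,
) -> list[OffTargetHit]:
    """Exhaustive genome scan for near-matches of the protospacer.

    Every 20-mer on either strand whose Hamming distance to the protospacer
    is <= ``max_mm`` and whose adjacent 3-nt PAM matches one of ``pams``
    (N-ambiguous first base) is reported. N in the genome never matches. The
    design locus itself, passed as ``self_locus = (chrom, strand,
    plus-strand protospacer start)``, is flagged ``is_self``.
    """
    protospacer = (
        candidate.protospacer if isinstance(candidate, GuideCandidate) else candidate
    )
    if len(protospacer) != 20:
        raise ValueError("protospacer must be 20 nt")
    proto = _LUT[_encode(protospacer)]
    comp = np.array([3, 2, 1, 0, 4], dtype=np.uint8)
    proto_rc = comp[proto][::-1]  # plus-strand image of the minus-strand protospacer

    want_second = {p[1] for p in pams}  # {'G'}, {'A'}, or both
    hits: list[OffTargetHit] = []
    for chrom, seq in genome.chromosomes.items():
        codes = _LUT[_encode(seq)]
        L = len(codes)
        if L < 23:
            continue
        n_pos = L - 22  # candidate 23-mer start positions
        # --- plus strand: window p..p+19 protospacer, p+20..p+22 PAM ---
        mm = np.zeros(n_pos, dtype=np.int16)
        for k in range(20):
            mm += codes[k : k + n_pos] != proto[k]
        pam_ok = np.zeros(n_pos, dtype=bool)
        b2 = codes[21 : 21 + n_pos]
        b3 = codes[22 : 22 + n_pos]
        if "G" in want_second:
            pam_ok |= (b2 == _CODE["G"]) & (b3 == _CODE["G"])
        if "A" in want_second:
            pam_ok |= (b2 == _CODE["A"]) & (b3 == _CODE["G"])
        for p in np.nonzero((mm <= max_mm) & pam_ok)[0]:
            p = int(p)
            mpos = tuple(
                k + 1 for k in range(20) if codes[p + k] != proto[k]
            )
            pam_class = "NGG" if codes[p + 21] == _CODE["G"] else "NAG"
            hits.append(OffTargetHit(chrom, "+", p, pam_class, mpos))
        # --- minus strand: plus-span [p, p+23), PAM at [p, p+3) (revcomp NGG = CCN) ---
        mm = np.zeros(n_pos, dtype=np.int16)
        for k in range(20):
            mm += codes[3 + k : 3 + k + n_pos] != proto_rc[k]
        pam_ok = np.zeros(n_pos, dtype=bool)
        b1 = codes[0:n_pos]
        b2 = codes[1 : 1 + n_pos]
        if "G" in want_second:
            pam_ok |= (b1 == _CODE["C"]) & (b2 == _CODE["C"])
        if "A" in want_second:
            pam_ok |= (b1 == _CODE["C"]) & (b2 == _CODE["T"])
        for p in np.nonzero((mm <= max_mm) & pam_ok)[0]:
            p = int(p)
            # protospacer position k (PAM-distal=1) sits at plus coord p+22-k0
            mpos = tuple(
                k + 1
                for k in range(20)
                if codes[p + 22 - k] != comp[proto[k]]
            )
            pam_class = "NGG" if codes[p + 1] == _CODE["C"] else "NAG"
            hits.append(OffTargetHit(chrom, "-", p + 3, pam_class, mpos))
    if self_locus is not None:
        for h in hits:
            if h.m == 0 and (h.chrom, h.strand, h.start) == tuple(self_locus):
                h.is_self = True
    return hits


def mit_single_hit(hit: OffTargetHit, constants: MitConstants = DEFAULT_MIT) -> float:
    """MIT single-hit likelihood of cleavage at an off-target locus, in [0,100].

    100 * prod(1 - W[p]) * 1/(((19 - dbar)/19)*4 + 1) * 1/m^2 with dbar the
    mean gap between consecutive mismatch positions (dbar = 19 when m = 1);
    a perfect match scores 100 by convention.
    """
    m = hit.m
    if m == 0:
        return 100.0
    if any(not 1 <= p <= 20 for p in hit.mismatch_positions):
        raise ValueError(f"mismatch positions out of 1..20: {hit.mismatch_positions}")
    score = 1.0
    for p in hit.mismatch_positions:
        score *= 1.0 - constants.weights[p - 1]
    if m == 1:
        dbar = constants.distance_denominator
    else:
        pos = sorted(hit.mismatch_positions)
        dbar = (pos[-1] - pos[0]) / (m - 1)
    d_term = 1.0 / (
        ((constants.distance_denominator - dbar) / constants.distance_denominator)
        * constants.distance_scale
        + 1.0
    )
    return 100.0 * score * d_term * (1.0 / (m * m))


def mit_aggregate(
    hits: list[OffTargetHit], constants: MitConstants = DEFAULT_MIT
) -> float:
    """Aggregate guide specificity in [0,100]: 100*100/(100 + sum of single-hit
    scores) over non-self hits; 100 when there are none."""
    total = sum(mit_single_hit(h, constants) for h in hits if not h.is_self)
    return 100.0 * 100.0 / (100.0 + total)


def score_candidate(
    candidate: GuideCandidate,
    region: DesignRegion,
    genome: GenomeSequence,
    max_mm: int = 3,
    pams: tuple[str, ...] = ("NGG", "NAG"),
    model: LinearOnTargetModel | None = None,
    constants: MitConstants = DEFAULT_MIT,
) -> bool:
    """Fill ontarget, specificity and offtarget_counts in place.

    Returns False (candidate unscorable) when the 30-nt context is not
    extractable from the region.
    """
    score = ontarget_score(candidate, region, model)
    if score is None:
        return False
    candidate.ontarget = score
    # the protospacer occupies region plus-coords [region_offset, region_offset+20)
    g_strand = "+" if candidate.strand == region.strand else "-"
    gpos = region.genomic_positions
    self_locus = None
    if 0 <= candidate.region_offset and candidate.region_offset + 20 <= len(gpos):
        g = gpos[candidate.region_offset : candidate.region_offset + 20]
        self_locus = (region.chrom, g_strand, min(g))
    hits = find_offtargets(candidate, genome, max_mm, pams, self_locus)
    nonself = [h for h in hits if not h.is_self]
    counts = [0, 0, 0, 0]
    for h in nonself:
        if h.m <= 3:
            counts[h.m] += 1
    candidate.offtarget_counts = tuple(counts)
    candidate.specificity = mit_aggregate(hits, constants)
    return True
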