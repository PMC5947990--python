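"""SpCas9 candidate enumeration, cut-site geometry, and guide ranking.

Candidate sites match N20-NGG on either strand of the design region. The cut
site is the blunt double-strand break 3 nt 5' of the PAM (between protospacer
positions 17|18). ``cut_offset`` is the region coordinate (plus-strand
convention) of the first base 3' of the cut bond, so ``cut_to_stop =
cut_offset - (stop_offset + 3)`` is 0 when the cut bond abuts the last stop
base, positive downstream in the 3'UTR and negative inside/upstream of the
stop.

Ranking policy: guides cutting in the 3'UTR with an aggregate specificity at
or above the floor survive; those whose cut falls in the preferred 8-15 nt
window form the first tier; within a tier higher predicted efficiency wins,
with ties broken by shorter cut-to-stop distance and then protospacer
lexicographic order. Batch mode additionally caps cut-to-stop at 30 nt. The
top two survivors are returned by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .annotation_io import DesignRegion, revcomp

logger = logging.getLogger(__name__)

#: canonical 16-nt crRNA repeat prefix pairing with the tracrRNA (configurable)
DEFAULT_CRRNA_REPEAT = "GUUUUAGAGCUAUGCU"

#: constant 67-nt tracrRNA scaffold (metadata; only its length is contractual)
TRACRRNA_67 = "AGCAUAGCAAGUUAAAAUAAGGCUAGUCCGUUAUCAACUUGAAAAAGUGGCACCGAGUCGGUGCUUU"


@dataclass
class GuideCandidate:
    """A 20-nt protospacer + NGG PAM with its geometry and (later) scores."""

    protospacer: str  # on the strand of the guide
    pam: str
    strand: str  # '+' or '-' relative to the region orientation
    region_offset: int  # plus-strand region coordinate of the protospacer start
    cut_offset: int  # first region base 3' of the blunt cut, plus-strand coords
    cut_to_stop: int | None = None
    in_utr3: bool = False
    ontarget: float | None = None
    specificity: float | None = None
    offtarget_counts: tuple[int, int, int, int] | None = None

    @property
    def site_span(self) -> tuple[int, int]:
        """Plus-strand region interval covered by protospacer + PAM (23 nt)."""
        if self.strand == "+":
            return (self.region_offset, self.region_offset + 23)
        return (self.region_offset - 3, self.region_offset + 20)

    @property
    def pam_span(self) -> tuple[int, int]:
        if self.strand == "+":
            return (self.region_offset + 20, self.region_offset + 23)
        return (self.region_offset - 3, self.region_offset)


@dataclass
class DesignConfig:
    """Tunable design policy; defaults follow the published pipeline."""

    preferred_window: tuple[int, int] = (8, 15)
    batch_max_distance: int = 30
    top_k: int = 2
    window_nt: int = 200
    ssodn_cap: int = 200
    min_arm: int = 30
    offtarget_max_mm: int = 3
    offtarget_pams: tuple[str, ...] = ("NGG", "NAG")
    pam_block_policy: str = "NGC"  # or "NGT"
    specificity_floor: float = 50.0
    emit_strand: str = "pam"  # or "nonpam"
    always_block: bool = False
    crrna_repeat: str = DEFAULT_CRRNA_REPEAT

    def __post_init__(self):
        lo, hi = self.preferred_window
        if not (0 <= lo <= hi <= self.batch_max_distance):
            raise ValueError(
                f"preferred_window {self.preferred_window} must lie within "
                f"[0, batch_max_distance={self.batch_max_distance}]"
            )
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if self.pam_block_policy not in ("NGC", "NGT"):
            raise ValueError("pam_block_policy must be 'NGC' or 'NGT'")


def enumerate_guides(region: DesignRegion) -> list[GuideCandidate]:
    """All N20-NGG sites on both strands of the region.

    Windows containing N are excluded. The returned list is ordered by
    plus-strand protospacer offset, '+' strand before '-' at a tie.
    """
    seq = region.sequence
    if len(seq) < 23:
        raise ValueError(f"region too short ({len(seq)} nt) to contain a 23-nt site")
    out: list[GuideCandidate] = []
    for i in range(len(seq) - 22):
        window = seq[i : i + 23]
        if "N" in window:
            continue
        # plus strand: protospacer [i, i+20), PAM [i+20, i+23) = NGG
        if window[21] == "G" and window[22] == "G":
            out.append(
                GuideCandidate(
                    protospacer=window[:20],
                    pam=window[20:],
                    strand="+",
                    region_offset=i,
                    cut_offset=i + 17,
                )
            )
        # minus strand: plus-strand CCN at [i, i+3) is the PAM, protospacer [i+3, i+23)
        if window[0] == "C" and window[1] == "C":
            out.append(
                GuideCandidate(
                    protospacer=revcomp(window[3:]),
                    pam=revcomp(window[:3]),
                    strand="-",
                    region_offset=i + 3,
                    cut_offset=i + 6,
                )
            )
    for cand in out:
        cand.cut_to_stop = cut_to_stop_distance(cand, region)
        cand.in_utr3 = (
            cand.cut_to_stop >= 0
            and cand.cut_offset < len(region)
            and region.annotation[cand.cut_offset] == "UTR3"
        )
    out.sort(key=lambda c: (c.region_offset, 0 if c.strand == "+" else 1))
    return out


def cut_to_stop_distance(candidate: GuideCandidate, region: DesignRegion) -> int:
    """Signed nt between the last stop-codon base and the cut bond (0 = abutting)."""
    return candidate.cut_offset - (region.stop_offset + 3)


def rank_guides(
    candidates: list[GuideCandidate],
    config: DesignConfig | None = None,
    batch_mode: bool = False,
) -> list[GuideCandidate]:
    """Filter and order scored candidates; return the top ``config.top_k``.

    Hard filters: cut in the 3'UTR, specificity >= floor, and (batch mode)
    cut_to_stop <= batch_max_distance. Ordering: preferred-window tier first,
    then descending on-target score, ascending cut distance, protospacer.
    """
    config = config or DesignConfig()
    lo, hi = config.preferred_window
    survivors = []
    for c in candidates:
        if c.ontarget is None or c.specificity is None:
            raise ValueError("rank_guides requires scored candidates")
        if not c.in_utr3:
            logger.debug("dropped %s: cut not in 3'UTR", c.protospacer)
            continue
        if c.specificity < config.specificity_floor:
            logger.debug("dropped %s: specificity %.1f below floor", c.protospacer, c.specificity)
            continue
        if batch_mode and c.cut_to_stop > config.batch_max_distance:
            logger.debug("dropped %s: cut distance %d beyond batch cap", c.protospacer, c.cut_to_stop)
            continue
        survivors.append(c)
    survivors.sort(
        key=lambda c: (
            0 if lo <= c.cut_to_stop <= hi else 1,
            -c.ontarget,
            c.cut_to_stop,
            c.protospacer,
        )
    )
    if not survivors:
        logger.warning("no guide survives the filters (batch_mode=%s)", batch_mode)
    return survivors[: config.top_k]


def build_crrna_oligo(candidate, repeat_16nt: str = DEFAULT_CRRNA_REPEAT) -> str:
    """36-nt crRNA ordering oligo: RNA protospacer + 16-nt repeat."""
    protospacer = (
        candidate.protospacer if isinstance(candidate, GuideCandidate) else candidate
    )
    if len(protospacer) != 20:
        raise ValueError(f"protospacer must be 20 nt, got {len(protospacer)}")
    if len(repeat_16nt) != 16:
        raise ValueError(f"crRNA repeat must be 16 nt, got {len(repeat_16nt)}")
    return protospacer.replace("T", "U") + repeat_16nt
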