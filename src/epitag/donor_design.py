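"""ssODN HDR donor construction.

The donor inserts the epitope tag coding sequence immediately 5' of the stop
codon, flanked by symmetric homology arms, under a total cap of 200 nt. The
stop codon is budgeted inside the 3' arm, so for a tag of t nt the arms are
floor((200 - t)/2) each: 3XFLAG 66 -> 67/67, V5 42 -> 79/79, Myc 30 -> 85/85,
HA 27 -> 86/86 (199 total). The donor carries a PAM-blocking mutation so Cas9
cannot re-cut the edited allele: NGG -> NGC (or NGT) when the PAM lies in the
3'UTR; a synonymous codon substitution when the PAM base is coding; failing
that, the most conservative substitution by Kyte-Doolittle hydropathy and
charge class. When the tag insertion itself splits the protospacer/PAM
register no edit is needed. The oligo is emitted on the PAM strand (the
guide's strand) by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from .annotation_io import DesignRegion, STOP_CODONS, revcomp
from .guide_design import GuideCandidate

logger = logging.getLogger(__name__)

_FORWARD = dict(standard_dna_table.forward_table)  # sense codon -> amino acid

# Kyte-Doolittle hydropathy index
KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}


def charge_class(aa: str) -> str:
    if aa in "DE":
        return "negative"
    if aa in "KRH":
        return "positive"
    return "neutral"


@dataclass(frozen=True)
class EpitopeTag:
    """A named in-frame peptide tag with its coding sequence."""

    name: str
    aa: str
    nt: str

    def __post_init__(self):
        if len(self.nt) != 3 * len(self.aa):
            raise ValueError(
                f"{self.name}: nt length {len(self.nt)} != 3 x aa length {len(self.aa)}"
            )
        translated = str(Seq(self.nt).translate())
        if "*" in translated:
            raise ValueError(f"{self.name}: tag coding sequence contains an internal stop")
        if translated != self.aa:
            raise ValueError(
                f"{self.name}: nt translates to {translated}, expected {self.aa}"
            )

    @property
    def length_nt(self) -> int:
        return len(self.nt)


#: standard published peptide tags for C-terminal knock-in
TAG_CATALOGUE = {
    "V5": EpitopeTag(
        "V5",
        "GKPIPNPLLGLDST",
        "GGTAAGCCTATCCCTAACCCTCTCCTCGGTCTCGATTCTACG",
    ),
    "3XFLAG": EpitopeTag(
        "3XFLAG",
        "DYKDHDGDYKDHDIDYKDDDDK",
        "GACTACAAAGACCATGACGGTGATTATAAAGATCATGACATCGATTACAAGGATGACGATGACAAG",
    ),
    "HA": EpitopeTag("HA", "YPYDVPDYA", "TACCCATACGATGTTCCAGATTACGCT"),
    "Myc": EpitopeTag("Myc", "EQKLISEEDL", "GAACAAAAACTCATCTCAGAAGAGGATCTG"),
}


def get_tag(name: str, aa: str | None = None, nt: str | None = None) -> EpitopeTag:
    """Look up a catalogue tag, or validate a user-supplied one.

    A user tag requires ``nt`` (and optionally ``aa``; when omitted it is
    derived by translation).
    """
    if nt is None and aa is None:
        key = name.upper() if name.upper() in TAG_CATALOGUE else name
        if key == "MYC":
            key = "Myc"
        if key not in TAG_CATALOGUE:
            raise KeyError(
                f"unknown tag {name!r}; catalogue: {sorted(TAG_CATALOGUE)} "
                "(or supply nt= for a custom tag)"
            )
        return TAG_CATALOGUE[key]
    if nt is None:
        raise ValueError("a custom tag requires its nucleotide sequence (nt=)")
    nt = nt.upper()
    if len(nt) % 3 != 0:
        raise ValueError(f"custom tag nt length {len(nt)} not divisible by 3")
    if aa is None:
        aa = str(Seq(nt).translate())
        if "*" in aa:
            raise ValueError("custom tag coding sequence contains an internal stop")
    return EpitopeTag(name, aa, nt)


def compute_arm_lengths(
    tag_len_nt: int, cap: int = 200, min_arm: int = 30
) -> tuple[int, int]:
    """Symmetric homology-arm lengths under the oligo cap.

    The stop codon counts inside the 3' arm, so total = tag + 2*arm <= cap
    (one nt unused when cap - tag is odd).
    """
    if cap <= tag_len_nt:
        raise ValueError(f"cap {cap} must exceed tag length {tag_len_nt}")
    arm = (cap - tag_len_nt) // 2
    if arm < min_arm:
        raise ValueError(
            f"insufficient homology: arms of {arm} nt < minimum {min_arm} "
            f"for a {tag_len_nt}-nt tag under a {cap}-mer cap"
        )
    return arm, arm


def silent_substitutions(codon: str, mutable_position: int) -> set[str]:
    """Synonymous codons differing from ``codon`` only at ``mutable_position``."""
    codon = codon.upper()
    if codon in STOP_CODONS:
        raise ValueError("the stop codon is never edited")
    if codon not in _FORWARD:
        raise ValueError(f"{codon!r} is not a sense codon")
    if mutable_position not in (0, 1, 2):
        raise ValueError("mutable_position must be 0, 1 or 2")
    aa = _FORWARD[codon]
    out = set()
    for b in "ACGT":
        alt = codon[:mutable_position] + b + codon[mutable_position + 1 :]
        if alt != codon and _FORWARD.get(alt) == aa:
            out.add(alt)
    return out


@dataclass
class MutationPlan:
    """Planned donor edits that block Cas9 re-cutting.

    Edits are single-base substitutions in region plus-strand coordinates.
    Rationales: PAM_NGG_to_NGC / PAM_NGG_to_NGT (3'UTR PAM edit), silent_CDS
    (synonymous codon change), conservative_CDS (hydropathy/charge-minimising
    change), none_needed (tag insertion already splits the site).
    """

    edits: list[tuple[int, str, str, str]] = field(default_factory=list)
    residual_protospacer_match: bool | None = None

    @property
    def rationales(self) -> list[str]:
        return [e[3] for e in self.edits] or ["none_needed"]


@dataclass
class SsodnDesign:
    """An assembled <=200-nt single-stranded HDR donor."""

    arm5: str
    tag_insert: str
    stop: str
    arm3: str  # bases after the stop codon, with blocking edits applied
    strand_emitted: str  # 'PAM' or 'non-PAM'
    plan: MutationPlan
    oligo: str = ""  # the sequence actually ordered (strand applied)
    warnings: list[str] = field(default_factory=list)

    @property
    def full(self) -> str:
        """Donor in region (coding-strand) orientation."""
        return self.arm5 + self.tag_insert + self.stop + self.arm3

    @property
    def arm_lengths(self) -> tuple[int, int]:
        """(5' arm, 3' arm) with the stop codon budgeted inside the 3' arm."""
        return (len(self.arm5), 3 + len(self.arm3))

    def __len__(self) -> int:
        return len(self.full)


def _codon_start_for(pos: int, stop_offset: int) -> int:
    """Region offset of the CDS codon containing ``pos`` (frame anchored so
    that [stop_offset-3, stop_offset) is the last sense codon)."""
    return pos - ((pos - stop_offset) % 3)


def plan_pam_block(
    candidate: GuideCandidate,
    region: DesignRegion,
    tag_len_nt: int,
    policy: str = "NGC",
    always_block: bool = False,
) -> MutationPlan:
    """Choose donor edits that prevent Cas9 from re-cutting the tagged allele.

    Cases, in order: (a) the tag insertion point falls strictly inside the
    protospacer+PAM span, which splits the site -- no edit needed (unless
    ``always_block``); (b) the PAM's two G bases lie in the 3'UTR -- the
    PAM-proximal G is changed per policy (NGG->NGC default, NGT optional);
    (c) a PAM G is coding -- the alphabetically first synonymous codon change
    that breaks the site without recreating an NGG/NAG PAM; (d) no synonymous
    option -- the substitution minimising |delta Kyte-Doolittle hydropathy|,
    then charge-class change, of the altered residue.
    """
    if policy not in ("NGC", "NGT"):
        raise ValueError("policy must be 'NGC' or 'NGT'")
    plan = MutationPlan()
    insertion = region.stop_offset
    s, e = candidate.site_span
    if not always_block and s < insertion < e:
        plan.edits = []
        return plan

    seq = region.sequence
    labels = region.annotation
    # plus-strand coordinates of the PAM's two G bases, PAM-proximal G first
    if candidate.strand == "+":
        ps, _ = candidate.pam_span
        g_positions = [ps + 2, ps + 1]  # pam[2] (edited by NGC/NGT), pam[1]
    else:
        ps, _ = candidate.pam_span
        g_positions = [ps, ps + 1]  # plus-strand C bases complementing pam[2], pam[1]

    stop_span = range(region.stop_offset, region.stop_offset + 3)
    editable = [p for p in g_positions if p not in stop_span and 0 <= p < len(seq)]
    if not editable:
        raise ValueError("cannot block re-cutting: PAM G bases are not editable")

    def apply_edit(pos: int, alt: str) -> str:
        return seq[:pos] + alt + seq[pos + 1 :]

    def breaks_site(edited: str) -> bool:
        w = edited[s:e]
        if candidate.strand == "+":
            return not (w[:20] == candidate.protospacer and w[21:23] == "GG")
        return not (w[3:23] == revcomp(candidate.protospacer) and w[:2] == "CC")

    def recreates_pam(edited: str) -> bool:
        """Would the edited PAM still license cleavage (NGG or NAG) at the register?"""
        ps0, ps1 = candidate.pam_span
        pam = edited[ps0:ps1]
        if candidate.strand == "-":
            pam = revcomp(pam)
        return pam[1:] in ("GG", "AG")

    if all(labels[p] == "UTR3" for p in g_positions if 0 <= p < len(labels)):
        # (b) UTR PAM edit: change the PAM-proximal G (pam position 3)
        pos = g_positions[0]
        new_base = "C" if policy == "NGC" else "T"
        alt = new_base if candidate.strand == "+" else revcomp(new_base)
        edited = apply_edit(pos, alt)
        if breaks_site(edited) and not recreates_pam(edited):
            plan.edits = [(pos, seq[pos], alt, f"PAM_NGG_to_{policy}")]
            return plan
        raise ValueError("cannot block re-cutting: PAM edit does not break the site")

    # (c)/(d): a PAM G base is coding
    cds_positions = [p for p in editable if labels[p] == "CDS"]
    if not cds_positions:
        raise ValueError("cannot block re-cutting: PAM G bases neither UTR3 nor CDS")
    for pos in cds_positions:
        cstart = _codon_start_for(pos, region.stop_offset)
        if cstart < 0 or cstart + 3 > len(seq):
            continue
        codon = seq[cstart : cstart + 3]
        mut_pos = pos - cstart
        if codon in STOP_CODONS:
            continue
        try:
            alts = silent_substitutions(codon, mut_pos)
        except ValueError:
            continue
        for alt_codon in sorted(alts):
            alt = alt_codon[mut_pos]
            edited = apply_edit(pos, alt)
            if breaks_site(edited) and not recreates_pam(edited):
                plan.edits = [(pos, seq[pos], alt, "silent_CDS")]
                return plan
    # (d) conservative substitution: minimise |dKD| then charge-class change
    best = None
    for pos in cds_positions:
        cstart = _codon_start_for(pos, region.stop_offset)
        if cstart < 0 or cstart + 3 > len(seq):
            continue
        codon = seq[cstart : cstart + 3]
        mut_pos = pos - cstart
        if codon not in _FORWARD:
            continue
        aa0 = _FORWARD[codon]
        for b in "ACGT":
            if b == seq[pos]:
                continue
            alt_codon = codon[:mut_pos] + b + codon[mut_pos + 1 :]
            if alt_codon in STOP_CODONS or alt_codon not in _FORWARD:
                continue
            edited = apply_edit(pos, b)
            if not breaks_site(edited) or recreates_pam(edited):
                continue
            aa1 = _FORWARD[alt_codon]
            key = (
                abs(KYTE_DOOLITTLE[aa1] - KYTE_DOOLITTLE[aa0]),
                0 if charge_class(aa1) == charge_class(aa0) else 1,
                b,
            )
            if best is None or key < best[0]:
                best = (key, pos, b)
    if best is None:
        raise ValueError("cannot block re-cutting: no substitution breaks the site")
    _, pos, b = best
    plan.edits = [(pos, seq[pos], b, "conservative_CDS")]
    return plan


def assemble_ssodn(
    region: DesignRegion,
    tag: EpitopeTag,
    candidate: GuideCandidate,
    plan: MutationPlan,
    arms: tuple[int, int],
    emit_strand: str = "pam",
    min_arm: int = 30,
) -> SsodnDesign:
    """Assemble the donor: arm5 + tag + stop + arm3(with edits), on the PAM strand.

    Arms shorter than requested (region truncated) are symmetrically reduced
    with a warning, erroring below ``min_arm``. The residual-site flag of the
    plan is re-verified on the assembled sequence.
    """
    arm5_req, arm3_req = arms
    stop = region.stop_offset
    warnings_: list[str] = []
    avail5 = stop
    avail3 = len(region) - stop
    arm_len = min(arm5_req, arm3_req, avail5, avail3)
    if arm_len < min_arm:
        raise ValueError(
            f"region supplies only {arm_len}-nt arms (< min_arm {min_arm})"
        )
    if arm_len < min(arm5_req, arm3_req):
        warnings_.append(
            f"arms truncated symmetrically to {arm_len} nt (region too short)"
        )
        logger.warning("%s: %s", region.transcript_id, warnings_[-1])

    seq = region.sequence
    for pos, ref, _alt, _r in plan.edits:
        if seq[pos] != ref:
            raise ValueError(f"edit reference mismatch at region offset {pos}")
    edited = list(seq)
    for pos, _ref, alt, _r in plan.edits:
        edited[pos] = alt
    edited = "".join(edited)

    arm5 = edited[stop - arm_len : stop]  # CDS-side blocking edits land here
    stop_seq = seq[stop : stop + 3]  # the stop codon is never edited
    arm3_tail = edited[stop + 3 : stop + arm_len]
    donor_plus = arm5 + tag.nt + stop_seq + arm3_tail

    # verify no intact site survives at the original register of the tagged allele
    s, _e = candidate.site_span
    tagged_plus = edited[:stop] + tag.nt + edited[stop:]
    site_in_tagged = s if s < stop else s + tag.length_nt
    w = tagged_plus[site_in_tagged : site_in_tagged + 23]
    if candidate.strand == "+":
        residual = len(w) == 23 and w[:20] == candidate.protospacer and w[21:23] == "GG"
    else:
        residual = (
            len(w) == 23 and w[3:23] == revcomp(candidate.protospacer) and w[:2] == "CC"
        )
    plan.residual_protospacer_match = residual
    if residual:
        raise ValueError("assembled donor retains an intact protospacer+PAM site")

    emit_pam = emit_strand.lower() in ("pam", "pam-strand")
    if not emit_pam:
        strand_emitted = "non-PAM"
        oligo = donor_plus if candidate.strand == "-" else revcomp(donor_plus)
    else:
        strand_emitted = "PAM"
        oligo = donor_plus if candidate.strand == "+" else revcomp(donor_plus)

    design = SsodnDesign(
        arm5=arm5,
        tag_insert=tag.nt,
        stop=stop_seq,
        arm3=arm3_tail,
        strand_emitted=strand_emitted,
        plan=plan,
        warnings=warnings_,
    )
    design.oligo = oligo
    return design
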