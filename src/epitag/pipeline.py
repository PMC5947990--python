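"""Single-target and 96-well batch orchestration.

``design_for_target`` runs the full chain for one transcript: design-region
extraction, candidate enumeration, efficiency/specificity scoring, ranking,
and ssODN assembly for each selected guide. ``batch_design`` maps a target
list onto 96-well plates (row-major A1..H12, spilling to further plates) with
optional repeated control wells. Design failures are data, not exceptions:
a bundle with zero guides carries a machine-readable reason.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .annotation_io import (
    DesignRegion,
    GenomeSequence,
    TranscriptModel,
    extract_design_region,
)
from .donor_design import (
    EpitopeTag,
    SsodnDesign,
    assemble_ssodn,
    compute_arm_lengths,
    plan_pam_block,
)
from .guide_design import (
    TRACRRNA_67,
    DesignConfig,
    GuideCandidate,
    build_crrna_oligo,
    enumerate_guides,
    rank_guides,
)
from .scoring import LinearOnTargetModel, score_candidate

logger = logging.getLogger(__name__)

ROWS = "ABCDEFGH"
COLS = range(1, 13)
WELLS = [f"{r}{c}" for r in ROWS for c in COLS]  # row-major A1..H12


@dataclass
class GuideDesign:
    """One selected guide with its ordering oligo and matched donor."""

    rank: int
    candidate: GuideCandidate
    crrna_oligo: str
    ssodn: SsodnDesign


@dataclass
class DesignBundle:
    transcript_id: str
    tag_name: str
    guides: list[GuideDesign] = field(default_factory=list)
    tracrrna: str = TRACRRNA_67
    region: DesignRegion | None = None
    failure_reason: str | None = None
    warnings: list[str] = field(default_factory=list)


def design_for_target(
    transcript_id: str,
    tag: EpitopeTag,
    genome: GenomeSequence,
    catalog: dict[str, TranscriptModel],
    config: DesignConfig | None = None,
    batch_mode: bool = False,
    model: LinearOnTargetModel | None = None,
) -> DesignBundle:
    """Full design chain for one transcript; deterministic for fixed inputs."""
    config = config or DesignConfig()
    bundle = DesignBundle(transcript_id=transcript_id, tag_name=tag.name)
    try:
        region = extract_design_region(transcript_id, catalog, genome, config.window_nt)
    except (KeyError, ValueError) as err:
        raise type(err)(f"{transcript_id}: {err}") from err
    bundle.region = region
    bundle.warnings.extend(region.warnings)

    candidates = enumerate_guides(region)
    scored = []
    for cand in candidates:
        if score_candidate(
            cand,
            region,
            genome,
            max_mm=config.offtarget_max_mm,
            pams=config.offtarget_pams,
            model=model,
        ):
            scored.append(cand)
        else:
            bundle.warnings.append(
                f"candidate at offset {cand.region_offset} unscorable "
                "(30-nt context not available); dropped"
            )
    selected = rank_guides(scored, config, batch_mode=batch_mode)
    if not selected:
        cap = f" within {config.batch_max_distance} bp of the stop" if batch_mode else ""
        bundle.failure_reason = f"no guide{cap} passed the 3'UTR/specificity filters"
        return bundle

    arms = compute_arm_lengths(tag.length_nt, config.ssodn_cap, config.min_arm)
    for rank, cand in enumerate(selected, start=1):
        try:
            plan = plan_pam_block(
                cand,
                region,
                tag.length_nt,
                policy=config.pam_block_policy,
                always_block=config.always_block,
            )
            ssodn = assemble_ssodn(
                region, tag, cand, plan, arms, config.emit_strand, config.min_arm
            )
        except ValueError as err:
            bundle.warnings.append(f"guide rank {rank} dropped: {err}")
            continue
        bundle.guides.append(
            GuideDesign(
                rank=rank,
                candidate=cand,
                crrna_oligo=build_crrna_oligo(cand, config.crrna_repeat),
                ssodn=ssodn,
            )
        )
    if not bundle.guides:
        bundle.failure_reason = "no donor could be assembled for any selected guide"
    return bundle


def _bundle_rows(bundle: DesignBundle, well: str | None = None) -> list[dict]:
    rows = []
    if not bundle.guides:
        rows.append(
            {
                "transcript_id": bundle.transcript_id,
                "tag": bundle.tag_name,
                "well": well,
                "rank": None,
                "status": "failed",
                "reason": bundle.failure_reason,
            }
        )
        return rows
    for g in bundle.guides:
        c = g.candidate
        plan_str = ";".join(
            f"{pos}:{ref}>{alt}:{rat}" for pos, ref, alt, rat in g.ssodn.plan.edits
        ) or "none_needed"
        rows.append(
            {
                "transcript_id": bundle.transcript_id,
                "tag": bundle.tag_name,
                "well": well,
                "rank": g.rank,
                "status": "ok",
                "reason": None,
                "protospacer": c.protospacer,
                "pam": c.pam,
                "strand": c.strand,
                "cut_to_stop": c.cut_to_stop,
                "ontarget": round(c.ontarget, 4),
                "specificity": round(c.specificity, 2),
                "offtargets_0_1_2_3": ",".join(map(str, c.offtarget_counts)),
                "crrna_oligo": g.crrna_oligo,
                "ssodn": g.ssodn.oligo,
                "ssodn_len": len(g.ssodn.oligo),
                "arm5_len": g.ssodn.arm_lengths[0],
                "arm3_len": g.ssodn.arm_lengths[1],
                "ssodn_strand": g.ssodn.strand_emitted,
                "mutation_plan": plan_str,
            }
        )
    return rows


def batch_design(
    targets: list[str],
    tag: EpitopeTag,
    genome: GenomeSequence,
    catalog: dict[str, TranscriptModel],
    config: DesignConfig | None = None,
    controls: dict[str, str] | None = None,
    model: LinearOnTargetModel | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Design a plate run: one row per emitted guide, plus a plate map.

    ``controls`` maps well names (e.g. ``{"A1": "TX001", "H12": "TX001"}``)
    to a control transcript placed at those wells on every plate; remaining
    targets fill free wells row-major, spilling onto further plates.
    Duplicate target ids are an error; an empty target list yields an empty
    table with a warning.
    """
    config = config or DesignConfig()
    controls = controls or {}
    if len(set(targets)) != len(targets):
        dupes = sorted({t for t in targets if targets.count(t) > 1})
        raise ValueError(f"duplicate target ids: {dupes}")
    for well in controls:
        if well not in WELLS:
            raise ValueError(f"invalid control well {well!r}")
    if not targets and not controls:
        logger.warning("empty target list: nothing to design")
        return pd.DataFrame(), pd.DataFrame(), {"designed": 0, "failed": 0, "plates": 0}
    if targets and len(controls) >= len(WELLS):
        raise ValueError("control wells occupy the whole plate; no room for targets")

    # assign wells: controls first (every plate), then targets row-major
    assignments: list[tuple[str, str, str, bool]] = []  # (plate, well, target, is_control)
    remaining = list(targets)
    plate_no = 0
    while remaining or plate_no == 0:
        plate_no += 1
        plate = f"plate{plate_no}"
        for well in WELLS:
            if well in controls:
                assignments.append((plate, well, controls[well], True))
            elif remaining:
                assignments.append((plate, well, remaining.pop(0), False))
        if not remaining:
            break

    cache: dict[str, DesignBundle] = {}
    rows: list[dict] = []
    plate_rows: list[dict] = []
    designed = failed = 0
    for plate, well, target, is_control in assignments:
        if target not in cache:
            cache[target] = design_for_target(
                target, tag, genome, catalog, config, batch_mode=True, model=model
            )
        bundle = cache[target]
        if bundle.guides:
            designed += 0 if is_control else 1
        else:
            failed += 0 if is_control else 1
        for r in _bundle_rows(bundle, well=well):
            r["plate"] = plate
            r["is_control"] = is_control
            rows.append(r)
        plate_rows.append(
            {
                "plate": plate,
                "well": well,
                "transcript_id": target,
                "is_control": is_control,
                "status": "ok" if bundle.guides else "failed",
            }
        )
    table = pd.DataFrame(rows)
    plate_map = pd.DataFrame(plate_rows)
    summary = {
        "designed": designed,
        "failed": failed,
        "plates": plate_no,
        "n_guide_rows": int((table["status"] == "ok").sum()) if len(table) else 0,
    }
    return table, plate_map, summary


def predict_genotyping_amplicons(
    primer_offsets: tuple[int, int],
    tag_len_nt: int,
    insertion_offset: int,
) -> tuple[int, int]:
    """Predicted wild-type and knock-in PCR amplicon sizes.

    ``primer_offsets`` = (forward primer 5' start, reverse primer 3' end) in
    the same coordinates as ``insertion_offset`` (the tag insertion point).
    The knock-in amplicon is the wild-type size plus the tag length. Warns
    when the wild-type amplicon is outside the recommended 400-600 bp
    genotyping range.
    """
    left, right = primer_offsets
    if not (left < insertion_offset < right):
        raise ValueError(
            f"primers [{left},{right}) do not flank the insertion point {insertion_offset}"
        )
    wt = right - left
    ki = wt + tag_len_nt
    if not 400 <= wt <= 600:
        logger.warning(
            "wild-type amplicon %d bp is outside the recommended 400-600 bp range", wt
        )
    return wt, ki


# ---------------------------------------------------------------------------
# output writers


def write_design_table(bundles: list[DesignBundle], path) -> Path:
    rows = [r for b in bundles for r in _bundle_rows(b)]
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path


def write_oligo_fasta(bundles: list[DesignBundle], path) -> Path:
    """FASTA of ssODN donors and crRNA ordering oligos, one pair per guide."""
    lines = []
    for b in bundles:
        for g in b.guides:
            head = f"{b.transcript_id}|{b.tag_name}|{g.rank}"
            lines.append(f">{head}|ssODN\n{g.ssodn.oligo}")
            lines.append(f">{head}|crRNA\n{g.crrna_oligo}")
    path = Path(path)
    path.write_text("\n".join(lines) + ("\n" if lines else ""))
    return path


def write_guide_bed(bundles: list[DesignBundle], path) -> Path:
    """BED6 of protospacer+PAM genomic intervals; score = round(ontarget*1000)."""
    lines = []
    for b in bundles:
        region = b.region
        for g in b.guides:
            c = g.candidate
            s, e = c.site_span
            gpos = region.genomic_positions[s:e]
            g_strand = "+" if c.strand == region.strand else "-"
            lines.append(
                "\t".join(
                    [
                        region.chrom,
                        str(min(gpos)),
                        str(max(gpos) + 1),
                        f"{b.transcript_id}|{b.tag_name}|{g.rank}",
                        str(round(c.ontarget * 1000)),
                        g_strand,
                    ]
                )
            )
    path = Path(path)
    path.write_text("\n".join(lines) + ("\n" if lines else ""))
    return path


def write_run_metadata(path, config: DesignConfig, extra: dict | None = None) -> Path:
    meta = {
        "tool": "epitag",
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(config).items()
        },
        "conventions": {
            "cut_site": "blunt cut 3 nt 5' of the PAM (protospacer 17|18)",
            "cut_to_stop": "cut bond minus last stop-codon base; 0 = abutting",
            "hydropathy_scale": "Kyte-Doolittle",
            "charge_classes": "D/E negative; K/R/H positive; others neutral",
        },
    }
    if extra:
        meta.update(extra)
    path = Path(path)
    path.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    return path
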