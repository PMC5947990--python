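"""On-target featurization/score, off-target scan, MIT specificity."""

import numpy as np
import pytest

from epitag.annotation_io import GenomeSequence, revcomp
from epitag.guide_design import enumerate_guides
from epitag.scoring import (
    Context30,
    HSU_WEIGHTS,
    LinearOnTargetModel,
    OffTargetHit,
    extract_context30,
    fallback_ontarget,
    find_offtargets,
    mit_aggregate,
    mit_single_hit,
    ontarget_score,
    ruleset2_features,
)

from test_guide_design import bare_region


def ctx30(protospacer, up="AAAA", pam="TGG", down="AAA"):
    return Context30(up + protospacer + pam + down)


class TestContext30:
    def test_length_and_pam_validated(self):
        with pytest.raises(ValueError, match="30 nt"):
            Context30("ACGT")
        with pytest.raises(ValueError, match="GG"):
            Context30("A" * 30)
        c = ctx30("ACGT" * 5)
        assert c.protospacer == "ACGT" * 5

    def test_extraction_needs_full_flanks(self):
        # site flush with the region start has no upstream context
        region = bare_region("ACGACGTACGTACGTACGTA" + "CGG" + "T" * 7)
        (c,) = enumerate_guides(region)
        assert extract_context30(c, region) is None
        region = bare_region("TTTT" + "ACGACGTACGTACGTACGTA" + "CGG" + "TTT")
        (c,) = enumerate_guides(region)
        got = extract_context30(c, region)
        assert got.sequence == region.sequence

    def test_minus_strand_context_is_revcomp(self):
        plus = "TTTT" + "ACGACGTACGTACGTACGTA" + "CGG" + "TTT"
        region = bare_region(revcomp(plus))
        (c,) = enumerate_guides(region)
        assert c.strand == "-"
        assert extract_context30(c, region).sequence == plus


class TestRuleset2Features:
    def test_order1_block_is_one_hot(self):
        feats = ruleset2_features(ctx30("ACGT" * 5))
        order1 = {k: v for k, v in feats.items() if len(k.split("_")[0]) == 1}
        assert len(order1) == 120
        assert sum(order1.values()) == 30

    def test_order2_block_is_one_hot(self):
        feats = ruleset2_features(ctx30("ACGT" * 5))
        order2 = {
            k: v
            for k, v in feats.items()
            if len(k.split("_")[0]) == 2 and not k.startswith(("count", "NGGN", "gc"))
        }
        assert len(order2) == 29 * 16
        assert sum(order2.values()) == 29

    def test_gc_count_extremes(self):
        assert ruleset2_features(ctx30("A" * 20))["gc_count"] == 0
        assert ruleset2_features(ctx30("G" * 20))["gc_count"] == 20
        assert ruleset2_features(ctx30("A" * 20))["gc_low"] == 1
        assert ruleset2_features(ctx30("G" * 20))["gc_high"] == 1

    def test_nggn_indicator(self):
        feats = ruleset2_features(Context30("AAAA" + "A" * 20 + "TGG" + "CAA"))
        assert feats["NGGN_TGGC"] == 1
        assert sum(v for k, v in feats.items() if k.startswith("NGGN_")) == 1

    def test_feature_names_stable(self):
        a = list(ruleset2_features(ctx30("ACGT" * 5)))
        b = list(ruleset2_features(ctx30("TTTT" * 5)))
        assert a == b

    def test_non_acgt_rejected(self):
        with pytest.raises(ValueError):
            Context30("AAAN" + "A" * 20 + "TGG" + "AAA")


class TestOnTargetScore:
    def test_fallback_balanced_gc_no_runs_scores_one(self):
        assert fallback_ontarget("ACGT" * 5) == 1.0  # GC20 = 10

    def test_fallback_poly_a_scores_zero(self):
        assert fallback_ontarget("A" * 20) == 0.0

    def test_fallback_gc15_no_runs(self):
        # GC20 = 15, no homonucleotide run >= 5: 0.5*(1 - 5/10) + 0.5
        assert fallback_ontarget("GCGCG" + "CGCGC" + "GCGCG" + "ATATA") == pytest.approx(0.75)

    def test_run_penalty(self):
        # balanced GC (10) but a 5-run of G zeroes the run term
        s = "GGGGG" + "CCCCC" + "ATATA" + "TATAT"
        assert fallback_ontarget(s) == pytest.approx(0.5)

    def test_model_prediction_clipped(self):
        region = bare_region("TTTT" + "ACGT" * 5 + "CGG" + "TTT")
        (c,) = enumerate_guides(region)
        model = LinearOnTargetModel(weights={"gc_count": 1.0}, intercept=0.0)
        assert ontarget_score(c, region, model) == 1.0  # 10 clipped to 1
        model = LinearOnTargetModel(weights={"gc_count": -1.0})
        assert ontarget_score(c, region, model) == 0.0

    def test_model_feature_mismatch_errors(self):
        region = bare_region("TTTT" + "ACGT" * 5 + "CGG" + "TTT")
        (c,) = enumerate_guides(region)
        model = LinearOnTargetModel(weights={"no_such_feature": 1.0})
        with pytest.raises(ValueError, match="no_such_feature"):
            ontarget_score(c, region, model)


def brute_force_offtargets(protospacer, genome, max_mm=3, pams=("NGG", "NAG")):
    """Literal double-loop oracle over every position of both strands."""
    second = {p[1] for p in pams}
    hits = set()
    for chrom, seq in genome.chromosomes.items():
        L = len(seq)
        for strand in "+-":
            for start in range(L - 19):
                if strand == "+":
                    word = seq[start : start + 20]
                    pam = seq[start + 20 : start + 23]
                else:
                    word = revcomp(seq[start : start + 20])
                    pam = revcomp(seq[start - 3 : start]) if start >= 3 else ""
                if len(pam) < 3 or pam[2] != "G" or pam[1] not in second:
                    continue
                mm = sum(1 for a, b in zip(word, protospacer) if a != b or a == "N")
                if mm <= max_mm:
                    hits.add((chrom, strand, start, mm))
    return hits


class TestOffTargetScan:
    def test_identity_hit_flagged_self(self):
        proto = "ACGACGTACGTACGTACGTA"
        genome = GenomeSequence({"c": "TTT" + proto + "CGG" + "TTT"})
        hits = find_offtargets(proto, genome, self_locus=("c", "+", 3))
        assert len(hits) == 1
        assert hits[0].m == 0 and hits[0].is_self

    def test_planted_mismatch_ladder(self, fixture_set, genome, catalog):
        """Decoys at Hamming 1-4: exactly the <=3 set is reported."""
        truth = fixture_set.truth
        site = truth[(truth.kind == "guide_site") & (truth.tx_index == 0)
                     & (truth.guide_index == 0)].iloc[0]
        hits = find_offtargets(site.protospacer, genome)
        decoy_hits = [h for h in hits if h.chrom == "chrOT"]
        planted = truth[truth.kind == "offtarget"]
        expected = planted[planted.mm <= 3]
        assert sorted(h.m for h in decoy_hits) == sorted(expected.mm)
        assert sorted(h.pam_class for h in decoy_hits) == sorted(expected.pam_class)
        assert {h.start for h in decoy_hits} == set(expected.genomic_start)

    def test_no_pam_no_hit(self):
        proto = "ACGACGTACGTACGTACGTA"
        genome = GenomeSequence({"c": "TTT" + proto + "TTT" + "TTT"})
        assert find_offtargets(proto, genome) == []

    def test_nag_pam_reported_with_class(self):
        proto = "ACGACGTACGTACGTACGTA"
        genome = GenomeSequence({"c": "TTT" + proto + "TAG" + "TTT"})
        (h,) = find_offtargets(proto, genome)
        assert h.pam_class == "NAG"

    def test_scanner_equals_brute_force_oracle(self, fixture_set, genome):
        truth = fixture_set.truth
        site = truth[truth.kind == "guide_site"].iloc[0]
        got = {
            (h.chrom, h.strand, h.start if h.strand == "+" else h.start + 20, h.m)
            for h in find_offtargets(site.protospacer, genome)
        }
        # oracle indexes minus-strand words by their plus-strand *end*+... map:
        # oracle start s (word [s,s+20) revcomp) equals scanner start for '+',
        # and scanner start + 20 == oracle start + 20 for '-'
        expected = {
            (c, s, p if s == "+" else p + 20, m)
            for c, s, p, m in brute_force_offtargets(site.protospacer, genome)
        }
        assert got == expected

    def test_strand_symmetry_of_hit_counts(self, fixture_set, genome):
        truth = fixture_set.truth
        site = truth[truth.kind == "guide_site"].iloc[0]
        flipped = GenomeSequence(
            {c: revcomp(s) for c, s in genome.chromosomes.items()}
        )
        assert len(find_offtargets(site.protospacer, genome)) == len(
            find_offtargets(site.protospacer, flipped)
        )

    def test_mismatch_positions_pam_distal_convention(self):
        proto = "ACGACGTACGTACGTACGTA"
        variant = proto[:19] + ("G" if proto[19] != "G" else "T")  # PAM-proximal
        genome = GenomeSequence({"c": "TTT" + variant + "AGG" + "TTT"})
        (h,) = find_offtargets(proto, genome)
        assert h.mismatch_positions == (20,)
        # same check on the minus strand
        genome = GenomeSequence({"c": "TTT" + revcomp(variant + "AGG") + "TTT"})
        (h,) = find_offtargets(proto, genome)
        assert h.strand == "-"
        assert h.mismatch_positions == (20,)


def hit(*positions):
    return OffTargetHit("c", "+", 0, "NGG", tuple(positions))


class TestMitScores:
    def test_perfect_match_scores_100(self):
        assert mit_single_hit(hit()) == 100.0

    def test_single_pam_proximal_mismatch(self):
        assert mit_single_hit(hit(20)) == pytest.approx(41.7)
        assert HSU_WEIGHTS[19] == 0.583

    def test_single_pam_distal_mismatch_unweighted(self):
        assert mit_single_hit(hit(1)) == pytest.approx(100.0)

    def test_two_adjacent_mismatches_formula(self):
        # positions 19,20: prod(1-W) * 1/(((19-1)/19)*4+1) * 1/4
        expected = 100 * (1 - 0.685) * (1 - 0.583) / (((19 - 1) / 19) * 4 + 1) / 4
        assert mit_single_hit(hit(19, 20)) == pytest.approx(expected)

    def test_monotone_in_mismatch_count(self):
        prev = mit_single_hit(hit(18))
        for extra in ([18, 19], [18, 19, 20]):
            cur = mit_single_hit(hit(*extra))
            assert cur <= prev
            prev = cur

    def test_position_out_of_range_errors(self):
        with pytest.raises(ValueError):
            mit_single_hit(hit(21))

    def test_aggregate_empty_is_100(self):
        assert mit_aggregate([]) == 100.0

    def test_aggregate_one_perfect_offtarget_halves(self):
        assert mit_aggregate([hit()]) == pytest.approx(50.0)

    def test_aggregate_two_fifties(self):
        h1 = hit(20)
        h2 = hit(20)
        # two hits scoring 41.7 each -> 100*100/(100+83.4)
        assert mit_aggregate([h1, h2]) == pytest.approx(100 * 100 / (100 + 2 * 41.7))

    def test_aggregate_monotone_nonincreasing(self):
        hits = []
        prev = 100.0
        for p in range(1, 21):
            hits.append(hit(p))
            cur = mit_aggregate(hits)
            assert cur <= prev
            prev = cur

    def test_self_hit_excluded_from_aggregate(self):
        self_hit = OffTargetHit("c", "+", 0, "NGG", (), is_self=True)
        assert mit_aggregate([self_hit]) == 100.0

    def test_scores_bounded(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            m = int(rng.integers(0, 5))
            pos = tuple(sorted(rng.choice(np.arange(1, 21), m, replace=False).tolist()))
            s = mit_single_hit(hit(*pos))
            assert 0.0 <= s <= 100.0
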