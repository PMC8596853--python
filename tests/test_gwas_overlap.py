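"""Sentinel pruning, gene sets, enrichment folds, MH combination, screens."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from exwas import gwas_overlap as go
from exwas.gwas_overlap import (
    EnrichmentStratum,
    assign_gene_set,
    enrichment_fold,
    expected_by_chance,
    mantel_haenszel,
    match_trait_to_disease,
    prune_signals,
    screen_protective,
    two_by_two_or,
)
from exwas.synthetic_cohort import gen_gwas_landscape

MB = 1_000_000


def sig(trait, pos, p, chrom="1"):
    return {"trait_id": trait, "chrom": chrom, "pos": pos, "pvalue": p}


class TestPruneSignals:
    def test_close_pair_drops_weaker(self):
        s = pd.DataFrame([sig("t", 10 * MB, 1e-20), sig("t", 15 * MB, 1e-10)])
        out = prune_signals(s)
        assert list(out["pos"]) == [10 * MB]

    def test_pair_11mb_apart_both_kept(self):
        s = pd.DataFrame([sig("t", 10 * MB, 1e-20), sig("t", 21 * MB, 1e-10)])
        assert len(prune_signals(s)) == 2

    def test_three_colinear_greedy(self):
        # p increases with position: keep 0 Mb, drop 8 Mb (too close to 0),
        # keep 16 Mb (16 Mb from the kept signal)
        s = pd.DataFrame([sig("t", 1, 1e-30), sig("t", 8 * MB, 1e-20),
                          sig("t", 16 * MB, 1e-10)])
        out = prune_signals(s)
        assert sorted(out["pos"]) == [1, 16 * MB]

    def test_traits_and_chromosomes_independent(self):
        s = pd.DataFrame([
            sig("t1", 10 * MB, 1e-20), sig("t2", 12 * MB, 1e-10),
            sig("t1", 12 * MB, 1e-9, chrom="2"),
        ])
        assert len(prune_signals(s)) == 3


class TestAssignGeneSet:
    genes = pd.DataFrame({
        "gene_id": ["A", "B", "C"],
        "chrom": ["1", "1", "1"],
        "start": [5 * MB, 8 * MB, 30 * MB],
        "end": [5 * MB + 10_000, 8 * MB + 10_000, 30 * MB + 10_000],
    })

    def test_gene_containing_sentinel_in_every_rule(self):
        signals = pd.DataFrame([sig("t", 5 * MB + 500, 1e-20)])
        for rule in [("within", MB), ("within", 10_000), "nearest",
                     ("nth_nearest", 2)]:
            assert "A" in assign_gene_set(self.genes, signals, rule)["t"]

    def test_distance_window_excludes_far_gene(self):
        signals = pd.DataFrame([sig("t", 6_510_000, 1e-20)])
        # gene A ends at 5.01 Mb -> distance 1.5 Mb
        in_set = assign_gene_set(self.genes, signals, ("within", MB))["t"]
        assert "A" not in in_set

    def test_nearest_rank_one(self):
        signals = pd.DataFrame([sig("t", 7 * MB, 1e-20)])
        assert assign_gene_set(self.genes, signals, "nearest")["t"] == {"B"}

    def test_monotone_in_window_size(self):
        signals, genes, _ = gen_gwas_landscape(
            n_traits=3, n_signals_per_trait=8, genome_length=80 * MB,
            n_genes=300, n_causal_per_trait=5, seed=3)
        pruned = prune_signals(signals)
        prev = {t: set() for t in signals["trait_id"].unique()}
        for d in (int(0.5 * MB), MB, 5 * MB, 10 * MB):
            cur = assign_gene_set(genes, pruned, ("within", d))
            for t, s in cur.items():
                assert prev[t] <= s
            prev = cur

    def test_synthetic_landscape_matches_direct_counting(self):
        signals, genes, _ = gen_gwas_landscape(
            n_traits=2, n_signals_per_trait=5, genome_length=60 * MB,
            n_genes=120, n_causal_per_trait=5, seed=9)
        in_sets = assign_gene_set(genes, signals, ("within", MB))
        for trait_id, sub in signals.groupby("trait_id"):
            expected = set()
            for _, g in genes.iterrows():
                for p in sub["pos"]:
                    d = max(0, max(g["start"] - p, p - g["end"]))
                    if d <= MB:
                        expected.add(g["gene_id"])
            assert in_sets[str(trait_id)] == expected


class TestEnrichmentFold:
    def test_balanced_equals_one(self):
        fold, ok = enrichment_fold(EnrichmentStratum("t", 5, 5, 7, 7))
        assert ok and fold == pytest.approx(1.0)

    def test_printed_formula(self):
        fold, ok = enrichment_fold(EnrichmentStratum("t", 2, 8, 10, 980))
        assert ok and fold == pytest.approx(24.5)

    def test_zero_numerator(self):
        fold, ok = enrichment_fold(EnrichmentStratum("t", 0, 8, 10, 980))
        assert ok and fold == 0.0

    def test_undefined_flagged_not_corrected(self):
        fold, ok = enrichment_fold(EnrichmentStratum("t", 2, 0, 10, 980))
        assert not ok and np.isnan(fold)


class TestMantelHaenszel:
    def test_single_stratum_reduces_to_sample_or(self):
        s = EnrichmentStratum("t", 4, 16, 10, 970)
        out = mantel_haenszel([s])
        assert out["or_mh"] == pytest.approx((4 * 970) / (16 * 10))

    def test_duplicate_strata_leave_or_unchanged(self):
        s = EnrichmentStratum("t", 4, 16, 10, 970)
        one = mantel_haenszel([s])["or_mh"]
        two = mantel_haenszel([s, s])["or_mh"]
        assert one == pytest.approx(two)

    def test_matches_hand_formula(self):
        strata = [EnrichmentStratum("a", 3, 17, 8, 972),
                  EnrichmentStratum("b", 1, 9, 20, 1970),
                  EnrichmentStratum("c", 0, 12, 5, 983)]
        out = mantel_haenszel(strata)
        num = sum(s.a * s.d / (s.a + s.b + s.c + s.d) for s in strata)
        den = sum(s.b * s.c / (s.a + s.b + s.c + s.d) for s in strata)
        assert out["or_mh"] == pytest.approx(num / den)

    def test_or_bounded_by_stratum_ors(self):
        strata = [EnrichmentStratum("a", 3, 17, 8, 972),
                  EnrichmentStratum("b", 6, 14, 20, 1960)]
        ors = [(s.a * s.d) / (s.b * s.c) for s in strata]
        out = mantel_haenszel(strata)
        assert min(ors) <= out["or_mh"] <= max(ors)

    def test_recovers_common_or_over_many_strata(self, rng):
        # 188 trait strata with a common true OR of 5
        strata = []
        for t in range(188):
            n_genes, k, p0 = 1000, 40, 0.01
            odds1 = 5 * p0 / (1 - p0)
            p1 = odds1 / (1 + odds1)
            a = int(rng.binomial(k, p1))
            c = int(rng.binomial(n_genes - k, p0))
            strata.append(EnrichmentStratum(f"T{t}", a, k - a, c,
                                            n_genes - k - c))
        out = mantel_haenszel(strata)
        lo, hi = out["ci95"]
        assert lo <= 5.0 <= hi

    def test_null_chi2_size_calibrated(self):
        # no planted enrichment: MH test rejects at ~ the nominal rate
        rejections = 0
        runs = 300
        for seed in range(runs):
            rng = np.random.default_rng(seed)
            strata = []
            for t in range(30):
                a = int(rng.binomial(40, 0.02))
                c = int(rng.binomial(960, 0.02))
                strata.append(EnrichmentStratum(f"T{t}", a, 40 - a, c, 960 - c))
            if mantel_haenszel(strata)["p"] < 0.05:
                rejections += 1
        se = np.sqrt(0.05 * 0.95 / runs)
        assert abs(rejections / runs - 0.05) < 3.5 * se

    def test_all_degenerate_rejected(self):
        with pytest.raises(ValueError):
            mantel_haenszel([EnrichmentStratum("t", 0, 0, 0, 0)])


class TestExpectedByChance:
    def test_printed_arithmetic_with_rounding(self):
        out = expected_by_chance(8_865, 311_080_453, 131_077_005, rounding=3)
        assert out.p_hat == pytest.approx(2.85e-5)
        assert round(out.expected) == 3736

    def test_unrounded_differs_by_one(self):
        out = expected_by_chance(8_865, 311_080_453, 131_077_005, rounding=None)
        assert round(out.expected) == 3735

    def test_zero_in_window_tests(self):
        assert expected_by_chance(10, 100, 0).expected == 0.0

    def test_linear_in_k(self):
        e1 = expected_by_chance(10, 1000, 50).expected
        e2 = expected_by_chance(10, 1000, 100).expected
        assert e2 == pytest.approx(2 * e1)

    def test_a_exceeding_n_rejected(self):
        with pytest.raises(ValueError):
            expected_by_chance(11, 10, 5)


class TestTwoByTwo:
    def test_drug_target_table(self):
        out = two_by_two_or([[36, 528], [345, 17_972]])
        assert out["or"] == pytest.approx(3.6, abs=0.05)
        assert out["fisher_p"] < 1e-8

    def test_symmetric_table(self):
        out = two_by_two_or([[5, 5], [5, 5]])
        assert out["or"] == pytest.approx(1.0)
        assert out["fisher_p"] == pytest.approx(1.0)

    def test_zero_denominator_flagged_with_exact_p(self):
        out = two_by_two_or([[10, 0], [0, 10]])
        assert not out["or_defined"]
        # oracle: hypergeometric enumeration of tables with fixed margins
        probs = hypergeom.pmf(np.arange(11), 20, 10, 10)
        pobs = hypergeom.pmf(10, 20, 10, 10)
        expected = probs[probs <= pobs * (1 + 1e-12)].sum()
        assert out["fisher_p"] == pytest.approx(float(expected), rel=1e-9)


class TestTraitDiseaseMatch:
    rg = pd.DataFrame({
        "trait_id": ["eos", "eos", "iop", "bmd"],
        "disease_id": ["asthma", "copd", "glaucoma", "t2d"],
        "rg": [0.37, 0.20, 0.66, 0.05],
        "rg_p": [1e-12, 1e-3, 1e-20, 0.5],
    })

    def test_min_p_selected_among_significant(self):
        matches = {m.trait_id: m for m in match_trait_to_disease(self.rg)}
        assert matches["eos"].disease_id == "asthma"
        assert matches["eos"].rg == pytest.approx(0.37)
        assert matches["iop"].disease_id == "glaucoma"

    def test_no_match_when_nothing_significant(self):
        matches = {m.trait_id: m for m in match_trait_to_disease(self.rg)}
        assert matches["bmd"].disease_id is None


class TestScreenProtective:
    quant = pd.DataFrame({
        "gene_id": ["g1", "g2", "g3", "g4"],
        "trait_id": ["eos", "eos", "unknown_trait", "eos"],
        "effect": [-0.3, +0.3, -0.5, -0.2],
        "p": [1e-15, 1e-15, 1e-15, 1e-12],
    })
    disease = pd.DataFrame({
        "gene_id": ["g1", "g4"],
        "disease_id": ["asthma", "asthma"],
        "effect": [-0.4, +0.2],          # g1 protective, g4 risk-increasing
        "p": [1e-5, 1e-5],
    })

    def test_four_step_filter(self):
        matches = match_trait_to_disease(TestTraitDiseaseMatch.rg)
        out = screen_protective(self.quant, {"eos": -1}, matches, self.disease)
        # unknown-direction trait excluded at step 1; wrong-direction g2 at
        # step 2; g4 (disease OR > 1) at step 4; g1 retained
        assert out.surviving_counts["known_direction"] == 3
        assert out.surviving_counts["favourable_effect"] == 2
        assert out.surviving_counts["protective"] == 1
        assert list(out.candidates["gene_id"]) == ["g1"]
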