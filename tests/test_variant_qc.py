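"""Boundary-exact filter tests, HWE oracle and the somatic screen."""

import math

import numpy as np
import pandas as pd
import pytest

from exwas import variant_qc as vq
from exwas.synthetic_cohort import MISSING, GenotypeMatrix


def make_gm(dosage, vtypes, dp=None, ad=None):
    dosage = np.asarray(dosage, dtype=np.int8)
    n, v = dosage.shape
    variants = pd.DataFrame({
        "variant_id": [f"v{j}" for j in range(v)],
        "chrom": "1",
        "pos": np.arange(1, v + 1) * 100,
        "ref": "A",
        "alt": "G",
        "variant_type": vtypes,
        "gene_id": "G00000",
    })
    return GenotypeMatrix(
        dosage=dosage,
        samples=[f"S{i}" for i in range(n)],
        variants=variants,
        dp=None if dp is None else np.asarray(dp),
        ad=None if ad is None else np.asarray(ad),
    )


class TestDepthFilter:
    @pytest.mark.parametrize("vtype,dp,expect_missing", [
        ("SNV", 6, True),     # below the SNV cutoff of 7
        ("SNV", 7, False),    # boundary retained
        ("indel", 9, True),   # below the indel cutoff of 10
        ("indel", 10, False),
    ])
    def test_boundaries_bit_exact(self, vtype, dp, expect_missing):
        gm = make_gm([[1]], [vtype], dp=[[dp]], ad=[[dp // 2]])
        out = vq.genotype_depth_filter(gm)
        assert (out.dosage[0, 0] == MISSING) == expect_missing

    def test_retained_dosages_unchanged_and_idempotent(self, rng):
        dosage = rng.integers(0, 3, size=(30, 8)).astype(np.int8)
        dp = rng.integers(0, 40, size=(30, 8))
        gm = make_gm(dosage, ["SNV", "indel"] * 4, dp=dp, ad=dp // 3)
        once = vq.genotype_depth_filter(gm)
        twice = vq.genotype_depth_filter(once)
        np.testing.assert_array_equal(once.dosage, twice.dosage)
        kept = once.dosage != MISSING
        np.testing.assert_array_equal(once.dosage[kept], dosage[kept])
        assert (once.dosage == MISSING).sum() >= (dosage == MISSING).sum()

    def test_unknown_variant_type_rejected(self):
        gm = make_gm([[1]], ["MNV"], dp=[[20]], ad=[[10]])
        with pytest.raises(vq.InputError):
            vq.genotype_depth_filter(gm)


class TestAlleleBalanceFilter:
    def _one_variant(self, vtype, dosages, dp, ad):
        return make_gm(np.array(dosages)[:, None], [vtype],
                       dp=np.array(dp)[:, None], ad=np.array(ad)[:, None])

    def test_hom_alt_rescues_low_ab_hets(self):
        gm = self._one_variant("SNV", [2, 1, 1], [20, 20, 20], [20, 1, 1])
        assert vq.allele_balance_filter(gm).n_variants == 1

    @pytest.mark.parametrize("vtype,ab_scaled,kept", [
        ("SNV", 14, False),    # max AB 0.14 < 0.15
        ("SNV", 15, True),     # boundary AB >= 0.15
        ("indel", 19, False),  # 0.19 < 0.20
        ("indel", 20, True),   # boundary AB >= 0.20
    ])
    def test_het_ab_boundaries_bit_exact(self, vtype, ab_scaled, kept):
        gm = self._one_variant(vtype, [1, 0], [100, 100], [ab_scaled, 0])
        assert vq.allele_balance_filter(gm).n_variants == (1 if kept else 0)

    def test_all_missing_variant_dropped_with_reason(self):
        gm = self._one_variant("SNV", [MISSING, MISSING], [3, 3], [1, 1])
        log = vq.ExclusionLog()
        out = vq.allele_balance_filter(gm, log=log)
        assert out.n_variants == 0
        assert log.records == [("variant", "v0", "no_nonmissing_calls")]

    def test_idempotent(self, small_cohort):
        gm = vq.genotype_depth_filter(small_cohort.genotypes)
        once = vq.allele_balance_filter(gm)
        twice = vq.allele_balance_filter(once)
        assert list(once.variants["variant_id"]) == list(twice.variants["variant_id"])


class TestHweExactTest:
    @staticmethod
    def brute_force_hwe(n_het, n_hom_ref, n_hom_alt):
        """Independent oracle: exact rational enumeration of the conditional
        genotype distribution given allele counts."""
        n = n_het + n_hom_ref + n_hom_alt
        n_rare = 2 * min(n_hom_ref, n_hom_alt) + n_het
        # integer weight 2^h * n! / (c! h! r!), normalized at the end
        weights = {}
        for h in range(n_rare % 2, n_rare + 1, 2):
            r = (n_rare - h) // 2
            c = n - h - r
            weights[h] = (2 ** h) * math.factorial(n) // (
                math.factorial(c) * math.factorial(h) * math.factorial(r))
        total = sum(weights.values())
        obs = weights[n_het]
        return sum(w for w in weights.values() if w <= obs) / total

    @pytest.mark.parametrize("het,ref,alt", [
        (10, 80, 10), (3, 95, 2), (0, 18, 2), (5, 0, 5), (57, 14, 50),
    ])
    def test_matches_exact_enumeration(self, het, ref, alt):
        assert vq.hwe_exact_test(het, ref, alt) == pytest.approx(
            self.brute_force_hwe(het, ref, alt), rel=1e-9)

    def test_extreme_het_deficit_is_astronomically_significant(self):
        # 2,000 samples, no hets at 50% frequency
        assert vq.hwe_exact_test(0, 1000, 1000) < 1e-15


class TestSiteFilters:
    def test_missingness_hwe_monomorphic_removed(self):
        n = 100
        d = np.zeros((n, 3), dtype=np.int8)
        d[:11, 0] = MISSING          # 11% missing
        d[:50, 1] = 2                # 50 hom-alt, 50 hom-ref, 0 het -> HWE
        d[:, 2] = 0                  # monomorphic
        d[0, 2] = 0
        gm = make_gm(d, ["SNV"] * 3)
        # give variant 0 some polymorphism so only missingness removes it
        gm.dosage[20:40, 0] = 1
        out, log = vq.site_filters(gm)
        assert out.n_variants == 0
        reasons = dict(zip(log.to_frame()["id"], log.to_frame()["reason"]))
        assert reasons == {"v0": "missingness", "v1": "hwe", "v2": "monomorphic"}

    def test_sample_missingness_removed_after_variant_filters(self):
        rng = np.random.default_rng(0)
        d = rng.binomial(2, 0.3, size=(50, 20)).astype(np.int8)
        d[0, :] = MISSING            # sample 0 missing everywhere
        gm = make_gm(d, ["SNV"] * 20)
        out, log = vq.site_filters(gm)
        assert "S0" not in out.samples
        assert ("sample", "S0", "sample_missingness") in log.records

    def test_idempotent(self, small_cohort):
        once, _ = vq.site_filters(small_cohort.genotypes)
        twice, log2 = vq.site_filters(once)
        assert twice.n_variants == once.n_variants
        assert twice.samples == once.samples
        assert len(log2.records) == 0

    def test_empty_result_is_not_an_error(self):
        d = np.zeros((10, 2), dtype=np.int8)
        gm = make_gm(d, ["SNV"] * 2)
        out, _ = vq.site_filters(gm)
        assert out.n_variants == 0


class TestSomaticScreen:
    def test_all_central_vaf_gives_zero_fraction(self):
        dosage = np.array([1, 1, 1, 0])
        dp = np.array([40, 40, 40, 40])
        ad = np.array([20, 20, 20, 0])
        rep = vq.somatic_screen(dosage, dp, ad, ages=np.array([50, 60, 70, 55]))
        assert rep.fraction_extreme_vaf == 0.0

    def test_one_low_vaf_carrier_of_four(self):
        dosage = np.array([1, 1, 1, 1, 0])
        dp = np.array([100] * 5)
        ad = np.array([30, 50, 50, 50, 0])  # VAF 0.30 < 0.35 for one carrier
        rep = vq.somatic_screen(dosage, dp, ad, ages=np.array([50] * 5))
        assert rep.fraction_extreme_vaf == pytest.approx(0.25)

    def test_fewer_than_two_carriers_flagged(self):
        dosage = np.array([1, 0, 0])
        rep = vq.somatic_screen(dosage, np.array([30, 30, 30]),
                                np.array([15, 0, 0]), np.array([50, 60, 70]))
        assert rep.flagged_insufficient_carriers
        assert np.isnan(rep.age_effect)

    def test_synthetic_somatic_variant_detected(self, somatic_cohort):
        # oracle: the generating parameters (VAF 0.2, carrier prob rising
        # with age) imply extreme VAF in most carriers and a positive age
        # coefficient
        gm = somatic_cohort.genotypes
        ages = somatic_cohort.demographics["age"].to_numpy()
        vids = list(gm.variants["variant_id"])
        found_positive = 0
        checked = 0
        for vid in somatic_cohort.somatic_variants:
            v = vids.index(vid)
            rep = vq.somatic_screen(gm.dosage[:, v], gm.dp[:, v], gm.ad[:, v],
                                    ages)
            if rep.flagged_insufficient_carriers or rep.n_carriers < 30:
                continue
            checked += 1
            assert rep.fraction_extreme_vaf > 0.5
            if rep.age_effect > 0:
                found_positive += 1
        assert checked >= 3
        assert found_positive >= 0.9 * checked

    def test_germline_extreme_vaf_matches_depth_model_tail(self, small_cohort):
        # oracle: P(VAF outside [0.35,0.65]) for a germline het = the NB-depth
        # mixture of binomial tails at AB = 0.5
        from scipy.stats import binom, nbinom

        spec_mean, spec_disp = 35.0, 8.0
        p_nb = spec_disp / (spec_disp + spec_mean)
        dmax = 200
        depths = np.arange(0, dmax)
        wd = nbinom.pmf(depths, spec_disp, p_nb)
        tails = np.empty(dmax)
        for i, d in enumerate(depths):
            if d == 0:
                tails[i] = 0.0  # VAF undefined; excluded by the screen
                continue
            k = np.arange(0, d + 1)
            vaf = k / d
            tails[i] = binom.pmf(k, d, 0.5)[(vaf < 0.35) | (vaf > 0.65)].sum()
        expected = (wd * tails).sum() / wd[1:].sum()

        gm = small_cohort.genotypes
        het = gm.dosage == 1
        dp = gm.dp[het].astype(float)
        ad = gm.ad[het].astype(float)
        ok = dp > 0
        vaf = ad[ok] / dp[ok]
        observed = ((vaf < 0.35) | (vaf > 0.65)).mean()
        se = np.sqrt(expected * (1 - expected) / ok.sum())
        assert abs(observed - expected) < 4 * se
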