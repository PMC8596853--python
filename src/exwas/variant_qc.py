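"""Genotype- and site-level quality filters, plus the somatic-origin screen.

The filters mirror standard joint-called exome QC: per-genotype read-depth
no-calling (SNV DP < 7, indel DP < 10), a variant-level allele-balance filter
(retain a variant only if it has a homozygous-alternate carrier or at least
one heterozygote with AB >= 0.15 for SNVs / 0.20 for indels), then site-level
exclusion of variants with missingness > 0.1, exact Hardy-Weinberg p < 1e-15
or monomorphic genotypes, and of samples with missingness > 0.1.

The somatic screen quantifies the two signatures of clonal-haematopoiesis
(CHIP) variants called from blood-derived DNA: variant allele fractions in
putative heterozygotes outside [0.35, 0.65], and carrier frequency that rises
with age.  It reports evidence; it does not classify.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .synthetic_cohort import MISSING, GenotypeMatrix

__all__ = [
    "SNV_MIN_DP",
    "INDEL_MIN_DP",
    "SNV_MIN_AB",
    "INDEL_MIN_AB",
    "SiteStats",
    "SomaticFlagReport",
    "ExclusionLog",
    "genotype_depth_filter",
    "allele_balance_filter",
    "hwe_exact_test",
    "site_stats",
    "site_filters",
    "somatic_screen",
]

SNV_MIN_DP = 7
INDEL_MIN_DP = 10
SNV_MIN_AB = 0.15
INDEL_MIN_AB = 0.20

VAF_LOW = 0.35
VAF_HIGH = 0.65


class InputError(ValueError):
    pass


@dataclass
class SiteStats:
    mac: int
    maf: float
    missingness: float
    hwe_p: float
    monomorphic: bool


@dataclass
class SomaticFlagReport:
    """Evidence that a variant (or burden) is of somatic rather than germline
    origin: fraction of het carriers with extreme VAF, and the logistic
    regression coefficient of carrier status on age."""

    n_carriers: int
    fraction_extreme_vaf: float
    age_effect: float
    age_p: float
    flagged_insufficient_carriers: bool = False


@dataclass
class ExclusionLog:
    """Append-only machine-readable record of QC exclusions."""

    records: list[tuple[str, str, str]] = field(default_factory=list)

    def add(self, kind: str, item: str, reason: str) -> None:
        self.records.append((kind, item, reason))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records, columns=["kind", "id", "reason"])

    def write(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Genotype-level depth filter
# ---------------------------------------------------------------------------

def genotype_depth_filter(gm: GenotypeMatrix) -> GenotypeMatrix:
    """Set sub-threshold genotypes to missing: SNV DP < 7, indel DP < 10.

    Idempotent; retained calls keep their dosage unchanged.
    """
    if gm.dp is None:
        raise InputError("read depths (DP) are required for the depth filter")
    vtypes = gm.variants["variant_type"].to_numpy()
    unknown = set(vtypes) - {"SNV", "indel"}
    if unknown:
        raise InputError(f"unknown variant types: {sorted(unknown)}")
    out = gm.copy()
    thresh = np.where(vtypes == "SNV", SNV_MIN_DP, INDEL_MIN_DP)
    out.dosage[out.dp < thresh[None, :]] = MISSING
    return out


# ---------------------------------------------------------------------------
# Variant-level allele-balance filter
# ---------------------------------------------------------------------------

def allele_balance_filter(gm: GenotypeMatrix, log: ExclusionLog | None = None
                          ) -> GenotypeMatrix:
    """Retain a variant iff it has >= 1 hom-alt carrier, or >= 1 het carrier
    with AB >= 0.15 (SNV) / 0.20 (indel).  Apply after the depth filter."""
    if gm.ad is None or gm.dp is None:
        raise InputError("AD and DP are required for the allele-balance filter")
    vtypes = gm.variants["variant_type"].to_numpy()
    cutoff = np.where(vtypes == "SNV", SNV_MIN_AB, INDEL_MIN_AB)

    with np.errstate(divide="ignore", invalid="ignore"):
        ab = np.where(gm.dp > 0, gm.ad / np.maximum(gm.dp, 1), 0.0)
    het = gm.dosage == 1
    hom = gm.dosage == 2
    nonmissing = gm.dosage != MISSING

    has_hom = hom.any(axis=0)
    has_good_het = (het & (ab >= cutoff[None, :])).any(axis=0)
    any_calls = nonmissing.any(axis=0)
    keep = has_hom | has_good_het

    if log is not None:
        vids = gm.variants["variant_id"].to_numpy()
        for v in np.flatnonzero(~keep):
            reason = "no_nonmissing_calls" if not any_calls[v] else "allele_balance"
            log.add("variant", vids[v], reason)
    return _subset_variants(gm, keep)


def _subset_variants(gm: GenotypeMatrix, keep: np.ndarray) -> GenotypeMatrix:
    return GenotypeMatrix(
        dosage=gm.dosage[:, keep],
        samples=list(gm.samples),
        variants=gm.variants.loc[keep].reset_index(drop=True),
        dp=None if gm.dp is None else gm.dp[:, keep],
        ad=None if gm.ad is None else gm.ad[:, keep],
    )


# ---------------------------------------------------------------------------
# Exact Hardy-Weinberg test
# ---------------------------------------------------------------------------

def hwe_exact_test(n_het: int, n_hom_ref: int, n_hom_alt: int) -> float:
    """Exact SNP-HWE test p-value (sum of genotype-configuration
    probabilities no larger than the observed one, conditional on the allele
    counts); no mid-p correction."""
    n = n_het + n_hom_ref + n_hom_alt
    if n == 0:
        return 1.0
    n_rare = 2 * min(n_hom_ref, n_hom_alt) + n_het
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    rare_hom = (n_rare - hets) // 2
    common_hom = n - hets - rare_hom
    # log P(het = h | allele counts) up to a shared constant
    logp = (hets * np.log(2.0) - gammaln(hets + 1) - gammaln(rare_hom + 1)
            - gammaln(common_hom + 1))
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    p_obs = p[hets == n_het][0]
    return float(min(1.0, p[p <= p_obs * (1 + 1e-12)].sum()))


def site_stats(gm: GenotypeMatrix) -> pd.DataFrame:
    """Per-variant MAC, MAF, missingness, exact-HWE p and monomorphic flag.

    MAF = MAC / (2 x non-missing samples), folded into [0, 0.5].
    """
    d = gm.dosage
    nonmiss = d != MISSING
    n_nm = nonmiss.sum(axis=0)
    alt = np.where(nonmiss, d, 0).sum(axis=0)
    ac_total = 2 * n_nm
    mac = np.minimum(alt, ac_total - alt)
    with np.errstate(divide="ignore", invalid="ignore"):
        maf = np.where(ac_total > 0, mac / np.maximum(ac_total, 1), 0.0)
    missingness = 1.0 - n_nm / d.shape[0]
    n_het = (d == 1).sum(axis=0)
    n_hom_alt = (d == 2).sum(axis=0)
    n_hom_ref = n_nm - n_het - n_hom_alt
    hwe = np.array([
        hwe_exact_test(int(h), int(r), int(a))
        for h, r, a in zip(n_het, n_hom_ref, n_hom_alt)
    ])
    return pd.DataFrame({
        "variant_id": gm.variants["variant_id"],
        "mac": mac,
        "maf": maf,
        "missingness": missingness,
        "hwe_p": hwe,
        "monomorphic": (mac == 0) | (n_nm == 0),
    })


def site_filters(
    gm: GenotypeMatrix,
    max_missingness: float = 0.1,
    hwe_threshold: float = 1e-15,
    max_sample_missingness: float = 0.1,
    log: ExclusionLog | None = None,
) -> tuple[GenotypeMatrix, ExclusionLog]:
    """Site- and sample-level filters, applied in order: variant missingness
    (> 0.1) -> HWE (p < 1e-15) -> monomorphic -> sample missingness (> 0.1).

    Strict inequalities throughout; an empty result is allowed.
    """
    log = log if log is not None else ExclusionLog()
    stats = site_stats(gm)
    vids = gm.variants["variant_id"].to_numpy()

    keep = np.ones(gm.n_variants, dtype=bool)
    drop_miss = stats["missingness"].to_numpy() > max_missingness
    for v in np.flatnonzero(drop_miss):
        log.add("variant", vids[v], "missingness")
    keep &= ~drop_miss

    drop_hwe = (stats["hwe_p"].to_numpy() < hwe_threshold) & keep
    for v in np.flatnonzero(drop_hwe):
        log.add("variant", vids[v], "hwe")
    keep &= ~drop_hwe

    drop_mono = stats["monomorphic"].to_numpy() & keep
    for v in np.flatnonzero(drop_mono):
        log.add("variant", vids[v], "monomorphic")
    keep &= ~drop_mono

    out = _subset_variants(gm, keep)

    if out.n_variants > 0:
        smiss = (out.dosage == MISSING).mean(axis=1)
    else:
        smiss = np.zeros(out.n_samples)
    keep_s = smiss <= max_sample_missingness
    for i in np.flatnonzero(~keep_s):
        log.add("sample", out.samples[i], "sample_missingness")
    out = GenotypeMatrix(
        dosage=out.dosage[keep_s],
        samples=[s for s, k in zip(out.samples, keep_s) if k],
        variants=out.variants,
        dp=None if out.dp is None else out.dp[keep_s],
        ad=None if out.ad is None else out.ad[keep_s],
    )
    return out, log


# ---------------------------------------------------------------------------
# Somatic-origin (CHIP) screen
# ---------------------------------------------------------------------------

def somatic_screen(carrier_dosage: np.ndarray, dp: np.ndarray, ad: np.ndarray,
                   ages: np.ndarray) -> SomaticFlagReport:
    """Somatic-evidence report for one variant (or collapsed burden).

    `carrier_dosage` is the per-sample dosage vector; `dp`/`ad` its per-call
    read evidence.  VAF is computed among heterozygous calls only.  Carrier
    status (dosage > 0) is regressed on age by logistic regression.
    """
    carrier_dosage = np.asarray(carrier_dosage)
    ages = np.asarray(ages, dtype=float)
    if len(ages) != len(carrier_dosage):
        raise InputError("ages must be available for all samples")

    het = carrier_dosage == 1
    n_carriers = int((carrier_dosage > 0).sum())
    if het.any():
        dp_h = np.asarray(dp, dtype=float)[het]
        ad_h = np.asarray(ad, dtype=float)[het]
        with np.errstate(divide="ignore", invalid="ignore"):
            vaf = np.where(dp_h > 0, ad_h / np.maximum(dp_h, 1), np.nan)
        vaf = vaf[np.isfinite(vaf)]
        frac = float(((vaf < VAF_LOW) | (vaf > VAF_HIGH)).mean()) if len(vaf) else 0.0
    else:
        frac = 0.0

    if n_carriers < 2:
        return SomaticFlagReport(n_carriers, frac, np.nan, np.nan,
                                 flagged_insufficient_carriers=True)

    import statsmodels.api as sm

    y = (carrier_dosage > 0).astype(float)
    X = sm.add_constant(ages)
    try:
        fit = sm.Logit(y, X).fit(disp=False, maxiter=100)
        coef, pval = float(fit.params[1]), float(fit.pvalues[1])
    except Exception:
        coef, pval = np.nan, np.nan
    return SomaticFlagReport(n_carriers, frac, coef, pval)
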