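"""Case-control power: empirical simulation and closed-form theory.

Empirical power simulates independent markers (alleles Binomial(2, EAF)) and
binary traits from ``logit(p) = mu + G beta`` with the intercept calibrated to
a target prevalence K, runs the logistic score test with Firth fallback per
replicate, and reports the fraction of replicates significant at alpha with an
exact binomial Monte-Carlo CI.

Theoretical power uses the logistic score-test non-centrality parameter

    eta = 2 N0 N1 (p' - p)^2 / ((N0 + N1) pbar (1 - pbar))

with p the control (~population) EAF, p' the case EAF and pbar the
case/control-weighted average; power is the upper-tail mass of a noncentral
1-df chi-square beyond the central (1 - alpha) quantile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from scipy.special import expit

from .association import FIRTH_FALLBACK_P, firth_logit, logistic_score_test
from .synthetic_cohort import CalibrationError, calibrate_intercept

__all__ = [
    "PowerSpec",
    "simulate_case_control",
    "empirical_power",
    "case_eaf_from_or",
    "theoretical_power",
    "expected_replications_by_chance",
]


@dataclass(frozen=True)
class PowerSpec:
    """One cell of the power grid."""

    n_samples: int
    prevalence: float
    eaf: float
    odds_ratio: float
    alpha: float
    n_marker_reps: int = 10
    n_pheno_reps: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must be in (0, 1)")
        if not 0.0 < self.eaf < 1.0:
            raise ValueError("EAF must be in (0, 1)")
        if self.odds_ratio <= 0:
            raise ValueError("odds ratio must be positive")


def simulate_case_control(spec: PowerSpec, rng: np.random.Generator
                          ) -> tuple[np.ndarray, np.ndarray]:
    """One marker + one phenotype replicate under the logistic model."""
    g = rng.binomial(2, spec.eaf, size=spec.n_samples).astype(float)
    beta = np.log(spec.odds_ratio)
    mu = calibrate_intercept(g * beta, spec.prevalence)
    y = rng.binomial(1, expit(mu + g * beta)).astype(float)
    return g, y


def _binary_pvalue(g: np.ndarray, y: np.ndarray,
                   fallback_p: float = FIRTH_FALLBACK_P) -> float:
    """Fast score-then-Firth p-value with an intercept-only null."""
    n = len(y)
    X0 = np.ones((n, 1))
    p0 = np.full(n, y.mean())
    _, p_score = logistic_score_test(g, y, X0, p0)
    if p_score >= fallback_p:
        return p_score
    X = np.column_stack([g, X0])
    beta, cov = firth_logit(y, X)
    z2 = beta[0] ** 2 / cov[0, 0]
    return float(sps.chi2.sf(z2, 1))


def empirical_power(spec: PowerSpec) -> dict:
    """Empirical power over n_marker_reps x n_pheno_reps replicates.

    Each replicate is tested by the score test with Firth fallback at 0.05;
    power is the fraction of replicates with p <= alpha, with an exact
    (Clopper-Pearson) 95% binomial CI.
    """
    rng = np.random.default_rng(spec.seed)
    beta = np.log(spec.odds_ratio)
    per_marker = np.zeros(spec.n_marker_reps)
    n_tot = spec.n_marker_reps * spec.n_pheno_reps
    for m in range(spec.n_marker_reps):
        g = rng.binomial(2, spec.eaf, size=spec.n_samples).astype(float)
        try:
            mu = calibrate_intercept(g * beta, spec.prevalence)
        except CalibrationError:
            continue
        p = expit(mu + g * beta)
        n_sig_m = 0
        for _ in range(spec.n_pheno_reps):
            y = rng.binomial(1, p).astype(float)
            if y.min() == y.max() or g.sum() == 0:
                continue
            if _binary_pvalue(g, y) <= spec.alpha:
                n_sig_m += 1
        per_marker[m] = n_sig_m / spec.n_pheno_reps
    n_sig = int(round(per_marker.sum() * spec.n_pheno_reps))
    ci = sps.binomtest(n_sig, n_tot).proportion_ci(confidence_level=0.95)
    phat = n_sig / n_tot
    # markers are the independent Monte-Carlo units: power varies with each
    # marker's realized allele count, so the SE comes from between-marker
    # variation.  The binomial part uses the Agresti-Coull adjusted
    # proportion so boundary outcomes (all or no replicates significant) do
    # not collapse the SE to zero.
    p_adj = (n_sig + 2) / (n_tot + 4)
    se_binom = float(np.sqrt(p_adj * (1 - p_adj) / n_tot))
    if spec.n_marker_reps > 1:
        se_cluster = float(per_marker.std(ddof=1) / np.sqrt(spec.n_marker_reps))
        mc_se = max(se_cluster, se_binom)
    else:
        mc_se = se_binom
    return {
        "power": phat,
        "n_significant": n_sig,
        "n_replicates": n_tot,
        "per_marker_power": per_marker,
        "ci95": (float(ci.low), float(ci.high)),
        "mc_se": mc_se,
    }


def case_eaf_from_or(p: float, odds_ratio: float, prevalence: float | None = None
                     ) -> float:
    """Case EAF from the population EAF and per-allele OR.

    Uses the odds identity p' / (1 - p') = OR * p / (1 - p), with the control
    EAF approximated by the population EAF (accurate for uncommon diseases;
    `prevalence` is accepted for signature symmetry but does not enter).
    """
    return odds_ratio * p / (1.0 - p + odds_ratio * p)


def theoretical_power(n_controls: int, n_cases: int, p: float, p_case: float,
                      alpha: float) -> float:
    """Score-test power from the non-centrality parameter.

    pbar is the case/control-weighted average EAF; power is
    P(chi2_1(eta) > q) with q the central chi2_1 (1 - alpha) quantile.
    """
    if n_controls <= 0 or n_cases <= 0:
        raise ValueError("case and control counts must be positive")
    n = n_controls + n_cases
    p_bar = (n_cases * p_case + n_controls * p) / n
    eta = (2.0 * n_controls * n_cases * (p_case - p) ** 2
           / (n * p_bar * (1.0 - p_bar)))
    q = sps.chi2.ppf(1.0 - alpha, 1)
    return float(sps.ncx2.sf(q, 1, eta)) if eta > 0 else float(alpha)


def expected_replications_by_chance(n_tested: int, alpha: float = 0.05) -> float:
    """Expected count of nominally significant, directionally consistent
    replications under the null: n_tested x alpha x 1/2."""
    if n_tested < 0:
        raise ValueError("n_tested must be >= 0")
    return n_tested * alpha * 0.5
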