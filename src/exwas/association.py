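"""Phenotype preparation and covariate-adjusted association tests.

Quantitative traits are averaged across visits, screened by mode-fraction /
unique-value heuristics for non-quantitative artefacts, rank-inverse-normal
transformed (Blom offset, average ties) and tested by ordinary least squares.
Binary traits are tested with a logistic score test; whenever the score-test
p-value falls below a fallback threshold (default 0.05) the model is refitted
by exact Firth penalized likelihood (Jeffreys-prior penalty) and the Firth
log-odds-ratio, SE and Wald p are reported.  The Firth path returns finite
estimates even under complete separation.

Polygenic-background adjustment (whole-genome LOCO predictors) is deliberately
absent: synthetic cohorts here have independent samples and no polygenic
background, so plain covariate adjustment is the exact analogue.  Conditional
analysis appends common-variant dosage vectors to the covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "FIRTH_FALLBACK_P",
    "PreparedTrait",
    "AssociationResult",
    "prepare_trait",
    "rint",
    "test_quantitative",
    "test_binary",
    "conditional_test",
    "firth_logit",
    "logistic_score_test",
]

FIRTH_FALLBACK_P = 0.05
Z975 = 1.959963984540054


class InputError(ValueError):
    pass


class ConvergenceError(RuntimeError):
    pass


@dataclass
class PreparedTrait:
    kind: str                       # "binary" | "quantitative"
    values: np.ndarray | None
    qc_status: str                  # "pass" | "rejected"
    reject_reason: str | None = None
    n_cases: int | None = None
    n_controls: int | None = None


@dataclass
class AssociationResult:
    effect: float
    se: float
    ci95: tuple[float, float]
    p: float
    n_carriers: int
    model_used: str                 # "linear" | "score" | "firth"
    conditioned_on: list[str] = field(default_factory=list)
    collinear_with_condition: bool = False


# ---------------------------------------------------------------------------
# Trait preparation
# ---------------------------------------------------------------------------

def rint(values: np.ndarray) -> np.ndarray:
    """Rank-based inverse-normal transform with Blom offset
    (r - 3/8) / (n + 1/4); ties get average ranks."""
    x = np.asarray(values, dtype=float)
    if len(np.unique(x)) < 2:
        raise InputError("rank-inverse-normal transform needs >= 2 distinct values")
    r = sps.rankdata(x, method="average")
    return sps.norm.ppf((r - 0.375) / (len(x) + 0.25))


def prepare_trait(
    values: np.ndarray,
    kind: str,
    min_cases: int = 100,
    mode_reject: float = 0.20,
    mode_flag: float = 0.005,
    min_unique: int = 100,
    max_unique: int = 10_000,
) -> PreparedTrait:
    """QC and transform one trait.

    `values` is 1-D (one measurement per participant) or 2-D
    (participants x visits, NaN for absent visits); multi-visit quantitative
    traits are averaged per participant first.  Quantitative rejection rules:
    mode observed in >= 20% of samples; mode in [0.5%, 20%) with < 100 unique
    values; mode in [0.5%, 20%) with > 10,000 unique values.  Binary traits
    with fewer than 100 cases are rejected.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim == 2:
        with np.errstate(invalid="ignore"):
            v = np.nanmean(v, axis=1)
    ok = np.isfinite(v)
    if not ok.any():
        return PreparedTrait(kind, None, "rejected", "all_missing")
    v = v[ok]

    if kind == "binary":
        n_cases = int((v == 1).sum())
        n_controls = int((v == 0).sum())
        if n_cases < min_cases:
            return PreparedTrait(kind, None, "rejected", "too_few_cases",
                                 n_cases, n_controls)
        return PreparedTrait(kind, v.astype(np.int64), "pass", None,
                             n_cases, n_controls)

    if kind != "quantitative":
        raise InputError(f"unknown trait kind {kind!r}")

    uniq, counts = np.unique(v, return_counts=True)
    mode_frac = counts.max() / len(v)
    if mode_frac >= mode_reject:
        return PreparedTrait(kind, None, "rejected", "mode_fraction")
    if mode_flag <= mode_frac < mode_reject:
        if len(uniq) < min_unique:
            return PreparedTrait(kind, None, "rejected", "too_few_unique_values")
        if len(uniq) > max_unique:
            return PreparedTrait(kind, None, "rejected", "too_many_unique_values")
    if len(uniq) < 2:
        return PreparedTrait(kind, None, "rejected", "constant")
    return PreparedTrait(kind, rint(v), "pass")


# ---------------------------------------------------------------------------
# Design-matrix helpers
# ---------------------------------------------------------------------------

def _design(covariates: pd.DataFrame | np.ndarray | None, n: int
            ) -> tuple[np.ndarray, list[str]]:
    """Intercept + covariates; raises on rank deficiency, naming columns."""
    if covariates is None:
        return np.ones((n, 1)), ["intercept"]
    if isinstance(covariates, pd.DataFrame):
        names = list(covariates.columns)
        C = covariates.to_numpy(dtype=float)
    else:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        names = [f"x{j}" for j in range(C.shape[1])]
    X = np.column_stack([np.ones(n), C])
    names = ["intercept"] + names
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        bad = []
        kept = X[:, :1]
        for j in range(1, X.shape[1]):
            cand = np.column_stack([kept, X[:, j]])
            if np.linalg.matrix_rank(cand) == kept.shape[1]:
                bad.append(names[j])
            else:
                kept = cand
        raise InputError(f"rank-deficient covariates: collinear columns {bad}")
    return X, names


# ---------------------------------------------------------------------------
# Quantitative trait: OLS
# ---------------------------------------------------------------------------

def test_quantitative(dosage: np.ndarray,
                      trait: np.ndarray,
                      covariates: pd.DataFrame | np.ndarray | None = None,
                      conditioned_on: list[str] | None = None,
                      ) -> AssociationResult:
    """OLS of the (transformed) trait on dosage + covariates; Wald CI/p."""
    import statsmodels.api as sm

    g = np.asarray(dosage, dtype=float)
    y = np.asarray(trait, dtype=float)
    X0, _ = _design(covariates, len(y))
    X = np.column_stack([g, X0])
    fit = sm.OLS(y, X).fit()
    beta, se = float(fit.params[0]), float(fit.bse[0])
    return AssociationResult(
        effect=beta,
        se=se,
        ci95=(beta - Z975 * se, beta + Z975 * se),
        p=float(fit.pvalues[0]),
        n_carriers=int((g > 0).sum()),
        model_used="linear",
        conditioned_on=list(conditioned_on or []),
    )


# ---------------------------------------------------------------------------
# Binary trait: logistic score test with Firth fallback
# ---------------------------------------------------------------------------

def _null_logit_fit(y: np.ndarray, X0: np.ndarray) -> np.ndarray:
    """Fitted null probabilities for y ~ X0 (intercept-only solved in closed
    form; otherwise Newton/IRLS via statsmodels)."""
    if X0.shape[1] == 1:
        return np.full(len(y), y.mean())
    import statsmodels.api as sm

    fit = sm.Logit(y, X0).fit(disp=False, maxiter=200)
    if not fit.mle_retvals.get("converged", True):
        raise ConvergenceError("null logistic model did not converge")
    return np.asarray(fit.predict(X0))


def logistic_score_test(g: np.ndarray, y: np.ndarray, X0: np.ndarray,
                        p0: np.ndarray | None = None) -> tuple[float, float]:
    """Rao score test for adding `g` to the null logistic model y ~ X0.

    Returns ``(chi2, p)``.  The efficient score variance projects g off the
    null design under the null-fit weights.
    """
    if p0 is None:
        p0 = _null_logit_fit(y, X0)
    w = p0 * (1.0 - p0)
    U = float(g @ (y - p0))
    XtWX = X0.T @ (X0 * w[:, None])
    XtWg = X0.T @ (g * w)
    V = float(g @ (g * w) - XtWg @ np.linalg.solve(XtWX, XtWg))
    if V <= 0:
        return 0.0, 1.0
    chi2 = U * U / V
    return chi2, float(sps.chi2.sf(chi2, 1))


def firth_logit(y: np.ndarray, X: np.ndarray, max_iter: int = 100,
                tol: float = 1e-8) -> tuple[np.ndarray, np.ndarray]:
    """Exact Firth penalized-likelihood logistic regression.

    Newton iterations on the Jeffreys-penalized score
    ``U*_j = sum_i (y_i - p_i + h_i (1/2 - p_i)) x_ij`` with step-halving on
    the penalized log-likelihood.  Returns ``(beta, cov)`` with the covariance
    taken as the inverse Fisher information at the optimum.  Estimates are
    finite even under complete separation.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    beta = np.zeros(k)

    def penalized_loglik(b: np.ndarray) -> float:
        eta = X @ b
        ll = float(y @ eta - np.logaddexp(0.0, eta).sum())
        p = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(p * (1.0 - p), 1e-12, None)
        _, logdet = np.linalg.slogdet(X.T @ (X * w[:, None]))
        return ll + 0.5 * logdet

    ll_old = penalized_loglik(beta)
    for _ in range(max_iter):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(p * (1.0 - p), 1e-12, None)
        XW = X * w[:, None]
        info = X.T @ XW
        info_inv = np.linalg.inv(info)
        # hat diagonal of W^{1/2} X I^{-1} X' W^{1/2}
        h = np.einsum("ij,jk,ik->i", X, info_inv, XW)
        U = X.T @ (y - p + h * (0.5 - p))
        step = info_inv @ U
        # step-halving
        for _ in range(20):
            cand = beta + step
            ll_new = penalized_loglik(cand)
            if ll_new >= ll_old - 1e-12:
                break
            step = step / 2.0
        beta = beta + step
        converged = np.max(np.abs(step)) < tol
        ll_old = ll_new
        if converged:
            break
    else:
        raise ConvergenceError(
            f"Firth regression did not converge in {max_iter} iterations; "
            f"last step size {np.max(np.abs(step)):.3g}")

    eta = X @ beta
    p = 1.0 / (1.0 + np.exp(-eta))
    w = np.clip(p * (1.0 - p), 1e-12, None)
    cov = np.linalg.inv(X.T @ (X * w[:, None]))
    return beta, cov


def test_binary(dosage: np.ndarray,
                case_status: np.ndarray,
                covariates: pd.DataFrame | np.ndarray | None = None,
                fallback_p: float = FIRTH_FALLBACK_P,
                conditioned_on: list[str] | None = None,
                ) -> AssociationResult:
    """Logistic score test with Firth fallback.

    The score test runs first against the covariate-only null model; if its
    p-value is below `fallback_p` (default 0.05) the model is refitted by
    exact Firth penalized likelihood and the Firth log-OR, SE and Wald p are
    reported (model_used = "firth").  Otherwise the score p is reported with
    the maximum-likelihood effect estimate (model_used = "score").
    """
    g = np.asarray(dosage, dtype=float)
    y = np.asarray(case_status, dtype=float)
    if y.min() == y.max():
        raise InputError("need at least one case and one control")
    X0, _ = _design(covariates, len(y))
    p0 = _null_logit_fit(y, X0)
    _, p_score = logistic_score_test(g, y, X0, p0)

    n_carriers = int((g > 0).sum())
    X = np.column_stack([g, X0])

    if p_score < fallback_p:
        beta_hat, cov = firth_logit(y, X)
        beta, se = float(beta_hat[0]), float(np.sqrt(cov[0, 0]))
        z = beta / se if se > 0 else 0.0
        return AssociationResult(
            effect=beta, se=se,
            ci95=(beta - Z975 * se, beta + Z975 * se),
            p=float(sps.chi2.sf(z * z, 1)),
            n_carriers=n_carriers, model_used="firth",
            conditioned_on=list(conditioned_on or []),
        )

    import statsmodels.api as sm

    try:
        fit = sm.Logit(y, X).fit(disp=False, maxiter=200)
        beta, se = float(fit.params[0]), float(fit.bse[0])
    except Exception:  # ML may diverge under separation; fall back to Firth effect
        beta_hat, cov = firth_logit(y, X)
        beta, se = float(beta_hat[0]), float(np.sqrt(cov[0, 0]))
    return AssociationResult(
        effect=beta, se=se,
        ci95=(beta - Z975 * se, beta + Z975 * se),
        p=p_score,
        n_carriers=n_carriers, model_used="score",
        conditioned_on=list(conditioned_on or []),
    )


# ---------------------------------------------------------------------------
# Conditional analysis
# ---------------------------------------------------------------------------

def conditional_test(dosage: np.ndarray,
                     trait: np.ndarray,
                     covariates: pd.DataFrame | np.ndarray | None,
                     conditioning: pd.DataFrame | dict[str, np.ndarray] | None,
                     kind: str = "quantitative",
                     **kwargs) -> AssociationResult:
    """Re-test with common-variant dosages appended to the covariates.

    With an empty conditioning set this is identical to the unconditional
    test.  A conditioning vector (near-)collinear with the test dosage flags
    the result instead of crashing.
    """
    if conditioning is None or len(conditioning) == 0:
        cond_df = None
        cond_ids: list[str] = []
    else:
        cond_df = pd.DataFrame(dict(conditioning)) if not isinstance(
            conditioning, pd.DataFrame) else conditioning
        cond_ids = list(cond_df.columns)

    g = np.asarray(dosage, dtype=float)
    collinear = False
    if cond_df is not None:
        for cid in cond_ids:
            v = cond_df[cid].to_numpy(dtype=float)
            gc, vc = g - g.mean(), v - v.mean()
            denom = np.linalg.norm(gc) * np.linalg.norm(vc)
            if denom > 0 and abs(gc @ vc) / denom > 1 - 1e-10:
                collinear = True
    if collinear:
        # conditioning absorbs the test dosage entirely: no residual signal
        return AssociationResult(
            effect=0.0, se=np.inf, ci95=(-np.inf, np.inf), p=1.0,
            n_carriers=int((g > 0).sum()),
            model_used="linear" if kind == "quantitative" else "score",
            conditioned_on=cond_ids, collinear_with_condition=True)

    if covariates is None:
        full = cond_df
    elif cond_df is None:
        full = covariates
    else:
        cov_df = covariates if isinstance(covariates, pd.DataFrame) else \
            pd.DataFrame(np.asarray(covariates, dtype=float))
        full = pd.concat(
            [cov_df.reset_index(drop=True), cond_df.reset_index(drop=True)], axis=1)

    if kind == "quantitative":
        res = test_quantitative(g, trait, full, conditioned_on=cond_ids, **kwargs)
    else:
        res = test_binary(g, trait, full, conditioned_on=cond_ids, **kwargs)
    res.collinear_with_condition = collinear
    return res
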