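"""Forward projections: pLOF carrier saturation and imputation accuracy.

Carrier saturation.  Per-gene carrier counts at cohort size N are modelled as
a mixture of beta-binomials: a gene's carrier frequency is beta-distributed
within its mixture component and its carrier count binomial given frequency.
Parameters are fitted by EM (log-domain responsibilities, exact weighted
per-component MLE in the M-step, seeded multi-start, BIC model selection over
1-5 components).  Projection to a larger cohort N' is empirical-Bayes: for a
gene observed with k carriers, the beta posterior within each component gives
a beta-binomial posterior predictive over the N' - N new samples; the
expected number of genes reaching a threshold K is the sum of per-gene
probabilities.  Heterozygous and homozygous carrier processes are modelled
independently.

Imputation accuracy.  r2-versus-panel-size points are fitted with logistic
curves r2 ~ c / (1 + exp(-(a + b log n))) — a two-parameter model with c
fixed at 1 and a three-parameter model constrained to c <= 1 — by nonlinear
least squares on the log(n) scale, with delta-method 95% CIs for
extrapolated r2, truncated to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, logsumexp
from scipy.stats import betabinom, norm

__all__ = [
    "BetaBinomMixtureFit",
    "SaturationProjection",
    "LogisticCurveFit",
    "fit_bbmix",
    "project_carriers",
    "fit_logistic_curve",
    "extrapolate_r2",
]


@dataclass
class BetaBinomMixtureFit:
    n_components: int
    weights: np.ndarray
    alphas: np.ndarray
    betas: np.ndarray
    log_likelihood: float
    n_samples: int                  # cohort size N the counts refer to
    n_genes: int
    iterations: int
    converged: bool
    loglik_trace: list[float] = field(default_factory=list)

    @property
    def bic(self) -> float:
        k = 3 * self.n_components - 1
        return -2.0 * self.log_likelihood + k * np.log(self.n_genes)


@dataclass
class SaturationProjection:
    target_n: int
    threshold: int
    expected_genes: float
    per_gene_prob: np.ndarray


@dataclass
class LogisticCurveFit:
    model: str                      # "2p" | "3p"
    a: float
    b: float
    c: float
    cov: np.ndarray                 # covariance of the free parameters
    n: np.ndarray
    r2: np.ndarray

    def predict(self, n: np.ndarray | float) -> np.ndarray:
        return self.c * expit(self.a + self.b * np.log(np.asarray(n, dtype=float)))


# ---------------------------------------------------------------------------
# Beta-binomial mixture EM
# ---------------------------------------------------------------------------

def _component_loglik(k: np.ndarray, n: int, log_a: float, log_b: float
                      ) -> np.ndarray:
    return betabinom.logpmf(k, n, np.exp(log_a), np.exp(log_b))


def _weighted_mle(k: np.ndarray, n: int, resp: np.ndarray,
                  log_a0: float, log_b0: float) -> tuple[float, float]:
    """Weighted beta-binomial shape update starting from the current shapes.

    A bounded Nelder-Mead improvement step (generalized EM): the update is
    accepted only if it improves the weighted log-likelihood, so the EM
    objective never decreases even when the inner search stops early."""

    def neg(theta):
        return -float(resp @ _component_loglik(k, n, theta[0], theta[1]))

    x0 = np.array([log_a0, log_b0])
    res = optimize.minimize(neg, x0, method="Nelder-Mead",
                            options={"xatol": 1e-5, "fatol": 1e-8, "maxiter": 80})
    if res.fun <= neg(x0):
        return float(res.x[0]), float(res.x[1])
    return log_a0, log_b0


def _moment_init(k: np.ndarray, n: int) -> tuple[float, float]:
    """Method-of-moments beta-binomial shapes (with overdispersion floor)."""
    m = max(k.mean(), 0.5)
    v = max(k.var(), m * (1 - m / n) * 1.01 + 1e-6)
    p = m / n
    # solve v = n p (1-p) (1 + (n-1) rho) for rho = 1/(a+b+1)
    rho = (v / (n * p * (1 - p) + 1e-12) - 1) / max(n - 1, 1)
    rho = min(max(rho, 1e-4), 0.99)
    s = 1.0 / rho - 1.0
    a = max(p * s, 1e-3)
    b = max((1 - p) * s, 1e-3)
    return np.log(a), np.log(b)


def _fit_bbmix_once(k: np.ndarray, n: int, n_components: int,
                    rng: np.random.Generator, max_iter: int, tol: float
                    ) -> BetaBinomMixtureFit:
    g = len(k)
    # initialize components from quantile slices of the counts (jittered)
    order = np.argsort(k + rng.uniform(0, 1e-3, size=g))
    slices = np.array_split(order, n_components)
    log_a = np.empty(n_components)
    log_b = np.empty(n_components)
    for j, sl in enumerate(slices):
        la, lb = _moment_init(k[sl], n)
        log_a[j] = la + rng.normal(0, 0.1)
        log_b[j] = lb + rng.normal(0, 0.1)
    w = np.full(n_components, 1.0 / n_components)

    trace: list[float] = []
    ll_old = -np.inf
    converged = False
    for it in range(1, max_iter + 1):
        logpk = np.stack([
            np.log(w[j] + 1e-300) + _component_loglik(k, n, log_a[j], log_b[j])
            for j in range(n_components)
        ])  # (components, genes)
        norm_ = logsumexp(logpk, axis=0)
        ll = float(norm_.sum())
        trace.append(ll)
        resp = np.exp(logpk - norm_)
        w = resp.sum(axis=1) / g
        for j in range(n_components):
            log_a[j], log_b[j] = _weighted_mle(k, n, resp[j], log_a[j], log_b[j])
        if ll - ll_old < tol and it > 1:
            converged = True
            break
        ll_old = ll

    return BetaBinomMixtureFit(
        n_components=n_components, weights=w,
        alphas=np.exp(log_a), betas=np.exp(log_b),
        log_likelihood=trace[-1], n_samples=n, n_genes=g,
        iterations=len(trace), converged=converged, loglik_trace=trace,
    )


def fit_bbmix(table: pd.DataFrame, n_samples: int,
              n_components: int | str = "auto",
              count_column: str = "carrier_count",
              n_starts: int = 10, max_iter: int = 200, tol: float = 1e-6,
              seed: int = 0, max_components: int = 5) -> BetaBinomMixtureFit:
    """Fit a beta-binomial mixture to per-gene carrier counts by EM.

    ``n_components="auto"`` selects 1..`max_components` by BIC.  Multi-start
    with `n_starts` seeded initializations per component count; the best
    log-likelihood wins.  The EM log-likelihood trace is non-decreasing.
    """
    k = table[count_column].to_numpy(dtype=np.int64)
    if len(k) < 1:
        raise ValueError("need at least one gene")
    if k.min() < 0 or k.max() > n_samples:
        raise ValueError("carrier counts must lie in [0, n_samples]")

    candidates = (range(1, max_components + 1) if n_components == "auto"
                  else [int(n_components)])
    best: BetaBinomMixtureFit | None = None
    for nc in candidates:
        best_nc: BetaBinomMixtureFit | None = None
        for s in range(n_starts if nc > 1 else min(n_starts, 3)):
            rng = np.random.default_rng((seed, nc, s))
            fit = _fit_bbmix_once(k, n_samples, nc, rng, max_iter, tol)
            if best_nc is None or fit.log_likelihood > best_nc.log_likelihood:
                best_nc = fit
        if best is None or best_nc.bic < best.bic:
            best = best_nc
    return best


def project_carriers(fit: BetaBinomMixtureFit, table: pd.DataFrame,
                     target_n: int, thresholds: list[int],
                     count_column: str = "carrier_count"
                     ) -> list[SaturationProjection]:
    """Expected number of genes with >= K carriers at a larger cohort size.

    Empirical-Bayes posterior predictive per gene: component responsibilities
    from the observed count k, then extra carriers among the target_n - N new
    samples ~ BetaBinomial(target_n - N, alpha_j + k, beta_j + N - k).
    """
    n = fit.n_samples
    if target_n < n:
        raise ValueError("target cohort size must be >= the observed one")
    k = table[count_column].to_numpy(dtype=np.int64)
    m = target_n - n

    logr = np.stack([
        np.log(fit.weights[j] + 1e-300)
        + betabinom.logpmf(k, n, fit.alphas[j], fit.betas[j])
        for j in range(fit.n_components)
    ])
    resp = np.exp(logr - logsumexp(logr, axis=0))  # (components, genes)

    out = []
    for K in thresholds:
        if K <= 0:
            prob = np.ones(len(k))
        else:
            prob = np.zeros(len(k))
            already = k >= K
            prob[already] = 1.0
            todo = ~already
            if m > 0 and todo.any():
                kt = k[todo]
                need = K - kt  # >= 1
                acc = np.zeros(todo.sum())
                for j in range(fit.n_components):
                    acc += resp[j, todo] * betabinom.sf(
                        need - 1, m, fit.alphas[j] + kt, fit.betas[j] + n - kt)
                prob[todo] = acc
        out.append(SaturationProjection(target_n, K, float(prob.sum()), prob))
    return out


# ---------------------------------------------------------------------------
# Logistic accuracy curves
# ---------------------------------------------------------------------------

def _curve2(logn: np.ndarray, a: float, b: float) -> np.ndarray:
    return expit(a + b * logn)


def _curve3(logn: np.ndarray, a: float, b: float, c: float) -> np.ndarray:
    return c * expit(a + b * logn)


def fit_logistic_curve(points: pd.DataFrame, model: str = "3p"
                       ) -> LogisticCurveFit:
    """Nonlinear least squares of r2 on log(panel size).

    `points` columns: n, r2.  The two-parameter model fixes the asymptote c
    at 1; the three-parameter model constrains c <= 1.
    """
    n = points["n"].to_numpy(dtype=float)
    r2 = points["r2"].to_numpy(dtype=float)
    if (n <= 0).any():
        raise ValueError("panel sizes must be positive")
    min_pts = 3 if model == "2p" else 4
    if len(n) < min_pts:
        raise ValueError(f"{model} fit needs >= {min_pts} points")
    logn = np.log(n)

    b0 = 1.0
    a0 = -b0 * np.median(logn)
    try:
        if model == "2p":
            popt, pcov = optimize.curve_fit(_curve2, logn, r2, p0=[a0, b0],
                                            maxfev=20000)
            a, b = popt
            c = 1.0
        elif model == "3p":
            c0 = min(max(r2.max(), 0.05), 1.0)
            popt, pcov = optimize.curve_fit(
                _curve3, logn, r2, p0=[a0, b0, c0],
                bounds=([-np.inf, -np.inf, 1e-6], [np.inf, np.inf, 1.0]),
                ftol=1e-14, xtol=1e-14, gtol=1e-14, maxfev=20000)
            a, b, c = popt
        else:
            raise ValueError(f"unknown model {model!r}")
    except RuntimeError as exc:
        raise RuntimeError(f"logistic-curve fit failed: {exc}") from exc
    if not np.all(np.isfinite(pcov)):
        raise RuntimeError("singular Jacobian in logistic-curve fit; "
                           f"parameters at failure: a={a}, b={b}, c={c}")
    return LogisticCurveFit(model=model, a=float(a), b=float(b), c=float(c),
                            cov=pcov, n=n, r2=r2)


def extrapolate_r2(fit: LogisticCurveFit, target_n: float,
                   confidence: float = 0.95) -> dict:
    """Predicted r2 at a target panel size with a delta-method CI.

    The CI is computed on the untransformed r2 scale and truncated to [0, 1].
    """
    if target_n <= 0:
        raise ValueError("target panel size must be positive")
    logn = np.log(float(target_n))
    s = expit(fit.a + fit.b * logn)
    pred = fit.c * s
    ds = s * (1.0 - s)
    if fit.model == "2p":
        grad = np.array([ds, ds * logn])
    else:
        grad = np.array([fit.c * ds, fit.c * ds * logn, s])
    var = float(grad @ fit.cov @ grad)
    z = norm.ppf(0.5 + confidence / 2.0)
    half = z * np.sqrt(max(var, 0.0))
    return {
        "r2": float(pred),
        "ci": (float(np.clip(pred - half, 0.0, 1.0)),
               float(np.clip(pred + half, 0.0, 1.0))),
        "se": float(np.sqrt(max(var, 0.0))),
    }
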