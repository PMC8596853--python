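"""GWAS-locus machinery: sentinel pruning, gene-set assignment, enrichment.

Per trait, genes are partitioned into an in-set (near a pruned GWAS sentinel,
by a distance- or nearest-rank rule) and an out-set, and the 2x2 table
(a, b, c, d) of significant / non-significant burden genes inside / outside
the set gives a fold enrichment (a/b)/(c/d).  Trait strata are combined with
the Mantel-Haenszel estimator (chi-square test, Robins-Breslow-Greenland CI).
Also here: the expected-by-chance overlap count p x k, generic 2x2 odds
ratios with Fisher exact p, genetic-correlation-based trait-to-disease
matching, and the four-step protective-association screen.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "EnrichmentStratum",
    "ChanceExpectation",
    "TraitDiseaseMatch",
    "prune_signals",
    "assign_gene_set",
    "enrichment_fold",
    "mantel_haenszel",
    "expected_by_chance",
    "two_by_two_or",
    "match_trait_to_disease",
    "screen_protective",
]

PRUNE_SEPARATION = 10_000_000  # bp


@dataclass(frozen=True)
class EnrichmentStratum:
    """Per-trait 2x2 gene counts: a/b in-window with/without a significant
    burden signal, c/d out-of-window with/without."""

    trait_id: str
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("stratum counts must be non-negative")


@dataclass(frozen=True)
class ChanceExpectation:
    a_sig: int
    n_tests: int
    k_tests: int
    p_hat: float
    expected: float


@dataclass(frozen=True)
class TraitDiseaseMatch:
    trait_id: str
    disease_id: str | None
    rg: float | None
    rg_p: float | None
    bonferroni_denominator: int


# ---------------------------------------------------------------------------
# Sentinel pruning and gene-set assignment
# ---------------------------------------------------------------------------

def prune_signals(signals: pd.DataFrame,
                  min_separation: int = PRUNE_SEPARATION) -> pd.DataFrame:
    """Greedy per-trait pruning by ascending p-value: a signal within
    `min_separation` bp of an already-kept signal on the same chromosome is
    dropped, so kept signals are more than `min_separation` apart."""
    kept_rows = []
    for trait_id, sub in signals.groupby("trait_id", sort=False):
        sub = sub.sort_values("pvalue", kind="mergesort")
        kept: dict[str, list[int]] = {}
        for _, row in sub.iterrows():
            positions = kept.setdefault(str(row["chrom"]), [])
            if all(abs(int(row["pos"]) - q) > min_separation for q in positions):
                positions.append(int(row["pos"]))
                kept_rows.append(row)
    out = pd.DataFrame(kept_rows)
    return out.reset_index(drop=True) if len(out) else signals.iloc[:0].copy()


def _gene_distance(pos: int, start: np.ndarray, end: np.ndarray) -> np.ndarray:
    """Min base-pair distance from a position to closed gene intervals
    (0 if inside)."""
    return np.maximum(0, np.maximum(start - pos, pos - end))


def assign_gene_set(genes: pd.DataFrame, pruned_signals: pd.DataFrame,
                    rule: str | tuple[str, int | float]) -> dict[str, set[str]]:
    """Per-trait in-sets of genes under a rule.

    ``rule`` is ``("within", d_bp)``, ``("nth_nearest", k)`` (the k nearest
    genes per signal) or ``"nearest"`` (= k of 1).  The in-set is the union
    across a trait's signals; genes on chromosomes with no signal stay out.
    """
    if rule == "nearest":
        rule = ("nth_nearest", 1)
    kind, param = rule
    if kind not in ("within", "nth_nearest"):
        raise ValueError(f"unknown gene-set rule {kind!r}")

    out: dict[str, set[str]] = {}
    gid = genes["gene_id"].to_numpy()
    for trait_id, sub in pruned_signals.groupby("trait_id", sort=False):
        in_set: set[str] = set()
        for _, sig in sub.iterrows():
            on_chrom = genes["chrom"].astype(str) == str(sig["chrom"])
            if not on_chrom.any():
                continue
            g = genes.loc[on_chrom]
            dist = _gene_distance(int(sig["pos"]),
                                  g["start"].to_numpy(), g["end"].to_numpy())
            if kind == "within":
                in_set.update(gid[on_chrom.to_numpy()][dist <= param])
            else:
                order = np.lexsort((g["start"].to_numpy(), dist))
                in_set.update(gid[on_chrom.to_numpy()][order[: int(param)]])
        out[str(trait_id)] = in_set
    return out


# ---------------------------------------------------------------------------
# Enrichment
# ---------------------------------------------------------------------------

def enrichment_fold(stratum: EnrichmentStratum) -> tuple[float, bool]:
    """(a/b)/(c/d); returns ``(fold, defined)``.  b = 0 or c = 0 leaves the
    fold undefined (nan, False) — no continuity correction is applied."""
    if stratum.b == 0 or stratum.c == 0:
        return float("nan"), False
    return (stratum.a / stratum.b) / (stratum.c / stratum.d), True


def mantel_haenszel(strata: list[EnrichmentStratum],
                    continuity_correction: bool = False) -> dict:
    """Mantel-Haenszel combined odds ratio over trait strata.

    Returns the pooled OR (sum a_i d_i / n_i over sum b_i c_i / n_i), the
    1-df MH chi-square (uncorrected by default) with p-value, and the 95%
    Robins-Breslow-Greenland CI.
    """
    from statsmodels.stats.contingency_tables import StratifiedTable

    tables = [np.array([[s.a, s.b], [s.c, s.d]], dtype=float) for s in strata
              if (s.a + s.b) > 0 and (s.c + s.d) > 0]
    if not tables:
        raise ValueError("all strata are degenerate")
    st = StratifiedTable(tables)
    test = st.test_null_odds(correction=continuity_correction)
    lo, hi = st.oddsratio_pooled_confint(alpha=0.05)
    return {
        "or_mh": float(st.oddsratio_pooled),
        "chi2": float(test.statistic),
        "p": float(test.pvalue),
        "ci95": (float(lo), float(hi)),
        "n_strata": len(tables),
    }


def _round_sig(x: float, digits: int) -> float:
    if x == 0:
        return 0.0
    return float(f"{x:.{digits}g}")


def expected_by_chance(a_sig: int, n_tests: int, k_tests: int,
                       rounding: int | None = None) -> ChanceExpectation:
    """Expected significant associations among k in-window tests: p_hat x k.

    `rounding` optionally rounds p_hat to that many significant figures
    before multiplying (off by default; 3 reproduces printed arithmetic that
    reports p_hat to 3 significant figures).
    """
    if a_sig > n_tests:
        raise ValueError("a_sig cannot exceed n_tests")
    p_hat = a_sig / n_tests
    if rounding is not None:
        p_hat = _round_sig(p_hat, rounding)
    return ChanceExpectation(a_sig, n_tests, k_tests, p_hat, p_hat * k_tests)


def two_by_two_or(table: np.ndarray | list) -> dict:
    """Sample odds ratio and two-sided Fisher exact p for a 2x2 table."""
    t = np.asarray(table, dtype=float).reshape(2, 2)
    if (t < 0).any():
        raise ValueError("table counts must be non-negative")
    denom = t[0, 1] * t[1, 0]
    if denom == 0:
        or_, defined = float("nan"), False
    else:
        or_, defined = (t[0, 0] * t[1, 1]) / denom, True
    _, p = sps.fisher_exact(t.astype(int), alternative="two-sided")
    return {"or": or_, "or_defined": defined, "fisher_p": float(p)}


# ---------------------------------------------------------------------------
# Trait-disease matching and the protective screen
# ---------------------------------------------------------------------------

def match_trait_to_disease(rg_table: pd.DataFrame, denominator: int = 357,
                           alpha: float = 0.05) -> list[TraitDiseaseMatch]:
    """Match each quantitative trait to the disease with the most significant
    genetic correlation, among those Bonferroni-significant at
    alpha / denominator; none if no disease passes.

    `rg_table` columns: trait_id, disease_id, rg, rg_p.
    """
    threshold = alpha / denominator
    out = []
    for trait_id, sub in rg_table.groupby("trait_id", sort=False):
        passing = sub[sub["rg_p"] < threshold]
        if len(passing) == 0:
            out.append(TraitDiseaseMatch(str(trait_id), None, None, None,
                                         denominator))
        else:
            best = passing.loc[passing["rg_p"].idxmin()]
            out.append(TraitDiseaseMatch(str(trait_id), str(best["disease_id"]),
                                         float(best["rg"]), float(best["rg_p"]),
                                         denominator))
    return out


@dataclass
class ProtectiveScreenResult:
    candidates: pd.DataFrame
    surviving_counts: dict[str, int] = field(default_factory=dict)


def screen_protective(
    quantitative_results: pd.DataFrame,
    beneficial_direction: dict[str, int],
    matches: list[TraitDiseaseMatch],
    disease_results: pd.DataFrame,
    alpha: float = 0.05 / 129,
) -> ProtectiveScreenResult:
    """Four-step screen for protective candidates.

    Steps: (1) trait has a known beneficial direction (+1 trait-raising /
    -1 trait-lowering is good); (2) the gene's quantitative effect is in the
    favourable direction; (3) the trait has a matched, genetically correlated
    disease; (4) the gene's association with that disease is protective
    (log-OR < 0) at `alpha`.

    `quantitative_results` columns: gene_id, trait_id, effect, p;
    `disease_results` columns: gene_id, disease_id, effect (log-OR), p.
    """
    match_of = {m.trait_id: m.disease_id for m in matches}
    counts = {}
    q = quantitative_results.copy()

    q = q[q["trait_id"].isin(beneficial_direction)]
    counts["known_direction"] = len(q)

    direc = q["trait_id"].map(beneficial_direction)
    q = q[np.sign(q["effect"]) == direc]
    counts["favourable_effect"] = len(q)

    q = q[q["trait_id"].map(lambda t: match_of.get(t) is not None)]
    counts["matched_disease"] = len(q)

    d_index = disease_results.set_index(["gene_id", "disease_id"])
    keep = []
    for _, row in q.iterrows():
        disease = match_of.get(row["trait_id"])
        if disease is None:
            continue
        key = (row["gene_id"], disease)
        if key in d_index.index:
            dr = d_index.loc[key]
            if float(dr["effect"]) < 0 and float(dr["p"]) < alpha:
                keep.append({**row.to_dict(), "disease_id": disease,
                             "disease_effect": float(dr["effect"]),
                             "disease_p": float(dr["p"])})
    out = pd.DataFrame(keep)
    counts["protective"] = len(out)
    return ProtectiveScreenResult(out, counts)
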