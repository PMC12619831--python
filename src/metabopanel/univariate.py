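"""Group-wise descriptive statistics and nonparametric testing.

Two-group contrasts use the Mann-Whitney U test, three-group comparisons the
Kruskal-Wallis test, both with average-rank tie handling (scipy). Multiple
testing across a metabolite family is controlled by Benjamini-Hochberg FDR.
Metabolite-covariate association (e.g. uremic toxin vs GFR) uses Spearman
rank correlation, with an exact permutation p-value at very small n.
Clinical tables are summarized per group with a D'Agostino-Pearson normality
check deciding mean±sd vs median[IQR] display.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .preprocess import ProcessedMatrix


@dataclass
class GroupTestResult:
    metabolite_id: str
    test_name: str
    statistic: float
    p_value: float
    q_value: float
    direction: int = 0  # sign of median(group_b) - median(group_a)


@dataclass
class CorrelationResult:
    metabolite_id: str
    covariate: str
    rho: float
    p_value: float


def _frame(matrix) -> pd.DataFrame:
    if isinstance(matrix, ProcessedMatrix):
        return matrix.values
    if isinstance(matrix, pd.DataFrame):
        return matrix
    raise TypeError("expected ProcessedMatrix or DataFrame")


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def test_two_groups(matrix, labels: pd.Series, groups: tuple[str, str]) -> list[GroupTestResult]:
    """Per-metabolite two-sided Mann-Whitney U between ``groups``, with BH
    q-values computed across all tested metabolites (one family)."""
    x = _frame(matrix)
    labels = pd.Series(labels).reindex(x.index)
    a, b = groups
    ia = labels.index[labels == a]
    ib = labels.index[labels == b]
    if len(ia) < 2 or len(ib) < 2:
        raise ValueError(f"each of {groups} needs >= 2 samples")
    xa, xb = x.loc[ia], x.loc[ib]
    results = []
    for m in x.columns:
        res = stats.mannwhitneyu(xa[m], xb[m], alternative="two-sided")
        direction = int(np.sign(np.median(xb[m]) - np.median(xa[m])))
        results.append(
            GroupTestResult(m, "mann_whitney_u", float(res.statistic),
                            float(res.pvalue), np.nan, direction)
        )
    q = bh_fdr([r.p_value for r in results])
    for r, qv in zip(results, q):
        r.q_value = float(qv)
    return results


def _kw_h(rank_sums: np.ndarray, sizes: np.ndarray, n: int, tie_factor: float) -> float:
    h = 12.0 / (n * (n + 1)) * float((rank_sums**2 / sizes).sum()) - 3 * (n + 1)
    return h / tie_factor if tie_factor > 0 else 0.0


def kruskal_exact_p(samples, max_enumeration: int = 200_000) -> float | None:
    """Exact permutation p-value for the Kruskal-Wallis H statistic by
    exhaustive enumeration of distinct group assignments (average ranks,
    tie-corrected). Returns None when the assignment count exceeds
    ``max_enumeration``."""
    import itertools
    from math import comb

    sizes = np.array([len(s) for s in samples])
    n = int(sizes.sum())
    count = 1
    rem = n
    for k in sizes[:-1]:
        count *= comb(rem, int(k))
        rem -= int(k)
    if count > max_enumeration:
        return None
    pooled = np.concatenate([np.asarray(s, dtype=float) for s in samples])
    ranks = stats.rankdata(pooled)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_factor = 1.0 - float((tie_counts**3 - tie_counts).sum()) / (n**3 - n)
    obs_sums = np.array([
        ranks[start:start + k].sum()
        for start, k in zip(np.cumsum([0, *sizes[:-1]]), sizes)
    ])
    h_obs = _kw_h(obs_sums, sizes, n, tie_factor)

    def assignments(indices, remaining_sizes):
        if len(remaining_sizes) == 1:
            yield (tuple(indices),)
            return
        k = remaining_sizes[0]
        for chosen in itertools.combinations(indices, k):
            rest = [i for i in indices if i not in set(chosen)]
            for tail in assignments(rest, remaining_sizes[1:]):
                yield (chosen, *tail)

    ge = 0
    for groups in assignments(list(range(n)), list(sizes)):
        sums = np.array([ranks[list(g)].sum() for g in groups])
        ge += _kw_h(sums, sizes, n, tie_factor) >= h_obs - 1e-12
    return ge / count


def test_k_groups(matrix, labels: pd.Series, exact: bool = False) -> list[GroupTestResult]:
    """Per-metabolite Kruskal-Wallis across all label groups, BH-corrected.

    ``exact=True`` replaces the chi-square approximation with the exhaustive
    permutation p-value when the group sizes permit enumeration.
    """
    x = _frame(matrix)
    labels = pd.Series(labels).reindex(x.index)
    group_names = [g for g in labels.unique() if pd.notna(g)]
    if len(group_names) < 2:
        raise ValueError("need >= 2 groups")
    idx = [labels.index[labels == g] for g in group_names]
    results = []
    for m in x.columns:
        samples = [x.loc[i, m].to_numpy() for i in idx]
        pooled = np.concatenate(samples)
        if np.all(pooled == pooled[0]):
            stat, p = 0.0, 1.0
        else:
            stat, p = stats.kruskal(*samples)
            if exact:
                p_exact = kruskal_exact_p(samples)
                if p_exact is not None:
                    p = p_exact
        results.append(GroupTestResult(m, "kruskal_wallis", float(stat), float(p), np.nan))
    q = bh_fdr([r.p_value for r in results])
    for r, qv in zip(results, q):
        r.q_value = float(qv)
    return results


def _spearman_exact_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exact permutation two-sided p for Spearman rho at n < 10 by full
    enumeration of rank pairings."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    if denom == 0:
        return 0.0, 1.0
    rho = float(rx @ ry / denom)
    n = len(x)
    perms = np.array(list(itertools.permutations(range(n))))
    rho_perm = (rx[perms] @ ry) / denom
    p = float(np.mean(np.abs(rho_perm) >= abs(rho) - 1e-12))
    return rho, p


def correlate_with_covariate(matrix, covariate: pd.Series,
                             method: str = "spearman") -> list[CorrelationResult]:
    """Spearman correlation of every metabolite with a clinical covariate.

    p-values come from the t approximation for n >= 10 and from exact
    permutation enumeration for n < 10.
    """
    if method != "spearman":
        raise ValueError("only spearman correlation is supported")
    x = _frame(matrix)
    cov = pd.Series(covariate).reindex(x.index)
    if cov.isna().any() or not np.all(np.isfinite(cov.to_numpy(dtype=float))):
        raise ValueError("covariate must be finite for all samples")
    n = len(cov)
    name = cov.name if cov.name is not None else "covariate"
    results = []
    for m in x.columns:
        if n < 10:
            rho, p = _spearman_exact_p(x[m].to_numpy(), cov.to_numpy(dtype=float))
        else:
            r = stats.spearmanr(x[m], cov)
            rho, p = float(r.statistic), float(r.pvalue)
        results.append(CorrelationResult(m, str(name), rho, p))
    return results


def chi2_trend(outcome: pd.Series, ordered_groups: pd.Series) -> tuple[float, float]:
    """Chi-square test for linear trend (linear-by-linear association) of a
    binary outcome across ordered groups: chi2 = (N-1) * r^2 on 1 df."""
    y = pd.Series(outcome).astype(float).to_numpy()
    order = {g: i for i, g in enumerate(pd.Series(ordered_groups).unique())}
    score = pd.Series(ordered_groups).map(order).to_numpy(dtype=float)
    n = len(y)
    if n < 2 or np.std(y) == 0 or np.std(score) == 0:
        return 0.0, 1.0
    r = np.corrcoef(score, y)[0, 1]
    chi2 = (n - 1) * r**2
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def summarize_clinical(metadata) -> pd.DataFrame:
    """Long-form clinical summary table.

    Numeric variables: per-group n/mean/sd/median/IQR, a D'Agostino-Pearson
    normality flag choosing the display style, and a Kruskal-Wallis p.
    Categorical variables: per-group counts and percentages with a chi-square
    test for trend (first category treated as the outcome).
    """
    from .synthetic_data import SampleMetadata

    table = metadata.table if isinstance(metadata, SampleMetadata) else metadata
    if "group" not in table.columns:
        raise ValueError("metadata must contain a 'group' column")
    groups = [g for g in table["group"].unique()]
    rows = []
    for var in [c for c in table.columns if c != "group"]:
        col = table[var]
        if pd.api.types.is_numeric_dtype(col):
            vals_by_g = [col[table["group"] == g].dropna() for g in groups]
            if all(len(v) == 0 for v in vals_by_g):
                rows.append({"variable": var, "group": "all", "kind": "numeric",
                             "p_value": np.nan, "test_name": "NA"})
                continue
            nonconstant = [v.to_numpy() for v in vals_by_g if len(v) > 1]
            pooled = col.dropna().to_numpy()
            if len(groups) > 1 and len(nonconstant) == len(groups) and np.ptp(pooled) > 0:
                _, p = stats.kruskal(*[v.to_numpy() for v in vals_by_g])
            else:
                p = np.nan
            normal = True
            if len(pooled) >= 20 and np.ptp(pooled) > 0:
                normal = stats.normaltest(pooled).pvalue >= 0.05
            for g, v in zip(groups, vals_by_g):
                q1, med, q3 = (np.percentile(v, [25, 50, 75]) if len(v) else
                               (np.nan, np.nan, np.nan))
                rows.append({
                    "variable": var, "group": g, "kind": "numeric",
                    "n": len(v),
                    "mean": float(v.mean()) if len(v) else np.nan,
                    "sd": float(v.std(ddof=1)) if len(v) > 1 else (0.0 if len(v) else np.nan),
                    "median": med, "iqr_low": q1, "iqr_high": q3,
                    "display": "mean_sd" if normal else "median_iqr",
                    "p_value": p, "test_name": "kruskal_wallis",
                })
        else:
            cats = col.astype(str)
            first = sorted(cats.unique())[0]
            stat, p = chi2_trend((cats == first).astype(int), table["group"])
            for g in groups:
                sub = cats[table["group"] == g]
                rows.append({
                    "variable": var, "group": g, "kind": "categorical",
                    "n": len(sub),
                    "count": int((sub == first).sum()),
                    "percent": 100.0 * (sub == first).mean() if len(sub) else np.nan,
                    "category": first,
                    "p_value": p, "test_name": "chi2_trend",
                })
    return pd.DataFrame(rows)


def results_to_frame(results) -> pd.DataFrame:
    """Flatten a list of result dataclasses into a DataFrame."""
    return pd.DataFrame([r.__dict__ for r in results])
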