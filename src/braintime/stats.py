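"""Group statistics: rank-sum tests with BH-FDR and Cohen's d, summary-stat
ANOVA and χ² for cohort tables, robust outlier exclusion, covariate
regression control, correlation families, and w-score normalization."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


@dataclass
class GroupComparison:
    """One feature's two-group comparison (rank-sum, BH-adjusted p, effect size)."""

    feature: str
    statistic: float
    p: float
    p_adj: float
    d: float
    n1: int
    n2: int
    excluded: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p out of range")
        if self.p_adj < self.p - 1e-15 or self.p_adj > 1.0:
            raise ValueError("p_adj must satisfy p <= p_adj <= 1")


class SummaryStats(NamedTuple):
    """Per-group published summary: mean, SD, n."""

    mean: float
    sd: float
    n: int


def ranksum_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact p when the smaller sample has ≤ 8 observations and the pooled
    data has no ties; tie-corrected normal approximation otherwise.
    Returns (U statistic of the first sample, two-sided p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        # all observations identical: no evidence either way
        return float(x.size * y.size / 2.0), 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(x.size, y.size) <= 8 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def cohens_d(x: Sequence[float], y: Sequence[float]) -> float:
    """Cohen's d = (mean(x) - mean(y)) / pooled SD (pooled across groups)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 observations per group")
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    if sp2 == 0:
        raise ValueError("pooled SD is zero")
    return float((x.mean() - y.mean()) / np.sqrt(sp2))


def anova_f_from_summary(g1: SummaryStats, g2: SummaryStats) -> tuple[float, float]:
    """One-way ANOVA F (and p) for two groups from published mean/SD/n.

    For two groups F = t² of the pooled-variance t-test, with
    df = (1, n1 + n2 - 2); this lets printed demographic tables be checked
    without raw data.
    """
    n1, n2 = g1.n, g2.n
    if min(n1, n2) < 2:
        raise ValueError("need n >= 2 per group")
    sp2 = ((n1 - 1) * g1.sd**2 + (n2 - 1) * g2.sd**2) / (n1 + n2 - 2)
    if sp2 == 0:
        raise ValueError("both group SDs are zero")
    t = (g1.mean - g2.mean) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    F = float(t * t)
    p = float(sps.f.sf(F, 1, n1 + n2 - 2))
    return F, p


def chi2_2x2(table: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Pearson χ² on a 2×2 contingency table, no continuity correction, 1 df."""
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2):
        raise ValueError("expected a 2×2 table")
    if np.any(arr < 0):
        raise ValueError("counts must be nonnegative")
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValueError("zero margin")
    chi2, p, _, _ = sps.chi2_contingency(arr, correction=False)
    return float(chi2), float(p)


class MadResult(NamedTuple):
    kept: np.ndarray
    excluded: np.ndarray
    mask: np.ndarray  # True = kept


def mad_exclude(values: Sequence[float], k: float = 3.0,
                exclude_on_zero_mad: bool = False) -> MadResult:
    """Exclude values more than ``k`` scaled MADs from the median.

    Scaled MAD = 1.4826·median(|v - median|) (normal-consistent). When the
    MAD is zero the rule is degenerate: by default everything is kept with
    a warning; with ``exclude_on_zero_mad`` any value off the median goes.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError("need at least 3 values")
    med = np.median(v)
    smad = 1.4826 * np.median(np.abs(v - med))
    if smad == 0:
        if exclude_on_zero_mad:
            mask = v == med
        else:
            if np.ptp(v) > 0:
                warnings.warn("scaled MAD is zero; no values excluded")
            mask = np.ones(v.size, dtype=bool)
    else:
        mask = np.abs(v - med) <= k * smad
    return MadResult(kept=v[mask], excluded=v[~mask], mask=mask)


def covariate_adjust(feature: Sequence[float], covariates: pd.DataFrame) -> np.ndarray:
    """OLS residuals of a feature on intercept + covariates.

    The residuals carry the group comparison downstream, removing linear
    demographic confounds (age and education by default in the pipeline).
    """
    y = np.asarray(feature, dtype=float)
    X = sm.add_constant(np.asarray(covariates, dtype=float))
    if y.size <= X.shape[1]:
        raise ValueError("need n > number of covariates + 1")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    return np.asarray(sm.OLS(y, X).fit().resid)


def correlate_with_fdr(
    x: pd.DataFrame,
    y: pd.DataFrame,
    pairs: Sequence[tuple[str, str]],
) -> pd.DataFrame:
    """Pearson correlations for named column pairs, BH-adjusted as one family.

    Returns a DataFrame (x, y, n, r, p, p_adj), one row per requested pair.
    """
    rows = []
    for xc, yc in pairs:
        a = np.asarray(x[xc], dtype=float)
        b = np.asarray(y[yc], dtype=float)
        ok = np.isfinite(a) & np.isfinite(b)
        a, b = a[ok], b[ok]
        if a.size < 4:
            raise ValueError(f"pair ({xc}, {yc}): need at least 4 paired observations")
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            raise ValueError(f"pair ({xc}, {yc}): constant input")
        r, p = sps.pearsonr(a, b)
        rows.append({"x": xc, "y": yc, "n": int(a.size), "r": float(r), "p": float(p)})
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_fdr(out["p"].to_numpy())
    return out


def wscore(
    observed: Sequence[float],
    covariates: pd.DataFrame,
    normative_mask: Sequence[bool],
) -> np.ndarray:
    """Covariate-adjusted w-scores against a normative (control) group.

    An OLS of observed on intercept + covariates is fitted on the normative
    subjects only; every subject's w is (observed - predicted) / SD of the
    normative residuals. w = 0 on the normative regression line, w = 1 one
    normative-residual SD above it.
    """
    y = np.asarray(observed, dtype=float)
    mask = np.asarray(normative_mask, dtype=bool)
    X = sm.add_constant(np.asarray(covariates, dtype=float))
    if mask.sum() <= X.shape[1] + 1:
        raise ValueError("normative group too small for the covariate set")
    fit = sm.OLS(y[mask], X[mask]).fit()
    resid_sd = float(np.std(fit.resid, ddof=X.shape[1]))
    if resid_sd == 0:
        raise ValueError("normative residual SD is zero")
    predicted = X @ fit.params
    return (y - predicted) / resid_sd


def compare_groups(
    values: Sequence[float],
    groups: Sequence[str],
    feature: str,
    group_a: str = "HC",
    group_b: str = "AD",
    mad_k: float | None = 3.0,
) -> GroupComparison:
    """Rank-sum comparison of one feature between two groups.

    MAD-based outlier exclusion (per group pooled family: exclusion is
    applied to each group separately) runs before testing when ``mad_k``
    is set. ``p_adj`` is initialized to p; families are adjusted jointly
    by the caller via `adjust_family`.
    """
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    a = v[g == group_a]
    b = v[g == group_b]
    excluded = 0
    if mad_k is not None and a.size >= 3 and b.size >= 3:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ra = mad_exclude(a, k=mad_k)
            rb = mad_exclude(b, k=mad_k)
        excluded = int(ra.excluded.size + rb.excluded.size)
        a, b = ra.kept, rb.kept
    stat, p = ranksum_test(a, b)
    d = cohens_d(a, b)
    return GroupComparison(feature=feature, statistic=stat, p=p, p_adj=p,
                           d=d, n1=int(a.size), n2=int(b.size), excluded=excluded)


def adjust_family(comparisons: list[GroupComparison]) -> list[GroupComparison]:
    """BH-adjust p-values across one family of comparisons, in place."""
    if not comparisons:
        return comparisons
    adj = bh_fdr([c.p for c in comparisons])
    for c, pa in zip(comparisons, adj):
        c.p_adj = float(pa)
    return comparisons
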