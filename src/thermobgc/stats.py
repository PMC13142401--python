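"""Univariate statistics: Shannon diversity, rank-based group tests with
multiplicity corrections, and per-sample novelty regressions.

Shannon diversity uses natural logarithms (nats).  The Kruskal--Wallis H
statistic, Dunn's post-hoc z, and the Wilcoxon rank-sum test are computed
from explicit rank formulas with tie corrections; the Wilcoxon test is
exact (full assignment enumeration over mid-ranks) for small pooled sizes
and switches to the tie- and continuity-corrected normal approximation
above ``exact_max_n``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps

from thermobgc.ordination import TestResult

logger = logging.getLogger("thermobgc.stats")

EXACT_MAX_N = 20

SIGNIFICANCE_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_stars(p: float) -> str:
    for thr, stars in SIGNIFICANCE_THRESHOLDS:
        if p < thr:
            return stars
    return ""


def shannon(counts) -> float:
    """Shannon diversity H = -sum p_i ln p_i (natural log)."""
    c = np.asarray(counts, dtype=float)
    if (c < 0).any():
        raise ValueError("negative counts")
    total = c.sum()
    if total == 0:
        raise ValueError("all-zero count vector")
    p = c[c > 0] / total
    return float(-(p * np.log(p)).sum())


def _tie_term(ranks_source: np.ndarray) -> float:
    """sum(t^3 - t) over tie groups of the pooled values."""
    _, counts = np.unique(ranks_source, return_counts=True)
    return float((counts**3 - counts).sum())


def kruskal_wallis(values, groups) -> TestResult:
    """Tie-corrected Kruskal--Wallis H with chi-square p (g - 1 df).

    All-identical values make the statistic undefined; reported as a
    degenerate result (NaN statistic, p = 1).
    """
    v = np.asarray(values, dtype=float)
    g = np.asarray(pd.Series(groups).astype(str))
    labels = np.unique(g)
    if len(labels) < 2:
        raise ValueError("need >= 2 groups")
    if any((g == lab).sum() == 0 for lab in labels):
        raise ValueError("empty group")
    N = len(v)
    ranks = sps.rankdata(v)
    if np.ptp(v) == 0:
        return TestResult("KW chi2", float("nan"), 1.0, note="degenerate: all values identical")
    h = 12.0 / (N * (N + 1)) * sum(
        (g == lab).sum() * (ranks[g == lab].mean() - (N + 1) / 2) ** 2 for lab in labels
    )
    correction = 1.0 - _tie_term(v) / (N**3 - N)
    h /= correction
    p = float(sps.chi2.sf(h, len(labels) - 1))
    return TestResult("KW chi2", float(h), p, df=(len(labels) - 1, 0))


def dunn_posthoc(values, groups, adjust: str = "holm") -> pd.DataFrame:
    """Dunn's pairwise post-hoc comparisons after Kruskal--Wallis.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j))
    with T the tie term; two-sided normal p, adjusted by Holm (default) or
    Benjamini--Hochberg.  Intended after a significant omnibus test (not
    enforced; logged).
    """
    logger.info("dunn_posthoc: run after a significant omnibus test")
    v = np.asarray(values, dtype=float)
    g = np.asarray(pd.Series(groups).astype(str))
    labels = sorted(np.unique(g))
    sizes = {lab: int((g == lab).sum()) for lab in labels}
    if any(n == 0 for n in sizes.values()):
        raise ValueError("empty group")
    N = len(v)
    ranks = sps.rankdata(v)
    mean_rank = {lab: ranks[g == lab].mean() for lab in labels}
    var_term = N * (N + 1) / 12.0 - _tie_term(v) / (12.0 * (N - 1))
    rows = []
    for a, b in combinations(labels, 2):
        se = np.sqrt(var_term * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = 0.0 if se == 0 else (mean_rank[a] - mean_rank[b]) / se
        p = float(2 * sps.norm.sf(abs(z)))
        rows.append((a, b, float(z), p))
    out = pd.DataFrame(rows, columns=["group_a", "group_b", "z", "p_value"])
    out["p_adjusted"] = adjust_pvalues(out["p_value"].to_numpy(), method=adjust)
    out["method"] = adjust
    return out


def _u_statistic(ranks_x: np.ndarray, nx: int, ny: int) -> float:
    return float(ranks_x.sum() - nx * (nx + 1) / 2)


def wilcoxon_rank_sum(x, y, exact_max_n: int = EXACT_MAX_N) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann--Whitney U) test.

    Exact p by full enumeration of rank assignments (mid-ranks under ties)
    when n_x + n_y <= exact_max_n; otherwise the normal approximation with
    tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    nx, ny = len(x), len(y)
    n = nx + ny
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    u = _u_statistic(ranks[:nx], nx, ny)
    mu = nx * ny / 2.0
    if n <= exact_max_n:
        # enumerate every way the x-labels could fall on the pooled mid-ranks
        total = comb(n, nx)
        dev = abs(u - mu)
        hits = 0
        for idx in combinations(range(n), nx):
            u_star = float(ranks[list(idx)].sum() - nx * (nx + 1) / 2)
            if abs(u_star - mu) >= dev - 1e-12:
                hits += 1
        p = min(1.0, hits / total)
        return TestResult("Mann-Whitney U", u, p, note=f"exact, {total} assignments")
    tie = _tie_term(pooled)
    sigma2 = nx * ny / 12.0 * ((n + 1) - tie / (n * (n - 1)))
    if sigma2 <= 0:
        return TestResult("Mann-Whitney U", u, 1.0, note="degenerate: all values tied")
    z = (abs(u - mu) - 0.5) / np.sqrt(sigma2)
    p = float(min(1.0, 2 * sps.norm.sf(max(z, 0.0))))
    return TestResult("Mann-Whitney U", u, p, note="normal approximation")


def adjust_pvalues(p, method: str = "BH") -> np.ndarray:
    """Benjamini--Hochberg (step-up) or Holm (step-down) adjustment.

    Monotonicity is enforced and output clipped to [0, 1].
    """
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must be in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    out = np.empty(m)
    if method.upper() == "BH":
        ranked = p[order] * m / (np.arange(m) + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        out[order] = ranked
    elif method.lower() == "holm":
        ranked = p[order] * (m - np.arange(m))
        ranked = np.maximum.accumulate(ranked)
        out[order] = ranked
    else:
        raise ValueError(f"unknown method {method!r} (use 'BH' or 'holm')")
    return np.clip(out, 0.0, 1.0)


@dataclass
class RegressionFit:
    """Simple OLS fit of a per-sample statistic on one covariate."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int
    covariate: str = ""
    line_x: np.ndarray | None = None
    line_y: np.ndarray | None = None
    ci_low: np.ndarray | None = None
    ci_high: np.ndarray | None = None


def novelty_regression(response: pd.Series, covariate: pd.Series, name: str = "") -> RegressionFit:
    """OLS of per-sample minimum novelty on an environmental covariate.

    Returns slope, intercept, R², the two-sided F-test p (identical to the
    slope t-test for one predictor), and a fitted line with a 95% CI band
    for plotting.  Only samples present in both series enter the fit.
    """
    joined = pd.concat([response, covariate], axis=1, join="inner").dropna()
    if len(joined) < 3:
        raise ValueError("need >= 3 paired observations")
    yv = joined.iloc[:, 0].to_numpy(dtype=float)
    xv = joined.iloc[:, 1].to_numpy(dtype=float)
    if np.ptp(xv) == 0:
        raise ValueError("constant covariate")
    fit = sps.linregress(xv, yv)
    n = len(xv)
    grid = np.linspace(xv.min(), xv.max(), 50)
    pred = fit.intercept + fit.slope * grid
    resid = yv - (fit.intercept + fit.slope * xv)
    s2 = (resid**2).sum() / (n - 2)
    se_mean = np.sqrt(s2 * (1.0 / n + (grid - xv.mean()) ** 2 / ((xv - xv.mean()) ** 2).sum()))
    tcrit = sps.t.ppf(0.975, n - 2)
    return RegressionFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
        n=n,
        covariate=name or str(covariate.name),
        line_x=grid,
        line_y=pred,
        ci_low=pred - tcrit * se_mean,
        ci_high=pred + tcrit * se_mean,
    )


def diversity_table(matrix: pd.DataFrame, class_counts: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-sample Shannon H and richness.

    By default H is computed on per-sample GCF class count vectors
    (``class_counts``: samples x classes counts of detected GCFs); when
    *class_counts* is None it falls back to the presence matrix rows.
    Richness is the count of detected GCFs in the presence matrix.
    """
    source = class_counts if class_counts is not None else matrix
    rows = []
    for s in matrix.index:
        counts = source.loc[s].to_numpy(dtype=float)
        richness = int((matrix.loc[s] > 0).sum())
        h = shannon(counts) if counts.sum() > 0 else float("nan")
        rows.append((s, h, richness))
    return pd.DataFrame(rows, columns=["sample_id", "shannon_H", "richness"]).set_index("sample_id")
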