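"""Multivariate inference on community matrices, from first principles.

Implements depth-conditioned partial redundancy analysis (RDA) with
permutation tests, marginal PERMANOVA via the McArdle--Anderson
partitioning of a Gower-centered distance matrix, ANOSIM, homogeneity of
multivariate dispersion (betadisper-style), variation partitioning with
Ezekiel-adjusted R², and k-means clustering of ordination site scores with
elbow/silhouette k selection.

Because the community matrix is Hellinger-transformed upstream, RDA on the
transformed matrix is equivalent to distance-based RDA (capscale) on
Hellinger--Euclidean distances; the RDA form is implemented here.

Permutation p-values follow p = (1 + #{stat* >= stat}) / (1 + n_permutations).
With conditioning variables present, permutation is of reduced-model
residuals (Freedman--Lane); otherwise plain row permutation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

logger = logging.getLogger("thermobgc.ordination")

DEFAULT_N_PERMUTATIONS = 999
DEFAULT_K_RANGE = (2, 8)


@dataclass
class TestResult:
    """Outcome of one statistical test."""

    name: str
    statistic: float
    p_value: float
    n_permutations: int = 0
    effect_size: float | None = None  # R^2 where defined
    df: tuple[int, int] | None = None
    note: str = ""


@dataclass
class OrdinationResult:
    """Constrained-ordination output.

    Two flavours of site scores are kept: ``site_scores`` (weighted-average,
    "wa": the residualized community matrix projected on the constrained
    axes — residual structure, including technical gradients, remains
    visible there) and ``lc_scores`` (linear combinations of the
    constraints: the fitted positions, the cleaner substrate for clustering
    sites by their constrained signal).
    """

    site_scores: pd.DataFrame
    lc_scores: pd.DataFrame
    eigenvalues: np.ndarray
    r_squared: float
    overall: TestResult
    terms: dict[str, TestResult] = field(default_factory=dict)
    condition_names: list[str] = field(default_factory=list)
    dropped_terms: list[str] = field(default_factory=list)


@dataclass
class PartitionResult:
    """Variation partitioning of Y between two explanatory blocks.

    Fractions are Ezekiel-adjusted R²: ``unique_x1`` [a], ``unique_x2``
    [b], ``shared`` [c], ``residual`` [d] = 1 - a - b - c.
    """

    unique_x1: float
    unique_x2: float
    shared: float
    residual: float
    adj_r2_x1: float
    adj_r2_x2: float
    adj_r2_both: float
    p_unique_x1: float | None = None
    p_unique_x2: float | None = None


@dataclass
class ClusterResult:
    labels: pd.Series
    chosen_k: int
    wss: dict[int, float]
    silhouette: dict[int, float]
    silhouette_best_k: int | None
    rule: str = "elbow (max second difference of log WSS)"
    degenerate: bool = False


# ---------------------------------------------------------------------------
# design-matrix helpers


def design_matrix(table: pd.DataFrame | pd.Series | None) -> tuple[np.ndarray, list[str], list[str]]:
    """Expand a covariate table to a numeric design matrix (no intercept).

    Categorical/object columns become treatment-coded indicator columns
    (first level dropped).  Returns (matrix, column names, term of each
    column) so grouped columns can be tested as one term.
    """
    if table is None:
        return np.empty((0, 0)), [], []
    if isinstance(table, pd.Series):
        table = table.to_frame()
    cols, names, terms = [], [], []
    for name in table.columns:
        col = table[name]
        if col.dtype.kind in "OUSb" or isinstance(col.dtype, pd.CategoricalDtype):
            levels = sorted(pd.unique(col.astype(str)))
            for lev in levels[1:]:
                cols.append((col.astype(str) == lev).to_numpy(float))
                names.append(f"{name}[{lev}]")
                terms.append(str(name))
        else:
            cols.append(col.to_numpy(float))
            names.append(str(name))
            terms.append(str(name))
    mat = np.column_stack(cols) if cols else np.empty((len(table), 0))
    return mat, names, terms


def _drop_collinear(X: np.ndarray, names: list[str], tol: float = 1e-9) -> tuple[np.ndarray, list[str], list[str]]:
    """Greedily drop columns that add no rank (after centering)."""
    keep: list[int] = []
    dropped: list[str] = []
    Xc = X - X.mean(axis=0) if X.size else X
    for j in range(X.shape[1]):
        cand = Xc[:, keep + [j]]
        if np.linalg.matrix_rank(cand, tol=tol) > len(keep):
            keep.append(j)
        else:
            dropped.append(names[j])
    if dropped:
        logger.warning("dropped collinear constraint columns: %s", dropped)
    return X[:, keep], [names[i] for i in keep], dropped


def _hat(X: np.ndarray) -> np.ndarray:
    """Orthogonal-projection (hat) matrix onto the column space of X."""
    if X.size == 0:
        return np.zeros((X.shape[0], X.shape[0]))
    q, r = np.linalg.qr(X)
    rank = (np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(r).max())).sum()
    q = q[:, :rank]
    return q @ q.T


def _with_intercept(n: int, *blocks: np.ndarray) -> np.ndarray:
    parts = [np.ones((n, 1))] + [b for b in blocks if b is not None and b.size]
    return np.hstack(parts)


# ---------------------------------------------------------------------------
# partial RDA


def partial_rda(
    Y: pd.DataFrame,
    X: pd.DataFrame | pd.Series,
    Z: pd.DataFrame | pd.Series | None = None,
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    seed: int = 0,
    by_margin: bool = False,
) -> OrdinationResult:
    """Partial redundancy analysis of Y on X, conditioning on Z.

    Y and X are residualized on [1, Z] by least squares; the constrained
    axes come from the SVD of the fitted values of Y_res on X_res.  Site
    scores are weighted-average (wa) scores, i.e. the residualized community
    matrix projected onto the constrained axes, so technical gradients still
    visible in the community data show up on the axes — which is what the
    depth-conditioning check inspects.  R² = SS(fitted)/SS(Y_res).  The
    overall and optional per-term (marginal) pseudo-F tests use
    Freedman--Lane permutation of reduced-model residuals.
    """
    rng = np.random.default_rng(seed)
    Yv = Y.to_numpy(dtype=float)
    n = Yv.shape[0]
    Xm, all_names, xterms = design_matrix(X)
    Zm, znames, _ = design_matrix(Z)
    # collinear columns are reported (and excluded from the rank) but kept in
    # the design: projections are rank-safe, and a duplicated term must show
    # zero marginal sum of squares rather than silently vanish
    _, _, dropped = _drop_collinear(Xm, all_names)

    Hz = _hat(_with_intercept(n, Zm))
    Yr = Yv - Hz @ Yv
    Xr = Xm - Hz @ Xm if Xm.size else Xm

    Hx = _hat(Xr)
    fitted = Hx @ Yr
    ss_tot = float((Yr**2).sum())
    ss_fit = float((fitted**2).sum())
    ss_res = ss_tot - ss_fit
    r2 = ss_fit / ss_tot if ss_tot > 0 else 0.0

    p_x = np.linalg.matrix_rank(Xr) if Xr.size else 0
    q_z = np.linalg.matrix_rank(_with_intercept(n, Zm)) - 1
    df_res = n - 1 - q_z - p_x

    u, s, vt = np.linalg.svd(fitted, full_matrices=False)
    pos = s > 1e-9 * (s[0] if s.size and s[0] > 0 else 1.0)
    u, s, vt = u[:, pos], s[pos], vt[pos]
    eig = (s**2) / max(n - 1, 1)
    axes = [f"RDA{i + 1}" for i in range(vt.shape[0])]
    site_scores = pd.DataFrame(Yr @ vt.T, index=Y.index, columns=axes)
    lc_scores = pd.DataFrame(u * s, index=Y.index, columns=axes)

    def stat(Yp: np.ndarray) -> float:
        Ypr = Yp - Hz @ Yp
        ssf = float(((Hx @ Ypr) ** 2).sum())
        sst = float((Ypr**2).sum())
        ssr = sst - ssf
        return (ssf / max(p_x, 1)) / (ssr / df_res) if ssr > 0 and df_res > 0 else np.inf

    f_obs = (ss_fit / max(p_x, 1)) / (ss_res / df_res) if ss_res > 0 and df_res > 0 else np.inf
    exceed = 0
    base = Hz @ Yv  # reduced-model (condition-only) fit; Yr are its residuals
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        if stat(base + Yr[perm]) >= f_obs - 1e-12:
            exceed += 1
    p_overall = (1 + exceed) / (1 + n_permutations)
    overall = TestResult(
        name="pseudo-F",
        statistic=f_obs,
        p_value=p_overall,
        n_permutations=n_permutations,
        effect_size=r2,
        df=(p_x, df_res),
    )

    terms: dict[str, TestResult] = {}
    if by_margin:
        for term in dict.fromkeys(xterms):
            other = Xr[:, [i for i, t in enumerate(xterms) if t != term]]
            H_other = _hat(other)
            ss_term = float(((Hx - H_other) @ Yr * Yr).sum())
            df_t = max(np.linalg.matrix_rank(Xr) - np.linalg.matrix_rank(other), 0)
            if df_t == 0:
                terms[term] = TestResult("pseudo-F", 0.0, 1.0, n_permutations, 0.0, (0, df_res),
                                         note="collinear with remaining terms")
                continue
            f_t = (ss_term / df_t) / (ss_res / df_res)
            Y_red = H_other @ Yr
            R_red = Yr - Y_red
            ex = 0
            for _ in range(n_permutations):
                perm = rng.permutation(n)
                Yp = Y_red + R_red[perm]
                Ypr = Yp - Hz @ Yp
                ssf_t = float(((Hx - H_other) @ Ypr * Ypr).sum())
                ssr_p = float((Ypr**2).sum()) - float(((Hx @ Ypr) * Ypr).sum())
                f_p = (ssf_t / df_t) / (ssr_p / df_res) if ssr_p > 0 else np.inf
                if f_p >= f_t - 1e-12:
                    ex += 1
            terms[term] = TestResult(
                name="pseudo-F",
                statistic=f_t,
                p_value=(1 + ex) / (1 + n_permutations),
                n_permutations=n_permutations,
                effect_size=ss_term / ss_tot if ss_tot > 0 else 0.0,
                df=(df_t, df_res),
            )

    return OrdinationResult(
        site_scores=site_scores,
        lc_scores=lc_scores,
        eigenvalues=eig,
        r_squared=r2,
        overall=overall,
        terms=terms,
        condition_names=znames,
        dropped_terms=dropped,
    )


# ---------------------------------------------------------------------------
# PERMANOVA


def gower_center(D: np.ndarray) -> np.ndarray:
    """Gower-centered matrix G = -1/2 J D^2 J with J = I - 11'/n."""
    A = -0.5 * D**2
    return A - A.mean(axis=0) - A.mean(axis=1)[:, None] + A.mean()


def _as_distance(data: pd.DataFrame | np.ndarray, is_distance: bool) -> tuple[np.ndarray, pd.Index | None]:
    if isinstance(data, pd.DataFrame):
        idx = data.index
        arr = data.to_numpy(dtype=float)
    else:
        idx = None
        arr = np.asarray(data, dtype=float)
    if is_distance:
        if arr.shape[0] != arr.shape[1]:
            raise ValueError("distance matrix must be square")
        return arr, idx
    return squareform(pdist(arr, metric="euclidean")), idx


def permanova(
    data: pd.DataFrame | np.ndarray,
    model: pd.DataFrame | pd.Series,
    *,
    is_distance: bool = False,
    by_margin: bool = True,
    condition: pd.DataFrame | pd.Series | None = None,
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    seed: int = 0,
) -> tuple[TestResult, dict[str, TestResult]]:
    """PERMANOVA via McArdle--Anderson partitioning of the Gower matrix.

    *data* is either a raw coordinate matrix (Euclidean distances are
    computed — on Hellinger-transformed profiles this gives the
    Hellinger--Euclidean distance) or a distance matrix
    (``is_distance=True``).  Marginal terms measure the sum of squares of
    each model term given all others.  With a conditioning block the
    permutation scheme is Freedman--Lane on reduced-model residuals of the
    Gower matrix; otherwise plain row/column permutation.

    Returns (overall result, per-term results).
    """
    rng = np.random.default_rng(seed)
    D, _ = _as_distance(data, is_distance)
    n = D.shape[0]
    G = gower_center(D)

    Xm, all_names, xterms = design_matrix(model)
    _drop_collinear(Xm, all_names)  # log collinear columns; keep them (rank-safe)
    Zm, _, _ = design_matrix(condition)

    Hz = _hat(_with_intercept(n, Zm))
    Hfull = _hat(_with_intercept(n, Zm, Xm))
    p_x = int(round(np.trace(Hfull - Hz)))
    df_res = n - int(round(np.trace(Hfull)))
    if df_res <= 0:
        raise ValueError("zero residual degrees of freedom")

    R_full = np.eye(n) - Hfull
    ss_x = float(np.sum((Hfull - Hz) * G))
    ss_res = float(np.sum(R_full * G))
    ss_tot = float(np.sum((np.eye(n) - Hz) * G))
    f_obs = (ss_x / max(p_x, 1)) / (ss_res / df_res)

    def _permute_G(Gr: np.ndarray) -> np.ndarray:
        perm = rng.permutation(n)
        return Gr[np.ix_(perm, perm)]

    has_cond = Zm.size > 0
    G_res = (np.eye(n) - Hz) @ G @ (np.eye(n) - Hz) if has_cond else G
    ex = 0
    for _ in range(n_permutations):
        Gp = _permute_G(G_res)
        ssx_p = float(np.sum((Hfull - Hz) * Gp))
        ssr_p = float(np.sum(R_full * Gp))
        f_p = (ssx_p / max(p_x, 1)) / (ssr_p / df_res) if ssr_p > 0 else np.inf
        if f_p >= f_obs - 1e-12:
            ex += 1
    overall = TestResult(
        name="pseudo-F",
        statistic=f_obs,
        p_value=(1 + ex) / (1 + n_permutations),
        n_permutations=n_permutations,
        effect_size=ss_x / ss_tot if ss_tot > 0 else 0.0,
        df=(p_x, df_res),
    )

    terms: dict[str, TestResult] = {}
    if by_margin and len(dict.fromkeys(xterms)) >= 1:
        for term in dict.fromkeys(xterms):
            other = Xm[:, [i for i, t in enumerate(xterms) if t != term]]
            H_red = _hat(_with_intercept(n, Zm, other))
            df_t = int(round(np.trace(Hfull - H_red)))
            ss_t = float(np.sum((Hfull - H_red) * G))
            if df_t == 0:
                terms[term] = TestResult("pseudo-F", 0.0, 1.0, n_permutations, 0.0, (0, df_res),
                                         note="collinear with remaining terms")
                continue
            f_t = (ss_t / df_t) / (ss_res / df_res)
            G_r = (np.eye(n) - H_red) @ G @ (np.eye(n) - H_red)
            ex_t = 0
            for _ in range(n_permutations):
                perm = rng.permutation(n)
                Gp = G_r[np.ix_(perm, perm)]
                ssx_p = float(np.sum((Hfull - H_red) * Gp))
                ssr_p = float(np.sum(R_full * Gp))
                f_p = (ssx_p / df_t) / (ssr_p / df_res) if ssr_p > 0 else np.inf
                if f_p >= f_t - 1e-12:
                    ex_t += 1
            terms[term] = TestResult(
                name="pseudo-F",
                statistic=f_t,
                p_value=(1 + ex_t) / (1 + n_permutations),
                n_permutations=n_permutations,
                effect_size=ss_t / ss_tot if ss_tot > 0 else 0.0,
                df=(df_t, df_res),
            )
    return overall, terms


# ---------------------------------------------------------------------------
# ANOSIM


def anosim(
    D: pd.DataFrame | np.ndarray,
    groups: pd.Series | np.ndarray,
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    seed: int = 0,
) -> TestResult:
    """ANOSIM R with permutation p.

    R = (mean rank of between-group distances - mean rank of within-group
    distances) / (M / 2) with M = n(n-1)/2; ties are mid-ranked.
    """
    rng = np.random.default_rng(seed)
    Dm, _ = _as_distance(D, is_distance=True)
    g = np.asarray(pd.Series(groups).astype(str))
    labels, counts = np.unique(g, return_counts=True)
    if len(labels) < 2:
        raise ValueError("need >= 2 groups")
    if (counts < 2).any():
        raise ValueError("each group needs >= 2 members")
    n = Dm.shape[0]
    iu = np.triu_indices(n, 1)
    ranks = sps.rankdata(Dm[iu])
    M = n * (n - 1) / 2

    def r_stat(gv: np.ndarray) -> float:
        within = gv[iu[0]] == gv[iu[1]]
        return (ranks[~within].mean() - ranks[within].mean()) / (M / 2)

    r_obs = r_stat(g)
    ex = sum(r_stat(rng.permutation(g)) >= r_obs - 1e-12 for _ in range(n_permutations))
    return TestResult(
        name="ANOSIM R",
        statistic=r_obs,
        p_value=(1 + ex) / (1 + n_permutations),
        n_permutations=n_permutations,
    )


# ---------------------------------------------------------------------------
# multivariate dispersion homogeneity (betadisper-style)


def pcoa_embedding(D: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Principal-coordinate embedding of a distance matrix.

    Returns (real-axis coordinates, imaginary-axis coordinates); the latter
    come from negative eigenvalues of the Gower matrix and enter distance
    computations with a negative sign (imaginary-part correction).
    """
    G = gower_center(np.asarray(D, dtype=float))
    eigval, eigvec = np.linalg.eigh(G)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = 1e-8 * max(abs(eigval[0]), 1.0)
    pos = eigval > tol
    neg = eigval < -tol
    real = eigvec[:, pos] * np.sqrt(eigval[pos])
    imag = eigvec[:, neg] * np.sqrt(-eigval[neg])
    return real, imag


def betadisper(
    D: pd.DataFrame | np.ndarray,
    groups: pd.Series | np.ndarray,
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    seed: int = 0,
) -> tuple[TestResult, pd.Series]:
    """Homogeneity of multivariate dispersion among groups.

    Embeds the distances by principal coordinates, computes each sample's
    distance to its group centroid (squared distances on imaginary axes
    subtract), and tests equality of mean dispersion with a one-way F whose
    null distribution comes from permuting group labels.

    Returns (test result, per-sample distances to group centroid).
    """
    rng = np.random.default_rng(seed)
    Dm, idx = _as_distance(D, is_distance=True)
    g = np.asarray(pd.Series(groups).astype(str))
    labels, counts = np.unique(g, return_counts=True)
    if len(labels) < 2 or (counts < 2).any():
        raise ValueError("need >= 2 groups with >= 2 members each")
    real, imag = pcoa_embedding(Dm)

    def centroid_dists(gv: np.ndarray) -> np.ndarray:
        d = np.empty(len(gv))
        for lab in np.unique(gv):
            m = gv == lab
            dr = real[m] - real[m].mean(axis=0)
            di = imag[m] - imag[m].mean(axis=0) if imag.size else np.zeros((m.sum(), 0))
            d2 = (dr**2).sum(axis=1) - (di**2).sum(axis=1)
            d[m] = np.sqrt(np.clip(d2, 0.0, None))
        return d

    def f_stat(dists: np.ndarray, gv: np.ndarray) -> float:
        grand = dists.mean()
        ssb = sum(m.sum() * (dists[m].mean() - grand) ** 2 for m in (gv == l for l in np.unique(gv)))
        ssw = sum(((dists[gv == l] - dists[gv == l].mean()) ** 2).sum() for l in np.unique(gv))
        k = len(np.unique(gv))
        if ssw <= 0:
            return np.inf if ssb > 0 else 0.0
        return (ssb / (k - 1)) / (ssw / (len(gv) - k))

    d_obs = centroid_dists(g)
    f_obs = f_stat(d_obs, g)
    ex = 0
    for _ in range(n_permutations):
        gp = rng.permutation(g)
        if f_stat(centroid_dists(gp), gp) >= f_obs - 1e-12:
            ex += 1
    dists = pd.Series(d_obs, index=idx if idx is not None else range(len(g)), name="dist_to_centroid")
    return (
        TestResult(
            name="dispersion F",
            statistic=f_obs,
            p_value=(1 + ex) / (1 + n_permutations),
            n_permutations=n_permutations,
            df=(len(labels) - 1, len(g) - len(labels)),
        ),
        dists,
    )


# ---------------------------------------------------------------------------
# variation partitioning


def adjusted_r2(r2: float, n: int, p: int, n_condition: int = 0) -> float:
    """Ezekiel correction, with conditioning df removed from n."""
    ne = n - n_condition
    if ne - p - 1 <= 0:
        raise ValueError("n - p - 1 <= 0: too many predictors for adjusted R^2")
    return 1.0 - (1.0 - r2) * (ne - 1) / (ne - p - 1)


def _block_r2(Yr: np.ndarray, Xr: np.ndarray) -> tuple[float, int]:
    H = _hat(Xr)
    ss_tot = float((Yr**2).sum())
    r2 = float(((H @ Yr) ** 2).sum()) / ss_tot if ss_tot > 0 else 0.0
    return r2, int(np.linalg.matrix_rank(Xr)) if Xr.size else 0


def varpart(
    Y: pd.DataFrame,
    X1: pd.DataFrame | pd.Series,
    X2: pd.DataFrame | pd.Series,
    condition: pd.DataFrame | pd.Series | None = None,
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    seed: int = 0,
) -> PartitionResult:
    """Partition Y's explained variation between blocks X1 and X2.

    All R² are computed in the conditioned space (Y and the blocks
    residualized on [1, condition]), then Ezekiel-adjusted.  Fractions:
    [a] = adjR2(X1+X2) - adjR2(X2), [b] = adjR2(X1+X2) - adjR2(X1),
    [c] = adjR2(X1) + adjR2(X2) - adjR2(X1+X2), [d] = 1 - a - b - c.
    The unique fractions [a] and [b] are tested by Freedman--Lane
    permutation of reduced-model residuals.
    """
    Yv = Y.to_numpy(dtype=float)
    n = Yv.shape[0]
    X1m, n1, _ = design_matrix(X1)
    X2m, n2, _ = design_matrix(X2)
    X1m, _, _ = _drop_collinear(X1m, n1)
    X2m, _, _ = _drop_collinear(X2m, n2)
    Zm, _, _ = design_matrix(condition)
    q = int(np.linalg.matrix_rank(_with_intercept(n, Zm)) - 1)

    Hz = _hat(_with_intercept(n, Zm))
    Yr = Yv - Hz @ Yv
    X1r = X1m - Hz @ X1m if X1m.size else X1m
    X2r = X2m - Hz @ X2m if X2m.size else X2m
    X12r = np.hstack([b for b in (X1r, X2r) if b.size]) if (X1r.size or X2r.size) else np.empty((n, 0))

    r2_1, p1 = _block_r2(Yr, X1r)
    r2_2, p2 = _block_r2(Yr, X2r)
    r2_12, p12 = _block_r2(Yr, X12r)
    a1 = adjusted_r2(r2_1, n, p1, q)
    a2 = adjusted_r2(r2_2, n, p2, q)
    a12 = adjusted_r2(r2_12, n, p12, q)
    a = a12 - a2
    b = a12 - a1
    c = a1 + a2 - a12
    d = 1.0 - a12

    # test unique fraction of each block given the other block (+ condition)
    p_a = _test_block(Yv, X1m, np.hstack([b for b in (Zm, X2m) if b.size]) if (Zm.size or X2m.size) else None,
                      n_permutations, seed)
    p_b = _test_block(Yv, X2m, np.hstack([b for b in (Zm, X1m) if b.size]) if (Zm.size or X1m.size) else None,
                      n_permutations, seed + 1)
    return PartitionResult(
        unique_x1=a, unique_x2=b, shared=c, residual=d,
        adj_r2_x1=a1, adj_r2_x2=a2, adj_r2_both=a12,
        p_unique_x1=p_a, p_unique_x2=p_b,
    )


def _test_block(Yv: np.ndarray, X_test: np.ndarray, cond: np.ndarray | None,
                n_permutations: int, seed: int) -> float:
    """Permutation p for the effect of X_test given a conditioning block."""
    Yf = pd.DataFrame(Yv)
    Xf = pd.DataFrame(X_test, columns=[f"x{i}" for i in range(X_test.shape[1])])
    Zf = None if cond is None or cond.size == 0 else pd.DataFrame(
        cond, columns=[f"z{i}" for i in range(cond.shape[1])]
    )
    return partial_rda(Yf, Xf, Z=Zf, n_permutations=n_permutations, seed=seed).overall.p_value


# ---------------------------------------------------------------------------
# clustering of site scores


def cluster_sites(
    scores: pd.DataFrame,
    k_range: tuple[int, int] = DEFAULT_K_RANGE,
    restarts: int = 20,
    seed: int = 0,
) -> ClusterResult:
    """k-means over ordination site scores with elbow/silhouette k selection.

    WSS is computed for k = 1..k_max with multiple seeded restarts keeping
    the minimal-WSS solution.  The elbow rule picks the k maximizing the
    second difference of log(WSS) within the requested range — the relative
    form, because the absolute WSS drop is always largest at the dominant
    split and would select k-1 whenever cluster separations are uneven,
    whereas the relative drop decelerates exactly past the true k.  Mean
    silhouette per k is reported alongside, as the two criteria can
    disagree — the elbow choice is what the pipeline uses, and both are
    logged.
    """
    X = scores.to_numpy(dtype=float)
    n = X.shape[0]
    k_lo, k_hi = k_range
    if not (2 <= k_lo <= k_hi <= n - 1):
        raise ValueError(f"k_range {k_range} must lie within [2, n-1] = [2, {n - 1}]")
    total_ss = float(((X - X.mean(axis=0)) ** 2).sum())
    if total_ss == 0:
        labels = pd.Series(np.zeros(n, dtype=int), index=scores.index, name="cluster")
        return ClusterResult(labels, k_lo, {k: 0.0 for k in range(1, k_hi + 1)}, {}, None,
                             degenerate=True, rule="degenerate: identical points")
    wss: dict[int, float] = {1: total_ss}
    fits: dict[int, KMeans] = {}
    sil: dict[int, float] = {}
    for k in range(2, k_hi + 1):
        km = KMeans(n_clusters=k, n_init=restarts, random_state=seed + k).fit(X)
        wss[k] = float(km.inertia_)
        fits[k] = km
        if k_lo <= k <= k_hi and len(np.unique(km.labels_)) > 1:
            sil[k] = float(silhouette_score(X, km.labels_))
    candidates = [
        k for k in range(max(2, k_lo), k_hi)
        if k + 1 in wss and k - 1 in wss and wss[k] > 0 and wss[k + 1] > 0
    ]
    if candidates:
        second_diff = {
            k: np.log(wss[k - 1]) - 2 * np.log(wss[k]) + np.log(wss[k + 1]) for k in candidates
        }
        chosen = max(candidates, key=lambda k: (second_diff[k], -k))
    else:
        chosen = k_lo
    sil_best = max(sil, key=sil.get) if sil else None
    logger.info("k-means: elbow k=%d, silhouette-best k=%s", chosen, sil_best)
    labels = pd.Series(fits[chosen].labels_, index=scores.index, name="cluster")
    return ClusterResult(labels, chosen, wss, sil, sil_best)


# ---------------------------------------------------------------------------
# axis vs depth diagnostics


def axis_depth_check(scores: pd.DataFrame, depth: pd.Series) -> pd.DataFrame:
    """Spearman rho (tie-corrected) and p of each ordination axis vs depth.

    Constant axes yield NaN rho with a note.  At least 3 samples required.
    """
    if len(scores) < 3:
        raise ValueError("need >= 3 samples")
    d = depth.reindex(scores.index).to_numpy(dtype=float)
    rows = []
    for ax in scores.columns:
        v = scores[ax].to_numpy(dtype=float)
        if np.ptp(v) == 0 or np.ptp(d) == 0:
            rows.append((ax, np.nan, np.nan, "constant input"))
            continue
        rho, p = sps.spearmanr(v, d)
        rows.append((ax, float(rho), float(p), ""))
    return pd.DataFrame(rows, columns=["axis", "rho", "p_value", "note"]).set_index("axis")
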