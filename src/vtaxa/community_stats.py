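"""Rarefaction, specificity, ordination, Mantel and regression machinery.

These are the occurrence statistics run on VT x category tables: randomized
rarefaction with a hypergeometric closed-form cross-check, endemism /
host-specificity fractions, host-range vs geographic-range regression,
Bray-Curtis dissimilarity, non-metric multidimensional scaling (Kruskal
stress-1, SMACOF-style majorization with isotonic disparities), the Mantel
permutation test, and between-category composition-similarity regressions.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import IsotonicRegression
from skbio import DistanceMatrix

from .occurrence import IncidenceMatrix, SampleMetadata
from .vt_delimit import VTAssignment

logger = logging.getLogger("vtaxa")


@dataclass
class RarefactionCurve:
    depths: np.ndarray
    mean_richness: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    expected: np.ndarray  # hypergeometric closed form, for cross-checking
    mc_se: np.ndarray
    n_iter: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "depth": self.depths,
                "mean_richness": self.mean_richness,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "expected": self.expected,
            }
        )


@dataclass
class OrdinationResult:
    points: np.ndarray  # n x k
    stress: float  # Kruskal stress-1 of the best start
    n_starts: int
    seed: int | None
    converged: bool
    labels: list[str]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"axis{i + 1}" for i in range(self.points.shape[1])]
        return pd.DataFrame(self.points, index=self.labels, columns=cols)


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int
    tail: str


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


# ---------------------------------------------------------------------------
# Rarefaction
# ---------------------------------------------------------------------------

def rarefaction(
    sample_labels: Sequence[str],
    n_iter: int = 1000,
    seed: int | None = None,
    depths: Sequence[int] | None = None,
) -> RarefactionCurve:
    """Expected VT richness at subsample depths, by randomization.

    At each depth n the curve reports the mean and 95 % percentile interval of
    the distinct-label count over ``n_iter`` subsamples without replacement.
    The exact hypergeometric expectation
    E[S_n] = sum_v (1 - C(N-N_v, n) / C(N, n)) is carried alongside.
    """
    labels = np.asarray(sample_labels)
    N = len(labels)
    if N == 0:
        raise ValueError("need at least 1 sequence")
    if depths is None:
        depths = np.arange(1, N + 1)
    depths = np.asarray(sorted(set(int(d) for d in depths)))
    if depths.max() > N or depths.min() < 1:
        raise ValueError("depths must lie in [1, total sequence count]")

    _, inv, cts = np.unique(labels, return_inverse=True, return_counts=True)
    rng = np.random.default_rng(seed)

    # one permutation yields richness at every depth: cumulative count of
    # first occurrences
    rich = np.empty((n_iter, N), dtype=np.int32)
    for it in range(n_iter):
        perm = rng.permutation(N)
        codes = inv[perm]
        seen = np.zeros(len(cts), dtype=bool)
        first = np.empty(N, dtype=bool)
        for pos, c in enumerate(codes):
            first[pos] = not seen[c]
            seen[c] = True
        rich[it] = np.cumsum(first)

    sel = rich[:, depths - 1].astype(float)
    mean = sel.mean(axis=0)
    lo = np.percentile(sel, 2.5, axis=0)
    hi = np.percentile(sel, 97.5, axis=0)
    se = sel.std(axis=0, ddof=1) / np.sqrt(n_iter)

    expected = np.array(
        [
            float(np.sum(1.0 - stats.hypergeom.pmf(0, N, cts, n)))
            for n in depths
        ]
    )
    return RarefactionCurve(
        depths=depths, mean_richness=mean, ci_low=lo, ci_high=hi,
        expected=expected, mc_se=se, n_iter=n_iter,
    )


# ---------------------------------------------------------------------------
# Specificity / endemism
# ---------------------------------------------------------------------------

def specificity(matrix: IncidenceMatrix) -> tuple[float, dict[str, float]]:
    """Endemism fractions from the presence view.

    Overall: fraction of VTs present in exactly one column.  Per column c:
    (VTs present only in c) / (VTs present in c); NaN for empty columns.
    """
    pres = matrix.presence
    occupied = pres.sum(axis=1) > 0
    pres = pres.loc[occupied]
    if pres.empty or pres.shape[1] == 0:
        raise ValueError("empty incidence matrix")
    n_cols_per_vt = pres.sum(axis=1)
    overall = float((n_cols_per_vt == 1).mean())
    per_col: dict[str, float] = {}
    for col in pres.columns:
        in_c = pres[col]
        if in_c.sum() == 0:
            per_col[col] = float("nan")
        else:
            only_c = in_c & (n_cols_per_vt == 1)
            per_col[col] = float(only_c.sum() / in_c.sum())
    return overall, per_col


def host_range_vs_geo(
    assignment: VTAssignment,
    meta: Sequence[SampleMetadata],
    origin: str | None = "root",
) -> RegressionResult:
    """OLS of per-VT location count on host-order count (root sequences)."""
    by_id = {m.seq_id: m for m in meta}
    xs, ys = [], []
    for vt, members in assignment.members.items():
        hosts: set[str] = set()
        locs: set[str] = set()
        for s in members:
            m = by_id.get(s)
            if m is None or (origin is not None and m.origin != origin):
                continue
            hosts.add(m.host_order)
            locs.add(m.location_id)
        if hosts:
            xs.append(len(hosts))
            ys.append(len(locs))
    if len(xs) < 3:
        raise ValueError("need at least 3 VTs with usable metadata")
    return _ols(np.asarray(xs, float), np.asarray(ys, float))


def _ols(x: np.ndarray, y: np.ndarray) -> RegressionResult:
    res = stats.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n=len(x),
    )


# ---------------------------------------------------------------------------
# Bray-Curtis
# ---------------------------------------------------------------------------

def bray_curtis(
    matrix: IncidenceMatrix | pd.DataFrame, by: Literal["rows", "columns"] = "columns"
) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity, BC = 1 - 2 sum(min) / sum(x + y).

    Two all-zero vectors get distance 0 by convention (logged).
    """
    df = matrix.counts if isinstance(matrix, IncidenceMatrix) else matrix
    if (df.values < 0).any():
        raise ValueError("negative entries not allowed")
    if by == "columns":
        df = df.T
    X = df.values.astype(float)
    labels = [str(i) for i in df.index]
    if len(labels) < 2:
        raise ValueError("need at least 2 units")
    n = X.shape[0]
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        tot = X[i].sum() + X[j].sum()
        if tot == 0:
            logger.info("bray_curtis: two empty vectors (%s, %s) -> 0", labels[i], labels[j])
            bc = 0.0
        else:
            bc = 1.0 - 2.0 * np.minimum(X[i], X[j]).sum() / tot
        d[i, j] = d[j, i] = bc
    return DistanceMatrix(d, labels)


# ---------------------------------------------------------------------------
# NMDS
# ---------------------------------------------------------------------------

def stress1(
    config: np.ndarray, dissim: np.ndarray
) -> float:
    """Kruskal stress-1 of a configuration against condensed dissimilarities.

    Disparities are the isotonic (monotone in the input dissimilarities)
    least-squares fit to the configuration distances.
    """
    d = pdist(config)
    order = np.argsort(dissim, kind="stable")
    iso = IsotonicRegression(increasing=True)
    dhat = np.empty_like(d)
    dhat[order] = iso.fit_transform(np.arange(len(d)), d[order])
    denom = float((d**2).sum())
    if denom == 0:
        return 0.0
    return float(np.sqrt(((d - dhat) ** 2).sum() / denom))


def _classical_scaling(D: np.ndarray, k: int) -> np.ndarray:
    """Torgerson classical scaling, used as the first NMDS start."""
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    w, V = np.linalg.eigh(B)
    idx = np.argsort(w)[::-1][:k]
    w = np.clip(w[idx], 0, None)
    return V[:, idx] * np.sqrt(w)


def nmds(
    dm: DistanceMatrix,
    k: int = 2,
    n_starts: int = 20,
    max_iter: int = 300,
    tol: float = 1e-6,
    seed: int | None = None,
) -> OrdinationResult:
    """Non-metric MDS minimising Kruskal stress-1.

    Each start alternates an isotonic-regression disparity fit with a Guttman
    majorization update; the stress sequence within a start is non-increasing
    (an increasing step reverts and stops the start).  Start 0 is classical
    scaling; the rest are random.  The best configuration is returned.
    """
    n = dm.shape[0]
    if k >= n:
        raise ValueError("k must be smaller than the number of units")
    D = dm.data
    dissim = squareform(D, checks=False)
    order = np.argsort(dissim, kind="stable")
    rng = np.random.default_rng(seed)
    iso = IsotonicRegression(increasing=True)

    best_X, best_stress, converged = None, np.inf, False
    for start in range(n_starts):
        if start == 0:
            X = _classical_scaling(D, k)
            if X.shape[1] < k:  # degenerate rank
                X = np.hstack([X, rng.standard_normal((n, k - X.shape[1])) * 1e-3])
        else:
            X = rng.standard_normal((n, k))
        prev = np.inf
        this_converged = False
        for _ in range(max_iter):
            d = pdist(X)
            dhat = np.empty_like(d)
            dhat[order] = iso.fit_transform(np.arange(len(d)), d[order])
            denom = float((d**2).sum())
            s = 0.0 if denom == 0 else float(np.sqrt(((d - dhat) ** 2).sum() / denom))
            if s > prev:  # keep stress monotone: revert and stop
                X = X_prev
                s = prev
                break
            if prev - s < tol:
                prev = s
                this_converged = True
                break
            prev = s
            X_prev = X
            # Guttman transform
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(d > 0, dhat / d, 0.0)
            R = squareform(ratio, checks=False)
            B = -R
            np.fill_diagonal(B, R.sum(axis=1))
            X = (B @ X) / n
            X = X - X.mean(axis=0)
        final = stress1(X, dissim)
        if final < best_stress:
            best_stress, best_X, converged = final, X.copy(), this_converged
    if not converged:
        logger.warning("nmds: best start did not converge within %d iterations", max_iter)
    return OrdinationResult(
        points=best_X, stress=best_stress, n_starts=n_starts, seed=seed,
        converged=converged, labels=list(dm.ids),
    )


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------

def mantel(
    dm1: DistanceMatrix,
    dm2: DistanceMatrix,
    n_perm: int = 999,
    seed: int | None = None,
    tail: Literal["positive", "negative", "two-sided"] = "positive",
) -> MantelResult:
    """Mantel permutation test on two distance matrices with shared labels.

    r is the Pearson correlation of the lower-triangle vectors; the null
    distribution permutes rows and columns of ``dm2`` simultaneously;
    p = (1 + #{permuted statistic at least as extreme}) / (1 + n_perm).
    """
    if list(dm1.ids) != list(dm2.ids):
        raise ValueError("distance matrices must share labels in the same order")
    x = squareform(dm1.data, checks=False)
    M2 = dm2.data
    y = squareform(M2, checks=False)
    r_obs = float(stats.pearsonr(x, y)[0])

    # permuting rows/cols permutes the condensed entries, so the permuted
    # vector is y re-indexed; z-scores can be precomputed once
    n = M2.shape[0]
    m = len(x)
    xs = (x - x.mean()) / x.std()
    ys = (y - y.mean()) / y.std()
    idx = np.zeros((n, n), dtype=np.int64)
    iu = np.triu_indices(n, k=1)
    idx[iu] = np.arange(m)
    idx = idx + idx.T

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        rp = float(xs @ ys[idx[np.ix_(perm, perm)][iu]]) / m
        if tail == "positive":
            extreme = rp >= r_obs - 1e-12
        elif tail == "negative":
            extreme = rp <= r_obs + 1e-12
        else:
            extreme = abs(rp) >= abs(r_obs) - 1e-12
        count += extreme
    p = (1 + count) / (1 + n_perm)
    return MantelResult(r=r_obs, p=float(p), n_perm=n_perm, tail=tail)


# ---------------------------------------------------------------------------
# Composition similarity regression
# ---------------------------------------------------------------------------

def composition_similarity_regression(
    vt_matrix: IncidenceMatrix,
    plant_matrix: IncidenceMatrix,
) -> RegressionResult:
    """Do categories with similar plant composition share VT composition?

    For every unordered category pair, x = Bray-Curtis similarity (1 - BC) of
    the plant-order composition and y = the same for VT composition; OLS of
    y on x.
    """
    cols1 = list(vt_matrix.counts.columns)
    cols2 = list(plant_matrix.counts.columns)
    if sorted(cols1) != sorted(cols2):
        raise ValueError("matrices must share the same category columns")
    if len(cols1) < 3:
        raise ValueError("need at least 3 categories (3 pairs)")
    cols = sorted(cols1)
    bc_vt = bray_curtis(vt_matrix.counts[cols], by="columns")
    bc_pl = bray_curtis(plant_matrix.counts[cols], by="columns")
    xs, ys = [], []
    for a, b in itertools.combinations(cols, 2):
        xs.append(1.0 - bc_pl[a, b])
        ys.append(1.0 - bc_vt[a, b])
    return _ols(np.asarray(xs), np.asarray(ys))
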