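"""PCA score construction and recursive path-model (SEM) fitting.

The structural stage asks how much of the variation in AMF community
composition across sampling locations is carried directly by spatial and
environmental strata (ecosystem, climate, continent, biogeographical realm)
versus mediated by the host-plant community.  Each variable is the first
principal-component score of the relevant composition table across locations;
the model is recursive (acyclic): exogenous strata -> plant -> amf, plus
optional direct exogenous -> amf paths.

Estimation is per-equation standardized OLS, which coincides with full ML in
the population for recursive models with observed variables.  Indirect
effects are products of the constituent standardized paths (sums over
mediated routes); fit indices use the ML discrepancy between the sample and
model-implied covariance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_EXOGENOUS = ("ecosystem", "climate", "continent", "biogeography")


@dataclass
class ScoreVector:
    """First-principal-component scores per unit (location)."""

    labels: list[str]
    scores: np.ndarray

    def to_series(self, name: str = "score") -> pd.Series:
        return pd.Series(self.scores, index=self.labels, name=name)


@dataclass
class PathSpec:
    """Directed edge structure of the recursive model.

    Default: every exogenous stratum -> plant and -> amf, plant -> amf, with
    free covariances among the exogenous block.
    """

    variables: tuple[str, ...] = DEFAULT_EXOGENOUS + ("plant", "amf")
    edges: tuple[tuple[str, str], ...] = tuple(
        [(v, "plant") for v in DEFAULT_EXOGENOUS]
        + [(v, "amf") for v in DEFAULT_EXOGENOUS]
        + [("plant", "amf")]
    )

    def __post_init__(self) -> None:
        for s, d in self.edges:
            if s not in self.variables or d not in self.variables:
                raise ValueError(f"edge ({s!r}, {d!r}) uses unknown variable")
        self.topological_order()  # raises if cyclic

    @property
    def endogenous(self) -> tuple[str, ...]:
        targets = {d for _, d in self.edges}
        return tuple(v for v in self.variables if v in targets)

    @property
    def exogenous(self) -> tuple[str, ...]:
        targets = {d for _, d in self.edges}
        return tuple(v for v in self.variables if v not in targets)

    def parents(self, v: str) -> tuple[str, ...]:
        return tuple(s for s, d in self.edges if d == v)

    def topological_order(self) -> list[str]:
        parents = {v: set(self.parents(v)) for v in self.variables}
        order: list[str] = []
        remaining = set(self.variables)
        while remaining:
            ready = sorted(v for v in remaining if parents[v] <= set(order))
            if not ready:
                raise ValueError("path model must be recursive (acyclic)")
            order.extend(ready)
            remaining -= set(ready)
        return order


@dataclass
class PathModelResult:
    direct: dict[tuple[str, str], float]  # edge -> standardized coefficient
    indirect: dict[tuple[str, str], float]  # (source, endogenous) -> effect
    total: dict[tuple[str, str], float]
    r_squared: dict[str, float]
    n: int
    fit: dict[str, float] = field(default_factory=dict)

    def effects_on(self, target: str) -> pd.DataFrame:
        rows = []
        for (s, d), t in sorted(self.total.items()):
            if d == target:
                rows.append(
                    {
                        "source": s,
                        "direct": self.direct.get((s, d), 0.0),
                        "indirect": self.indirect.get((s, d), 0.0),
                        "total": t,
                    }
                )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# PCA scores
# ---------------------------------------------------------------------------

def pca_first_component(matrix: pd.DataFrame) -> ScoreVector:
    """Scores on the leading principal component of a units x features table.

    Columns are centered; the sign is fixed so the loading of the first
    feature in lexicographic order (with nonzero loading) is nonnegative.
    """
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 units")
    X = matrix.values.astype(float)
    Xc = X - X.mean(axis=0)
    if np.allclose(Xc, 0):
        raise ValueError("all features are constant; no principal component")
    cov = np.cov(Xc, rowvar=False)
    cov = np.atleast_2d(cov)
    w, V = np.linalg.eigh(cov)
    vec = V[:, np.argmax(w)]
    order = np.argsort([str(c) for c in matrix.columns], kind="stable")
    for j in order:
        if abs(vec[j]) > 1e-12:
            if vec[j] < 0:
                vec = -vec
            break
    scores = Xc @ vec
    return ScoreVector(labels=[str(i) for i in matrix.index], scores=scores)


def composition_scores(counts: pd.DataFrame) -> ScoreVector:
    """Row-normalise a units x categories count table to proportions, then
    take first-PC scores ('categorical composition' pipeline)."""
    sums = counts.sum(axis=1)
    if (sums == 0).any():
        raise ValueError("units with zero total count cannot be normalised")
    props = counts.div(sums, axis=0)
    return pca_first_component(props)


# ---------------------------------------------------------------------------
# Model fitting
# ---------------------------------------------------------------------------

def fit_path_model(
    data: pd.DataFrame, spec: PathSpec | None = None, with_fit: bool = True
) -> PathModelResult:
    """Standardized per-equation OLS estimation of a recursive path model.

    Each endogenous variable is regressed on its parents after z-scoring all
    variables; indirect effects come from path tracing (total effect matrix
    (I - B)^-1 - I); total = direct + indirect exactly.
    """
    spec = spec or PathSpec()
    missing = set(spec.variables) - set(data.columns)
    if missing:
        raise ValueError(f"data missing variables: {sorted(missing)}")
    n = len(data)
    nfree = _n_free_params(spec)
    if n < nfree:
        raise ValueError(f"n={n} below the number of free parameters ({nfree})")
    Z = (data[list(spec.variables)] - data[list(spec.variables)].mean()) / data[
        list(spec.variables)
    ].std(ddof=1)
    idx = {v: i for i, v in enumerate(spec.variables)}
    p = len(spec.variables)
    B = np.zeros((p, p))  # B[target, source]
    direct: dict[tuple[str, str], float] = {}
    r2: dict[str, float] = {}
    resid_var: dict[str, float] = {}
    for v in spec.endogenous:
        parents = sorted(spec.parents(v))
        Xp = Z[parents].values
        y = Z[v].values
        rank = np.linalg.matrix_rank(Xp)
        if rank < len(parents):
            raise ValueError(
                f"collinear predictors for {v!r}: {parents} (rank {rank})"
            )
        beta, *_ = np.linalg.lstsq(Xp, y, rcond=None)
        for pa, b in zip(parents, beta):
            direct[(pa, v)] = float(b)
            B[idx[v], idx[pa]] = b
        yhat = Xp @ beta
        sst = float((y**2).sum())
        ssr = float(((y - yhat) ** 2).sum())
        r2[v] = 1.0 - ssr / sst
        resid_var[v] = ssr / (n - 1)

    T = np.linalg.inv(np.eye(p) - B) - np.eye(p)  # total effects
    total: dict[tuple[str, str], float] = {}
    indirect: dict[tuple[str, str], float] = {}
    for tgt in spec.endogenous:
        for src in spec.variables:
            if src == tgt:
                continue
            tot = float(T[idx[tgt], idx[src]])
            if tot == 0.0 and (src, tgt) not in direct:
                continue
            d = direct.get((src, tgt), 0.0)
            total[(src, tgt)] = tot
            indirect[(src, tgt)] = tot - d

    result = PathModelResult(
        direct=direct, indirect=indirect, total=total, r_squared=r2, n=n
    )
    if with_fit:
        result.fit = fit_indices(data, spec, result)
    return result


def _n_free_params(spec: PathSpec) -> int:
    n_exo = len(spec.exogenous)
    return (
        len(spec.edges)  # path coefficients
        + n_exo  # exogenous variances
        + n_exo * (n_exo - 1) // 2  # exogenous covariances
        + len(spec.endogenous)  # residual variances
    )


def implied_covariance(
    spec: PathSpec,
    direct: Mapping[tuple[str, str], float],
    exo_cov: np.ndarray,
    resid_var: Mapping[str, float],
) -> np.ndarray:
    """Sigma = (I-B)^-1 Psi (I-B)^-T for the recursive model."""
    p = len(spec.variables)
    idx = {v: i for i, v in enumerate(spec.variables)}
    B = np.zeros((p, p))
    for (s, d), b in direct.items():
        B[idx[d], idx[s]] = b
    Psi = np.zeros((p, p))
    exo = list(spec.exogenous)
    for i, a in enumerate(exo):
        for j, b in enumerate(exo):
            Psi[idx[a], idx[b]] = exo_cov[i, j]
    for v in spec.endogenous:
        Psi[idx[v], idx[v]] = resid_var[v]
    A = np.linalg.inv(np.eye(p) - B)
    return A @ Psi @ A.T


def fit_indices(
    data: pd.DataFrame, spec: PathSpec, fitted: PathModelResult
) -> dict[str, float]:
    """ML-discrepancy fit block: chi2, df, p, RMSEA, TLI.

    chi2 = (n-1) * F_ML comparing the sample covariance of the z-scored
    variables with the model-implied covariance; df = p(p+1)/2 - free
    parameters.  A saturated model gives chi2 = 0 and RMSEA = 0; df <= 0
    leaves p and TLI undefined (NaN) with a flag.
    """
    n = fitted.n
    varlist = list(spec.variables)
    Z = (data[varlist] - data[varlist].mean()) / data[varlist].std(ddof=1)
    S = np.cov(Z.values, rowvar=False, ddof=1)
    p = len(varlist)
    idx = {v: i for i, v in enumerate(varlist)}
    exo = list(spec.exogenous)
    exo_cov = S[np.ix_([idx[v] for v in exo], [idx[v] for v in exo])]
    resid_var = {v: (1.0 - fitted.r_squared[v]) for v in spec.endogenous}
    Sigma = implied_covariance(spec, fitted.direct, exo_cov, resid_var)

    sign_S, logdet_S = np.linalg.slogdet(S)
    sign_M, logdet_M = np.linalg.slogdet(Sigma)
    if sign_S <= 0 or sign_M <= 0:
        raise ValueError("covariance matrix not positive definite")
    F = logdet_M + float(np.trace(S @ np.linalg.inv(Sigma))) - logdet_S - p
    chi2 = max((n - 1) * F, 0.0)
    df = p * (p + 1) // 2 - _n_free_params(spec)

    # independence baseline for TLI
    F_b = -float(np.linalg.slogdet(np.corrcoef(Z.values, rowvar=False))[1])
    chi2_b = max((n - 1) * F_b, 0.0)
    df_b = p * (p - 1) // 2

    out: dict[str, float] = {
        "chi2": float(chi2),
        "df": float(df),
        "baseline_chi2": float(chi2_b),
        "baseline_df": float(df_b),
        "saturated": float(df <= 0),
    }
    if df > 0:
        out["p"] = float(stats.chi2.sf(chi2, df))
        out["rmsea"] = float(np.sqrt(max(chi2 - df, 0.0) / (df * (n - 1))))
        if df_b > 0 and chi2_b / df_b > 1.0:
            out["tli"] = float(
                ((chi2_b / df_b) - (chi2 / df)) / ((chi2_b / df_b) - 1.0)
            )
        else:
            out["tli"] = float("nan")
    else:
        out["p"] = float("nan")
        out["rmsea"] = 0.0 if chi2 < 1e-8 else float("nan")
        out["tli"] = float("nan")
    return out
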