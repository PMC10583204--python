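"""Isolation by distance / environment and RDA variance partitioning.

Distance matrices (great-circle geographic, Bray–Curtis environmental on
standardized min-shifted variables, FST/(1−FST) genetic), simple and
partial Mantel tests with seeded permutations, the classical PCNM spatial
eigenvector basis (minimum-spanning-tree truncation), forward selection
with the double stopping rule, redundancy analysis with Ezekiel-adjusted R²
and permutation tests, and the two-block environment/geography variance
partition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.stats import rankdata

__all__ = [
    "DistanceMatrix",
    "MantelResult",
    "PCNMBasis",
    "RDAResult",
    "RDAPartition",
    "geo_distance",
    "env_distance",
    "mantel",
    "partial_mantel",
    "pcnm",
    "forward_select",
    "rda",
    "variance_partition",
]

EARTH_RADIUS_KM = 6371.0088


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray
    kind: str = "generic"

    def __post_init__(self) -> None:
        v = self.values
        if v.shape[0] != v.shape[1] or len(self.labels) != v.shape[0]:
            raise ValueError("shape/label mismatch")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("matrix not symmetric")
        if not np.allclose(np.diag(v), 0, atol=1e-12):
            raise ValueError("diagonal not zero")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def upper(self) -> np.ndarray:
        iu = np.triu_indices(len(self.labels), k=1)
        return self.values[iu]


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int
    partial_controlled: str | None = None


@dataclass
class PCNMBasis:
    eigenvectors: np.ndarray  # populations × positive axes, scaled by sqrt(eigval)
    eigenvalues: np.ndarray
    truncation_distance: float
    retained: list[int]
    labels: list[str]

    def frame(self, which: str = "retained") -> pd.DataFrame:
        idx = self.retained if which == "retained" else range(self.eigenvectors.shape[1])
        return pd.DataFrame(
            self.eigenvectors[:, list(idx)],
            index=self.labels,
            columns=[f"PCNM{i + 1}" for i in idx],
        )


@dataclass
class RDAResult:
    r2: float
    adj_r2: float
    p_value: float | None
    axes: np.ndarray  # site scores on constrained axes
    eigenvalues: np.ndarray
    n_predictors: int


@dataclass
class RDAPartition:
    fractions: dict[str, float]
    p_values: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("F~geog.", "geog_combined"),
            ("F~env.", "env_combined"),
            ("F~geog.|env.", "geog_given_env"),
            ("F~env.|geog.", "env_given_geog"),
            ("Total explained", "total_explained"),
            ("Total confounded", "total_confounded"),
            ("Total unexplained", "total_unexplained"),
        ]
        return pd.DataFrame(
            {
                "fraction": [self.fractions[k] for _, k in rows],
                "p": [self.p_values.get(k, np.nan) for _, k in rows],
            },
            index=[name for name, _ in rows],
        )


# ---------------------------------------------------------------------------
# Distances


def geo_distance(sheet, flat: bool = False) -> DistanceMatrix:
    """Great-circle distance (km) between population coordinates.

    ``sheet`` is a SampleSheet or a DataFrame with population_id/lon/lat.
    ``flat=True`` switches to naive Euclidean degrees (sensitivity option).
    """
    table = sheet.population_table() if hasattr(sheet, "population_table") else sheet
    if "population_id" in getattr(table, "columns", []):
        table = table.set_index("population_id")
    lon = np.radians(table["lon"].to_numpy(dtype=float))
    lat = np.radians(table["lat"].to_numpy(dtype=float))
    if (np.abs(table["lon"].to_numpy()) > 180).any() or (
        np.abs(table["lat"].to_numpy()) > 90
    ).any():
        raise ValueError("coordinates out of range")
    labels = [str(x) for x in table.index]
    if flat:
        xy = np.column_stack([table["lon"], table["lat"]])
        diff = xy[:, None, :] - xy[None, :, :]
        d = np.sqrt((diff**2).sum(axis=2))
    else:
        dlat = lat[:, None] - lat[None, :]
        dlon = lon[:, None] - lon[None, :]
        h = (
            np.sin(dlat / 2) ** 2
            + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
        )
        d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2
    return DistanceMatrix(labels=labels, values=d, kind="geographic_km")


def env_distance(env_table: pd.DataFrame, variables=None) -> DistanceMatrix:
    """Bray–Curtis distance on standardized, min-shifted variables.

    Variables are centred/scaled, then shifted per variable so the minimum
    is 0 (Bray–Curtis requires non-negative inputs); zero-variance variables
    are dropped with a warning.
    """
    if variables is not None:
        env_table = env_table[list(variables)]
    if env_table.shape[1] < 1:
        raise ValueError("need at least one variable")
    if env_table.isna().any().any():
        raise ValueError("missing values in environmental table")
    sd = env_table.std(ddof=0)
    drop = [v for v in env_table.columns if sd[v] == 0]
    if drop:
        warnings.warn(f"dropping zero-variance variables: {drop}")
        env_table = env_table.drop(columns=drop)
        if env_table.shape[1] == 0:
            raise ValueError("all variables zero-variance")
        sd = env_table.std(ddof=0)
    z = (env_table - env_table.mean()) / sd
    z = z - z.min()
    X = z.to_numpy(dtype=float)
    num = np.abs(X[:, None, :] - X[None, :, :]).sum(axis=2)
    den = (X[:, None, :] + X[None, :, :]).sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(den > 0, num / den, 0.0)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2
    return DistanceMatrix(labels=[str(i) for i in env_table.index], values=d,
                          kind="environment_braycurtis")


# ---------------------------------------------------------------------------
# Mantel tests


def _check_labels(*dms: DistanceMatrix) -> None:
    ref = dms[0].labels
    for dm in dms[1:]:
        if dm.labels != ref:
            raise ValueError("distance-matrix labels do not match")


def _mantel_r(a: np.ndarray, b: np.ndarray, method: str) -> float:
    if method == "spearman":
        a, b = rankdata(a), rankdata(b)
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        raise ValueError("constant distance matrix: correlation undefined")
    return float(np.corrcoef(a, b)[0, 1])


def mantel(
    dm_a: DistanceMatrix,
    dm_b: DistanceMatrix,
    n_perm: int = 999,
    method: str = "pearson",
    seed: int = 0,
) -> MantelResult:
    """Simple Mantel test with a one-sided (positive) permutation p-value.

    r is the correlation of upper-triangle entries; the null permutes rows
    and columns of ``dm_b`` jointly; p = (1 + #{r_perm ≥ r_obs})/(n_perm+1).
    """
    _check_labels(dm_a, dm_b)
    n = len(dm_a.labels)
    iu = np.triu_indices(n, k=1)
    a = dm_a.values[iu]
    r_obs = _mantel_r(a, dm_b.values[iu], method)
    rng = np.random.default_rng(seed)
    count = 0
    B = dm_b.values
    a_rank = rankdata(a) if method == "spearman" else a
    a_c = a_rank - a_rank.mean()
    a_norm = np.sqrt((a_c**2).sum())
    for _ in range(n_perm):
        perm = rng.permutation(n)
        b = B[np.ix_(perm, perm)][iu]
        if method == "spearman":
            b = rankdata(b)
        b_c = b - b.mean()
        denom = a_norm * np.sqrt((b_c**2).sum())
        r_perm = (a_c @ b_c) / denom if denom > 0 else 0.0
        if r_perm >= r_obs:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return MantelResult(r=r_obs, p=p, n_perm=n_perm)


def partial_mantel(
    dm_a: DistanceMatrix,
    dm_b: DistanceMatrix,
    dm_c: DistanceMatrix,
    n_perm: int = 999,
    seed: int = 0,
) -> MantelResult:
    """Partial Mantel: correlation of a and b residualized on c.

    Residual matrices (entrywise OLS residuals of a~c and b~c) are formed;
    the permutation scheme permutes the residualized b matrix's rows and
    columns jointly (residual permutation).
    """
    _check_labels(dm_a, dm_b, dm_c)
    n = len(dm_a.labels)
    iu = np.triu_indices(n, k=1)

    def residual_matrix(m: np.ndarray, c: np.ndarray) -> np.ndarray:
        x, y = c[iu], m[iu]
        if x.std() == 0:
            raise ValueError("constant control matrix")
        beta = np.cov(x, y, ddof=0)[0, 1] / x.var()
        alpha = y.mean() - beta * x.mean()
        res = np.zeros_like(m)
        res[iu] = y - (alpha + beta * x)
        return res + res.T

    ra = residual_matrix(dm_a.values, dm_c.values)
    rb = residual_matrix(dm_b.values, dm_c.values)
    a = ra[iu]
    scale_b = max(np.abs(dm_b.values).max(), 1.0)
    if rb[iu].std() <= 1e-12 * scale_b:
        # dm_b fully explained by the control: partial association is zero
        return MantelResult(r=0.0, p=1.0, n_perm=n_perm,
                            partial_controlled=dm_c.kind)
    r_obs = _mantel_r(a, rb[iu], "pearson")
    rng = np.random.default_rng(seed)
    a_c = a - a.mean()
    a_norm = np.sqrt((a_c**2).sum())
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        b = rb[np.ix_(perm, perm)][iu]
        b_c = b - b.mean()
        denom = a_norm * np.sqrt((b_c**2).sum())
        r_perm = (a_c @ b_c) / denom if denom > 0 else 0.0
        if r_perm >= r_obs:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return MantelResult(r=r_obs, p=p, n_perm=n_perm,
                        partial_controlled=dm_c.kind)


# ---------------------------------------------------------------------------
# PCNM


def pcnm(dm_geo: DistanceMatrix) -> PCNMBasis:
    """Classical PCNM basis from a geographic distance matrix.

    Truncate at t = the longest edge of the minimum spanning tree; replace
    entries > t by 4t; double-center −½D²; positive-eigenvalue eigenvectors
    scaled by √eigenvalue.  ``retained`` defaults to the first half of the
    positive axes.
    """
    n = len(dm_geo.labels)
    if n < 3:
        raise ValueError("need at least 3 populations")
    D = dm_geo.values.copy()
    mst = minimum_spanning_tree(D).toarray()
    t = mst.max()
    Dt = np.where(D > t, 4 * t, D)
    np.fill_diagonal(Dt, 0.0)
    A = -0.5 * Dt**2
    J = np.eye(n) - np.ones((n, n)) / n
    G = J @ A @ J
    G = (G + G.T) / 2
    evals, evecs = np.linalg.eigh(G)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = 1e-8 * max(abs(evals[0]), 1.0)
    pos = evals > tol
    evals_pos = evals[pos]
    vecs = evecs[:, pos] * np.sqrt(evals_pos)
    # deterministic sign: largest-|entry| positive
    for k in range(vecs.shape[1]):
        j = int(np.argmax(np.abs(vecs[:, k])))
        if vecs[j, k] < 0:
            vecs[:, k] *= -1
    n_pos = vecs.shape[1]
    retained = list(range(int(np.ceil(n_pos / 2))))
    return PCNMBasis(
        eigenvectors=vecs,
        eigenvalues=evals_pos,
        truncation_distance=float(t),
        retained=retained,
        labels=dm_geo.labels,
    )


# ---------------------------------------------------------------------------
# RDA


def _adj_r2(r2: float, n: int, p: int) -> float:
    """Ezekiel's adjusted R²."""
    if n - p - 1 <= 0:
        return np.nan
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def _residualize(M: np.ndarray, C: np.ndarray) -> np.ndarray:
    Cc = np.column_stack([np.ones(M.shape[0]), C])
    beta, *_ = np.linalg.lstsq(Cc, M, rcond=None)
    return M - Cc @ beta


def _fit_r2(Y: np.ndarray, X: np.ndarray) -> float:
    Xc = np.column_stack([np.ones(Y.shape[0]), X])
    beta, *_ = np.linalg.lstsq(Xc, Y, rcond=None)
    fitted = Xc @ beta
    ss_tot = ((Y - Y.mean(axis=0)) ** 2).sum()
    if ss_tot == 0:
        return 0.0
    return float(((fitted - fitted.mean(axis=0)) ** 2).sum() / ss_tot)


def rda(
    freqs: pd.DataFrame,
    predictors: pd.DataFrame,
    condition: pd.DataFrame | None = None,
    n_perm: int = 999,
    seed: int = 0,
) -> RDAResult:
    """Redundancy analysis of population allele frequencies on predictors.

    Response is centred; predictors standardized; with ``condition`` both
    response and predictors are first residualized on it (partial RDA).
    Constrained axes are the PCA of the fitted values; R² is
    SS_fitted/SS_total of the (residualized) response; adjusted R² uses
    Ezekiel's formula with the number of predictors; the global permutation
    test permutes rows of the (residualized) predictors.
    """
    Y = freqs.to_numpy(dtype=float)
    Y = Y - Y.mean(axis=0)
    X = predictors.to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=0)
    keep = sd > 1e-12
    if not keep.all():
        warnings.warn("dropping collinear/constant predictors")
        X = X[:, keep]
    X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=0)
    if X.shape[1] > X.shape[0] - 1:
        raise ValueError("more predictors than populations - 1")
    # drop exactly collinear columns
    q, r = np.linalg.qr(X)
    indep = np.abs(np.diag(r)) > 1e-9 * max(1.0, np.abs(r).max())
    if not indep.all():
        warnings.warn("dropping collinear predictors")
        X = X[:, indep]
    n, p = X.shape
    n_cond = 0
    if condition is not None:
        C = condition.to_numpy(dtype=float)
        C = (C - C.mean(axis=0)) / np.where(C.std(axis=0, ddof=0) > 0,
                                            C.std(axis=0, ddof=0), 1.0)
        n_cond = C.shape[1]
        Y = _residualize(Y, C)
        X = _residualize(X, C)
    if p > n - 1 - n_cond:
        raise ValueError("more predictors than populations - 1")

    Xc = np.column_stack([np.ones(n), X])
    beta, *_ = np.linalg.lstsq(Xc, Y, rcond=None)
    fitted = Xc @ beta
    fitted = fitted - fitted.mean(axis=0)
    ss_tot = (Y**2).sum()
    r2 = float((fitted**2).sum() / ss_tot) if ss_tot > 0 else 0.0
    adj = _adj_r2(r2, n, p)

    U, S, _ = np.linalg.svd(fitted, full_matrices=False)
    k = min(p, n - 1)
    axes = U[:, :k] * S[:k]
    eigenvalues = (S[:k] ** 2) / (n - 1)

    p_value = None
    if n_perm and n_perm > 0:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            r2_perm = _fit_r2(Y, X[perm])
            if r2_perm >= r2:
                count += 1
        p_value = (1 + count) / (n_perm + 1)
    return RDAResult(r2=r2, adj_r2=adj, p_value=p_value, axes=axes,
                     eigenvalues=eigenvalues, n_predictors=p)


def forward_select(
    response_freqs: pd.DataFrame,
    candidate_vars: pd.DataFrame,
    alpha: float = 0.05,
    max_adjr2: float | None = None,
    n_perm: int = 999,
    seed: int = 0,
) -> list[str]:
    """Forward selection of predictors with the double stopping rule.

    At each step the candidate giving the largest adjusted-R² increase is
    tested by permutation (conditional on already-selected variables); it
    enters iff p < ``alpha`` and the cumulative adjusted R² stays at or
    below the full-model adjusted R² (``max_adjr2``; computed from all
    candidates when None).  Returns the selected variable names in entry
    order (possibly empty).
    """
    Y = response_freqs.to_numpy(dtype=float)
    Y = Y - Y.mean(axis=0)
    n = Y.shape[0]
    cols = list(candidate_vars.columns)
    Xall = candidate_vars.to_numpy(dtype=float)
    sd = Xall.std(axis=0, ddof=0)
    Xall = (Xall - Xall.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    if max_adjr2 is None:
        p_full = min(len(cols), n - 2)
        r2_full = _fit_r2(Y, Xall[:, :p_full]) if p_full else 0.0
        max_adjr2 = _adj_r2(r2_full, n, p_full) if p_full else 0.0
    rng = np.random.default_rng(seed)

    selected: list[int] = []
    while len(selected) < len(cols) and len(selected) < n - 2:
        remaining = [j for j in range(len(cols)) if j not in selected]
        best_j, best_adj, best_r2 = None, -np.inf, 0.0
        for j in remaining:
            idx = selected + [j]
            r2 = _fit_r2(Y, Xall[:, idx])
            adj = _adj_r2(r2, n, len(idx))
            if adj > best_adj:
                best_j, best_adj, best_r2 = j, adj, r2
        if best_j is None:
            break
        # permutation test of the added variable, conditional on selected
        if selected:
            Ycond = _residualize(Y, Xall[:, selected])
            xcand = _residualize(Xall[:, [best_j]], Xall[:, selected])
        else:
            Ycond, xcand = Y, Xall[:, [best_j]]
        r2_obs = _fit_r2(Ycond, xcand)
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            if _fit_r2(Ycond, xcand[perm]) >= r2_obs:
                count += 1
        p = (1 + count) / (n_perm + 1)
        if p > alpha:
            break
        selected.append(best_j)
        # double stopping rule: once the cumulative adjusted R² reaches the
        # full-model adjusted R², adding more variables is overfitting
        if best_adj > max_adjr2:
            break
    return [cols[j] for j in selected]


def variance_partition(
    freqs: pd.DataFrame,
    env_vars: pd.DataFrame,
    geo_vars: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
) -> RDAPartition:
    """Two-block variance partition (environment vs geography).

    Combined fractions are adjR²(F~geog) and adjR²(F~env); individual
    fractions are differences of adjusted R² (adjR²(F~env+geog) minus the
    other block's combined fraction, the vegan varpart convention, which
    makes the ledger close exactly): confounded = explained − geog|env −
    env|geog; unexplained = 1 − explained.  p-values come from the
    corresponding full/partial RDA permutation tests.
    """
    res_geo = rda(freqs, geo_vars, n_perm=n_perm, seed=seed)
    res_env = rda(freqs, env_vars, n_perm=n_perm, seed=seed + 1)
    both = pd.concat([env_vars, geo_vars], axis=1)
    res_both = rda(freqs, both, n_perm=n_perm, seed=seed + 2)
    res_geo_env = rda(freqs, geo_vars, condition=env_vars, n_perm=n_perm, seed=seed + 3)
    res_env_geo = rda(freqs, env_vars, condition=geo_vars, n_perm=n_perm, seed=seed + 4)

    explained = res_both.adj_r2
    geog_only = explained - res_env.adj_r2
    env_only = explained - res_geo.adj_r2
    confounded = explained - geog_only - env_only
    fractions = {
        "geog_combined": res_geo.adj_r2,
        "env_combined": res_env.adj_r2,
        "geog_given_env": geog_only,
        "env_given_geog": env_only,
        "total_explained": explained,
        "total_confounded": confounded,
        "total_unexplained": 1.0 - explained,
    }
    p_values = {
        "geog_combined": res_geo.p_value,
        "env_combined": res_env.p_value,
        "geog_given_env": res_geo_env.p_value,
        "env_given_geog": res_env_geo.p_value,
        "total_explained": res_both.p_value,
    }
    return RDAPartition(fractions=fractions, p_values=p_values)
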