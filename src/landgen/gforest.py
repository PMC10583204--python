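"""Gradient-forest turnover modelling and genetic-offset mapping.

One random-forest regression per SNP (population allele frequency on
environmental variables); each split's impurity reduction is binned along
its predictor's gradient, density-normalized, accumulated into a monotone
cumulative-importance function I_v, and scaled so the SNP's total allocated
importance equals its out-of-bag R².  SNP functions are aggregated by
R²-weighted averaging.  Landscape cells are transformed through the
aggregate I_v functions; the genetic offset of a cell is the Euclidean
distance between its transformed current and future coordinates, and the
vulnerable fraction is the share of cells whose offset exceeds a fraction
of the maximum observed offset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

__all__ = [
    "GFModel",
    "OffsetMap",
    "select_env_variables",
    "fit_gradient_forest",
    "transform_grid",
    "genetic_offset",
    "vulnerable_fraction",
]


@dataclass
class GFModel:
    """Fitted gradient forest: aggregate turnover functions and importances."""

    predictors: list[str]
    snp_r2: pd.Series  # OOB R² per SNP (all fitted SNPs; <=0 excluded from aggregation)
    snp_importance: pd.DataFrame  # SNP × predictor total allocated importance
    predictor_importance: pd.Series  # R²-weighted importance per predictor
    bin_edges: dict[str, np.ndarray]  # predictor → edges (n_bins,)
    cumulative: dict[str, np.ndarray]  # predictor → I_v at edges (starts at 0)
    n_trees: int

    @property
    def included_snps(self) -> pd.Index:
        return self.snp_r2.index[self.snp_r2 > 0]

    def ranking(self) -> list[str]:
        return list(self.predictor_importance.sort_values(ascending=False).index)


@dataclass
class OffsetMap:
    """Per-cell genetic offset for one scenario."""

    scenario: str
    offsets: pd.Series

    def __post_init__(self) -> None:
        if (self.offsets < 0).any():
            raise ValueError("offsets must be non-negative")

    @property
    def max(self) -> float:
        return float(self.offsets.max())


def select_env_variables(
    env_table: pd.DataFrame,
    gf_ranking: list[str],
    r_threshold: float = 0.7,
    keep_top: int = 3,
) -> list[str]:
    """Greedy correlation pruning that always keeps the top-ranked variables.

    The top ``keep_top`` variables of ``gf_ranking`` are always kept; the
    remaining variables are visited in rank order and kept iff their
    absolute Pearson correlation with every already-kept variable is below
    ``r_threshold``.
    """
    ranking = [v for v in gf_ranking if v in env_table.columns]
    if len(ranking) <= keep_top:
        return ranking
    corr = env_table[ranking].corr().abs()
    kept = ranking[:keep_top]
    for v in ranking[keep_top:]:
        if all(corr.loc[v, k] < r_threshold for k in kept):
            kept.append(v)
    return kept


def _split_improvements(tree, n_features: int):
    """(feature, threshold, impurity-decrease) for every internal node."""
    t = tree.tree_
    node = np.arange(t.node_count)
    internal = t.children_left != -1
    w = t.weighted_n_node_samples
    imp = t.impurity
    left, right = t.children_left, t.children_right
    gain = np.zeros(t.node_count)
    gain[internal] = (
        w[internal] * imp[internal]
        - w[left[internal]] * imp[left[internal]]
        - w[right[internal]] * imp[right[internal]]
    )
    return t.feature[internal], t.threshold[internal], gain[internal]


def fit_gradient_forest(
    af,
    env_table: pd.DataFrame,
    n_trees: int = 2000,
    n_bins: int = 201,
    seed: int = 0,
    snp_subset=None,
    max_features: int | None = None,
) -> GFModel:
    """Fit per-SNP random forests and build cumulative importance functions.

    ``af`` is an :class:`~landgen.variants.AlleleFreqMatrix` or a populations
    × SNPs frequency DataFrame (no missing values); ``env_table`` the
    matching populations × variables table.  Regression-forest conventions:
    bootstrap rows, ⌈p/3⌉ predictors per split (``max_features`` overrides),
    min leaf 2, no depth cap.
    SNPs with non-positive out-of-bag R² are recorded but excluded from
    aggregation; constant SNPs are skipped.
    """
    F = af.freq if hasattr(af, "freq") else af
    if snp_subset is not None:
        F = F[list(snp_subset)]
    if F.isna().any().any():
        raise ValueError("allele frequencies must be imputed (no NaN)")
    env = env_table.loc[F.index]
    predictors = list(env.columns)
    X = env.to_numpy(dtype=float)
    n, p = X.shape
    if n < 8:
        raise ValueError("need at least 8 populations")

    edges = {
        v: np.linspace(env[v].min(), env[v].max(), n_bins) for v in predictors
    }
    dens = {}
    for i, v in enumerate(predictors):
        counts, _ = np.histogram(X[:, i], bins=edges[v])
        # moving-average smoothing so bins between observed values keep support
        kernel = np.ones(5) / 5
        sm = np.convolve(counts, kernel, mode="same")
        dens[v] = sm / max(sm.sum(), 1e-12) + 1e-9

    rng = np.random.default_rng(seed)
    snp_ids = list(F.columns)
    r2 = pd.Series(np.nan, index=snp_ids, dtype=float)
    alloc = pd.DataFrame(0.0, index=snp_ids, columns=predictors)
    agg_num = {v: np.zeros(n_bins - 1) for v in predictors}
    w_sum = 0.0
    max_feat = max_features if max_features is not None else max(int(np.ceil(p / 3)), 1)

    n_skipped = 0
    for s in snp_ids:
        y = F[s].to_numpy(dtype=float)
        if y.std() == 0:
            n_skipped += 1
            continue
        rf = RandomForestRegressor(
            n_estimators=n_trees,
            max_features=max_feat,
            min_samples_leaf=2,
            bootstrap=True,
            oob_score=True,
            random_state=int(rng.integers(2**31 - 1)),
            n_jobs=1,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rf.fit(X, y)
        r2_s = float(rf.oob_score_)
        r2[s] = r2_s
        # raw split-improvement histograms per predictor
        hists = {v: np.zeros(n_bins - 1) for v in predictors}
        for est in rf.estimators_:
            feats, thrs, gains = _split_improvements(est, p)
            for f in np.unique(feats):
                sel = feats == f
                v = predictors[f]
                h, _ = np.histogram(thrs[sel], bins=edges[v], weights=gains[sel])
                hists[v] += h
        total_gain = sum(h.sum() for h in hists.values())
        if r2_s <= 0 or total_gain <= 0:
            continue
        for v in predictors:
            # density normalization then rescale so Σ_v totals = OOB R²
            norm = hists[v] / dens[v]
            share = hists[v].sum() / total_gain
            tot = norm.sum()
            if tot > 0:
                norm = norm * (share * r2_s / tot)
            alloc.loc[s, v] = share * r2_s
            agg_num[v] += r2_s * np.cumsum(norm)  # R²-weighted per-SNP I_v
        w_sum += r2_s

    if w_sum <= 0:
        if n_skipped == len(snp_ids):
            raise ValueError("all SNPs constant; nothing to fit")
        raise ValueError("no SNP achieved positive out-of-bag R²")

    # aggregate I_v: R²-weighted mean over included SNPs of the per-SNP
    # turnover functions (each totalling its share of that SNP's OOB R²);
    # the aggregate endpoint is the predictor's importance, so poor fits
    # shrink the aggregate towards zero.
    cumulative = {}
    for v in predictors:
        c = np.concatenate([[0.0], agg_num[v] / w_sum])
        cumulative[v] = np.maximum.accumulate(c)  # guard monotonicity numerically

    weights = r2.clip(lower=0.0).fillna(0.0)
    imp = alloc.mul(weights, axis=0).sum(axis=0) / w_sum
    return GFModel(
        predictors=predictors,
        snp_r2=r2,
        snp_importance=alloc,
        predictor_importance=imp,
        bin_edges=edges,
        cumulative=cumulative,
        n_trees=n_trees,
    )


def transform_grid(gf: GFModel, grid_env: pd.DataFrame) -> pd.DataFrame:
    """Map each cell through the aggregate cumulative-importance functions.

    Monotone linear interpolation of I_v between bin edges; values beyond
    the training range clamp to the endpoint importances.  Returns a cells ×
    predictors DataFrame of transformed coordinates.
    """
    missing = [v for v in gf.predictors if v not in grid_env.columns]
    if missing:
        raise ValueError(f"grid lacks model predictor(s): {missing}")
    out = {}
    for v in gf.predictors:
        out[v] = np.interp(
            grid_env[v].to_numpy(dtype=float), gf.bin_edges[v], gf.cumulative[v]
        )
    return pd.DataFrame(out, index=grid_env.index)


def genetic_offset(
    gf: GFModel,
    grid_current: pd.DataFrame,
    grid_future: pd.DataFrame,
    scenario: str = "future",
) -> OffsetMap:
    """Euclidean distance between transformed current and future coordinates."""
    if not grid_current.index.equals(grid_future.index):
        raise ValueError("scenario grids misaligned (different cells)")
    tc = transform_grid(gf, grid_current)
    tf = transform_grid(gf, grid_future)
    off = np.sqrt(((tc - tf) ** 2).sum(axis=1))
    return OffsetMap(scenario=scenario, offsets=off)


def vulnerable_fraction(offset_maps, fraction_of_max: float = 0.5) -> dict[str, float]:
    """Share of cells strictly above ``fraction_of_max`` × the maximum offset.

    ``offset_maps`` is one :class:`OffsetMap` or a list; the threshold uses
    the maximum across all scenarios considered, mirroring a multi-scenario
    vulnerability assessment.
    """
    if isinstance(offset_maps, OffsetMap):
        offset_maps = [offset_maps]
    if not offset_maps or any(len(m.offsets) == 0 for m in offset_maps):
        raise ValueError("empty offset map")
    overall_max = max(m.max for m in offset_maps)
    threshold = fraction_of_max * overall_max
    return {
        m.scenario: float((m.offsets > threshold).mean()) for m in offset_maps
    }
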