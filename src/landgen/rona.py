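"""Risk of non-adaptedness (RONA).

Per SNP and per environmental variable, an ordinary least-squares
regression of population allele frequency on the variable across
populations; the expected future frequency of each population is predicted
from its future value of the variable, and RONA is the mean absolute
difference between the observed current frequency and the clamped
prediction.  Per-population summaries carry both the plain mean and the
R²-weighted mean over SNPs (weighting by each regression's fit), with a
standard error across SNPs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["RONAModels", "RONATable", "fit_rona_models", "compute_rona", "top_variables"]


@dataclass
class RONAModels:
    """Per-SNP × variable OLS fits (slope, intercept, R², p)."""

    variables: list[str]
    locus_ids: list[str]
    populations: list[str]
    slope: pd.DataFrame  # loci × variables
    intercept: pd.DataFrame
    r2: pd.DataFrame
    p: pd.DataFrame
    current_freq: pd.DataFrame  # populations × loci (observed)
    p_filter: float | None


@dataclass
class RONATable:
    """Population × variable RONA with R²-weighted means and SEs."""

    table: pd.DataFrame  # columns: population, variable, rona, weighted_rona, se, n_snps, mean_r2
    scenario: str = "future"


def fit_rona_models(
    af,
    env_table: pd.DataFrame,
    snp_subset=None,
    p_filter: float | None = 0.05,
) -> RONAModels:
    """Fit frequency ~ variable OLS per SNP per environmental variable.

    ``af`` is an :class:`~landgen.variants.AlleleFreqMatrix` or a populations
    × SNPs frequency DataFrame; ``snp_subset`` restricts to a locus-id list
    (e.g. the GEA outliers).  Constant-frequency SNPs are skipped with a
    warning.  ``p_filter`` marks regressions whose p ≥ threshold for
    exclusion from RONA (set None to keep all).
    """
    F = af.freq if hasattr(af, "freq") else af
    if snp_subset is not None:
        F = F[[l for l in snp_subset if l in F.columns]]
    if F.shape[0] < 3:
        raise ValueError("need at least 3 populations")
    if F.isna().any().any():
        raise ValueError("allele frequencies must be imputed (no NaN)")
    env = env_table.loc[F.index]
    Y = F.to_numpy(dtype=float)  # pops × loci
    n = Y.shape[0]
    const = Y.std(axis=0) == 0
    if const.any():
        warnings.warn(f"skipping {int(const.sum())} constant-frequency SNP(s)")
    keep = ~const
    F = F.loc[:, keep]
    Y = Y[:, keep]

    slopes, intercepts, r2s, ps = {}, {}, {}, {}
    Yc = Y - Y.mean(axis=0)
    ss_y = (Yc**2).sum(axis=0)
    for v in env.columns:
        x = env[v].to_numpy(dtype=float)
        xc = x - x.mean()
        ss_x = (xc**2).sum()
        if ss_x == 0:
            slopes[v] = np.zeros(Y.shape[1])
            intercepts[v] = Y.mean(axis=0)
            r2s[v] = np.zeros(Y.shape[1])
            ps[v] = np.ones(Y.shape[1])
            continue
        b = (xc @ Yc) / ss_x
        a = Y.mean(axis=0) - b * x.mean()
        fitted_ss = b**2 * ss_x
        with np.errstate(invalid="ignore", divide="ignore"):
            r2 = np.where(ss_y > 0, fitted_ss / ss_y, 0.0)
        r2 = np.clip(r2, 0.0, 1.0)
        dof = n - 2
        with np.errstate(invalid="ignore", divide="ignore"):
            f = r2 * dof / np.maximum(1.0 - r2, 1e-300)
        pv = stats.f.sf(f, 1, dof)
        slopes[v], intercepts[v], r2s[v], ps[v] = b, a, r2, pv

    idx = list(F.columns)
    return RONAModels(
        variables=list(env.columns),
        locus_ids=idx,
        populations=list(F.index),
        slope=pd.DataFrame(slopes, index=idx),
        intercept=pd.DataFrame(intercepts, index=idx),
        r2=pd.DataFrame(r2s, index=idx),
        p=pd.DataFrame(ps, index=idx),
        current_freq=F.copy(),
        p_filter=p_filter,
    )


def compute_rona(
    models: RONAModels,
    env_current: pd.DataFrame,
    env_future: pd.DataFrame,
    scenario: str = "future",
    use_fitted_current: bool = False,
) -> RONATable:
    """Project the fitted regressions to a future climate.

    Per SNP: predicted future frequency = clamp₀₁(a + b·x_future); the
    change is |prediction − current frequency| where "current" is the
    observed value by default (``use_fitted_current=True`` switches to the
    model's own prediction at the current climate, which makes RONA vanish
    exactly when future equals current).  RONA per population × variable is
    the mean change over SNPs passing the significance pre-filter;
    ``weighted_rona`` weights SNPs by their regression R².
    """
    missing = [p for p in models.populations if p not in env_future.index]
    if missing:
        raise ValueError(f"population(s) absent from future env table: {missing}")
    rows = []
    for v in models.variables:
        b = models.slope[v].to_numpy()
        a = models.intercept[v].to_numpy()
        r2 = models.r2[v].to_numpy()
        pv = models.p[v].to_numpy()
        sig = np.ones(len(b), dtype=bool) if models.p_filter is None else pv < models.p_filter
        for pop in models.populations:
            x_fut = float(env_future.loc[pop, v])
            pred_fut = np.clip(a + b * x_fut, 0.0, 1.0)
            if use_fitted_current:
                x_cur = float(env_current.loc[pop, v])
                cur = np.clip(a + b * x_cur, 0.0, 1.0)
            else:
                cur = models.current_freq.loc[pop].to_numpy()
            change = np.abs(pred_fut - cur)[sig]
            w = r2[sig]
            n_snps = int(sig.sum())
            if n_snps == 0:
                continue
            rona = float(change.mean())
            weighted = float((change * w).sum() / w.sum()) if w.sum() > 0 else rona
            se = float(change.std(ddof=1) / np.sqrt(n_snps)) if n_snps > 1 else 0.0
            rows.append(
                {
                    "population": pop,
                    "variable": v,
                    "rona": rona,
                    "weighted_rona": weighted,
                    "se": se,
                    "n_snps": n_snps,
                    "mean_r2": float(w.mean()) if n_snps else np.nan,
                }
            )
    return RONATable(table=pd.DataFrame(rows), scenario=scenario)


def top_variables(rona_table: RONATable, k: int = 3) -> list[str]:
    """Variables ranked by mean weighted RONA across populations (top k).

    Ties break lexicographically for determinism; if ``k`` exceeds the
    variable count all are returned with a warning.
    """
    t = rona_table.table
    means = t.groupby("variable")["weighted_rona"].mean()
    if k > len(means):
        warnings.warn("k exceeds number of variables; returning all")
        k = len(means)
    order = sorted(means.index, key=lambda v: (-means[v], v))
    return order[:k]
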