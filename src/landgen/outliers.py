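"""Selection-signature scans and consensus outlier sets.

Four scans mirror the standard landscape-genomics toolbox:

* :func:`pcadapt_scan` — PCA-based Mahalanobis outlier test (z-scores of
  each SNP on the first K principal components, robust covariance, genomic
  inflation rescaling, χ²_K p-values, Bonferroni control).
* :func:`outflank_scan` — trimmed FST-distribution test: per-locus FST
  without sample-size correction, loci with low expected heterozygosity
  excluded, a scaled χ² null fitted by truncated maximum likelihood to the
  trimmed body, right-tail p-values, Benjamini–Hochberg q-values.
* :func:`lfmm_scan` — latent-factor mixed model in its deterministic
  ridge/least-squares form: K latent factors estimated from residuals,
  per-SNP environmental effects, genomic-inflation-calibrated p-values.
* :func:`structured_assoc_scan` — structure-corrected association on
  population allele frequencies: generalized least squares whitened by the
  neutral among-population covariance Ω, dual-gated with the top-5 %
  Spearman |ρ| rule (a deterministic stand-in for Bayes-factor MCMC
  association, preserving its decision rule).

:func:`consensus_sets` combines the per-method flags into the four SNP
categories (all / FST / GEA / all-outlier) with Venn counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .variants import AlleleFreqMatrix, GenotypeMatrix

__all__ = [
    "OutlierReport",
    "pca_structure",
    "pcadapt_scan",
    "outflank_scan",
    "lfmm_scan",
    "structured_assoc_scan",
    "consensus_sets",
    "top_fraction",
]


@dataclass
class OutlierReport:
    """Per-locus scan statistics and flags for one method."""

    method: str
    locus_ids: np.ndarray
    stats: pd.DataFrame  # per-locus columns (method specific)
    flagged: np.ndarray  # boolean per locus
    K_used: int | None = None
    extra: dict = field(default_factory=dict)

    @property
    def flagged_ids(self) -> set[str]:
        return set(self.locus_ids[self.flagged])


# ---------------------------------------------------------------------------
# PCA


def pca_structure(x, n_components: int = 3, scale: bool = False):
    """PCA of a centered dosage (or frequency) matrix.

    Accepts a :class:`GenotypeMatrix` (must be imputed), an
    :class:`AlleleFreqMatrix`, or a plain array.  Sign convention: in each
    loading vector the largest-|loading| element is positive.

    Returns ``(scores, loadings, explained_variance)``.
    """
    if isinstance(x, GenotypeMatrix):
        if (x.dosage < 0).any():
            raise ValueError("impute missing genotypes before PCA")
        M = x.dosage.astype(float)
    elif isinstance(x, AlleleFreqMatrix):
        M = x.freq.to_numpy(dtype=float)
    else:
        M = np.asarray(x, dtype=float)
    M = M - M.mean(axis=0)
    if scale:
        sd = M.std(axis=0, ddof=0)
        M = M / np.where(sd > 0, sd, 1.0)
    rank = min(M.shape) - 1 if min(M.shape) > 1 else 1
    if n_components > rank:
        raise ValueError(f"n_components={n_components} exceeds rank {rank}")
    U, S, Vt = np.linalg.svd(M, full_matrices=False)
    U, S, Vt = U[:, :n_components], S[:n_components], Vt[:n_components]
    # deterministic sign: largest-|loading| entry positive
    for k in range(n_components):
        j = int(np.argmax(np.abs(Vt[k])))
        if Vt[k, j] < 0:
            Vt[k] *= -1
            U[:, k] *= -1
    scores = U * S
    explained = S**2 / (M.shape[0] - 1)
    return scores, Vt.T, explained


# ---------------------------------------------------------------------------
# pcadapt-style scan


def _gif(chi2_vals: np.ndarray, df: int) -> float:
    """Genomic inflation factor: median χ² over the theoretical median."""
    return float(np.median(chi2_vals) / stats.chi2.ppf(0.5, df))


def pcadapt_scan(gm: GenotypeMatrix, K: int = 3, alpha: float = 0.05) -> OutlierReport:
    """PCA-based outlier scan with Bonferroni control.

    Each SNP is regressed on the first K PC scores; the K-vector of
    regression z-scores is standardized by a robust covariance (minimum
    covariance determinant, median/MAD diagonal fallback); Mahalanobis D²
    is rescaled by the genomic inflation factor and referred to χ²_K.
    Constant SNPs are excluded (flag False, NaN statistics) with a reason.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    G = gm.dosage.astype(float)
    if (G < 0).any():
        raise ValueError("impute missing genotypes before scanning")
    n, L = G.shape
    var = G.var(axis=0)
    ok = var > 0
    if not ok.any():
        raise ValueError("all SNPs are constant")
    scores, _, _ = pca_structure(G[:, ok], n_components=K)

    X = np.column_stack([np.ones(n), scores])
    XtX_inv = np.linalg.inv(X.T @ X)
    B = XtX_inv @ X.T @ G[:, ok]  # (K+1, L_ok)
    resid = G[:, ok] - X @ B
    dof = n - (K + 1)
    sigma2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(np.outer(np.diag(XtX_inv)[1:], sigma2))
    Z = (B[1:] / np.maximum(se, 1e-300)).T  # (L_ok, K)

    cov, loc = _robust_cov(Z)
    d = Z - loc
    d2 = np.einsum("ij,jk,ik->i", d, np.linalg.inv(cov), d)
    lam = _gif(d2, K)
    pvals = stats.chi2.sf(d2 / lam, K)

    p_full = np.full(L, np.nan)
    d2_full = np.full(L, np.nan)
    p_full[ok] = pvals
    d2_full[ok] = d2
    flagged = np.zeros(L, dtype=bool)
    flagged[ok] = pvals * ok.sum() < alpha  # Bonferroni
    return OutlierReport(
        method="pcadapt",
        locus_ids=gm.locus_ids,
        stats=pd.DataFrame(
            {"mahalanobis_d2": d2_full, "pcadapt_p": p_full}, index=gm.locus_ids
        ),
        flagged=flagged,
        K_used=K,
        extra={"gif": lam, "n_excluded_constant": int((~ok).sum())},
    )


def _robust_cov(Z: np.ndarray):
    """Robust covariance/location of z-score vectors; MCD with MAD fallback."""
    from sklearn.covariance import MinCovDet

    # canonical row order so the MCD subsampling (hence the fitted
    # covariance) is invariant to locus ordering
    Zc = Z[np.lexsort(Z.T)]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mcd = MinCovDet(random_state=0).fit(Zc)
        if np.linalg.cond(mcd.covariance_) < 1e10:
            return mcd.covariance_, mcd.location_
    except Exception:
        pass
    med = np.median(Z, axis=0)
    mad = stats.median_abs_deviation(Z, axis=0, scale="normal")
    return np.diag(np.maximum(mad, 1e-12) ** 2), med


# ---------------------------------------------------------------------------
# OutFLANK-style scan


def _fst_nocorr(gm: GenotypeMatrix, grouping) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus FST without sample-size correction, and pooled He.

    Infinite-sample Weir–Cockerham ratio s²/(p̄q̄ + s²/r): the shape of its
    null distribution (a scaled χ²) is what the trimmed-likelihood fit
    estimates, so the finite-sample correction terms are unnecessary here.
    """
    from .popgen import _group_stats

    labels, n, p, _ = _group_stats(gm, grouping)
    r = len(labels)
    with np.errstate(invalid="ignore", divide="ignore"):
        nsum = n.sum(axis=0)
        pbar = (n * p).sum(axis=0) / nsum
        nbar = n.mean(axis=0)
        s2 = (n * (p - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        pq = pbar * (1 - pbar)
        fst = np.where(pq + s2 / r > 0, s2 / (pq + s2 / r), np.nan)
        he = 2 * pq
    return fst, he


def outflank_scan(
    gm: GenotypeMatrix,
    grouping="population",
    left_trim: float = 0.05,
    right_trim: float = 0.05,
    min_het: float = 0.1,
    fdr: float = 0.05,
) -> OutlierReport:
    """Trimmed FST-distribution outlier test.

    Loci with pooled expected heterozygosity ≤ ``min_het`` are excluded from
    the null fit; the central body of the FST distribution (trimming the
    lowest/highest 5 % by default) is fitted by maximum likelihood to a
    scaled χ² (free df and mean), truncated to the trim bounds; right-tail
    p-values for all loci come from the fitted null, with BH q-values and a
    flag at q < ``fdr``.
    """
    fst, he = _fst_nocorr(gm, grouping)
    L = gm.n_loci
    eligible = np.isfinite(fst) & (he > min_het) & (fst > 0)
    vals = fst[eligible]
    if vals.size:
        lo, hi = np.quantile(vals, [left_trim, 1 - right_trim])
        body = vals[(vals >= lo) & (vals <= hi)]
    else:
        body = vals
    if body.size < 20:
        raise ValueError("fewer than 20 loci in the trimmed body; cannot fit null")

    df_fit, mean_fit = _fit_trunc_chi2(body, lo, hi)

    pvals = np.full(L, np.nan)
    with np.errstate(invalid="ignore"):
        scale = mean_fit / df_fit
        pvals[eligible] = stats.chi2.sf(fst[eligible] / scale, df_fit)
    qvals = np.full(L, np.nan)
    qvals[eligible] = multipletests(pvals[eligible], method="fdr_bh")[1]
    flagged = np.zeros(L, dtype=bool)
    flagged[eligible] = qvals[eligible] < fdr
    return OutlierReport(
        method="outflank",
        locus_ids=gm.locus_ids,
        stats=pd.DataFrame(
            {"fst_nocorr": fst, "he": he, "outflank_p": pvals, "outflank_q": qvals},
            index=gm.locus_ids,
        ),
        flagged=flagged,
        extra={"df": df_fit, "mean_fst": mean_fit,
               "n_excluded_lowhet": int((he <= min_het).sum())},
    )


def _fit_trunc_chi2(body: np.ndarray, lo: float, hi: float) -> tuple[float, float]:
    """ML fit of FST ~ (mean/df)·χ²_df truncated to [lo, hi]."""
    from scipy.optimize import minimize

    def nll(theta):
        log_df, log_mean = theta
        df, mean = np.exp(log_df), np.exp(log_mean)
        scale = mean / df
        x = body / scale
        ll = stats.chi2.logpdf(x, df) - np.log(scale)
        z = stats.chi2.cdf(hi / scale, df) - stats.chi2.cdf(lo / scale, df)
        if z <= 0:
            return 1e12
        return -(ll.sum() - body.size * np.log(z))

    x0 = np.log([2.0, float(np.mean(body))])
    res = minimize(nll, x0, method="Nelder-Mead",
                   options={"xatol": 1e-6, "fatol": 1e-6, "maxiter": 2000})
    df_fit, mean_fit = np.exp(res.x)
    return float(df_fit), float(mean_fit)


# ---------------------------------------------------------------------------
# LFMM-style scan


def lfmm_scan(
    gm: GenotypeMatrix,
    env: pd.DataFrame,
    K: int = 3,
    p_adj_threshold: float = 0.001,
    fdr: float = 0.05,
    n_sweeps: int = 1,
) -> OutlierReport:
    """Latent-factor association scan (deterministic ridge form).

    ``env`` is a populations × variables table (mapped to individuals via
    the genotype matrix's population labels) or an individuals × variables
    table indexed by individual id; variables are standardized internally.
    For each variable: regress genotypes on the variable, estimate K latent
    factors from the residuals by truncated SVD, refit genotype ~ variable +
    factors, calibrate z² by the genomic inflation factor and refer to χ²₁.
    Flags combine the calibrated p < ``p_adj_threshold`` rule with BH
    q < ``fdr``; a SNP is flagged if any variable flags it.
    """
    G = gm.dosage.astype(float)
    if (G < 0).any():
        raise ValueError("impute missing genotypes before scanning")
    n, L = G.shape
    if K >= min(n, L):
        raise ValueError("K must be smaller than both matrix dimensions")
    X_ind = _env_per_individual(gm, env)
    X_ind = X_ind - X_ind.mean(axis=0)
    sd = X_ind.std(axis=0, ddof=0)
    keep_vars, dropped = [], []
    for i, v in enumerate(X_ind.columns):
        if sd.iloc[i] == 0:
            dropped.append(v)
            continue
        keep_vars.append(v)
    if dropped:
        warnings.warn(f"dropping constant env variables: {dropped}")
    X_ind = X_ind[keep_vars] / sd[keep_vars]
    # drop exact duplicates (collinear columns)
    _, uniq_idx = np.unique(np.round(X_ind.T, 12), axis=0, return_index=True)
    if len(uniq_idx) < len(keep_vars):
        warnings.warn("dropping duplicate env columns")
        keep_vars = [keep_vars[i] for i in sorted(uniq_idx)]
        X_ind = X_ind[keep_vars]

    Gc = G - G.mean(axis=0)
    z_cols, p_cols = {}, {}
    lams = {}
    for v in keep_vars:
        x = X_ind[v].to_numpy()
        W = np.zeros((n, 0))
        for _ in range(n_sweeps):
            D = np.column_stack([np.ones(n), x, W])
            B, *_ = np.linalg.lstsq(D, Gc, rcond=None)
            R = Gc - D @ B
            U, S, _ = np.linalg.svd(R, full_matrices=False)
            W = U[:, :K] * S[:K]
        D = np.column_stack([np.ones(n), x, W])
        DtD_inv = np.linalg.inv(D.T @ D)
        B = DtD_inv @ D.T @ Gc
        resid = Gc - D @ B
        dof = max(n - D.shape[1], 1)
        sigma2 = (resid**2).sum(axis=0) / dof
        se = np.sqrt(DtD_inv[1, 1] * sigma2)
        z = B[1] / np.maximum(se, 1e-300)
        lam = _gif(z**2, 1)
        p = stats.chi2.sf(z**2 / lam, 1)
        z_cols[f"gea_z_{v}"] = z
        p_cols[v] = p
        lams[v] = lam

    P = pd.DataFrame(p_cols, index=gm.locus_ids)
    Q = P.apply(lambda c: multipletests(c, method="fdr_bh")[1], axis=0)
    flag_p = (P < p_adj_threshold).any(axis=1).to_numpy()
    flag_q = (Q < fdr).any(axis=1).to_numpy()
    # the dual rule applies per variable: the same variable must satisfy
    # both the calibrated-p and the FDR gate
    flag_both = ((P < p_adj_threshold) & (Q < fdr)).any(axis=1).to_numpy()
    stats_df = pd.DataFrame(z_cols, index=gm.locus_ids)
    stats_df["gea_p_adjusted"] = P.min(axis=1)
    stats_df["gea_q"] = Q.min(axis=1)
    return OutlierReport(
        method="lfmm",
        locus_ids=gm.locus_ids,
        stats=stats_df,
        flagged=flag_both,
        K_used=K,
        extra={"gif": lams, "p_by_variable": P, "q_by_variable": Q,
               "flag_p": flag_p, "flag_q": flag_q},
    )


def _env_per_individual(gm: GenotypeMatrix, env: pd.DataFrame) -> pd.DataFrame:
    """Broadcast a per-population env table to individuals (or pass through)."""
    pops = gm.populations
    if set(pops.unique()) <= set(env.index):
        out = env.loc[pops.to_numpy()].copy()
        out.index = gm.individual_ids
        return out
    if set(gm.individual_ids) <= set(env.index):
        return env.loc[gm.individual_ids].copy()
    raise ValueError("env table index matches neither populations nor individuals")


# ---------------------------------------------------------------------------
# Structure-corrected association (Bayes-factor-style stand-in)


def structured_assoc_scan(
    af: AlleleFreqMatrix,
    env: pd.DataFrame,
    neutral_set,
    score_tail: float = 0.99,
    rho_top_frac: float = 0.05,
) -> OutlierReport:
    """GLS association on population allele frequencies, whitened by the
    neutral among-population covariance Ω, dual-gated by Spearman |ρ|.

    ``neutral_set`` lists locus ids presumed neutral (non-FST-outlier);
    Ω is the covariance of populations across standardized neutral
    frequencies (ridge-regularized if singular).  Per SNP × variable the
    score is the squared GLS t-statistic; the evidence threshold is the
    χ²₁ ``score_tail`` quantile scaled by the genomic inflation factor of
    the neutral scores (mapping the "strong evidence" Bayes-factor rule to
    a calibrated tail), and a SNP is flagged for a variable iff its score
    exceeds the threshold AND |ρ| is in the top ``rho_top_frac`` for that
    variable.
    """
    F = af.freq
    pops = list(F.index)
    env = env.loc[pops]
    env_sd = env.std(ddof=0)
    keep = [v for v in env.columns if env_sd[v] > 0]
    if not keep:
        warnings.warn("all environmental variables constant; nothing to test")
        return OutlierReport(
            method="assoc",
            locus_ids=np.asarray(F.columns, dtype=object),
            stats=pd.DataFrame(index=F.columns),
            flagged=np.zeros(F.shape[1], dtype=bool),
            extra={"degenerate": True},
        )
    env = (env[keep] - env[keep].mean()) / env_sd[keep]

    Fv = F.to_numpy(dtype=float)
    Fv = np.where(np.isnan(Fv), np.nanmean(Fv, axis=0, keepdims=True), Fv)
    mu = Fv.mean(axis=0)
    sd = Fv.std(axis=0, ddof=0)
    Zf = (Fv - mu) / np.where(sd > 0, sd, 1.0)

    neutral_mask = np.isin(np.asarray(F.columns, dtype=object), list(neutral_set))
    if neutral_mask.sum() < 2:
        raise ValueError("neutral set too small to estimate covariance")
    omega = np.cov(Zf[:, neutral_mask])
    # centering makes Omega structurally rank-deficient (rows sum to ~0);
    # a base ridge restores invertibility, larger jitter is warned about
    jitter = 1e-6
    while np.linalg.cond(omega + jitter * np.eye(len(pops))) > 1e10:
        jitter *= 10
        if jitter > 1.0:
            break
    if jitter > 1e-4:
        warnings.warn(f"Omega near-singular; ridge jitter {jitter:g} applied")
    omega = omega + jitter * np.eye(len(pops))
    evals, evecs = np.linalg.eigh(omega)
    Wm = evecs @ np.diag(1.0 / np.sqrt(np.maximum(evals, 1e-12))) @ evecs.T  # Ω^{-1/2}

    n = len(pops)
    L = F.shape[1]
    scores = {}
    rhos = {}
    Yw_all = Wm @ Zf
    ones_w = Wm @ np.ones(n)
    for v in env.columns:
        xw = Wm @ env[v].to_numpy()
        X = np.column_stack([ones_w, xw])
        XtX_inv = np.linalg.inv(X.T @ X)
        B = XtX_inv @ X.T @ Yw_all
        resid = Yw_all - X @ B
        dof = n - 2
        sigma2 = (resid**2).sum(axis=0) / dof
        se = np.sqrt(XtX_inv[1, 1] * sigma2)
        t = B[1] / np.maximum(se, 1e-300)
        scores[v] = t**2
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # constant loci give NaN rho
            rho = np.array(
                [stats.spearmanr(Fv[:, j], env[v].to_numpy()).statistic
                 for j in range(L)]
            )
        rhos[v] = rho

    S = pd.DataFrame(scores, index=F.columns)
    R = pd.DataFrame(rhos, index=F.columns)
    flags = pd.DataFrame(False, index=F.columns, columns=env.columns)
    thresholds = {}
    for v in env.columns:
        neut_scores = S.loc[neutral_mask, v].to_numpy()
        lam = max(_gif(neut_scores, 1), 1e-12)
        thr = lam * stats.chi2.ppf(score_tail, 1)
        thresholds[v] = thr
        rho_cut = np.nanquantile(np.abs(R[v]), 1 - rho_top_frac)
        with np.errstate(invalid="ignore"):
            flags[v] = (S[v] > thr) & (np.abs(R[v]) >= rho_cut).fillna(False)

    stats_df = pd.concat(
        [S.add_prefix("assoc_score_"), R.add_prefix("spearman_rho_")], axis=1
    )
    return OutlierReport(
        method="assoc",
        locus_ids=np.asarray(F.columns, dtype=object),
        stats=stats_df,
        flagged=flags.any(axis=1).to_numpy(),
        extra={"thresholds": thresholds, "flags_by_variable": flags,
               "omega_jitter": jitter},
    )


# ---------------------------------------------------------------------------
# Consensus


def consensus_sets(reports: dict[str, OutlierReport], mode: str = "union"):
    """Combine scan flags into the four SNP categories.

    ``reports`` maps method name ('pcadapt', 'outflank', 'lfmm', 'assoc') to
    its report; all must share one locus universe.  Within each family
    (FST-based: pcadapt+outflank; GEA-based: lfmm+assoc) sets are combined
    by ``mode`` ('union' default, or 'intersection'); the all-outlier set is
    always FST ∪ GEA.  Returns a dict with the three sets and Venn counts.
    """
    universes = {tuple(r.locus_ids) for r in reports.values()}
    if len(universes) != 1:
        raise ValueError("reports do not share a locus universe")
    if mode not in ("union", "intersection"):
        raise ValueError("mode must be 'union' or 'intersection'")

    def combine(a: set, b: set) -> set:
        return (a | b) if mode == "union" else (a & b)

    fst_members = [reports[m].flagged_ids for m in ("pcadapt", "outflank") if m in reports]
    gea_members = [reports[m].flagged_ids for m in ("lfmm", "assoc") if m in reports]
    fst_set = combine(*fst_members) if len(fst_members) == 2 else (
        fst_members[0] if fst_members else set()
    )
    gea_set = combine(*gea_members) if len(gea_members) == 2 else (
        gea_members[0] if gea_members else set()
    )
    all_outlier = fst_set | gea_set
    venn = {}
    if len(fst_members) == 2:
        venn["fst"] = _venn2(*fst_members)
    if len(gea_members) == 2:
        venn["gea"] = _venn2(*gea_members)
    venn["families"] = _venn2(fst_set, gea_set)
    return {
        "fst": fst_set,
        "gea": gea_set,
        "all_outlier": all_outlier,
        "venn": venn,
    }


def _venn2(a: set, b: set) -> dict[str, int]:
    return {
        "only_a": len(a - b),
        "only_b": len(b - a),
        "shared": len(a & b),
        "union": len(a | b),
    }


def top_fraction(report: OutlierReport, stat: str, frac: float = 0.2,
                 largest: bool = True) -> set[str]:
    """Top-``frac`` flagged loci ranked by a statistic (sub-ranking helper)."""
    flagged = report.stats.loc[report.flagged, stat].dropna()
    k = max(int(round(frac * len(flagged))), 0)
    ordered = flagged.sort_values(ascending=not largest)
    return set(ordered.index[:k])
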