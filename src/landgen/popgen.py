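"""Diversity and differentiation statistics.

Weir & Cockerham (1984) FST (per-locus variance components a/b/c, multilocus
ratio-of-sums), observed/expected heterozygosity with the small-sample
2n/(2n−1) correction, nucleotide diversity over windows including invariant
callable sites (the pixy estimator), rarefied allelic richness, and
private-allele / polymorphic-locus counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .variants import MISSING, GenotypeMatrix

__all__ = [
    "FstResult",
    "DiversitySummary",
    "wc_fst",
    "pairwise_fst",
    "fst_linear",
    "heterozygosity",
    "pi_windows",
    "allelic_richness",
    "private_and_polymorphic",
    "diversity_summary",
]


@dataclass
class FstResult:
    """Weir–Cockerham variance components and the ratio-of-sums estimate."""

    groups: list[str]
    per_locus_a: np.ndarray
    per_locus_b: np.ndarray
    per_locus_c: np.ndarray
    fst_per_locus: np.ndarray
    fst_multilocus: float
    locus_ids: np.ndarray


@dataclass
class DiversitySummary:
    """Per-group diversity table: N, N_P, PL(%), H_O, H_E, pi, AR."""

    table: pd.DataFrame


def _group_stats(gm: GenotypeMatrix, grouping):
    """Per-group per-locus (n called, alt freq, obs het fraction)."""
    if isinstance(grouping, str):
        groups = gm.grouping(grouping)
    else:
        groups = np.asarray(grouping)
    labels = list(dict.fromkeys(groups))
    d = gm.dosage
    called = d != MISSING
    n = np.empty((len(labels), gm.n_loci))
    p = np.empty_like(n)
    h = np.empty_like(n)
    for i, g in enumerate(labels):
        rows = groups == g
        nc = called[rows].sum(axis=0).astype(float)
        alt = np.where(called[rows], d[rows], 0).sum(axis=0)
        het = ((d[rows] == 1) & called[rows]).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            n[i] = nc
            p[i] = np.where(nc > 0, alt / (2 * nc), np.nan)
            h[i] = np.where(nc > 0, het / nc, np.nan)
    return labels, n, p, h


def wc_fst(gm: GenotypeMatrix, grouping="population") -> FstResult:
    """Weir & Cockerham (1984) theta over ``grouping``.

    Per locus the components are::

        a = (n̄/nc) [s² − (p̄q̄ − s²(r−1)/r − h̄/4) / (n̄−1)]
        b = (n̄/(n̄−1)) [p̄q̄ − s²(r−1)/r − h̄(2n̄−1)/(4n̄)]
        c = h̄/2

    with r groups, n̄ mean sample size, nc the sample-size correction,
    p̄ the weighted mean frequency, s² the weighted among-group variance and
    h̄ the weighted mean heterozygote fraction.  The multilocus estimate is
    Σa / Σ(a+b+c); loci monomorphic across all groups are excluded.
    Small negative per-locus values are retained.
    """
    labels, n, p, h = _group_stats(gm, grouping)
    r = len(labels)
    if r < 2:
        raise ValueError("need at least 2 groups")
    # require every group to have at least one called genotype at a locus
    usable = (n > 0).all(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = n.mean(axis=0)
        nsum = n.sum(axis=0)
        nc = (nsum - (n**2).sum(axis=0) / nsum) / (r - 1)
        pbar = (n * p).sum(axis=0) / nsum
        s2 = (n * (p - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n * h).sum(axis=0) / nsum
        pq = pbar * (1 - pbar)

        a = (nbar / nc) * (
            s2 - (pq - s2 * (r - 1) / r - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pq - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
        )
        c = hbar / 2

    poly = usable & ~np.isclose(pbar * (1 - pbar) + s2, 0.0)
    a = np.where(poly, a, np.nan)
    b = np.where(poly, b, np.nan)
    c = np.where(poly, c, np.nan)
    denom = a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        per_locus = np.where(np.abs(denom) > 0, a / denom, np.nan)
    multi = float(np.nansum(a) / np.nansum(denom))
    return FstResult(
        groups=[str(g) for g in labels],
        per_locus_a=a,
        per_locus_b=b,
        per_locus_c=c,
        fst_per_locus=per_locus,
        fst_multilocus=multi,
        locus_ids=gm.locus_ids,
    )


def pairwise_fst(gm: GenotypeMatrix, grouping="population",
                 snp_set=None) -> pd.DataFrame:
    """Symmetric matrix of pairwise multilocus WC FST between groups.

    ``snp_set`` optionally restricts to a list of locus ids.  Groups with
    fewer than 2 individuals are kept with a warning (components remain
    defined).
    """
    import warnings

    g = gm if snp_set is None else gm.select_loci_by_id(snp_set)
    if isinstance(grouping, str):
        groups = g.grouping(grouping)
    else:
        groups = np.asarray(grouping)
    labels = list(dict.fromkeys(groups))
    sizes = pd.Series(groups).value_counts()
    if (sizes < 2).any():
        warnings.warn("some groups have < 2 individuals")
    out = pd.DataFrame(0.0, index=labels, columns=labels)
    for i, gi in enumerate(labels):
        for gj in labels[i + 1:]:
            rows = np.isin(groups, [gi, gj])
            sub = GenotypeMatrix(
                dosage=g.dosage[rows],
                individual_ids=g.individual_ids[rows],
                locus_ids=g.locus_ids,
                chrom=g.chrom,
                pos=g.pos,
                samples=g.samples,
            )
            val = wc_fst(sub, groups[rows]).fst_multilocus
            out.loc[gi, gj] = out.loc[gj, gi] = val
    return out


def fst_linear(fst: pd.DataFrame) -> pd.DataFrame:
    """FST/(1−FST) linearization (negative estimates clipped at 0)."""
    f = fst.clip(lower=0.0)
    return f / (1.0 - f)


def heterozygosity(gm: GenotypeMatrix, grouping="population") -> pd.DataFrame:
    """Mean observed and expected heterozygosity per group.

    H_O is the heterozygote fraction among called genotypes; H_E is
    2p(1−p)·2n/(2n−1) (unbiased).  Group values are means over loci that
    are called and polymorphic in that group.
    """
    labels, n, p, h = _group_stats(gm, grouping)
    rows = []
    with np.errstate(invalid="ignore"):
        for i, g in enumerate(labels):
            ok = (n[i] > 0) & (p[i] > 0) & (p[i] < 1)
            two_n = 2 * n[i, ok]
            he = 2 * p[i, ok] * (1 - p[i, ok]) * two_n / (two_n - 1)
            rows.append(
                {
                    "group": str(g),
                    "H_O": float(np.mean(h[i, ok])) if ok.any() else np.nan,
                    "H_E": float(np.mean(he)) if ok.any() else np.nan,
                }
            )
    return pd.DataFrame(rows).set_index("group")


def pi_windows(
    gm: GenotypeMatrix,
    grouping="population",
    total_sites_per_window=None,
) -> pd.DataFrame:
    """Nucleotide diversity per group, averaging windows that include
    invariant callable sites (pixy estimator).

    Windows are the VCF contigs (one RAD locus group per contig);
    ``total_sites_per_window`` is a dict contig → callable sites or a scalar
    applied to every window (required: invariant sites are absent from the
    VCF).  Per window::

        π = Σ_sites (# differing allele pairs) / Σ_sites (# compared pairs)

    where invariant callable sites contribute zero differences but a full
    complement of comparisons (the window's mean per-site pair count).
    Windows with zero comparisons are excluded from the mean.
    """
    if total_sites_per_window is None:
        raise ValueError("total callable sites per window are required")
    if isinstance(grouping, str):
        groups = gm.grouping(grouping)
    else:
        groups = np.asarray(grouping)
    labels = list(dict.fromkeys(groups))
    contigs = pd.Series(gm.chrom)
    d = gm.dosage
    called = d != MISSING

    def sites_for(c):
        if np.isscalar(total_sites_per_window):
            return float(total_sites_per_window)
        return float(total_sites_per_window[c])

    rows = []
    for g in labels:
        sel = groups == g
        pis = []
        for c, idx in contigs.groupby(contigs, sort=False).groups.items():
            idx = np.asarray(idx)
            n_all = 2 * called[np.ix_(sel, idx)].sum(axis=0).astype(float)
            alt = np.where(called[np.ix_(sel, idx)], d[np.ix_(sel, idx)], 0).sum(axis=0)
            ref = n_all - alt
            diffs = (alt * ref).sum()
            pairs_var = (n_all * (n_all - 1) / 2)
            variant_ok = n_all >= 2
            comp_var = pairs_var[variant_ok].sum()
            n_variant = int(variant_ok.sum())
            if n_variant == 0:
                continue
            mean_pairs = comp_var / n_variant
            total = sites_for(c)
            comp = comp_var + mean_pairs * max(total - n_variant, 0)
            if comp > 0:
                pis.append(diffs / comp)
        rows.append({"group": str(g), "pi": float(np.mean(pis)) if pis else np.nan})
    return pd.DataFrame(rows).set_index("group")


def allelic_richness(gm: GenotypeMatrix, grouping="population",
                     rarefaction_n: int | None = None) -> pd.DataFrame:
    """Rarefied allelic richness per group.

    Per locus, alleles are rarefied to ``g`` gene copies — by default the
    smallest 2n of called genotypes across groups at that locus — and::

        AR = Σ_alleles [1 − C(2n − k_a, g) / C(2n, g)]

    (hypergeometric probability the allele appears in a sample of g copies).
    Group AR is the mean over loci where every group has ≥ 1 called genotype.
    """
    labels, n, p, _ = _group_stats(gm, grouping)
    two_n = 2 * n
    usable = (n > 0).all(axis=0)
    if rarefaction_n is None:
        g_loc = two_n.min(axis=0)
    else:
        g_loc = np.full(gm.n_loci, float(rarefaction_n))
        usable &= (two_n >= g_loc).all(axis=0)
    usable &= g_loc >= 2

    def log_comb(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    rows = []
    with np.errstate(invalid="ignore", divide="ignore"):
        for i, lab in enumerate(labels):
            ar_loci = []
            tn = two_n[i]
            k_alt = np.round(p[i] * tn)
            for j in np.flatnonzero(usable):
                g = g_loc[j]
                total = 0.0
                for k in (k_alt[j], tn[j] - k_alt[j]):  # alt, ref counts
                    if k <= 0:
                        continue
                    if tn[j] - k >= g:
                        p_absent = np.exp(log_comb(tn[j] - k, g) - log_comb(tn[j], g))
                    else:
                        p_absent = 0.0
                    total += 1.0 - p_absent
                ar_loci.append(total)
            rows.append({"group": str(lab),
                         "AR": float(np.mean(ar_loci)) if ar_loci else np.nan})
    return pd.DataFrame(rows).set_index("group")


def private_and_polymorphic(gm: GenotypeMatrix, grouping="population") -> pd.DataFrame:
    """Private-allele counts and % polymorphic loci per group.

    An allele is private iff it is observed in exactly one group; a locus is
    polymorphic within a group iff both alleles are observed there.
    """
    labels, n, p, _ = _group_stats(gm, grouping)
    two_n = 2 * n
    k_alt = np.round(np.nan_to_num(p) * two_n)
    k_ref = two_n - k_alt
    has_alt = k_alt > 0
    has_ref = k_ref > 0
    priv_alt = has_alt & (has_alt.sum(axis=0, keepdims=True) == 1)
    priv_ref = has_ref & (has_ref.sum(axis=0, keepdims=True) == 1)
    poly = has_alt & has_ref
    rows = []
    for i, lab in enumerate(labels):
        rows.append(
            {
                "group": str(lab),
                "N_P": int(priv_alt[i].sum() + priv_ref[i].sum()),
                "PL": float(100.0 * poly[i].mean()),
            }
        )
    return pd.DataFrame(rows).set_index("group")


def diversity_summary(
    gm: GenotypeMatrix,
    grouping="lineage",
    total_sites_per_window=None,
) -> DiversitySummary:
    """Combined diversity table (N, N_P, PL, H_O, H_E, pi, AR) per group."""
    if isinstance(grouping, str):
        groups = gm.grouping(grouping)
    else:
        groups = np.asarray(grouping)
    pops = gm.grouping("population")
    # N = mean individuals per population within the group
    n_col = {}
    for g in dict.fromkeys(groups):
        sel = groups == g
        n_col[str(g)] = float(pd.Series(pops[sel]).value_counts().mean())
    het = heterozygosity(gm, grouping)
    pp = private_and_polymorphic(gm, grouping)
    ar = allelic_richness(gm, grouping)
    tbl = pd.concat([pp, het, ar], axis=1)
    tbl.insert(0, "N", pd.Series(n_col))
    if total_sites_per_window is not None:
        tbl["pi"] = pi_windows(gm, grouping, total_sites_per_window)["pi"]
    return DiversitySummary(table=tbl)
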