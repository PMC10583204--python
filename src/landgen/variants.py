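"""Genotype containers, VCF I/O, SNP filtering and structure-aware imputation.

The pipeline's spine is :class:`GenotypeMatrix`: an individuals × loci
alternate-allele dosage matrix (0/1/2, −1 for missing) with per-locus
coordinates and per-individual population labels.  Filtering applies the
standard RAD-seq quality rules in a fixed order (observed heterozygosity,
biallelic, one SNP per locus, MAF, per-population call rate, overall
missingness) with per-rule attribution, and imputation replaces missing
calls via a deterministic K-cluster matrix factorization of the genotype
indicator matrix (a least-squares analogue of sparse non-negative matrix
factorization ancestry models).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1  # sentinel dosage; all statistics must skip it

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "AlleleFreqMatrix",
    "FilterReport",
    "StructureModel",
    "read_vcf",
    "write_vcf",
    "filter_snps",
    "allele_frequencies",
    "impute_missing",
]


@dataclass
class GenotypeMatrix:
    """Diploid dosage matrix with locus and sample metadata.

    ``dosage[i, j]`` counts alternate alleles of individual ``i`` at locus
    ``j`` (0/1/2) or is :data:`MISSING`.  ``samples`` is indexed by
    individual_id and carries at least ``population_id`` (and usually
    ``lineage_id``).
    """

    dosage: np.ndarray
    individual_ids: np.ndarray
    locus_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        d = self.dosage
        ok = (d == MISSING) | ((d >= 0) & (d <= 2))
        if not ok.all():
            raise ValueError("dosage values must be in {0,1,2,MISSING}")
        if len(set(self.locus_ids)) != len(self.locus_ids):
            raise ValueError("locus_id not unique")
        missing_meta = set(self.individual_ids) - set(self.samples.index)
        if missing_meta:
            raise ValueError(f"individuals without metadata: {sorted(missing_meta)[:5]}")

    @property
    def n_individuals(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_loci(self) -> int:
        return self.dosage.shape[1]

    @property
    def populations(self) -> pd.Series:
        """population_id per individual, in matrix row order."""
        return self.samples.loc[self.individual_ids, "population_id"]

    def grouping(self, level: str = "population") -> np.ndarray:
        """Group label per individual: 'population', 'lineage', or a column name."""
        col = {"population": "population_id", "lineage": "lineage_id"}.get(level, level)
        return self.samples.loc[self.individual_ids, col].to_numpy()

    def called(self) -> np.ndarray:
        return self.dosage != MISSING

    def select_loci(self, idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            dosage=self.dosage[:, idx],
            individual_ids=self.individual_ids,
            locus_ids=self.locus_ids[idx],
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            samples=self.samples,
        )

    def select_loci_by_id(self, ids) -> "GenotypeMatrix":
        index = {l: i for i, l in enumerate(self.locus_ids)}
        idx = np.array([index[l] for l in ids], dtype=int)
        return self.select_loci(idx)


@dataclass
class AlleleFreqMatrix:
    """Populations × loci alternate-allele frequencies with call counts.

    ``freq`` is NaN where a population has zero called genotypes at a locus;
    ``n_called`` counts called *alleles* (2 × called genotypes).
    """

    freq: pd.DataFrame
    n_called: pd.DataFrame

    def __post_init__(self) -> None:
        f = self.freq.to_numpy()
        with np.errstate(invalid="ignore"):
            if np.nanmin(f, initial=0) < 0 or np.nanmax(f, initial=0) > 1:
                raise ValueError("frequencies outside [0,1]")
        n = self.n_called.to_numpy()
        if (n < 0).any() or (n % 2 != 0).any():
            raise ValueError("n_called must be even and >= 0")

    @property
    def populations(self) -> list[str]:
        return list(self.freq.index)

    @property
    def locus_ids(self) -> list[str]:
        return list(self.freq.columns)


_RULES = ("het", "biallelic", "one_per_locus", "maf", "pop_call_rate", "missing")


@dataclass
class FilterReport:
    """Counts of loci removed per rule (first rule that removes wins)."""

    n_input: int
    removed: dict[str, int] = field(default_factory=dict)

    @property
    def n_retained(self) -> int:
        return self.n_input - sum(self.removed.values())

    def reconciles(self) -> bool:
        return sum(self.removed.values()) + self.n_retained == self.n_input

    def to_frame(self) -> pd.DataFrame:
        rows = [{"rule": r, "removed": self.removed.get(r, 0)} for r in _RULES]
        rows.append({"rule": "retained", "removed": self.n_retained})
        return pd.DataFrame(rows)


@dataclass
class StructureModel:
    """Latent-cluster model from imputation: ancestry Q and expected dosage."""

    K: int
    Q: np.ndarray  # individuals × K, rows on the simplex
    Gexp: np.ndarray  # individuals × loci expected dosage in [0,2]
    converged: bool = True
    loss: float = np.nan


# ---------------------------------------------------------------------------
# VCF I/O


def write_vcf(gm: GenotypeMatrix, path: str) -> None:
    """Write a minimal VCF v4.2 with GT only; missing calls as './.'."""
    contigs = list(dict.fromkeys(gm.chrom))
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=landgen\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.individual_ids)
            + "\n"
        )
        for j in range(gm.n_loci):
            gts = "\t".join(gt_map[int(v)] for v in gm.dosage[:, j])
            fh.write(
                f"{gm.chrom[j]}\t{gm.pos[j]}\t{gm.locus_ids[j]}\tA\tT\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_vcf(path: str, sheet=None, biallelic_only: bool = True):
    """Read a VCF into a :class:`GenotypeMatrix`.

    ``sheet`` is a :class:`~landgen.synth.SampleSheet` (or a DataFrame with
    individual_id / population_id / lineage_id columns) covering every sample
    in the VCF.  Multiallelic records are dropped when ``biallelic_only``
    (counted in the returned :class:`FilterReport`), else an error is raised.

    Returns ``(GenotypeMatrix, FilterReport)``.
    """
    from cyvcf2 import VCF

    vcf = VCF(path, gts012=False)
    vcf_samples = list(vcf.samples)

    if sheet is not None:
        table = sheet.table if hasattr(sheet, "table") else sheet
        meta = table.set_index("individual_id") if "individual_id" in table.columns else table
        unknown = [s for s in vcf_samples if s not in meta.index]
        if unknown:
            raise ValueError(f"VCF sample(s) missing from sample sheet: {unknown[:5]}")
        cols = [c for c in ("population_id", "lineage_id") if c in meta.columns]
        samples_df = meta.loc[vcf_samples, cols].copy()
    else:
        samples_df = pd.DataFrame(
            {"population_id": ["pop1"] * len(vcf_samples)}, index=vcf_samples
        )

    dosages, locus_ids, chroms, poss = [], [], [], []
    n_multi = 0
    for v in vcf:
        if len(v.ALT) != 1:
            if not biallelic_only:
                raise ValueError(f"multiallelic record at {v.CHROM}:{v.POS}")
            n_multi += 1
            continue
        row = np.full(len(vcf_samples), MISSING, dtype=np.int8)
        for i, g in enumerate(v.genotypes):
            a0, a1 = g[0], g[1]
            if a0 < 0 or a1 < 0:
                continue  # missing or half-call -> missing
            row[i] = a0 + a1
        dosages.append(row)
        locus_ids.append(v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}")
        chroms.append(v.CHROM)
        poss.append(v.POS)

    report = FilterReport(n_input=len(dosages) + n_multi,
                          removed={"biallelic": n_multi} if n_multi else {})
    gm = GenotypeMatrix(
        dosage=np.array(dosages, dtype=np.int8).T.copy()
        if dosages
        else np.zeros((len(vcf_samples), 0), dtype=np.int8),
        individual_ids=np.array(vcf_samples, dtype=object),
        locus_ids=np.array(locus_ids, dtype=object),
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        samples=samples_df,
    )
    return gm, report


# ---------------------------------------------------------------------------
# Filtering


def filter_snps(
    gm: GenotypeMatrix,
    max_obs_het: float = 0.70,
    min_maf: float = 0.05,
    min_pop_call_rate: float = 0.70,
    max_missing: float = 0.20,
    one_per_locus: bool = True,
    report: FilterReport | None = None,
):
    """Apply the RAD-seq SNP quality filters in a fixed order.

    Order: observed heterozygosity > ``max_obs_het`` → (biallelic, enforced
    at read time) → first SNP per contig when ``one_per_locus`` → pooled
    MAF < ``min_maf`` → any population calling < ``min_pop_call_rate`` of its
    individuals → overall missingness ≥ ``max_missing`` (inclusive removal).
    Each removed locus is attributed to the first rule that rejects it.

    Returns ``(GenotypeMatrix, FilterReport)``; raises if nothing survives.
    """
    for t in (max_obs_het, min_maf, min_pop_call_rate, max_missing):
        if not (0 <= t <= 1):
            raise ValueError("thresholds must lie in [0,1]")
    d = gm.dosage
    called = d != MISSING
    n_called = called.sum(axis=0)

    if report is None:
        report = FilterReport(n_input=gm.n_loci)
    else:
        report = FilterReport(n_input=report.n_input, removed=dict(report.removed))

    alive = np.ones(gm.n_loci, dtype=bool)

    with np.errstate(invalid="ignore", divide="ignore"):
        # 1. observed heterozygosity among called individuals
        n_het = ((d == 1) & called).sum(axis=0)
        obs_het = np.where(n_called > 0, n_het / np.maximum(n_called, 1), 0.0)
        kill = alive & (obs_het > max_obs_het)
        report.removed["het"] = int(kill.sum())
        alive &= ~kill

        # 2. biallelic — guaranteed by read_vcf / synth; slot kept for the ledger
        report.removed.setdefault("biallelic", 0)

        # 3. one SNP per locus group (contig)
        if one_per_locus:
            first = pd.Series(gm.pos).groupby(pd.Series(gm.chrom), sort=False).idxmin()
            keep_first = np.zeros(gm.n_loci, dtype=bool)
            keep_first[first.to_numpy()] = True
            kill = alive & ~keep_first
            report.removed["one_per_locus"] = int(kill.sum())
            alive &= ~kill
        else:
            report.removed["one_per_locus"] = 0

        # 4. pooled MAF (computed on post-het-filter loci)
        alt = np.where(called, d, 0).sum(axis=0)
        p = np.where(n_called > 0, alt / np.maximum(2 * n_called, 1), 0.0)
        maf = np.minimum(p, 1 - p)
        kill = alive & (maf < min_maf)
        report.removed["maf"] = int(kill.sum())
        alive &= ~kill

        # 5. per-population call rate
        groups = gm.grouping("population")
        pop_ok = np.ones(gm.n_loci, dtype=bool)
        for g in dict.fromkeys(groups):
            rows = groups == g
            rate = called[rows].sum(axis=0) / rows.sum()
            pop_ok &= rate >= min_pop_call_rate
        kill = alive & ~pop_ok
        report.removed["pop_call_rate"] = int(kill.sum())
        alive &= ~kill

        # 6. overall missingness, inclusive removal at the threshold
        miss = (gm.n_individuals - n_called) / gm.n_individuals
        kill = alive & (miss >= max_missing)
        report.removed["missing"] = int(kill.sum())
        alive &= ~kill

    if not alive.any():
        raise ValueError("no loci survive filtering")
    return gm.select_loci(np.flatnonzero(alive)), report


# ---------------------------------------------------------------------------
# Allele frequencies


def allele_frequencies(gm: GenotypeMatrix, by: str = "population") -> AlleleFreqMatrix:
    """Alternate-allele frequency per group per locus.

    freq = Σ dosage / (2 × called genotypes); NaN (with a warning) where a
    group has no called genotypes at a locus.
    """
    if gm.n_loci == 0:
        raise ValueError("empty genotype matrix")
    groups = gm.grouping(by)
    labels = list(dict.fromkeys(groups))
    d = gm.dosage
    called = d != MISSING
    freq = np.empty((len(labels), gm.n_loci))
    n_called = np.empty((len(labels), gm.n_loci), dtype=np.int64)
    for i, g in enumerate(labels):
        rows = groups == g
        n = called[rows].sum(axis=0)
        alt = np.where(called[rows], d[rows], 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq[i] = np.where(n > 0, alt / (2.0 * n), np.nan)
        n_called[i] = 2 * n
    if np.isnan(freq).any():
        warnings.warn("some groups have zero called genotypes at some loci")
    return AlleleFreqMatrix(
        freq=pd.DataFrame(freq, index=labels, columns=gm.locus_ids),
        n_called=pd.DataFrame(n_called, index=labels, columns=gm.locus_ids),
    )


# ---------------------------------------------------------------------------
# Imputation


def _one_hot(d: np.ndarray) -> np.ndarray:
    """individuals × (loci·3) indicator matrix; missing triples all-zero."""
    n, L = d.shape
    X = np.zeros((n, L, 3))
    for g in (0, 1, 2):
        X[:, :, g] = d == g
    return X.reshape(n, 3 * L)


def _project_simplex(v: np.ndarray) -> np.ndarray:
    """Euclidean projection of each row of v onto the probability simplex."""
    n, k = v.shape
    u = np.sort(v, axis=1)[:, ::-1]
    css = np.cumsum(u, axis=1) - 1.0
    ind = np.arange(1, k + 1)
    cond = u - css / ind > 0
    rho = k - np.argmax(cond[:, ::-1], axis=1) - 1
    theta = css[np.arange(n), rho] / (rho + 1.0)
    return np.maximum(v - theta[:, None], 0.0)


def impute_missing(
    gm: GenotypeMatrix,
    K: int = 3,
    seed: int = 0,
    max_iter: int = 50,
    tol: float = 1e-5,
):
    """Impute missing dosages from inferred genetic structure.

    Deterministic alternating least squares on the genotype indicator matrix
    ``X`` (individuals × loci·3, missing triples held at their current
    expectation): ``X ≈ Q F`` with ``Q`` row-stochastic ancestry coefficients
    (simplex-projected) and ``F`` non-negative per-cluster genotype
    frequencies normalized so each locus triple sums to 1.  Missing entries
    are re-estimated from ``QF`` between sweeps and finally replaced by the
    modal expected genotype; observed entries are never altered.

    Returns ``(GenotypeMatrix, StructureModel)``.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if gm.n_individuals < K:
        raise ValueError("need at least K individuals")
    d = gm.dosage.astype(np.int8)
    n, L = d.shape
    obs = d != MISSING
    X = _one_hot(d)
    obs3 = np.repeat(obs, 3, axis=1)

    # initialize missing triples with per-locus genotype frequencies
    with np.errstate(invalid="ignore", divide="ignore"):
        col_counts = X.sum(axis=0).reshape(L, 3)
        col_n = col_counts.sum(axis=1, keepdims=True)
        col_freq = np.where(col_n > 0, col_counts / np.maximum(col_n, 1), 1 / 3)
    fill = np.tile(col_freq.reshape(-1), (n, 1))
    X = np.where(obs3, X, fill)

    # deterministic init: K seeds spread by farthest-point on dosage rows
    rng = np.random.default_rng(seed)
    d_filled = X.reshape(n, L, 3) @ np.array([0.0, 1.0, 2.0])
    seeds = [int(rng.integers(n))]
    for _ in range(1, K):
        dist = np.min(
            [np.linalg.norm(d_filled - d_filled[s], axis=1) for s in seeds], axis=0
        )
        seeds.append(int(np.argmax(dist)))
    centers = d_filled[seeds]
    assign = np.argmin(
        ((d_filled[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2), axis=1
    )
    Q = np.full((n, K), 0.1 / max(K - 1, 1))
    Q[np.arange(n), assign] = 0.9 if K > 1 else 1.0
    Q /= Q.sum(axis=1, keepdims=True)

    prev_loss = np.inf
    converged = False
    loss = np.nan
    for _ in range(max_iter):
        # F-step: least squares, clip, per-locus renormalize
        F, *_ = np.linalg.lstsq(Q, X, rcond=None)
        F = np.clip(F, 1e-9, None)
        F3 = F.reshape(K, L, 3)
        F = (F3 / F3.sum(axis=2, keepdims=True)).reshape(K, 3 * L)
        # Q-step: least squares rows, project to simplex
        Qt, *_ = np.linalg.lstsq(F.T, X.T, rcond=None)
        Q = _project_simplex(Qt.T)
        P = Q @ F
        # refresh missing entries from the model
        P3 = P.reshape(n, L, 3)
        P3 = P3 / np.maximum(P3.sum(axis=2, keepdims=True), 1e-12)
        X = np.where(obs3, X, P3.reshape(n, 3 * L))
        loss = float(((X - P)[obs3] ** 2).sum())
        if prev_loss - loss < tol * max(prev_loss, 1.0):
            converged = True
            break
        prev_loss = loss

    P3 = (Q @ F).reshape(n, L, 3)
    # round before argmax so exact probability ties break to the lower
    # dosage (matching a counts-based mode) instead of on float noise
    modal = np.argmax(np.round(P3, 9), axis=2).astype(np.int8)
    out = d.copy()
    out[~obs] = modal[~obs]
    gexp = P3 @ np.array([0.0, 1.0, 2.0])
    model = StructureModel(K=K, Q=Q, Gexp=np.clip(gexp, 0.0, 2.0),
                           converged=converged, loss=loss)
    gm_out = GenotypeMatrix(
        dosage=out,
        individual_ids=gm.individual_ids,
        locus_ids=gm.locus_ids,
        chrom=gm.chrom,
        pos=gm.pos,
        samples=gm.samples,
    )
    return gm_out, model
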