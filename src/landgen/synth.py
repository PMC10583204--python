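"""Synthetic landscapes, populations and genotypes with known truth.

This module generates data with the structure of a range-wide RAD-seq
landscape-genomics study: a spatially autocorrelated environmental surface
with one or more future-climate scenarios, populations sampled on that
surface and grouped into a small number of geographically contiguous
lineages, and biallelic SNP genotypes whose population allele frequencies
follow a two-level Balding–Nichols hierarchy (lineage, then population)
with an optional logit-linear cline in a named environmental driver for
"adaptive" loci.  Every output is a pure function of its parameters and a
seed, and the truth labels (which loci are adaptive, which variable drives
them, the simulated slope) are retained so downstream scans can be scored
against ground truth.

The default study design mirrors a typical montane relict-tree dataset:
28 populations, 160 individuals in 3 lineages, ~8 k SNPs with lineage-level
differentiation in the 0.1–0.3 range, and WorldClim-like variable names
with low- and high-emission future deltas.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LandscapeGrid",
    "SampleSheet",
    "TruthLabels",
    "DEFAULT_VARIABLES",
    "DEFAULT_FUTURE_DELTAS",
    "simulate_landscape",
    "simulate_populations",
    "simulate_genotypes",
    "draw_effect_sizes",
    "population_env",
    "write_fixture",
    "study_fixture",
]

#: WorldClim-style predictor set: temperature regime (BIO02 mean diurnal
#: range, BIO03 isothermality, BIO04 seasonality, BIO07 annual range, BIO08
#: wettest-quarter mean), precipitation (BIO13 wettest month, BIO15
#: seasonality) and elevation.  (name, mean, sd) on roughly realistic scales.
DEFAULT_VARIABLES: tuple[tuple[str, float, float], ...] = (
    ("BIO02", 10.0, 2.0),
    ("BIO03", 35.0, 5.0),
    ("BIO04", 650.0, 120.0),
    ("BIO07", 28.0, 4.0),
    ("BIO08", 15.0, 4.0),
    ("BIO13", 180.0, 60.0),
    ("BIO15", 60.0, 15.0),
    ("elevation", 2200.0, 600.0),
)

#: Additive shifts per scenario for the 2081–2100 horizon.  SSP585 deltas
#: dominate SSP126 per variable (nested scenarios), as in the CMIP6
#: projections the study design emulates: warming raises temperature range
#: and seasonality, precipitation grows more episodic; elevation is static.
DEFAULT_FUTURE_DELTAS: dict[str, dict[str, float]] = {
    "SSP126": {
        "BIO02": 0.5, "BIO03": 1.0, "BIO04": 40.0, "BIO07": 1.2,
        "BIO08": 1.8, "BIO13": 15.0, "BIO15": 4.0, "elevation": 0.0,
    },
    "SSP585": {
        "BIO02": 1.2, "BIO03": 2.5, "BIO04": 110.0, "BIO07": 3.2,
        "BIO08": 4.5, "BIO13": 40.0, "BIO15": 11.0, "elevation": 0.0,
    },
}

# Bounding box of the simulated range (lon/lat decimal degrees); roughly a
# subtropical montane belt spanning ~22 degrees of longitude.
_BBOX = (98.0, 120.0, 24.0, 36.0)


@dataclass
class LandscapeGrid:
    """Grid of cells with current and future environmental vectors.

    ``env_current`` is a DataFrame indexed by ``cell_id`` with one column per
    variable; ``env_future`` maps scenario name to a DataFrame with identical
    index and columns.  ``cells`` carries lon/lat per cell.
    """

    cells: pd.DataFrame  # columns: lon, lat; index: cell_id
    env_current: pd.DataFrame
    env_future: dict[str, pd.DataFrame] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.env_current.isna().any().any():
            raise ValueError("env_current contains missing values")
        lon, lat = self.cells["lon"], self.cells["lat"]
        if (lon.abs() > 180).any() or (lat.abs() > 90).any():
            raise ValueError("coordinates out of range")
        cols = list(self.env_current.columns)
        for name, df in self.env_future.items():
            if list(df.columns) != cols:
                raise ValueError(
                    f"scenario {name!r} variables differ from env_current"
                )
            if df.isna().any().any() or not np.isfinite(df.to_numpy()).all():
                raise ValueError(f"scenario {name!r} contains non-finite values")

    @property
    def variables(self) -> list[str]:
        return list(self.env_current.columns)

    @property
    def n_cells(self) -> int:
        return len(self.cells)


@dataclass
class SampleSheet:
    """Individual → population/lineage assignment with coordinates.

    All individuals of a population share the population's coordinates
    (population-level sampling).
    """

    table: pd.DataFrame  # individual_id, population_id, lineage_id, lon, lat, cell_id

    def __post_init__(self) -> None:
        t = self.table
        if t["individual_id"].duplicated().any():
            raise ValueError("duplicate individual_id")
        sizes = t.groupby("population_id").size()
        if (sizes < 2).any():
            raise ValueError("every population needs >= 2 individuals")
        nuniq = t.groupby("population_id")[["lon", "lat"]].nunique()
        if (nuniq > 1).any().any():
            raise ValueError("individuals within a population must share coordinates")

    @property
    def populations(self) -> list[str]:
        return list(dict.fromkeys(self.table["population_id"]))

    @property
    def n_individuals(self) -> int:
        return len(self.table)

    def population_table(self) -> pd.DataFrame:
        """One row per population: lineage, coordinates, cell, size."""
        g = self.table.groupby("population_id", sort=False)
        out = g.agg(
            lineage_id=("lineage_id", "first"),
            lon=("lon", "first"),
            lat=("lat", "first"),
            cell_id=("cell_id", "first"),
            n=("individual_id", "size"),
        )
        return out


@dataclass
class TruthLabels:
    """Per-locus simulation truth for parameter-recovery tests."""

    table: pd.DataFrame  # locus_id, is_adaptive, driver_variable, effect_size,
    #                      ancestral_freq, fst_lineage, fst_pop

    def __post_init__(self) -> None:
        t = self.table
        bad = (~t["is_adaptive"]) & (t["effect_size"] != 0)
        if bad.any():
            raise ValueError("effect_size must be 0 for non-adaptive loci")
        if ((t["ancestral_freq"] <= 0) | (t["ancestral_freq"] >= 1)).any():
            raise ValueError("ancestral_freq must lie in (0,1)")

    @property
    def adaptive_ids(self) -> list[str]:
        return list(self.table.loc[self.table["is_adaptive"], "locus_id"])


def _grf(
    coords: np.ndarray, autocorr_range: float, rng: np.random.Generator,
    n_features: int = 256,
) -> np.ndarray:
    """One standardized Gaussian-random-field realization at `coords`.

    Spectral (random Fourier feature) synthesis of a stationary
    Gaussian-kernel field with length scale ``autocorr_range``; marginal
    variance ~1.  Cost is O(n_cells · n_features) so large grids are cheap.
    """
    w = rng.normal(scale=1.0 / autocorr_range, size=(n_features, 2))
    b = rng.uniform(0, 2 * np.pi, size=n_features)
    a = rng.normal(size=n_features)
    phases = coords @ w.T + b  # (n, m)
    return np.sqrt(2.0 / n_features) * (np.cos(phases) @ a)


def simulate_landscape(
    n_cells: int = 600,
    variables: tuple[tuple[str, float, float], ...] = DEFAULT_VARIABLES,
    autocorr_range: float = 4.0,
    future_deltas: dict[str, dict[str, float]] | None = None,
    seed: int = 0,
    bbox: tuple[float, float, float, float] = _BBOX,
) -> LandscapeGrid:
    """Simulate a landscape of cells with autocorrelated environments.

    Parameters
    ----------
    n_cells : number of grid cells (uniform random placement in ``bbox``).
    variables : (name, mean, sd) triples; each variable is an independent
        Gaussian random field scaled to that mean/sd.
    autocorr_range : kernel length scale in degrees (> 0).
    future_deltas : scenario → {variable: additive shift}.  A scalar shift is
        applied uniformly; per-cell arrays (length n_cells) are also accepted.
        Defaults to :data:`DEFAULT_FUTURE_DELTAS`.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if autocorr_range <= 0:
        raise ValueError("autocorr_range must be > 0")
    names = [v[0] for v in variables]
    if len(set(names)) != len(names):
        raise ValueError("duplicate variable names")
    if future_deltas is None:
        future_deltas = DEFAULT_FUTURE_DELTAS
    rng = np.random.default_rng(seed)
    lon = rng.uniform(bbox[0], bbox[1], n_cells)
    lat = rng.uniform(bbox[2], bbox[3], n_cells)
    coords = np.column_stack([lon, lat])
    cells = pd.DataFrame({"lon": lon, "lat": lat})
    cells.index.name = "cell_id"

    env = {}
    for name, mu, sd in variables:
        env[name] = mu + sd * _grf(coords, autocorr_range, rng)
    env_current = pd.DataFrame(env, index=cells.index)

    env_future: dict[str, pd.DataFrame] = {}
    for scen, deltas in future_deltas.items():
        fut = env_current.copy()
        for var, d in deltas.items():
            if var not in fut.columns:
                raise ValueError(f"delta for unknown variable {var!r}")
            d_arr = np.asarray(d, dtype=float)
            if not np.isfinite(d_arr).all():
                raise ValueError(f"non-finite delta for {var!r}")
            fut[var] = fut[var] + d_arr
        env_future[scen] = fut
    return LandscapeGrid(cells=cells, env_current=env_current, env_future=env_future)


def simulate_populations(
    grid: LandscapeGrid,
    n_lineages: int = 3,
    n_pops: int = 28,
    inds_per_pop_range: tuple[int, int] = (4, 8),
    seed: int = 0,
) -> SampleSheet:
    """Place populations on grid cells with spatially contiguous lineages.

    Lineage membership is assigned by clustering the chosen cells'
    coordinates around ``n_lineages`` spread-out centroids, so lineages form
    contiguous geographic blocks.  Individual counts are uniform draws from
    ``inds_per_pop_range`` (inclusive).
    """
    if n_pops < n_lineages:
        raise ValueError("n_pops must be >= n_lineages")
    lo, hi = inds_per_pop_range
    if lo < 2 or hi > 50 or lo > hi:
        raise ValueError("inds_per_pop_range must lie within [2, 50]")
    if n_pops > grid.n_cells:
        raise ValueError("n_pops exceeds number of grid cells")
    rng = np.random.default_rng(seed)
    cell_ids = rng.choice(grid.n_cells, size=n_pops, replace=False)
    coords = grid.cells.iloc[cell_ids][["lon", "lat"]].to_numpy()

    # contiguous lineages: greedy farthest-point centroids, nearest assignment
    centroids = [coords[rng.integers(n_pops)]]
    for _ in range(1, n_lineages):
        d = np.min(
            [np.linalg.norm(coords - c, axis=1) for c in centroids], axis=0
        )
        centroids.append(coords[int(np.argmax(d))])
    lineage_idx = np.argmin(
        [np.linalg.norm(coords - c, axis=1) for c in centroids], axis=0
    )

    rows = []
    for p in range(n_pops):
        pop_id = f"P{p + 1:02d}"
        n_ind = int(rng.integers(lo, hi + 1))
        for i in range(n_ind):
            rows.append(
                {
                    "individual_id": f"{pop_id}_I{i + 1:02d}",
                    "population_id": pop_id,
                    "lineage_id": f"L{lineage_idx[p] + 1}",
                    "lon": coords[p, 0],
                    "lat": coords[p, 1],
                    "cell_id": int(cell_ids[p]),
                }
            )
    return SampleSheet(table=pd.DataFrame(rows))


def draw_effect_sizes(
    variables: list[str],
    n_adaptive: int,
    slope_range: tuple[float, float] = (1.5, 3.0),
    seed: int = 0,
) -> list[tuple[str, float]]:
    """Assign each adaptive locus a driver variable and a signed logit slope."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_adaptive):
        var = variables[i % len(variables)]
        slope = rng.uniform(*slope_range) * rng.choice([-1.0, 1.0])
        out.append((var, float(slope)))
    return out


def _balding_nichols(
    p: np.ndarray, fst: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw daughter frequencies from Beta(p(1−F)/F, (1−p)(1−F)/F)."""
    if fst <= 0:
        return p.copy()
    scale = (1.0 - fst) / fst
    a = np.clip(p * scale, 1e-6, None)
    b = np.clip((1.0 - p) * scale, 1e-6, None)
    return rng.beta(a, b)


def simulate_genotypes(
    sheet: SampleSheet,
    grid: LandscapeGrid,
    n_neutral: int = 7800,
    n_adaptive: int = 400,
    fst_lineage: float = 0.18,
    fst_pop: float = 0.05,
    effect_sizes: list[tuple[str, float]] | None = None,
    missing_rate: float = 0.05,
    seed: int = 0,
    snps_per_locus: int = 1,
):
    """Simulate diploid dosages under a hierarchical Balding–Nichols model.

    Neutral loci: ancestral frequency ~ U(0.1, 0.9); lineage frequencies are
    Balding–Nichols draws at concentration ``fst_lineage``; population
    frequencies are Balding–Nichols draws around their lineage frequency at
    ``fst_pop``.  Adaptive loci add a logit-linear cline in the standardized
    driver variable (standardized across the sampled populations) on top of
    the same hierarchical noise.  Genotypes are Binomial(2, p) per
    individual; missing calls are uniform at ``missing_rate``.

    Returns ``(GenotypeMatrix, TruthLabels)``.
    """
    from .variants import GenotypeMatrix  # local import to avoid a cycle

    if not (0 < fst_lineage < 1 and 0 < fst_pop < 1):
        raise ValueError("fst parameters must lie in (0,1)")
    if not (0 <= missing_rate < 1):
        raise ValueError("missing_rate must lie in [0,1)")
    if effect_sizes is None:
        drivers = [v for v in ("BIO04", "BIO13", "BIO15") if v in grid.variables]
        if not drivers:
            drivers = grid.variables[:1]
        effect_sizes = draw_effect_sizes(drivers, n_adaptive, seed=seed + 1)
    if len(effect_sizes) != n_adaptive:
        raise ValueError("effect_sizes must have one entry per adaptive locus")
    for var, _ in effect_sizes:
        if var not in grid.variables:
            raise ValueError(f"driver variable {var!r} absent from grid")

    rng = np.random.default_rng(seed)
    pops = sheet.population_table()
    pop_ids = list(pops.index)
    n_pops = len(pop_ids)
    lineages = pops["lineage_id"].to_numpy()
    lin_ids = list(dict.fromkeys(lineages))
    n_loci = n_neutral + n_adaptive

    # environment per population, standardized across populations
    env = grid.env_current.loc[pops["cell_id"].to_numpy()]
    env.index = pops.index
    z = (env - env.mean()) / env.std(ddof=0)

    p_anc = rng.uniform(0.1, 0.9, n_loci)
    # lineage frequencies: (n_lineages, n_loci)
    p_lin = np.vstack(
        [_balding_nichols(p_anc, fst_lineage, rng) for _ in lin_ids]
    )
    lin_index = {l: i for i, l in enumerate(lin_ids)}
    # population frequencies: (n_pops, n_loci)
    p_pop = np.vstack(
        [
            _balding_nichols(p_lin[lin_index[lineages[k]]], fst_pop, rng)
            for k in range(n_pops)
        ]
    )

    is_adaptive = np.zeros(n_loci, dtype=bool)
    driver = np.array([""] * n_loci, dtype=object)
    effect = np.zeros(n_loci)
    for j, (var, slope) in enumerate(effect_sizes):
        locus = n_neutral + j
        is_adaptive[locus] = True
        driver[locus] = var
        effect[locus] = slope
        if slope != 0.0:
            p_base = np.clip(p_pop[:, locus], 1e-4, 1 - 1e-4)
            logit = np.log(p_base / (1 - p_base))
            logit = logit + slope * z[var].to_numpy()
            p_pop[:, locus] = 1.0 / (1.0 + np.exp(-logit))

    # genotypes
    n_ind = sheet.n_individuals
    pop_of_ind = sheet.table["population_id"].map(
        {p: i for i, p in enumerate(pop_ids)}
    ).to_numpy()
    dosage = rng.binomial(2, p_pop[pop_of_ind, :]).astype(np.int8)
    if missing_rate > 0:
        mask = rng.random((n_ind, n_loci)) < missing_rate
        dosage[mask] = -1

    width = len(str(max(1, (n_loci + snps_per_locus - 1) // snps_per_locus)))
    group = np.arange(n_loci) // snps_per_locus
    chrom = np.array([f"locus_{g + 1:0{width}d}" for g in group], dtype=object)
    pos = (np.arange(n_loci) % snps_per_locus) * 50 + 1
    locus_ids = np.array(
        [f"{chrom[i]}:{pos[i]}" for i in range(n_loci)], dtype=object
    )

    gm = GenotypeMatrix(
        dosage=dosage,
        individual_ids=sheet.table["individual_id"].to_numpy(dtype=object),
        locus_ids=locus_ids,
        chrom=chrom,
        pos=pos.astype(np.int64),
        samples=sheet.table.set_index("individual_id")[
            ["population_id", "lineage_id"]
        ].copy(),
    )
    truth = TruthLabels(
        table=pd.DataFrame(
            {
                "locus_id": locus_ids,
                "is_adaptive": is_adaptive,
                "driver_variable": [d if d else "" for d in driver],
                "effect_size": effect,
                "ancestral_freq": p_anc,
                "fst_lineage": fst_lineage,
                "fst_pop": fst_pop,
            }
        )
    )
    return gm, truth


def population_env(
    grid: LandscapeGrid, sheet: SampleSheet, scenario: str | None = None
) -> pd.DataFrame:
    """Environmental table per population (current, or a named scenario)."""
    pops = sheet.population_table()
    src = grid.env_current if scenario is None else grid.env_future[scenario]
    out = src.loc[pops["cell_id"].to_numpy()].copy()
    out.index = pops.index
    return out


def write_fixture(gm, sheet: SampleSheet, grid: LandscapeGrid,
                  truth: TruthLabels, out_dir: str) -> dict[str, str]:
    """Write a complete plain-text fixture directory.

    Emits the genotypes as VCF v4.2 (GT only, one contig per locus group),
    the sample sheet, per-population environment tables (current and each
    scenario), the landscape grid, truth labels, and a callable-sites table
    (one 10-kb-style window per contig) for nucleotide-diversity estimation.
    """
    from .variants import write_vcf

    os.makedirs(out_dir, exist_ok=True)
    paths = {}

    paths["vcf"] = os.path.join(out_dir, "genotypes.vcf")
    write_vcf(gm, paths["vcf"])

    paths["samples"] = os.path.join(out_dir, "samples.csv")
    sheet.table.to_csv(paths["samples"], index=False)

    paths["env_current"] = os.path.join(out_dir, "pop_env_current.csv")
    population_env(grid, sheet).to_csv(paths["env_current"])
    for scen in grid.env_future:
        key = f"env_{scen}"
        paths[key] = os.path.join(out_dir, f"pop_env_{scen}.csv")
        population_env(grid, sheet, scen).to_csv(paths[key])

    paths["grid_current"] = os.path.join(out_dir, "grid_current.csv")
    pd.concat([grid.cells, grid.env_current], axis=1).to_csv(paths["grid_current"])
    for scen, df in grid.env_future.items():
        key = f"grid_{scen}"
        paths[key] = os.path.join(out_dir, f"grid_{scen}.csv")
        pd.concat([grid.cells, df], axis=1).to_csv(paths[key])

    paths["truth"] = os.path.join(out_dir, "truth.csv")
    truth.table.to_csv(paths["truth"], index=False)

    paths["callable_sites"] = os.path.join(out_dir, "callable_sites.csv")
    contigs = list(dict.fromkeys(gm.chrom))
    pd.DataFrame({"chrom": contigs, "total_sites": 120}).to_csv(
        paths["callable_sites"], index=False
    )
    return paths


def study_fixture(
    seed: int = 0,
    n_neutral: int = 7800,
    n_adaptive: int = 400,
    n_cells: int = 600,
    missing_rate: float = 0.05,
):
    """Full study-design simulation: landscape + 28 pops/160-ish inds + SNPs.

    Returns ``(grid, sheet, gm, truth)``.  Population count and per-population
    sample sizes follow the 28-population / 4–8-individuals design; lineage
    differentiation is calibrated to the 0.1–0.3 pairwise-FST range.
    """
    grid = simulate_landscape(n_cells=n_cells, seed=seed)
    sheet = simulate_populations(grid, n_lineages=3, n_pops=28,
                                 inds_per_pop_range=(4, 8), seed=seed + 10)
    gm, truth = simulate_genotypes(
        sheet, grid, n_neutral=n_neutral, n_adaptive=n_adaptive,
        missing_rate=missing_rate, seed=seed + 20,
    )
    return grid, sheet, gm, truth
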