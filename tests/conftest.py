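"""Shared fixtures: small synthetic study datasets and toy genotype builders."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from landgen import synth
from landgen.variants import GenotypeMatrix


def make_gm(dosage, pops, lineages=None, chrom=None, pos=None):
    """Build a GenotypeMatrix from a nested list / array of dosages.

    ``pops`` is one population label per row; missing dosage is -1.
    """
    d = np.asarray(dosage, dtype=np.int8)
    n, L = d.shape
    ind = np.array([f"I{i + 1:03d}" for i in range(n)], dtype=object)
    if lineages is None:
        lineages = pops
    samples = pd.DataFrame(
        {"population_id": pops, "lineage_id": lineages}, index=ind
    )
    if chrom is None:
        chrom = np.array([f"c{j + 1}" for j in range(L)], dtype=object)
    else:
        chrom = np.asarray(chrom, dtype=object)
    if pos is None:
        pos = np.ones(L, dtype=np.int64)
    else:
        pos = np.asarray(pos, dtype=np.int64)
    locus_ids = np.array([f"{chrom[j]}:{pos[j]}:{j}" for j in range(L)], dtype=object)
    return GenotypeMatrix(
        dosage=d, individual_ids=ind, locus_ids=locus_ids,
        chrom=chrom, pos=pos, samples=samples,
    )


@pytest.fixture(scope="session")
def small_study():
    """Compact version of the 28-pop / 3-lineage design with planted clines."""
    grid = synth.simulate_landscape(n_cells=150, seed=11)
    sheet = synth.simulate_populations(grid, n_lineages=3, n_pops=28,
                                       inds_per_pop_range=(4, 8), seed=11)
    es = synth.draw_effect_sizes(["BIO04", "BIO13", "BIO15"], 60, (1.5, 3.0), seed=11)
    gm, truth = synth.simulate_genotypes(
        sheet, grid, n_neutral=600, n_adaptive=60, effect_sizes=es,
        missing_rate=0.05, seed=11,
    )
    return {"grid": grid, "sheet": sheet, "gm": gm, "truth": truth}


@pytest.fixture(scope="session")
def small_study_complete():
    """Like small_study but without missing genotypes (for scan tests)."""
    grid = synth.simulate_landscape(n_cells=150, seed=7)
    sheet = synth.simulate_populations(grid, n_lineages=3, n_pops=28,
                                       inds_per_pop_range=(4, 8), seed=7)
    es = synth.draw_effect_sizes(["BIO04", "BIO13", "BIO15"], 60, (1.5, 3.0), seed=7)
    gm, truth = synth.simulate_genotypes(
        sheet, grid, n_neutral=600, n_adaptive=60, effect_sizes=es,
        missing_rate=0.0, seed=7,
    )
    return {"grid": grid, "sheet": sheet, "gm": gm, "truth": truth}
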