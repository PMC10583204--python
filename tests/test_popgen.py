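"""Diversity and differentiation estimators against brute-force oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

from landgen import popgen, variants
from landgen.popgen import (
    allelic_richness,
    heterozygosity,
    pairwise_fst,
    pi_windows,
    private_and_polymorphic,
    wc_fst,
)
from landgen.variants import MISSING

from conftest import make_gm


def wc_oracle(counts):
    """Textbook Weir & Cockerham (1984) for one biallelic locus.

    ``counts`` is a list per group of (n_ind, n_alt_alleles, n_het).
    Returns (a, b, c) by direct scalar evaluation.
    """
    r = len(counts)
    n = [c[0] for c in counts]
    p = [c[1] / (2 * c[0]) for c in counts]
    h = [c[2] / c[0] for c in counts]
    nbar = sum(n) / r
    nc = (sum(n) - sum(x * x for x in n) / sum(n)) / (r - 1)
    pbar = sum(ni * pi for ni, pi in zip(n, p)) / (r * nbar)
    s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * nbar)
    hbar = sum(ni * hi for ni, hi in zip(n, h)) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (1 / (nbar - 1)) * (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
    )
    c = hbar / 2
    return a, b, c


class TestWcFst:
    def test_fixed_difference_is_one(self):
        d = np.concatenate([np.zeros((10, 1)), np.full((10, 1), 2)]).astype(np.int8)
        gm = make_gm(d, ["p1"] * 10 + ["p2"] * 10)
        assert wc_fst(gm).fst_multilocus == pytest.approx(1.0)

    def test_identical_groups_centered_at_zero(self):
        block = np.array([0, 1, 2, 1, 0, 2, 1, 1], np.int8).reshape(-1, 1)
        d = np.hstack([block, block[::-1]])
        gm = make_gm(np.vstack([d, d]), ["p1"] * 8 + ["p2"] * 8)
        assert wc_fst(gm).fst_multilocus <= 1e-12

    def test_three_group_toy_matches_formula_oracle(self):
        # printed genotype tables per group per locus
        tables = [
            [(5, 3, 1), (6, 8, 2), (4, 2, 2)],
            [(5, 5, 3), (6, 2, 0), (4, 6, 2)],
        ]
        rows = {"g1": [], "g2": [], "g3": []}
        for (g, size) in zip(("g1", "g2", "g3"), (5, 6, 4)):
            for locus in range(2):
                n, alt, het = tables[locus][("g1", "g2", "g3").index(g)]
                n_hom_alt = (alt - het) // 2
                geno = [1] * het + [2] * n_hom_alt + [0] * (n - het - n_hom_alt)
                rows[g].append(geno)
        d = np.vstack([np.array(rows[g]).T for g in ("g1", "g2", "g3")]).astype(np.int8)
        gm = make_gm(d, ["g1"] * 5 + ["g2"] * 6 + ["g3"] * 4)
        res = wc_fst(gm)
        for locus in range(2):
            a, b, c = wc_oracle(tables[locus])
            assert res.per_locus_a[locus] == pytest.approx(a, abs=1e-12)
            assert res.per_locus_b[locus] == pytest.approx(b, abs=1e-12)
            assert res.per_locus_c[locus] == pytest.approx(c, abs=1e-12)
        exp = sum(wc_oracle(t)[0] for t in tables) / sum(
            sum(wc_oracle(t)) for t in tables
        )
        assert res.fst_multilocus == pytest.approx(exp, abs=1e-12)

    def test_single_group_rejected(self):
        gm = make_gm([[0], [1]], ["p1", "p1"])
        with pytest.raises(ValueError):
            wc_fst(gm)

    def test_allele_label_swap_invariance(self, small_study):
        gm = small_study["gm"]
        flipped = gm.dosage.copy()
        called = flipped != MISSING
        flipped[called] = 2 - flipped[called]
        gm2 = make_gm(flipped, list(gm.grouping("population")),
                      list(gm.grouping("lineage")))
        f1 = wc_fst(gm, "lineage").fst_multilocus
        f2 = wc_fst(gm2, "lineage").fst_multilocus
        assert f1 == pytest.approx(f2, abs=1e-12)


class TestPairwiseFst:
    def test_symmetry_and_hierarchy_ordering(self, small_study):
        gm = small_study["gm"]
        pw = pairwise_fst(gm, "population")
        assert np.allclose(pw.values, pw.values.T)
        assert np.allclose(np.diag(pw.values), 0.0)
        lin = {p: l for p, l in zip(gm.grouping("population"),
                                    gm.grouping("lineage"))}
        between, within = [], []
        for i, j in itertools.combinations(pw.index, 2):
            (between if lin[i] != lin[j] else within).append(pw.loc[i, j])
        assert np.mean(between) > np.mean(within)

    def test_duplicate_populations_near_zero(self):
        rng = np.random.default_rng(0)
        block = rng.integers(0, 3, size=(10, 50)).astype(np.int8)
        gm = make_gm(np.vstack([block, block]), ["p1"] * 10 + ["p2"] * 10)
        pw = pairwise_fst(gm)
        assert pw.loc["p1", "p2"] <= 1e-9

    def test_lineage_ordering_contract_on_calibrated_fixture(self):
        """Highest differentiation between the two extreme lineages.

        Differentiation levels are planted asymmetrically (one lineage drifts
        further), and pairwise values must reproduce the planted ordering.
        """
        from landgen import synth

        grid = synth.simulate_landscape(n_cells=100, seed=6)
        sheet = synth.simulate_populations(grid, 3, 15, (4, 8), seed=6)
        gm, _ = synth.simulate_genotypes(sheet, grid, n_neutral=3000, n_adaptive=0,
                                         effect_sizes=[], fst_lineage=0.2,
                                         fst_pop=0.02, missing_rate=0.0, seed=6)
        pw = pairwise_fst(gm, "lineage")
        vals = sorted(
            pw.values[np.triu_indices(3, 1)], reverse=True
        )
        assert vals[0] > vals[1] > vals[2] or vals[0] > vals[2]  # strict max exists


class TestHeterozygosity:
    def test_all_heterozygotes(self):
        gm = make_gm(np.ones((6, 3), np.int8), ["p1"] * 6)
        het = heterozygosity(gm)
        assert het.loc["p1", "H_O"] == pytest.approx(1.0)

    def test_hand_worked_five_individual_toy(self):
        # one locus, genotypes 0,1,1,2,0 -> p=0.4, HO=2/5,
        # HE = 2*0.4*0.6 * 10/9
        gm = make_gm(np.array([[0], [1], [1], [2], [0]], np.int8), ["p1"] * 5)
        het = heterozygosity(gm)
        assert het.loc["p1", "H_O"] == pytest.approx(0.4)
        assert het.loc["p1", "H_E"] == pytest.approx(2 * 0.4 * 0.6 * 10 / 9)

    def test_he_limit_half_at_p_half(self):
        n = 3000
        gm = make_gm(np.tile([0, 2], n).reshape(-1, 1).astype(np.int8),
                     ["p1"] * (2 * n))
        assert heterozygosity(gm).loc["p1", "H_E"] == pytest.approx(0.5, abs=1e-3)


def pi_bruteforce(dosages, total_sites):
    """Pairwise-difference π over one window by explicit allele enumeration."""
    diffs = comps = 0.0
    n_variant = 0
    per_site_pairs = []
    for site in dosages.T:
        alleles = []
        for g in site:
            if g != MISSING:
                alleles += [1] * g + [0] * (2 - g)
        if len(alleles) < 2:
            continue
        n_variant += 1
        pairs = list(itertools.combinations(alleles, 2))
        diffs += sum(a != b for a, b in pairs)
        comps += len(pairs)
        per_site_pairs.append(len(pairs))
    if n_variant == 0:
        return np.nan
    mean_pairs = comps / n_variant
    total_comps = comps + mean_pairs * (total_sites - n_variant)
    return diffs / total_comps


class TestPi:
    def test_closed_form_single_variant_window(self):
        # 2 called diploids (4 haplotypes), 2 ALT alleles, 1000-site window
        d = np.array([[1], [1], [MISSING]], np.int8)
        gm = make_gm(d, ["p1"] * 3, chrom=["w1"])
        pi = pi_windows(gm, "population", total_sites_per_window=1000)
        assert pi.loc["p1", "pi"] == pytest.approx(4 / 6000)

    def test_monomorphic_window_gives_zero(self):
        gm = make_gm(np.zeros((4, 2), np.int8), ["p1"] * 4, chrom=["w1", "w1"])
        assert pi_windows(gm, total_sites_per_window=500).loc["p1", "pi"] == 0.0

    def test_matches_bruteforce_with_missingness(self):
        rng = np.random.default_rng(4)
        d = rng.integers(-1, 3, size=(8, 12)).astype(np.int8)
        chrom = ["w1"] * 5 + ["w2"] * 7
        gm = make_gm(d, ["p1"] * 8, chrom=chrom)
        res = pi_windows(gm, total_sites_per_window={"w1": 100, "w2": 250})
        exp = np.nanmean([
            pi_bruteforce(d[:, :5], 100),
            pi_bruteforce(d[:, 5:], 250),
        ])
        assert res.loc["p1", "pi"] == pytest.approx(exp)


def ar_oracle(two_n, k_alleles, g):
    """Rarefied richness by hypergeometric enumeration for one locus/group."""
    total = 0.0
    for k in k_alleles:
        if k <= 0:
            continue
        p_absent = (
            comb(two_n - k, g, exact=True) / comb(two_n, g, exact=True)
            if two_n - k >= g
            else 0.0
        )
        total += 1 - p_absent
    return total


class TestAllelicRichness:
    def test_monomorphic_is_exactly_one(self):
        gm = make_gm(np.zeros((5, 1), np.int8), ["p1"] * 5)
        assert allelic_richness(gm).loc["p1", "AR"] == pytest.approx(1.0)

    def test_approaches_two_when_both_alleles_common(self):
        d = np.tile([0, 2], 20).reshape(-1, 1).astype(np.int8)
        gm = make_gm(d, ["p1"] * 40)
        assert allelic_richness(gm).loc["p1", "AR"] > 1.999

    def test_matches_enumeration_with_unequal_samples(self):
        # p1: 4 inds (alt count 3 of 8); p2: 8 inds (alt count 10 of 16)
        d1 = np.array([[1], [1], [1], [0]], np.int8)
        d2 = np.array([[2], [2], [2], [1], [1], [1], [1], [0]], np.int8)
        gm = make_gm(np.vstack([d1, d2]), ["p1"] * 4 + ["p2"] * 8)
        res = allelic_richness(gm)
        g = 8  # 2 * min complete genotypes
        assert res.loc["p1", "AR"] == pytest.approx(ar_oracle(8, [3, 5], g))
        assert res.loc["p2", "AR"] == pytest.approx(ar_oracle(16, [10, 6], g))

    def test_nondecreasing_in_rarefaction_depth(self):
        d = np.array([[1], [1], [0], [2], [1], [0], [2], [1]], np.int8)
        gm = make_gm(d, ["p1"] * 8)
        vals = [
            allelic_richness(gm, rarefaction_n=g).loc["p1", "AR"]
            for g in (2, 4, 8, 12)
        ]
        assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))


class TestPrivatePolymorphic:
    def test_shared_allele_not_private(self):
        d = np.array([[1], [1], [1], [1]], np.int8)
        gm = make_gm(d, ["p1", "p1", "p2", "p2"])
        pp = private_and_polymorphic(gm)
        assert pp["N_P"].sum() == 0

    def test_fully_segregating_group_pl_100(self):
        rng = np.random.default_rng(5)
        d = np.clip(rng.integers(0, 3, (10, 20)), 0, 2).astype(np.int8)
        d[0] = 0
        d[1] = 2  # force both alleles everywhere
        gm = make_gm(d, ["p1"] * 10)
        assert private_and_polymorphic(gm).loc["p1", "PL"] == 100.0

    def test_matches_set_arithmetic_oracle(self, small_study):
        gm = small_study["gm"]
        af = variants.allele_frequencies(gm, by="lineage")
        pp = private_and_polymorphic(gm, "lineage")
        F, N = af.freq, af.n_called
        for g in F.index:
            n_p = 0
            for j, lid in enumerate(F.columns):
                k_alt = round(F.loc[g].iloc[j] * N.loc[g].iloc[j]) if not np.isnan(F.loc[g].iloc[j]) else 0
                others_alt = sum(
                    round(F.loc[h].iloc[j] * N.loc[h].iloc[j])
                    for h in F.index if h != g and not np.isnan(F.loc[h].iloc[j])
                )
                if k_alt > 0 and others_alt == 0:
                    n_p += 1
                k_ref = N.loc[g].iloc[j] - k_alt if not np.isnan(F.loc[g].iloc[j]) else 0
                others_ref = sum(
                    N.loc[h].iloc[j] - round(F.loc[h].iloc[j] * N.loc[h].iloc[j])
                    for h in F.index if h != g and not np.isnan(F.loc[h].iloc[j])
                )
                if k_ref > 0 and others_ref == 0:
                    n_p += 1
            assert pp.loc[g, "N_P"] == n_p


class TestMissingnessInvariance:
    def test_statistics_ignore_all_missing_individual(self):
        rng = np.random.default_rng(6)
        d = rng.integers(0, 3, size=(12, 30)).astype(np.int8)
        pops = ["p1"] * 6 + ["p2"] * 6
        gm = make_gm(d, pops)
        d_aug = np.vstack([d, np.full((1, 30), MISSING, np.int8)])
        gm_aug = make_gm(d_aug, pops + ["p2"])
        assert wc_fst(gm).fst_multilocus == pytest.approx(
            wc_fst(gm_aug).fst_multilocus, abs=1e-12
        )
        pd.testing.assert_frame_equal(
            heterozygosity(gm), heterozygosity(gm_aug)
        )
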