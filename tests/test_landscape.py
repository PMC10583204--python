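"""Distances, Mantel tests, PCNM, forward selection, RDA and partitioning."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from landgen import landscape
from landgen.landscape import (
    DistanceMatrix,
    env_distance,
    forward_select,
    geo_distance,
    mantel,
    partial_mantel,
    pcnm,
    rda,
    variance_partition,
)


def pop_frame(coords):
    return pd.DataFrame(
        {"lon": [c[0] for c in coords], "lat": [c[1] for c in coords]},
        index=[f"P{i}" for i in range(len(coords))],
    )


def random_dm(rng, n, labels=None):
    x = rng.random((n, 2))
    d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))
    return DistanceMatrix(labels or [f"P{i}" for i in range(n)], d, "g")


class TestGeoDistance:
    def test_identical_coordinates_are_zero(self):
        dm = geo_distance(pop_frame([(10, 20), (10, 20)]))
        assert dm.values[0, 1] == 0.0

    def test_one_degree_longitude_at_equator(self):
        dm = geo_distance(pop_frame([(0, 0), (1, 0)]))
        assert dm.values[0, 1] == pytest.approx(111.195, abs=1e-3)

    @given(st.integers(0, 1000))
    @settings(max_examples=20, deadline=None)
    def test_metric_properties(self, seed):
        rng = np.random.default_rng(seed)
        coords = list(zip(rng.uniform(-170, 170, 5), rng.uniform(-80, 80, 5)))
        d = geo_distance(pop_frame(coords)).values
        assert np.allclose(d, d.T)
        for i in range(5):
            for j in range(5):
                for k in range(5):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-6

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            geo_distance(pop_frame([(200, 0), (0, 0)]))


class TestEnvDistance:
    def test_identical_environments_zero(self):
        env = pd.DataFrame({"a": [1.0, 1.0, 2.0], "b": [0.0, 0.0, 5.0]},
                           index=["P0", "P1", "P2"])
        dm = env_distance(env)
        assert dm.values[0, 1] == 0.0

    def test_two_populations_single_variable_is_one(self):
        env = pd.DataFrame({"a": [3.0, 9.0]}, index=["P0", "P1"])
        dm = env_distance(env)
        assert dm.values[0, 1] == pytest.approx(1.0)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(0)
        env = pd.DataFrame(rng.normal(size=(8, 4)), columns=list("abcd"),
                           index=[f"P{i}" for i in range(8)])
        dm = env_distance(env)
        z = (env - env.mean()) / env.std(ddof=0)
        z = z - z.min()
        X = z.to_numpy()
        for i in range(8):
            for j in range(8):
                num = np.abs(X[i] - X[j]).sum()
                den = (X[i] + X[j]).sum()
                exp = num / den if den > 0 else 0.0
                assert dm.values[i, j] == pytest.approx(exp, abs=1e-12)

    def test_zero_variance_variable_dropped(self):
        env = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]},
                           index=["P0", "P1", "P2"])
        with pytest.warns(UserWarning, match="zero-variance"):
            env_distance(env)


class TestMantel:
    def test_perfect_monotone_association(self):
        rng = np.random.default_rng(0)
        a = random_dm(rng, 15)
        b = DistanceMatrix(a.labels, 2 * a.values, "g")
        res = mantel(a, b, n_perm=999, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.p == pytest.approx(1 / 1000)

    def test_p_never_below_permutation_bound(self):
        rng = np.random.default_rng(1)
        for seed in range(5):
            res = mantel(random_dm(rng, 10), random_dm(rng, 10),
                         n_perm=99, seed=seed)
            assert res.p >= 1 / 100

    def test_constant_matrix_is_error(self):
        labels = ["P0", "P1", "P2"]
        c = DistanceMatrix(labels, np.ones((3, 3)) - np.eye(3), "g")
        flat = DistanceMatrix(labels, np.ones((3, 3)) - np.eye(3), "g")
        with pytest.raises(ValueError):
            mantel(c, flat, n_perm=9, seed=0)

    def test_label_mismatch_rejected(self):
        rng = np.random.default_rng(2)
        a = random_dm(rng, 6)
        b = random_dm(rng, 6, labels=[f"Q{i}" for i in range(6)])
        with pytest.raises(ValueError, match="labels"):
            mantel(a, b)

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(3)
        a, b = random_dm(rng, 12), random_dm(rng, 12)
        r1 = mantel(a, b, n_perm=199, seed=42)
        r2 = mantel(a, b, n_perm=199, seed=42)
        assert (r1.r, r1.p) == (r2.r, r2.p)


class TestPartialMantel:
    def test_full_confounding_gives_near_zero(self):
        rng = np.random.default_rng(4)
        a = random_dm(rng, 20)
        c = random_dm(rng, 20)
        res = partial_mantel(a, c, c, n_perm=99, seed=0)
        assert abs(res.r) < 1e-10

    def test_uncorrelated_control_preserves_simple_r(self):
        rng = np.random.default_rng(7)
        n = 30
        x = rng.random((n, 2))
        base = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))
        noise = rng.normal(0, 0.05, (n, n))
        b_vals = base + np.abs(noise + noise.T)
        np.fill_diagonal(b_vals, 0)
        labels = [f"P{i}" for i in range(n)]
        a = DistanceMatrix(labels, base, "a")
        b = DistanceMatrix(labels, (b_vals + b_vals.T) / 2, "b")
        c = random_dm(rng, n)
        simple = mantel(a, b, n_perm=0 or 9, seed=1).r
        part = partial_mantel(a, b, c, n_perm=9, seed=1).r
        assert abs(simple - part) < 0.05


class TestPcnm:
    def test_matches_dense_pcoa_oracle_on_equidistant_points(self):
        n = 4
        d = np.ones((n, n)) - np.eye(n)
        dm = DistanceMatrix([f"P{i}" for i in range(n)], d, "geographic_km")
        basis = pcnm(dm)
        # independent dense construction: truncation leaves d unchanged
        # (all edges equal the MST max edge), so PCoA of -d^2/2 centered
        A = -0.5 * d**2
        J = np.eye(n) - np.ones((n, n)) / n
        evals = np.linalg.eigvalsh(J @ A @ J)[::-1]
        pos = evals[evals > 1e-8]
        assert np.allclose(np.sort(basis.eigenvalues)[::-1], pos, atol=1e-9)

    def test_retained_is_subset_of_positive_axes(self):
        rng = np.random.default_rng(8)
        dm = random_dm(rng, 15)
        basis = pcnm(dm)
        assert all(0 <= i < basis.eigenvectors.shape[1] for i in basis.retained)
        assert len(basis.retained) == int(np.ceil(basis.eigenvectors.shape[1] / 2))

    def test_too_few_populations_rejected(self):
        dm = DistanceMatrix(["a", "b"], np.array([[0.0, 1], [1, 0]]), "g")
        with pytest.raises(ValueError):
            pcnm(dm)

    def test_first_half_then_forward_selection_workflow(self, small_study):
        """Retained first-half PCNMs reduce further under forward selection."""
        from landgen import popgen, variants

        sheet = small_study["sheet"]
        gm = small_study["gm"]
        dgeo = geo_distance(sheet)
        basis = pcnm(dgeo)
        geo = basis.frame("retained")
        igm, _ = variants.impute_missing(gm, K=3, seed=0)
        af = variants.allele_frequencies(igm)
        sel = forward_select(af.freq, geo, n_perm=99, seed=0)
        assert 0 < len(sel) <= len(basis.retained)


class TestForwardSelect:
    def test_recovers_planted_predictors(self):
        ok = 0
        for rep in range(20):
            rng = np.random.default_rng(rep)
            X = pd.DataFrame(rng.normal(size=(28, 6)),
                             columns=[f"v{i}" for i in range(6)])
            Y = (np.outer(X["v1"], rng.normal(size=30))
                 + np.outer(X["v4"], rng.normal(size=30))
                 + rng.normal(0, 0.5, (28, 30)))
            sel = forward_select(pd.DataFrame(Y), X, n_perm=199, seed=rep)
            ok += set(sel[:2]) == {"v1", "v4"} and len(sel) <= 3
        assert ok >= 18

    def test_pure_noise_selects_at_most_one(self):
        ok = 0
        for rep in range(20):
            rng = np.random.default_rng(100 + rep)
            X = pd.DataFrame(rng.normal(size=(28, 6)),
                             columns=[f"v{i}" for i in range(6)])
            sel = forward_select(pd.DataFrame(rng.normal(size=(28, 30))), X,
                                 n_perm=199, seed=rep)
            ok += len(sel) <= 1
        assert ok >= 18

    def test_alpha_one_without_cap_admits_everything(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(28, 6)),
                         columns=[f"v{i}" for i in range(6)])
        Y = pd.DataFrame(rng.normal(size=(28, 30)))
        sel = forward_select(Y, X, alpha=1.0, max_adjr2=np.inf, n_perm=49, seed=0)
        assert len(sel) == 6


class TestRda:
    def test_noiseless_linear_response_r2_one(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(12, 2)), columns=["a", "b"])
        Y = pd.DataFrame(X.to_numpy() @ rng.normal(size=(2, 8)))
        res = rda(Y, X, n_perm=99, seed=0)
        assert res.r2 == pytest.approx(1.0, abs=1e-10)
        assert res.p_value <= 0.05

    def test_self_conditioning_removes_everything(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.normal(size=(12, 2)), columns=["a", "b"])
        Y = pd.DataFrame(X.to_numpy() @ rng.normal(size=(2, 8)))
        res = rda(Y, X, condition=X, n_perm=0, seed=0)
        assert res.r2 == pytest.approx(0.0, abs=1e-10)

    def test_small_toy_matches_least_squares_oracle(self):
        rng = np.random.default_rng(3)
        Y = pd.DataFrame(rng.normal(size=(6, 4)))
        X = pd.DataFrame(rng.normal(size=(6, 2)), columns=["a", "b"])
        res = rda(Y, X, n_perm=0, seed=0)
        # direct least-squares + eigendecomposition oracle
        Yc = Y.to_numpy() - Y.to_numpy().mean(0)
        Xs = X.to_numpy()
        Xs = (Xs - Xs.mean(0)) / Xs.std(0, ddof=0)
        Xd = np.column_stack([np.ones(6), Xs])
        beta = np.linalg.lstsq(Xd, Yc, rcond=None)[0]
        fitted = Xd @ beta
        fitted -= fitted.mean(0)
        r2 = (fitted**2).sum() / (Yc**2).sum()
        assert res.r2 == pytest.approx(r2, abs=1e-10)
        ev = np.linalg.eigvalsh(fitted @ fitted.T / 5)[::-1][:2]
        assert np.allclose(np.sort(res.eigenvalues)[::-1], ev[ev > 1e-12],
                           atol=1e-10)
        assert res.adj_r2 == pytest.approx(1 - (1 - r2) * 5 / 3, abs=1e-10)

    def test_single_predictor_equals_multivariate_regression_r2(self):
        rng = np.random.default_rng(4)
        Y = pd.DataFrame(rng.normal(size=(10, 5)))
        x = pd.DataFrame({"a": rng.normal(size=10)})
        res = rda(Y, x, n_perm=0, seed=0)
        Yc = Y.to_numpy() - Y.to_numpy().mean(0)
        xv = x.to_numpy().ravel()
        xv = (xv - xv.mean())
        b = xv @ Yc / (xv @ xv)
        r2 = (np.outer(xv, b) ** 2).sum() / (Yc**2).sum()
        assert res.r2 == pytest.approx(r2, abs=1e-12)

    def test_too_many_predictors_rejected(self):
        rng = np.random.default_rng(5)
        Y = pd.DataFrame(rng.normal(size=(5, 4)))
        X = pd.DataFrame(rng.normal(size=(5, 6)))
        with pytest.raises(ValueError):
            rda(Y, X, n_perm=0)


class TestVariancePartition:
    def _orthogonal_blocks(self, rng, n=28):
        Q, _ = np.linalg.qr(rng.normal(size=(n, 4)))
        return Q[:, :2], Q[:, 2:4]

    def test_orthogonal_design_has_no_confounding(self):
        rng = np.random.default_rng(6)
        E, G = self._orthogonal_blocks(rng)
        Y = pd.DataFrame(E @ rng.normal(size=(2, 40))
                         + G @ rng.normal(size=(2, 40))
                         + rng.normal(0, 1.0, (28, 40)))
        part = variance_partition(
            Y, pd.DataFrame(E, columns=["e1", "e2"]),
            pd.DataFrame(G, columns=["g1", "g2"]), n_perm=0, seed=0,
        )
        f = part.fractions
        assert abs(f["total_confounded"]) < 0.03
        assert f["total_explained"] == pytest.approx(
            f["geog_combined"] + f["env_combined"], abs=0.03
        )

    def test_identical_blocks_fully_confounded(self):
        rng = np.random.default_rng(7)
        E, _ = self._orthogonal_blocks(rng)
        Y = pd.DataFrame(E @ rng.normal(size=(2, 40))
                         + rng.normal(0, 0.3, (28, 40)))
        env = pd.DataFrame(E, columns=["e1", "e2"])
        geo = pd.DataFrame(E, columns=["g1", "g2"])
        part = variance_partition(Y, env, geo, n_perm=0, seed=0)
        f = part.fractions
        assert abs(f["geog_given_env"]) < 0.02
        assert abs(f["env_given_geog"]) < 0.02
        assert f["total_confounded"] == pytest.approx(f["total_explained"],
                                                      abs=0.03)

    def test_planted_shares_recovered(self):
        errs = []
        for rep in range(20):
            rng = np.random.default_rng(200 + rep)
            n, L = 28, 200
            E, G = self._orthogonal_blocks(rng)
            Ye = E @ rng.normal(size=(2, L))
            Yg = G @ rng.normal(size=(2, L))
            noise = rng.normal(size=(n, L))
            Ye *= np.sqrt(0.10 / (Ye**2).sum())
            Yg *= np.sqrt(0.05 / (Yg**2).sum())
            noise *= np.sqrt(0.85 / (noise**2).sum())
            Y = pd.DataFrame(Ye + Yg + noise)
            part = variance_partition(
                Y, pd.DataFrame(E, columns=["e1", "e2"]),
                pd.DataFrame(G, columns=["g1", "g2"]), n_perm=0, seed=rep,
            )
            errs.append([part.fractions["env_given_geog"] - 0.10,
                         part.fractions["geog_given_env"] - 0.05])
        assert np.abs(np.array(errs)).max() < 0.03

    def test_ledger_identities_close_exactly(self, small_study):
        from landgen import variants

        igm, _ = variants.impute_missing(small_study["gm"], K=3, seed=0)
        af = variants.allele_frequencies(igm)
        env = __import__("landgen").synth.population_env(
            small_study["grid"], small_study["sheet"]
        )
        geo = pcnm(geo_distance(small_study["sheet"])).frame("retained")
        part = variance_partition(af.freq, env.loc[af.freq.index], geo,
                                  n_perm=49, seed=0)
        f = part.fractions
        assert f["total_explained"] + f["total_unexplained"] == pytest.approx(
            1.0, abs=1e-9
        )
        assert f["total_confounded"] == pytest.approx(
            f["total_explained"] - f["geog_given_env"] - f["env_given_geog"],
            abs=1e-9,
        )
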