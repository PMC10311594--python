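"""NNMF decomposition, clustering and the inter-factor RMSE test."""

import numpy as np
import pandas as pd
import pytest

import spartakit as sk
from spartakit.subpop import NNMFResult

from conftest import make_processed_batch

TIGHT = sk.AnalysisConfig(nnmf_max_iter=20000, nnmf_tol=1e-12)


def small_grid(n=200):
    return sk.WavenumberGrid(400 + 2.0 * np.arange(n))


class TestFactorization:
    def test_rank_one_batch_yields_duplicate_factors(self, rng):
        """One spectrum x positive scalars: error ~ 0, normalized factors equal."""
        g = small_grid()
        base = np.abs(np.sin(g.values / 100.0)) + 0.1
        s = sk.SpectrumSet(g, np.outer(rng.uniform(0.5, 2.0, 20), base))
        res = sk.nnmf_two_factor(s, TIGHT)
        assert res.reconstruction_error < 1e-5
        h = res.factor_spectra / np.linalg.norm(res.factor_spectra, axis=1, keepdims=True)
        assert np.abs(h[0] - h[1]).max() < 1e-3

    def test_rank_two_recovery_with_anchor_particles(self, rng):
        """Disjoint-support templates with near-pure particles: cosine > 0.99."""
        g = small_grid()
        t1 = np.zeros(len(g)); t1[20:40] = np.hanning(20)
        t2 = np.zeros(len(g)); t2[120:150] = np.hanning(30)
        scores = rng.uniform(0, 1.5, (30, 2))
        scores[:3, 1] = 0.0  # pure-carrier anchors
        scores[3:6, 0] = 0.0  # pure-cargo anchors
        s = sk.SpectrumSet(g, scores @ np.vstack([t1, t2]) + 1e-9)
        res = sk.nnmf_two_factor(s, TIGHT)
        cos = lambda u, v: u @ v / (np.linalg.norm(u) * np.linalg.norm(v))
        sims = sorted(max(cos(h, t1), cos(h, t2)) for h in res.factor_spectra)
        assert sims[0] > 0.99

    def test_error_non_increasing_per_iteration(self, et_two_pop, config):
        processed, _, _ = et_two_pop
        res = sk.nnmf_two_factor(processed, config)
        assert np.all(np.diff(res.error_history) <= 1e-12)

    def test_deterministic_across_runs(self, et_one_pop, config):
        processed, _, _ = et_one_pop
        r1 = sk.nnmf_two_factor(processed, config)
        r2 = sk.nnmf_two_factor(processed, config)
        np.testing.assert_array_equal(r1.factor_spectra, r2.factor_spectra)
        np.testing.assert_array_equal(r1.scores, r2.scores)

    def test_mean_score_normalization(self, two_pop_nnmf):
        np.testing.assert_allclose(two_pop_nnmf.scores.mean(axis=0), 1.0, rtol=1e-9)

    def test_matches_reference_solver_error(self, et_two_pop, config):
        """Reconstruction error no worse than ~5% above scikit-learn's NMF."""
        sklearn = pytest.importorskip("sklearn.decomposition")
        processed, _, _ = et_two_pop
        x = np.clip(processed.intensities, 0, None)
        model = sklearn.NMF(n_components=2, init="nndsvda", max_iter=500, tol=1e-6)
        wref = model.fit_transform(x)
        ref_err = np.linalg.norm(x - wref @ model.components_) / np.linalg.norm(x)
        ours = sk.nnmf_two_factor(processed, config).reconstruction_error
        assert ours <= ref_err * 1.05

    def test_all_zero_input_rejected(self):
        g = small_grid()
        s = sk.SpectrumSet(g, np.zeros((5, len(g))))
        with pytest.raises(ValueError, match="zero"):
            sk.nnmf_two_factor(s)


class TestOrderingAndClusters:
    def test_carrier_like_factor_comes_first(self, grid, config):
        from spartakit.simulate import et_cargo, polymersome_carrier

        h = np.vstack([et_cargo().profile(grid), polymersome_carrier().profile(grid)])
        res = NNMFResult(
            factor_spectra=h, scores=np.ones((4, 2)), labels=None,
            n_iter=1, converged=True, reconstruction_error=0.0,
        )
        ordered = sk.order_factors(res, config.carrier_window, config.cargo_window, grid)
        # the polymer-dominated spectrum must end up as factor 1
        assert ordered.factor_spectra[0] @ h[1] > ordered.factor_spectra[0] @ h[0]
        again = sk.order_factors(ordered, config.carrier_window, config.cargo_window, grid)
        np.testing.assert_array_equal(again.factor_spectra, ordered.factor_spectra)

    def test_cargo_like_factor_carries_dialkyne_area(self, two_pop_nnmf, config, grid):
        a1 = sk.peak_area(two_pop_nnmf.factor_spectra[0], grid, config.cargo_window)
        a2 = sk.peak_area(two_pop_nnmf.factor_spectra[1], grid, config.cargo_window)
        assert a2 > a1

    def test_cluster_assignment_and_tie_rule(self):
        res = NNMFResult(
            factor_spectra=np.ones((2, 4)),
            scores=np.array([[2.0, 1.0], [1.0, 2.0], [1.0, 1.0]]),
            labels=None, n_iter=1, converged=True, reconstruction_error=0.0,
        )
        np.testing.assert_array_equal(sk.assign_clusters(res), [1, 2, 1])

    def test_planted_outliers_land_in_cluster_two(self, et_two_pop, two_pop_nnmf):
        _, truth, _ = et_two_pop
        labels = two_pop_nnmf.labels
        captured = (labels[truth.is_outlier.to_numpy()] == 2).mean()
        assert captured >= 0.8


class TestFactorRMSE:
    def test_identical_factors_zero(self, grid, config):
        h = np.tile(np.linspace(0, 1, len(grid)), (2, 1))
        res = NNMFResult(h, np.ones((4, 2)), None, 1, True, 0.0)
        assert sk.factor_rmse(res, config.cargo_window, grid) == 0.0

    def test_unit_offset_gives_unit_rmse(self, grid, config):
        h0 = np.linspace(0, 1, len(grid))
        res = NNMFResult(np.vstack([h0, h0 + 1.0]), np.ones((4, 2)), None, 1, True, 0.0)
        assert sk.factor_rmse(res, config.cargo_window, grid) == pytest.approx(1.0)

    def test_two_population_batch_exceeds_single_population(
        self, two_pop_nnmf, one_pop_nnmf, config, grid
    ):
        rmse_two = sk.factor_rmse(two_pop_nnmf, config.cargo_window, grid)
        rmse_one = sk.factor_rmse(one_pop_nnmf, config.cargo_window, grid)
        assert rmse_two > rmse_one

    def test_rmse_invariant_to_particle_order_and_duplication(self, et_two_pop, config):
        processed, _, _ = et_two_pop
        base = sk.nnmf_two_factor(processed, config)
        base = sk.order_factors(base, config.carrier_window, config.cargo_window, processed.grid)
        rmse = sk.factor_rmse(base, config.cargo_window, processed.grid)

        rng = np.random.default_rng(0)
        perm = rng.permutation(processed.n_particles)
        shuffled = sk.SpectrumSet(processed.grid, processed.intensities[perm])
        res_p = sk.nnmf_two_factor(shuffled, config)
        res_p = sk.order_factors(res_p, config.carrier_window, config.cargo_window, processed.grid)
        assert sk.factor_rmse(res_p, config.cargo_window, processed.grid) == pytest.approx(rmse, rel=0.05)

        doubled = sk.SpectrumSet(
            processed.grid, np.vstack([processed.intensities, processed.intensities[:40]])
        )
        res_d = sk.nnmf_two_factor(doubled, config)
        res_d = sk.order_factors(res_d, config.carrier_window, config.cargo_window, processed.grid)
        assert sk.factor_rmse(res_d, config.cargo_window, processed.grid) == pytest.approx(rmse, rel=0.05)


class TestDetection:
    @pytest.mark.parametrize("rmse,expected", [(0.41, True), (0.39, False), (0.4, True)])
    def test_threshold_rule_inclusive(self, rmse, expected):
        assert sk.detect_subpopulations(rmse, 0.4) is expected

    def test_operating_characteristics_over_seeds(self, config, grid):
        """Paired batches over seeds: TPR >= 0.9 and FPR <= 0.1 at the 0.4 line."""
        hits, false_alarms, n_seeds = 0, 0, 20
        for seed in range(100, 100 + n_seeds):
            for outlier_fraction, planted in ((0.10, True), (0.0, False)):
                processed, _, _ = make_processed_batch(
                    config, grid, seed=seed, outlier_fraction=outlier_fraction
                )
                res = sk.nnmf_two_factor(processed, config)
                res = sk.order_factors(res, config.carrier_window, config.cargo_window, grid)
                detected = sk.detect_subpopulations(
                    sk.factor_rmse(res, config.cargo_window, grid), config.rmse_threshold
                )
                if planted and detected:
                    hits += 1
                if not planted and detected:
                    false_alarms += 1
        assert hits / n_seeds >= 0.9
        assert false_alarms / n_seeds <= 0.1


class TestClusterStats:
    def test_fraction_arithmetic(self):
        assert sk.cluster_fraction(np.array([1, 1, 1, 2])) == 25.0
        assert sk.cluster_fraction(np.array([1, 1])) == 0.0

    def test_recovered_outlier_fraction_near_truth(self, et_two_pop, two_pop_nnmf):
        _, truth, _ = et_two_pop
        pct = sk.cluster_fraction(two_pop_nnmf.labels)
        assert abs(pct - 100 * truth.is_outlier.mean()) <= 5.0

    def test_identical_positions_collapse_box(self):
        feats = pd.DataFrame({"cargo_position_cm1": [2220.0] * 6})
        stats = sk.cluster_peak_stats(np.ones(6, dtype=int), feats)
        row = stats.set_index("cluster").loc[1]
        assert row["median"] == 2220.0
        assert row["q3"] - row["q1"] == 0.0

    def test_median_of_three(self):
        feats = pd.DataFrame({"cargo_position_cm1": [2216.0, 2220.0, 2224.0]})
        stats = sk.cluster_peak_stats(np.ones(3, dtype=int), feats)
        assert stats.set_index("cluster").loc[1, "median"] == 2220.0

    def test_shifted_subpopulation_lowers_cluster_two_median(
        self, et_two_pop, two_pop_nnmf, config
    ):
        """Planted -3 cm^-1 band shift shows up as the cluster-2 median offset."""
        processed, _, _ = et_two_pop
        feats = sk.particle_features(processed, config.carrier_window, config.cargo_window)
        stats = sk.cluster_peak_stats(two_pop_nnmf.labels, feats).set_index("cluster")
        # grid resolution is 2 cm^-1, so a 3 cm^-1 shift lands 2-4 cm^-1 low
        shift = stats.loc[1, "median"] - stats.loc[2, "median"]
        assert 2.0 <= shift <= 4.0

    def test_empty_cluster_warns_and_is_omitted(self):
        feats = pd.DataFrame({"cargo_position_cm1": [2220.0, 2218.0]})
        with pytest.warns(UserWarning, match="cluster 2"):
            stats = sk.cluster_peak_stats(np.ones(2, dtype=int), feats)
        assert stats.cluster.tolist() == [1]
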