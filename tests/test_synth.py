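"""Synthetic-data generator: networks, hemodynamics, optics, counts."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nirsconn.errors import ParameterError
from nirsconn.glmm import ModelParameters
from nirsconn.preprocess import intensity_to_od, tddr
from nirsconn.synth import (
    SimulationConfig,
    simulate_cluster_network,
    simulate_degree_dataset,
    simulate_hemo,
    simulate_latent_network,
    simulate_optical,
)


class TestLatentNetwork:
    def test_edge_probability_extremes(self):
        empty = simulate_latent_network(44, 0.0, seed=3)
        assert empty.n_edges == 0 and np.all(empty.degrees == 0)
        full = simulate_latent_network(44, 1.0, seed=3)
        assert np.all(full.degrees == 43)

    def test_edge_count_follows_binomial_law(self):
        # mean edge count over seeds must sit inside the binomial 99%
        # interval for Binomial(45, 0.3)
        counts = [simulate_latent_network(10, 0.3, seed=s).n_edges for s in range(200)]
        lo, hi = stats.binom.interval(0.99, 45, 0.3)
        assert lo <= np.mean(counts) <= hi

    @pytest.mark.parametrize("n,p", [(1, 0.5), (5, -0.1), (5, 1.5)])
    def test_invalid_parameters_rejected(self, n, p):
        with pytest.raises(ParameterError):
            simulate_latent_network(n, p, seed=0)

    def test_cluster_network_is_disjoint_cliques(self):
        net = simulate_cluster_network(12, 3, seed=0, coupling=0.7)
        # every node's neighbourhood is a clique containing it
        for i in range(12):
            nb = np.flatnonzero(net.adjacency[i])
            sub = net.adjacency[np.ix_(nb, nb)]
            assert np.all(sub + np.eye(len(nb)) == 1)


class TestSimulateHemo:
    def test_full_coupling_without_noise_gives_unit_correlation(self):
        net = simulate_latent_network(4, 0.0, seed=0)
        A = np.zeros((4, 4), int)
        A[0, 1] = A[1, 0] = A[2, 3] = A[3, 2] = 1
        net = type(net)(4, A, np.where(A == 1, 1.0, 0.0))
        cfg = SimulationConfig(
            duration=120, n_long_channels=4, n_short_channels=2, seed=1,
            noise_sd=0, cardiac_amp=0, respiration_amp=0, mayer_amp=0,
            hbr_noise_sd=0,
        )
        hemo = simulate_hemo(net, cfg)
        r = np.corrcoef(hemo.hbo.T)
        assert r[0, 1] == pytest.approx(1.0, abs=1e-6)
        assert r[2, 3] == pytest.approx(1.0, abs=1e-6)
        assert abs(r[0, 2]) < 0.5

    def test_empty_network_off_diagonal_correlation_vanishes(self):
        def mean_abs_r(duration):
            vals = []
            for s in (2, 3, 4):
                net = simulate_latent_network(8, 0.0, seed=0)
                cfg = SimulationConfig(
                    duration=duration, n_long_channels=8, n_short_channels=2, seed=s
                )
                hemo = simulate_hemo(net, cfg)
                r = np.abs(np.corrcoef(hemo.hbo.T))
                vals.append(r[np.triu_indices(8, 1)].mean())
            return np.mean(vals)

        at_600 = mean_abs_r(600)
        assert at_600 < 0.15
        assert mean_abs_r(1200) < at_600  # decays with duration

    def test_correlation_monotone_in_coupling(self):
        # strong edges must out-correlate weak edges in >= 95% of runs
        wins = 0
        n_runs = 100
        for s in range(n_runs):
            A = np.zeros((4, 4), int)
            A[0, 1] = A[1, 0] = A[2, 3] = A[3, 2] = 1
            C = np.zeros((4, 4))
            C[0, 1] = C[1, 0] = 0.8
            C[2, 3] = C[3, 2] = 0.2
            net = simulate_latent_network(4, 0.0, seed=0)
            net = type(net)(4, A, C)
            cfg = SimulationConfig(
                duration=120, n_long_channels=4, n_short_channels=2, seed=s,
                cardiac_amp=0, respiration_amp=0, mayer_amp=0,
            )
            hemo = simulate_hemo(net, cfg)
            r = np.abs(np.corrcoef(hemo.hbo.T))
            wins += r[0, 1] > r[2, 3]
        assert wins >= 0.95 * n_runs

    def test_channel_count_mismatch_rejected(self, small_network):
        cfg = SimulationConfig(duration=60, n_long_channels=10, n_short_channels=2)
        with pytest.raises(ParameterError):
            simulate_hemo(small_network, cfg)


class TestSimulateOptical:
    def test_zero_concentration_gives_constant_intensity(self):
        net = simulate_latent_network(4, 0.0, seed=0)
        cfg = SimulationConfig(
            duration=60, n_long_channels=4, n_short_channels=2, seed=1,
            artifact_rate=0, superficial_weight=0, intensity_noise=0,
            hemo_amplitude=1.0,
        )
        hemo = simulate_hemo(net, cfg)
        hemo.hbo[:] = 0.0
        hemo.hbr[:] = 0.0
        rec = simulate_optical(hemo, cfg)
        assert np.allclose(rec.intensities, rec.intensities[0], atol=1e-12)

    def test_round_trip_recovers_concentrations(self, small_network):
        # forward optics then OD + Beer-Lambert inversion is the algebraic
        # inverse up to the arbitrary per-channel baseline
        cfg = SimulationConfig(
            duration=120, n_long_channels=12, n_short_channels=4, seed=3,
            artifact_rate=0, superficial_weight=0, intensity_noise=0,
        )
        hemo = simulate_hemo(small_network, cfg)
        rec = simulate_optical(hemo, cfg)
        from nirsconn.preprocess import od_to_hemo

        recovered = od_to_hemo(intensity_to_od(rec))
        err = recovered.hbo - hemo.hbo
        err -= err.mean(axis=0)
        assert np.sqrt((err**2).mean()) < 0.01 * hemo.hbo.std()

    def test_artifacts_increase_derivative_heavy_tailedness(self):
        net = simulate_latent_network(4, 0.0, seed=0)
        kurt = {}
        for rate in (0.0, 6.0):
            cfg = SimulationConfig(
                duration=300, n_long_channels=4, n_short_channels=2, seed=4,
                artifact_rate=rate,
            )
            hemo = simulate_hemo(net, cfg)
            rec = simulate_optical(hemo, cfg)
            od = intensity_to_od(rec).intensities[:, 0, 0]
            corrected = tddr(od, cfg.sampling_rate)
            # how much TDDR changed the series, relative to its scale
            kurt[rate] = np.abs(od - corrected).max() / od.std()
        assert kurt[6.0] > kurt[0.0]

    def test_short_channels_track_superficial_component(self, small_network):
        cfg = SimulationConfig(
            duration=300, n_long_channels=12, n_short_channels=4, seed=5,
            artifact_rate=0,
        )
        hemo = simulate_hemo(small_network, cfg)
        rec, truth = simulate_optical(hemo, cfg, return_truth=True)
        mont = truth["montage"]
        short_ix = mont.short_indices()
        long_ix = mont.long_indices()
        sup = truth["superficial"]
        short_cors = [
            abs(np.corrcoef(truth["hbo_total"][:, s], sup[:, k])[0, 1])
            for k, s in enumerate(short_ix)
        ]
        long_cors = [
            abs(np.corrcoef(truth["hbo_total"][:, c], sup[:, truth["region_of_long"][i]])[0, 1])
            for i, c in enumerate(long_ix)
        ]
        assert min(short_cors) > max(long_cors)

    def test_saturation_rate_produces_saturated_samples(self, small_network):
        cfg = SimulationConfig(
            duration=300, n_long_channels=12, n_short_channels=4, seed=6,
            artifact_rate=0, saturation_rate=3.0,
        )
        hemo = simulate_hemo(small_network, cfg)
        rec, truth = simulate_optical(hemo, cfg, return_truth=True)
        assert truth["saturation_windows"]
        from nirsconn.preprocess import od_to_hemo

        recovered = od_to_hemo(intensity_to_od(rec))
        assert np.abs(recovered.hbo).max() >= 10.0


class TestDegreeDataset:
    def test_log_link_identity_at_null(self):
        params = ModelParameters()
        df = simulate_degree_dataset(params, (5, 5, 5), n_channels=223, seed=0)
        y = df["degree"].to_numpy()[:10000]
        assert abs(y.mean() - 1.0) <= 3 * y.std() / np.sqrt(len(y))

    def test_poisson_mean_follows_intercept(self, degree_params):
        params = ModelParameters(beta0=np.log(15.0))
        df = simulate_degree_dataset(params, (9, 9, 9), n_channels=44, seed=1)
        y = df["degree"].to_numpy()
        assert abs(y.mean() - 15.0) <= 3 * y.std() / np.sqrt(len(y))

    def test_poisson_dispersion_without_random_effects(self):
        # intercept-only model: every observation shares one Poisson mean
        params = ModelParameters(beta0=np.log(15.0))
        df = simulate_degree_dataset(params, (26, 26, 26), n_channels=44, seed=2)
        y = df["degree"].to_numpy()
        assert len(y) >= 10000
        assert 0.8 <= y.var() / y.mean() <= 1.2

    def test_negative_sd_rejected(self):
        with pytest.raises(ParameterError):
            ModelParameters(sigma_u=-0.1)

    def test_clip_flag_bounds_counts(self):
        params = ModelParameters(beta0=np.log(40.0))
        df = simulate_degree_dataset(params, (3, 3, 3), n_channels=10, seed=3, clip=True)
        assert df["degree"].max() <= 9
        df_raw = simulate_degree_dataset(params, (3, 3, 3), n_channels=10, seed=3)
        assert df_raw["degree"].max() > 9  # unbounded by default

    def test_table_layout(self, degree_params):
        df = simulate_degree_dataset(degree_params, (2, 3, 4), n_channels=5, seed=4)
        assert list(df.columns) == ["participant", "group", "session", "channel", "degree"]
        assert len(df) == 9 * 3 * 5
        counts = df.groupby("group")["participant"].nunique()
        assert counts["Sham"] == 2 and counts["DLPFC"] == 3 and counts["VLPFC"] == 4


class TestDeterminism:
    def test_fixed_seed_bit_identical(self, small_network):
        cfg = SimulationConfig(duration=60, n_long_channels=12, n_short_channels=4, seed=11)
        a = simulate_hemo(small_network, cfg)
        b = simulate_hemo(small_network, cfg)
        assert np.array_equal(a.hbo, b.hbo) and np.array_equal(a.hbr, b.hbr)
        ra = simulate_optical(a, cfg)
        rb = simulate_optical(b, cfg)
        assert np.array_equal(ra.intensities, rb.intensities)
        params = ModelParameters(beta0=1.0, sigma_u=0.3, sigma_w=0.2)
        da = simulate_degree_dataset(params, (3, 3, 3), n_channels=6, seed=12)
        db = simulate_degree_dataset(params, (3, 3, 3), n_channels=6, seed=12)
        pd.testing.assert_frame_equal(da, db)
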