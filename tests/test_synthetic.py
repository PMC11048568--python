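"""Stochastic generators: KMC hopping, noise, OU series, toy structures."""

import json

import numpy as np
import pytest

import trpchain as tc
from trpchain.io import read_occupations_csv, write_occupations_csv


class TestSimulateKmc:
    def test_zero_rates_freeze_every_trajectory(self):
        ens = tc.simulate_kmc(tc.RateConstants(0, 0, 0, 0, 0, 0), 50.0, 1.0, 5, seed=1)
        assert np.array_equal(ens.occupations[:, :, 0], np.ones((5, 51)))

    def test_fast_forward_only_chain_absorbs_at_D(self):
        r = tc.RateConstants(1.0, 0.0, 1.0, 0.0, 1.0, 0.0)  # all taus 1 ps
        ens = tc.simulate_kmc(r, 1000.0, 1.0, 20, seed=2)
        assert np.array_equal(ens.occupations[:, -1, 3], np.ones(20))

    def test_reproducible_and_stream_stable_under_ensemble_growth(self, reference_rates):
        a = tc.simulate_kmc(reference_rates, 100.0, 1.0, 5, seed=7)
        b = tc.simulate_kmc(reference_rates, 100.0, 1.0, 5, seed=7)
        assert np.array_equal(a.occupations, b.occupations)
        bigger = tc.simulate_kmc(reference_rates, 100.0, 1.0, 8, seed=7)
        assert np.array_equal(bigger.occupations[:5], a.occupations)

    def test_ensemble_mean_converges_to_master_equation(self, reference_rates):
        """Law of large numbers: 2000-trajectory mean within 3 binomial SE."""
        n = 2000
        ens = tc.simulate_kmc(reference_rates, 1000.0, 1.0, n, seed=10)
        mean = tc.ensemble_mean(ens)
        ode = tc.propagate(reference_rates, mean.times)
        for t in (100, 500, 1000):
            p = ode.occ[t]
            se = np.sqrt(p * (1 - p) / n)
            assert np.abs(mean.occ[t] - p).max() <= (3 * se).max()

    def test_smoothed_mode_keeps_rows_normalized(self, reference_rates):
        ens = tc.simulate_kmc(
            reference_rates, 200.0, 1.0, 3, seed=3, smooth_window_ps=25.0
        )
        assert np.abs(ens.occupations.sum(axis=2) - 1.0).max() < 1e-9
        # smoothing produces fractional occupations
        assert np.any((ens.occupations > 0) & (ens.occupations < 1))

    def test_rejects_invalid_inputs(self, reference_rates):
        with pytest.raises(ValueError):
            tc.simulate_kmc(reference_rates, -1.0, 1.0, 1, seed=0)
        with pytest.raises(ValueError):
            tc.simulate_kmc(reference_rates, 10.0, 1.0, 0, seed=0)


class TestEnsembleMean:
    def test_mean_of_one_is_identity(self, reference_rates):
        ens = tc.simulate_kmc(reference_rates, 50.0, 1.0, 3, seed=4)
        m = tc.ensemble_mean(ens, subset=["sim_001"])
        assert np.array_equal(m.occ, ens.occupations[1])

    def test_mean_of_two_constant_traces(self):
        t = np.arange(0.0, 10.0)
        occ = np.zeros((2, 10, 4))
        occ[0, :, 0] = 1.0
        occ[1, :, 1] = 1.0
        ens = tc.TrajectoryEnsemble(t, occ, ("a", "b"))
        m = tc.ensemble_mean(ens)
        assert np.allclose(m.occ, np.tile([0.5, 0.5, 0.0, 0.0], (10, 1)))

    def test_empty_subset_rejected(self, reference_rates):
        ens = tc.simulate_kmc(reference_rates, 50.0, 1.0, 2, seed=4)
        with pytest.raises(ValueError):
            tc.ensemble_mean(ens, subset=[])


class TestObservationNoise:
    def test_sigma_zero_is_identity(self, reference_trace):
        out = tc.add_observation_noise(reference_trace, 0.0, seed=1)
        assert np.array_equal(out.occ, reference_trace.occ)

    def test_rows_sum_to_one(self, reference_trace):
        out = tc.add_observation_noise(reference_trace, 0.1, seed=2)
        assert np.abs(out.occ.sum(axis=1) - 1.0).max() <= 1e-9

    def test_clipping_bias_matches_direct_monte_carlo(self):
        """On a (1,0,0,0) trace the clipped/renormalized noise has a biased
        mean; compare against a direct simulation with the same rule."""
        sigma, n = 0.05, 10_000
        t = np.arange(0.0, float(n))
        occ = np.zeros((n, 4))
        occ[:, 0] = 1.0
        out = tc.add_observation_noise(tc.OccupationTrace(t, occ), sigma, seed=5)

        rng = np.random.default_rng(12345)
        raw = np.clip([1.0, 0, 0, 0] + rng.normal(0, sigma, size=(200_000, 4)), 0, 1)
        oracle = (raw / raw.sum(axis=1, keepdims=True)).mean(axis=0)
        tol = 3 * sigma / np.sqrt(n)
        assert np.abs(out.occ.mean(axis=0) - oracle).max() <= tol

    def test_negative_sigma_rejected(self, reference_trace):
        with pytest.raises(ValueError):
            tc.add_observation_noise(reference_trace, -0.1, seed=0)


class TestHeterogeneousEnsemble:
    def test_default_mixture_is_51_labeled_trajectories(self):
        ens = tc.make_heterogeneous_ensemble(seed=1)
        assert ens.n_traj == 51
        labels = list(ens.labels.values())
        assert labels.count("completed") == 23
        assert labels.count("stuck") == 28
        assert ens.times.size == 1001

    def test_all_completed_when_no_stuck_requested(self):
        ens = tc.make_heterogeneous_ensemble(n_completed=4, n_stuck=0, t_max=200.0, seed=2)
        assert set(ens.labels.values()) == {"completed"}

    def test_stuck_trajectories_never_reach_C_or_D(self):
        ens = tc.make_heterogeneous_ensemble(seed=3)
        for sim_id, label in ens.labels.items():
            occ = ens.occupations[ens.sim_ids.index(sim_id)]
            if label == "stuck":
                assert occ[:, 2:].max() == 0.0
            else:
                assert occ[:, 2:].max() >= 0.3

    def test_noisy_mixture_recovered_by_classifier(self):
        ens = tc.make_heterogeneous_ensemble(sigma=0.05, seed=4)
        res = tc.classify_ensemble(ens)
        assert res.agreement >= 0.95


class TestSiteSeries:
    def test_zero_sd_yields_constant_series(self):
        s = tc.simulate_site_series(
            {"A": 0.1, "B": 0.2}, sd=0.0, correlation_time=5.0,
            times=np.arange(0.0, 100.0), seed=1,
        )
        assert np.allclose(s.values["A"], 0.1) and np.allclose(s.values["B"], 0.2)

    def test_ou_sample_mean_within_three_standard_errors(self):
        """Stationary OU mean estimate: SE from the analytic autocorrelation,
        var(mean) ~ sd^2 * 2 tau / T for T >> tau."""
        mu, sd, tau, n = 0.1, 0.02, 10.0, 100_000
        s = tc.simulate_site_series(
            {"AB": mu}, sd=sd, correlation_time=tau,
            times=np.arange(0.0, float(n)), seed=6,
        )
        se = sd * np.sqrt(2 * tau / n)
        assert abs(s.values["AB"].mean() - mu) <= 3 * se

    def test_non_neighbour_pair_rejected(self):
        with pytest.raises(ValueError, match="non-neighbour"):
            tc.simulate_site_series(
                {"AC": 0.1}, sd=0.01, correlation_time=5.0,
                times=np.arange(0.0, 10.0), seed=0,
            )

    def test_non_neighbour_lookup_returns_zeros(self):
        s = tc.simulate_site_series(
            {"AB": 0.1, "BC": 0.05, "CD": 0.02}, sd=0.01, correlation_time=5.0,
            times=np.arange(0.0, 10.0), seed=0,
        )
        assert np.array_equal(s.get("AC"), np.zeros(10))


class TestToyFrames:
    def test_constructed_water_counts_and_boundary(self, tmp_path):
        path = tmp_path / "toy.pdb"
        _, truth = tc.make_toy_frames(
            n_frames=2,
            water_placements=[(373, 3.0, 2), (319, 5.0, 1), (370, 5.1, 1)],
            seed=1,
            out_path=path,
        )
        frames = tc.read_frames(path)
        assert len(frames) == 2
        for frame in frames:
            assert tc.count_waters_near(frame, 373) == 2
            assert tc.count_waters_near(frame, 319) == 1  # exactly at 5.0: counted
            assert tc.count_waters_near(frame, 370) == 0  # 5.1 is outside
        assert truth["frames"][0]["water_counts_5A"] == {
            "396": 0, "373": 2, "319": 1, "370": 0,
        }

    def test_constructed_edge_distance_is_exact(self, tmp_path):
        path = tmp_path / "toy.pdb"
        tc.make_toy_frames(n_frames=1, seed=2, separations=(5.0, 4.2, 5.0), out_path=path)
        frame = tc.read_frames(path)[0]
        assert tc.edge_to_edge(frame, 373, 319) == pytest.approx(4.2, abs=1e-6)

    def test_clashing_placement_rejected(self):
        with pytest.raises(ValueError, match="clash"):
            tc.make_toy_frames(water_placements=[(373, 0.5, 1)])

    def test_sidecar_written(self, tmp_path):
        path = tmp_path / "toy.pdb"
        _, truth = tc.make_toy_frames(n_frames=1, seed=3, out_path=path)
        on_disk = json.loads((tmp_path / "toy.pdb.json").read_text())
        assert on_disk["frames"][0]["edge_to_edge_A"] == truth["frames"][0]["edge_to_edge_A"]


class TestCsvRoundTrip:
    def test_occupations_roundtrip_at_twelve_significant_digits(self, tmp_path, reference_rates):
        ens = tc.simulate_kmc(
            reference_rates, 100.0, 1.0, 4, seed=8, smooth_window_ps=25.0
        )
        path = tmp_path / "occ.csv"
        write_occupations_csv(path, ens)
        back = read_occupations_csv(path)
        assert back.sim_ids == ens.sim_ids
        assert np.allclose(back.occupations, ens.occupations, rtol=5e-12, atol=1e-12)


class TestErgodicity:
    def test_long_time_average_matches_equilibrium(self, reference_rates):
        """A single long trajectory is ergodic: its time-average occupancy
        approaches the chain equilibrium (SE estimated by batch means)."""
        ens = tc.simulate_kmc(reference_rates, 200_000.0, 1.0, 1, seed=9)
        occ = ens.occupations[0]
        ss = tc.steady_state(reference_rates)
        occ = occ[1:]  # drop t=0 so the grid splits into 20 equal batches
        batches = occ.reshape(20, -1, 4).mean(axis=1)
        se = batches.std(axis=0, ddof=1) / np.sqrt(20)
        assert np.all(np.abs(occ.mean(axis=0) - ss) <= 3 * se + 1e-3)
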