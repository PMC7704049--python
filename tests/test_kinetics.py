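"""Trajectory denoising, clustering, rate estimation, and Arrhenius fits."""

import math

import numpy as np
import pytest

from foldrate.kinetics import (
    ClusterSet,
    StateTrajectory,
    TransitionRate,
    bootstrap_rates,
    cluster_by_threshold,
    denoise_hmm,
    estimate_transition_rates,
    extrapolate_rate,
    filter_rare_configurations,
    fit_all_arrhenius,
    fit_arrhenius,
    kinetic_distance_matrix,
    map_to_clusters,
    rates_by_temperature,
    survival_curve,
)
from foldrate.synthetic import SyntheticNetwork, simulate_kinetic_network

DT = 5e5


def traj(labels, T=1.0, dt=DT, tid="t0"):
    return StateTrajectory(trajectory_id=tid, T=T, dt=dt, labels=tuple(labels))


def two_state_net(k12=4e-7, k21=0.0):
    """Two configurations ∅ <-> a with temperature-independent-ish rates.

    Arrhenius with dE=0 makes the rate equal k0 at every temperature;
    folding back is suppressed by a large free-energy gap when k21 = 0.
    """
    dS = 50.0 if k21 == 0.0 else 0.0
    net = SyntheticNetwork(
        states=("∅", "a"),
        energies={"∅": 0.0, "a": 0.0},
        entropies={"∅": dS, "a": 0.0},
        unfold_edges={("a", "∅"): (k12, 0.0)},
    )
    return net


class TestFilterRare:
    def test_s_zero_is_identity(self):
        trajs = [traj(["a", "ab", "a", "∅"])]
        assert filter_rare_configurations(trajs, 0.0) == trajs

    def test_rare_configuration_reassigned_to_nearest_neighbor(self):
        # X = "ab" occurs once; Hamming(ab, a) = 1 < Hamming(ab, ∅) = 2
        trajs = [traj(["a", "a", "ab", "∅", "∅"])]
        out = filter_rare_configurations(trajs, 0.3, n_substructures=2)
        assert out[0].labels == ("a", "a", "a", "∅", "∅")

    def test_tie_goes_to_preceding_configuration(self):
        # Hamming(a, ab) = 1 = Hamming(a, ∅): preceding "ab" wins
        trajs = [traj(["ab", "ab", "a", "∅", "∅"])]
        out = filter_rare_configurations(trajs, 0.3, n_substructures=2)
        assert out[0].labels == ("ab", "ab", "ab", "∅", "∅")

    def test_overly_aggressive_s_raises(self):
        trajs = [traj(["a", "ab", "∅", "b"])]
        with pytest.raises(ValueError, match="fewer than 2"):
            filter_rare_configurations(trajs, 0.9, n_substructures=2)

    def test_iterative_until_all_frequent(self):
        labels = ["∅"] * 10 + ["a", "ab"] + ["abc"] * 10
        out = filter_rare_configurations([traj(labels)], 0.2, n_substructures=3)
        freqs = {lab: out[0].labels.count(lab) / len(labels) for lab in set(out[0].labels)}
        assert all(f >= 0.2 for f in freqs.values())


class TestDenoiseHMM:
    def test_m_zero_is_identity(self):
        trajs = [traj(["a", "ab", "a", "∅", "a"])]
        assert denoise_hmm(trajs, 0.0) == trajs

    def test_single_configuration_is_identity(self):
        trajs = [traj(["a"] * 5)]
        assert denoise_hmm(trajs, 0.2) == trajs

    def test_removes_isolated_misassignments(self):
        labels = ["a"] * 10 + ["∅"] * 10
        noisy = list(labels)
        noisy[4] = "∅"
        noisy[15] = "a"
        out = denoise_hmm([traj(noisy), traj(labels, tid="t1")], 0.1)
        assert out[0].labels == tuple(labels)

    def test_decoded_error_below_injected_noise(self, linear_network):
        clean = simulate_kinetic_network(linear_network, 1.35, 40, 150, DT, seed=3)
        noisy = simulate_kinetic_network(linear_network, 1.35, 40, 150, DT, seed=3, noise=0.1)
        decoded = denoise_hmm(noisy, 0.1)
        err = np.mean(
            [a != b for tn, tc in zip(decoded, clean) for a, b in zip(tn.labels, tc.labels)]
        )
        assert err < 0.10

    def test_invalid_m_raises(self):
        with pytest.raises(ValueError):
            denoise_hmm([traj(["a", "b"])], 1.0)


class TestKineticDistance:
    def test_single_passage_two_intervals(self):
        mat = kinetic_distance_matrix([traj(["a", "a", "ab"])])
        assert mat.loc["a", "ab"] == pytest.approx(2 * DT)
        assert mat.loc["ab", "a"] == mat.loc["a", "ab"]

    def test_never_cooccurring_pair_is_infinite(self):
        mat = kinetic_distance_matrix([traj(["a", "a"]), traj(["ab", "ab"], tid="t1")])
        assert np.isinf(mat.loc["a", "ab"])

    def test_third_state_interruption_excluded(self):
        # a -> ∅ -> ab: the a..ab passage is interrupted, contributes nothing
        mat = kinetic_distance_matrix([traj(["a", "∅", "ab"])])
        assert np.isinf(mat.loc["a", "ab"])
        assert mat.loc["a", "∅"] == pytest.approx(DT)

    def test_both_directions_pooled(self):
        # a->b passage of 1 interval, b->a passage of 2 intervals
        mat = kinetic_distance_matrix([traj(["a", "b", "b", "a"])])
        assert mat.loc["a", "b"] == pytest.approx((1 + 2) / 2 * DT)


class TestClustering:
    def test_threshold_below_minimum_gives_singletons(self):
        mat = kinetic_distance_matrix([traj(["a", "ab", "a", "ab"])])
        cs = cluster_by_threshold(mat, DT / 2)
        assert cs.names == ["a", "ab"]

    def test_threshold_above_maximum_gives_one_cluster(self):
        mat = kinetic_distance_matrix([traj(["a", "ab", "∅", "a", "ab", "∅"])])
        cs = cluster_by_threshold(mat, 1e12)
        assert len(cs.members) == 1

    def test_cluster_names_deterministic(self):
        mat = kinetic_distance_matrix([traj(["a", "ab", "a", "ab", "∅"])])
        cs = cluster_by_threshold(mat, 3 * DT)
        assert all("+" in n or n in ("a", "ab", "∅") for n in cs.names)
        # mapping covers every configuration exactly once
        seen = [lab for m in cs.members.values() for lab in m]
        assert sorted(seen) == sorted(set(seen)) == ["a", "ab", "∅"]


class TestSurvival:
    def test_survival_starts_at_one_and_never_increases(self):
        trajs = [traj(["∅", "a", "a", "∅", "a", "∅"], tid=f"t{i}") for i in range(3)]
        sc = survival_curve(trajs, "a", 1.0)
        assert sc.survival[0] == 1.0
        assert np.all(np.diff(sc.survival) <= 1e-12)

    def test_no_entries_raise(self):
        with pytest.raises(ValueError, match="entry"):
            survival_curve([traj(["a", "a", "a"])], "a", 1.0)

    def test_two_state_exit_rate_recovered(self):
        # reversible symmetric two-state system: exit rate from "a" is the
        # single unfolding rate; k * dt = 0.1 keeps within-interval returns
        # (invisible at snapshot resolution) negligible
        net = SyntheticNetwork(
            states=("∅", "a"),
            energies={"∅": 0.0, "a": 0.0},
            entropies={"∅": 0.0, "a": 0.0},
            unfold_edges={("a", "∅"): (2e-7, 0.0)},
        )
        trajs = simulate_kinetic_network(net, 1.0, 150, 300, DT, seed=9, start="a")
        sc = survival_curve(trajs, "a", 1.0)
        assert sc.n_entries >= 500
        assert sc.rate == pytest.approx(2e-7, rel=0.10)


class TestRateEstimation:
    def test_no_transitions_gives_no_rates(self):
        rates = estimate_transition_rates([traj(["a"] * 6)])
        assert rates == []

    def test_single_exit_channel_reduces_to_log_formula(self):
        # 10 occupancies of "a", 2 exits to "∅": p = 0.2
        labels = ["a", "a", "a", "a", "a", "∅", "a", "a", "a", "a", "a", "∅"]
        rates = estimate_transition_rates([traj(labels)])
        r = next(x for x in rates if x.source == "a" and x.dest == "∅")
        p = r.n_trans / r.n_occ
        assert r.k == pytest.approx(-math.log(1 - p) / DT)

    def test_two_state_ctmc_rate_within_five_percent(self):
        # effectively irreversible decay (huge entropy gap suppresses the
        # return); 2000 exit events put the standard error near 2%
        net = two_state_net(k12=1e-6)
        trajs = simulate_kinetic_network(net, 1.0, 2000, 50, DT, seed=21, start="a")
        rates = estimate_transition_rates(trajs, T=1.0)
        r = next(x for x in rates if x.source == "a" and x.dest == "∅")
        assert r.k == pytest.approx(1e-6, rel=0.05)

    def test_small_probability_limit_matches_counts_over_time(self):
        # p_out ~ 0.005 << 1: Eq-form rate within 1% of Z_trans/(Z_occ * dt)
        labels = ["a"] * 400 + ["∅", "a"] + ["a"] * 400 + ["∅"]
        rates = estimate_transition_rates([traj(labels)])
        r = next(x for x in rates if x.source == "a" and x.dest == "∅")
        naive = r.n_trans / (r.n_occ * DT)
        assert abs(r.k - naive) / naive < 0.01

    def test_immediate_exit_every_interval_raises(self):
        with pytest.raises(ValueError, match="coarse"):
            estimate_transition_rates([traj(["a", "∅", "a", "∅"])])
        # (every "a" occupancy except the last exits; construct a worse case)

    def test_deterministic_under_trajectory_permutation(self, linear_network):
        trajs = simulate_kinetic_network(linear_network, 1.35, 30, 100, DT, seed=5)
        a = rates_by_temperature(trajs)
        b = rates_by_temperature(list(reversed(trajs)))
        assert a.sort_values(["source", "dest", "T"]).reset_index(drop=True).equals(
            b.sort_values(["source", "dest", "T"]).reset_index(drop=True)
        )


class TestArrhenius:
    def rates_on_exact_line(self, k0=1e-2, dE=5.0, temps=(1.0, 1.2, 1.4, 1.6)):
        return [
            TransitionRate("a", "∅", T, k0 * math.exp(-dE / T), 50, 1000)
            for T in temps
        ]

    def test_exact_line_recovered_to_machine_precision(self):
        fit = fit_arrhenius(self.rates_on_exact_line())
        assert fit.ln_k0 == pytest.approx(math.log(1e-2), abs=1e-10)
        assert fit.dE == pytest.approx(5.0, abs=1e-10)

    def test_low_event_temperatures_excluded(self):
        rates = self.rates_on_exact_line()
        rates.append(TransitionRate("a", "∅", 2.0, 1e-3, 4, 1000))
        fit = fit_arrhenius(rates, min_events=5)
        assert fit.excluded == [2.0]
        assert len(fit.points) == 4

    def test_insufficient_temperatures_raise(self):
        rates = self.rates_on_exact_line(temps=(1.0,))
        with pytest.raises(ValueError, match="insufficient temperatures"):
            fit_arrhenius(rates)

    def test_extrapolation_reproduces_fitted_point(self):
        fit = fit_arrhenius(self.rates_on_exact_line())
        assert extrapolate_rate(fit, 1.2) == pytest.approx(1e-2 * math.exp(-5.0 / 1.2))

    def test_direct_substitution(self):
        fit = fit_arrhenius(
            [
                TransitionRate("a", "∅", T, 1.0 * math.exp(-10.0 / T), 50, 1000)
                for T in (2.0, 4.0)
            ]
        )
        assert extrapolate_rate(fit, 1.0) == pytest.approx(math.exp(-10.0), rel=1e-9)

    def test_noisy_simulated_rates_recover_activation_energy(self):
        net = SyntheticNetwork(
            states=("∅", "a"),
            energies={"∅": 0.0, "a": 0.0},
            entropies={"∅": 30.0, "a": 0.0},
            unfold_edges={("a", "∅"): (2e-6, 2.0)},
        )
        trajs = []
        for i, T in enumerate((1.1, 1.2, 1.3, 1.4, 1.5)):
            trajs += simulate_kinetic_network(net, T, 60, 200, DT, seed=100 + i, start="a")
        fits = fit_all_arrhenius(rates_by_temperature(trajs), min_events=5)
        fit = fits[("a", "∅")]
        se_slope = math.sqrt(fit.cov[0, 0])
        assert abs(fit.dE - 2.0) < 2 * se_slope + 0.2


class TestBootstrap:
    def test_single_trajectory_bootstrap_equals_point_estimate(self):
        # with one trajectory per temperature, resampling is the identity
        net = two_state_net(k12=6e-7, k21=1.0)  # reversible: many events
        trajs = []
        for i, T in enumerate((1.0, 1.5)):
            trajs += simulate_kinetic_network(net, T, 1, 400, DT, seed=40 + i, start="a")
        boot = bootstrap_rates(trajs, None, T_targets=[0.8], B=1, seed=0)
        fits = fit_all_arrhenius(rates_by_temperature(trajs), min_events=5)
        fit = fits[("a", "∅")]
        expected = fit.ln_k0 - fit.dE / 0.8
        assert boot[("a", "∅")][0.8][0] == pytest.approx(expected, abs=1e-12)

    def test_bootstrap_reproducible_from_seed(self):
        net = two_state_net(k12=6e-7)
        trajs = simulate_kinetic_network(net, 1.2, 20, 150, DT, seed=8, start="a") + \
            simulate_kinetic_network(net, 1.6, 20, 150, DT, seed=9, start="a")
        b1 = bootstrap_rates(trajs, None, T_targets=[0.9], B=25, seed=4)
        b2 = bootstrap_rates(trajs, None, T_targets=[0.9], B=25, seed=4)
        np.testing.assert_array_equal(b1[("a", "∅")][0.9], b2[("a", "∅")][0.9])
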