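"""The ground-truth generators themselves: simulator, sampler, structures."""

import math

import numpy as np
import pytest
from scipy import stats

from foldrate.contacts import ContactParams, assign_configuration, decompose_structure
from foldrate.synthetic import (
    HubSpec,
    SyntheticNetwork,
    linear_unfolding_network,
    make_hairpin_structure,
    replica_exchange_step,
    run_replica_exchange,
    simulate_kinetic_network,
    synthesize_toy_structures,
    toy_metropolis_sample,
)
from foldrate.thermo import SamplingCondition


class TestNetworkValidation:
    def test_non_adjacent_edge_rejected(self):
        with pytest.raises(ValueError, match="Hamming"):
            SyntheticNetwork(
                states=("∅", "a", "ab"),
                energies={"∅": 0, "a": -1, "ab": -2},
                entropies={"∅": 2, "a": 1, "ab": 0},
                unfold_edges={("ab", "∅"): (1e-6, 2.0)},
            )

    def test_equilibrium_normalized_at_every_temperature(self, linear_network):
        for T in (0.5, 1.0, 2.0):
            p = linear_network.p_eq(T)
            assert sum(p.values()) == pytest.approx(1.0, abs=1e-12)

    def test_melting_temperature_balances_end_states(self, linear_network):
        TM = linear_network.melting_temperature()
        p = linear_network.p_eq(TM)
        assert p["∅"] == pytest.approx(p["abcd"], rel=1e-9)

    def test_folding_rates_satisfy_detailed_balance(self, linear_network):
        T = 0.85
        p = linear_network.p_eq(T)
        for (src, dst) in linear_network.unfold_edges:
            k_u = linear_network.unfolding_rate(src, dst, T)
            k_f = linear_network.folding_rate(dst, src, T)
            assert k_f / k_u == pytest.approx(p[src] / p[dst], rel=1e-12)


class TestSimulator:
    def test_zero_rates_give_constant_trajectories(self):
        net = SyntheticNetwork(
            states=("∅", "a"),
            energies={"∅": 0, "a": 0},
            entropies={"∅": 0, "a": 0},
            unfold_edges={("a", "∅"): (1e-30, 60.0)},
        )
        trajs = simulate_kinetic_network(net, 1.0, 3, 50, 5e5, seed=0, start="a")
        for t in trajs:
            assert set(t.labels) == {"a"}

    def test_symmetric_two_state_occupancy_half(self):
        net = SyntheticNetwork(
            states=("∅", "a"),
            energies={"∅": 0, "a": 0},
            entropies={"∅": 0, "a": 0},
            unfold_edges={("a", "∅"): (4e-7, 0.0)},
        )
        trajs = simulate_kinetic_network(net, 1.0, 20, 2000, 5e5, seed=2, start="a")
        frac = np.mean([lab == "a" for t in trajs for lab in t.labels])
        assert frac == pytest.approx(0.5, abs=0.03)

    def test_count_estimator_matches_true_rate_within_3se(self):
        # absorbing decay (huge entropy gap suppresses refolding): the
        # per-interval exit probability is exactly 1 - exp(-k dt)
        k, dt = 3e-7, 5e5
        net = SyntheticNetwork(
            states=("∅", "a"),
            energies={"∅": 0, "a": 0},
            entropies={"∅": 50.0, "a": 0},
            unfold_edges={("a", "∅"): (k, 0.0)},
        )
        trajs = simulate_kinetic_network(net, 1.0, 500, 100, dt, seed=11, start="a")
        n_trans = sum(
            1 for t in trajs for x, y in zip(t.labels[:-1], t.labels[1:])
            if x == "a" and y == "∅"
        )
        occ = sum(lab == "a" for t in trajs for lab in t.labels)
        est_p = n_trans / occ
        exact_p = 1.0 - math.exp(-k * dt)
        se = math.sqrt(exact_p * (1 - exact_p) / occ)
        assert abs(est_p - exact_p) < 3 * se

    def test_trajectories_reproducible_and_order_independent(self, linear_network):
        a = simulate_kinetic_network(linear_network, 1.3, 5, 50, 5e5, seed=7)
        b = simulate_kinetic_network(linear_network, 1.3, 5, 50, 5e5, seed=7)
        assert [t.labels for t in a] == [t.labels for t in b]

    def test_too_coarse_dt_rejected(self, linear_network):
        with pytest.raises(ValueError, match="too coarse"):
            simulate_kinetic_network(linear_network, 1.5, 1, 10, 1e13, seed=0)

    def test_hub_preserves_observable_labels(self):
        hub = HubSpec(state="a", k_to_trap=2e-7, k_from_trap=5e-8)
        net = linear_unfolding_network(2, k0=(2e-6, 2.5e-6), dE=(3.0, 3.2), hub=hub)
        trajs = simulate_kinetic_network(net, 1.3, 5, 100, 5e5, seed=3)
        labels = {lab for t in trajs for lab in t.labels}
        assert labels <= set(net.states)


class TestMetropolisSampler:
    def test_infinite_temperature_is_uniform(self, small_landscape):
        # every proposal is accepted, so N flips parity each step: an odd
        # stride samples both parities and the pooled distribution is the
        # uniform (binomial-in-N) one, peaking at N = 3 with weight 20/64
        cond = SamplingCondition(T=1e6, condition_id="hot")
        rows = toy_metropolis_sample(small_landscape, cond, 120_001, seed=5, stride=7)
        counts = rows.groupby("natives").size()
        frac3 = counts.get(3.0, 0) / len(rows)
        assert frac3 == pytest.approx(20 / 64, abs=0.02)

    def test_two_level_occupancy_ratio(self, two_level_landscape):
        cond = SamplingCondition(T=0.8, condition_id="c")
        rows = toy_metropolis_sample(two_level_landscape, cond, 150_000, seed=6, stride=10)
        p_excited = np.mean(rows["natives"] == 0)
        expected = 1.0 / (1.0 + math.exp(1.5 / 0.8))
        assert p_excited == pytest.approx(expected, abs=0.01)

    def test_long_run_matches_boltzmann_chi_square(self, small_landscape):
        cond = SamplingCondition(T=1.0, S=3, k_bias=0.3, condition_id="c")
        rows = toy_metropolis_sample(small_landscape, cond, 400_000, seed=12, stride=40)
        exact = small_landscape.exact_coarse_probs(cond)
        observed = rows.groupby("config").size()
        labels = sorted(exact)
        obs = np.array([observed.get(lab, 0) for lab in labels], dtype=float)
        exp = np.array([exact[lab] for lab in labels]) * obs.sum()
        keep = exp > 5
        chi2 = ((obs[keep] - exp[keep]) ** 2 / exp[keep]).sum()
        pval = stats.chi2.sf(chi2, keep.sum() - 1)
        # correlated samples inflate chi2; the pre-registered seed and wide
        # stride keep this a meaningful (if approximate) consistency check
        assert pval > 0.01

    def test_empirical_detailed_balance_flux_symmetry(self, two_level_landscape):
        cond = SamplingCondition(T=1.0, condition_id="c")
        rows = toy_metropolis_sample(two_level_landscape, cond, 100_000, seed=9, stride=1)
        seq = rows["natives"].to_numpy()
        up = np.sum((seq[:-1] == 0) & (seq[1:] == 1))
        down = np.sum((seq[:-1] == 1) & (seq[1:] == 0))
        assert abs(up - down) <= 1  # alternating visits on a two-level system


class TestReplicaExchange:
    def test_identical_conditions_always_accept(self):
        cond = SamplingCondition(T=1.0, S=3, k_bias=0.3, condition_id="c")
        rng = np.random.default_rng(0)
        ok, p = replica_exchange_step(-3.0, 4, -3.0, 4, cond, cond, rng)
        assert p == pytest.approx(1.0)
        assert ok

    def test_equal_native_counts_cancel_bias_terms(self):
        # same temperature, different setpoints, N_m = N_n: bias cancels
        a = SamplingCondition(T=1.0, S=2, k_bias=0.5, condition_id="a")
        b = SamplingCondition(T=1.0, S=5, k_bias=0.5, condition_id="b")
        rng = np.random.default_rng(0)
        ok, p = replica_exchange_step(-1.0, 3, -4.0, 3, a, b, rng)
        assert p == pytest.approx(1.0)

    def test_unbiased_reduces_to_parallel_tempering_form(self):
        cold = SamplingCondition(T=1.0, condition_id="cold")
        hot = SamplingCondition(T=2.0, condition_id="hot")
        rng = np.random.default_rng(0)
        # cold chain holds the lower-energy configuration: swapping moves a
        # high-energy configuration into the cold chain, p = e^(-2)
        _, p = replica_exchange_step(-5.0, 0, -1.0, 0, cold, hot, rng)
        assert p == pytest.approx(
            math.exp((1 / 1.0 - 1 / 2.0) * (-1.0 - (-5.0)) * -1.0)
        )
        # the reverse arrangement is always favourable
        _, p = replica_exchange_step(-1.0, 0, -5.0, 0, cold, hot, rng)
        assert p == pytest.approx(1.0)

    def test_marginals_match_enumeration_with_exchanges(self, two_level_landscape):
        conds = [
            SamplingCondition(T=T, S=1, k_bias=0.4, condition_id=f"T{T}")
            for T in (0.7, 1.0, 1.5)
        ]
        rows = run_replica_exchange(
            two_level_landscape, conds, n_steps=60_000, exchange_every=200,
            seed=4, stride=10,
        )
        for c in conds:
            sub = rows[rows["condition_id"] == c.condition_id]
            exact = two_level_landscape.exact_boltzmann(c)
            p_ground = np.mean(sub["natives"] == 1)
            assert p_ground == pytest.approx(exact[1], abs=0.02)


class TestToyStructures:
    def test_unrealizable_layout_raises(self):
        with pytest.raises(ValueError, match="unrealizable"):
            make_hairpin_structure([1])

    def test_zero_perturbation_fully_folded(self):
        _, decomp, snaps = synthesize_toy_structures([6, 5])
        cfg = assign_configuration(snaps["native"], decomp.substructures, 1.7)
        assert cfg.label == "ab"

    def test_displacement_scale_is_exact(self):
        structure, decomp, snaps = synthesize_toy_structures(
            [6, 5], displacements={"b": 2.0}
        )
        from foldrate.contacts import mean_contact_distance

        sub = next(s for s in decomp.substructures if s.label == "b")
        d = mean_contact_distance(snaps["displaced_b"].coords, sub.contacts)
        assert d == pytest.approx(2.0 * sub.d0_mean, rel=1e-8)
        cfg = assign_configuration(snaps["displaced_b"], decomp.substructures, 1.7)
        assert cfg.label == "a"

    def test_contact_map_contains_exactly_planted_islands(self):
        structure = make_hairpin_structure([6, 6, 5])
        decomp = decompose_structure(structure, ContactParams(d_c=6.5, min_sep=3, c=5))
        assert len(decomp) == 3
        assert len(decomp.unassigned) == 0
        # islands live in disjoint residue ranges in hairpin order
        ranges = [
            (min(r for p in s.contacts for r in p), max(r for p in s.contacts for r in p))
            for s in decomp.substructures
        ]
        assert ranges == sorted(ranges)
        assert all(hi < lo2 for (_, hi), (lo2, _) in zip(ranges, ranges[1:]))
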