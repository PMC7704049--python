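"""Ground-truth generators for end-to-end validation.

Three families of synthetic inputs make every pipeline stage testable with
known answers:

* :class:`SyntheticNetwork` -- a continuous-time Markov chain over
  topological configurations whose unfolding rates follow exact Arrhenius
  laws and whose folding rates are constructed from detailed balance with
  prescribed state free energies G(T) = E - T*S_conf.  The generative model
  therefore embodies exactly the kinetic assumptions the analysis pipeline
  is built on, making parameter recovery a well-posed test.  An optional
  hidden hub/trap split of one state plants non-Markovian (condition-II)
  exit kinetics.
* :class:`ToyLandscape` -- a fully enumerable microstate landscape (binary
  contact units) with a single-flip move graph, sampled by a Metropolis
  chain with umbrella biasing and optional replica exchange; exact partition
  sums provide the oracle for the reweighting machinery.
* toy CA structures -- multi-hairpin traces whose contact maps contain
  exactly the planted islands, with controlled perturbations (substructure
  displacement, antiparallel nonnative mispairing) for the contact-map and
  nonnative-state analyses.

All generators are pure functions of their specification and seed.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .contacts import (
    NativeStructure,
    Snapshot,
    SubstructureDecomposition,
    TopologicalConfiguration,
    label_hamming,
)
from .kinetics import StateTrajectory
from .thermo import SamplingCondition, biased_energy

__all__ = [
    "SyntheticNetwork",
    "HubSpec",
    "linear_unfolding_network",
    "simulate_kinetic_network",
    "ToyLandscape",
    "toy_metropolis_sample",
    "replica_exchange_step",
    "run_replica_exchange",
    "synthesize_toy_structures",
    "make_hairpin_structure",
    "displace_substructure",
    "plant_antiparallel_pairing",
]


# ---------------------------------------------------------------------------
# Kinetic networks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HubSpec:
    """Hidden hub/trap split of one state's exit kinetics.

    Entries into ``state`` land in the hub; exits to other states occur only
    from the hub at the network's nominal edge rates; hub <-> trap exchange
    at ``k_to_trap`` / ``k_from_trap`` (MC step^-1, temperature independent)
    makes the observable dwell-time distribution multi-exponential while the
    inverse mean first-passage time stays Arrhenius:
    1/tau = pi_hub * k_exit with pi_hub = k_from_trap/(k_from_trap+k_to_trap).
    """

    state: str
    k_to_trap: float
    k_from_trap: float

    @property
    def pi_hub(self) -> float:
        return self.k_from_trap / (self.k_from_trap + self.k_to_trap)


@dataclass(frozen=True)
class SyntheticNetwork:
    """A reversible configuration network with known thermodynamics/kinetics.

    ``states`` are configuration labels; ``energies``/``entropies`` define
    free energies G_i(T) = E_i - T * S_i so P_eq(T) prop exp(-E_i/T + S_i);
    ``unfold_edges`` maps (more-folded, less-folded) label pairs to Arrhenius
    parameters (k0, dE) of the unfolding direction.  Folding rates follow by
    detailed balance.  Edges must connect configurations at Hamming
    distance 1.
    """

    states: tuple
    energies: Dict[str, float]
    entropies: Dict[str, float]
    unfold_edges: Dict[Tuple[str, str], Tuple[float, float]]
    noise: float = 0.0
    hub: Optional[HubSpec] = None

    def __post_init__(self) -> None:
        n = self.n_substructures
        for (a, b), (k0, dE) in self.unfold_edges.items():
            if a not in self.states or b not in self.states:
                raise ValueError(f"edge ({a}, {b}) references unknown state")
            if label_hamming(a, b, n) != 1:
                raise ValueError(
                    f"edge ({a}, {b}) does not connect Hamming-1 configurations"
                )
            if k0 <= 0:
                raise ValueError("Arrhenius prefactors must be positive")
        if not 0 <= self.noise < 1:
            raise ValueError("noise must be in [0, 1)")
        if self.hub is not None and self.hub.state not in self.states:
            raise ValueError(f"hub state {self.hub.state!r} not in network")

    @property
    def n_substructures(self) -> int:
        n = 1
        for s in self.states:
            if s not in ("", "∅"):
                n = max(n, max(ord(c) - ord("a") + 1 for c in s))
        return n

    def p_eq(self, T: float) -> Dict[str, float]:
        logw = {s: -self.energies[s] / T + self.entropies[s] for s in self.states}
        mx = max(logw.values())
        w = {s: math.exp(v - mx) for s, v in logw.items()}
        z = sum(w.values())
        return {s: v / z for s, v in w.items()}

    def unfolding_rate(self, src: str, dst: str, T: float) -> float:
        k0, dE = self.unfold_edges[(src, dst)]
        return k0 * math.exp(-dE / T)

    def folding_rate(self, src: str, dst: str, T: float) -> float:
        """Rate of the folding direction (src less folded than dst)."""
        p = self.p_eq(T)
        return (p[dst] / p[src]) * self.unfolding_rate(dst, src, T)

    def rates(self, T: float) -> Dict[Tuple[str, str], float]:
        """All edge rates (both directions) at temperature T."""
        out = {}
        for (a, b) in self.unfold_edges:
            out[(a, b)] = self.unfolding_rate(a, b, T)
            out[(b, a)] = self.folding_rate(b, a, T)
        return out

    def generator(self, T: float) -> Tuple[np.ndarray, List[str]]:
        """Observable-state CTMC generator (columns sum to zero)."""
        names = list(self.states)
        idx = {s: i for i, s in enumerate(names)}
        M = np.zeros((len(names), len(names)))
        for (a, b), k in self.rates(T).items():
            M[idx[b], idx[a]] += k
        M[np.diag_indices(len(names))] -= M.sum(axis=0)
        return M, names

    def melting_temperature(self) -> float:
        """Temperature at which the most- and least-folded states have equal
        free energy."""
        order = sorted(self.states, key=lambda s: 0 if s == "∅" else len(s))
        u, f = order[0], order[-1]
        dS = self.entropies[u] - self.entropies[f]
        if dS <= 0:
            raise ValueError("unfolded state must have higher entropy")
        return (self.energies[u] - self.energies[f]) / dS

    def _hidden_space(self, T: float):
        """Hidden-state generator including the hub/trap split, plus the
        observation map hidden index -> observable label."""
        if self.hub is None:
            M, names = self.generator(T)
            return M, names, list(names)
        hub = self.hub
        hidden: List[str] = []
        obs: List[str] = []
        for s in self.states:
            if s == hub.state:
                hidden += [f"{s}#hub", f"{s}#trap"]
                obs += [s, s]
            else:
                hidden.append(s)
                obs.append(s)
        idx = {h: i for i, h in enumerate(hidden)}
        n = len(hidden)
        M = np.zeros((n, n))

        def h_of(label: str, entering: bool) -> str:
            if label == hub.state:
                return f"{label}#hub"
            return label

        for (a, b), k in self.rates(T).items():
            src = f"{a}#hub" if a == hub.state else a  # exits only from hub
            dst = h_of(b, entering=True)
            M[idx[dst], idx[src]] += k
        M[idx[f"{hub.state}#trap"], idx[f"{hub.state}#hub"]] += hub.k_to_trap
        M[idx[f"{hub.state}#hub"], idx[f"{hub.state}#trap"]] += hub.k_from_trap
        M -= np.diag(M.sum(axis=0))
        return M, hidden, obs

    def true_inverse_mfpt(self, src: str, dst: str, T: float) -> float:
        """Ground-truth inverse MFPT for one transition.

        Equals the plain rate for Markovian states; for the hub state the
        exit rate is scaled by the hub's equilibrium occupancy within the
        state (1/tau = pi_hub * k_exit)."""
        k = self.rates(T)[(src, dst)]
        if self.hub is not None and src == self.hub.state:
            return self.hub.pi_hub * k
        return k


def linear_unfolding_network(
    n_substructures: int = 4,
    k0: Sequence[float] = (2.0e-6, 1.5e-6, 1.2e-6, 2.5e-6),
    dE: Sequence[float] = (3.0, 3.5, 2.5, 3.2),
    dE_state: float = 3.0,
    dS_state: float = 3.0,
    noise: float = 0.0,
    hub: Optional[HubSpec] = None,
) -> SyntheticNetwork:
    """Linear folding pathway ∅ -> a -> ab -> ... with uniform per-step
    stability.

    Each formed substructure lowers the energy by ``dE_state`` and the
    conformational entropy by ``dS_state``, so the two-state melting
    temperature is dE_state / dS_state for every step.  ``k0``/``dE`` give
    the Arrhenius parameters of each unfolding step, ordered from the most
    folded transition (abcd -> abc) down to (a -> ∅).
    """
    labels = ["∅"] + [
        "".join(chr(ord("a") + j) for j in range(i + 1)) for i in range(n_substructures)
    ]
    energies = {lab: -dE_state * (0 if lab == "∅" else len(lab)) for lab in labels}
    entropies = {
        lab: dS_state * (n_substructures - (0 if lab == "∅" else len(lab)))
        for lab in labels
    }
    edges = {}
    for step in range(n_substructures):
        src = labels[n_substructures - step]
        dst = labels[n_substructures - step - 1]
        edges[(src, dst)] = (float(k0[step]), float(dE[step]))
    return SyntheticNetwork(
        states=tuple(labels),
        energies=energies,
        entropies=entropies,
        unfold_edges=edges,
        noise=noise,
        hub=hub,
    )


def simulate_kinetic_network(
    net: SyntheticNetwork,
    T: float,
    n_traj: int,
    n_snapshots: int,
    dt: float,
    seed: int = 0,
    start: Optional[str] = None,
    noise: Optional[float] = None,
) -> List[StateTrajectory]:
    """Exact CTMC trajectories discretized at the snapshot interval dt.

    Waiting times are exponential (Gillespie); the label recorded at each
    grid time is the state occupied then.  Optional misassignment noise
    replaces each recorded label, independently with the stated probability,
    by a uniformly random *other* state.  Each trajectory has its own RNG
    stream derived from (seed, trajectory index), so results are
    reproducible and order-independent.
    """
    if T <= 0:
        raise ValueError("temperature must be positive")
    M, hidden, obs = net._hidden_space(T)
    exit_rates = -np.diag(M)
    p_jump = 1.0 - np.exp(-exit_rates * dt)
    if np.any(p_jump >= 0.5):
        raise ValueError("dt too coarse for this network (per-interval jump probability >= 0.5)")
    if start is None:
        start = max(net.states, key=lambda s: 0 if s == "∅" else len(s))
    if net.hub is not None and start == net.hub.state:
        start_hidden = f"{start}#hub"
    else:
        start_hidden = start
    s0 = hidden.index(start_hidden)
    n_hidden = len(hidden)
    jump_probs = []
    for j in range(n_hidden):
        col = M[:, j].copy()
        col[j] = 0.0
        tot = col.sum()
        jump_probs.append(col / tot if tot > 0 else None)
    states_arr = np.array(net.states)
    noise_level = net.noise if noise is None else noise

    trajs = []
    for tr in range(n_traj):
        rng = np.random.default_rng([seed, tr])
        labels = np.empty(n_snapshots, dtype=object)
        cur = s0
        t_now = 0.0
        t_next_jump = (
            rng.exponential(1.0 / exit_rates[cur]) if exit_rates[cur] > 0 else np.inf
        )
        for snap in range(n_snapshots):
            t_grid = snap * dt
            while t_now + t_next_jump <= t_grid:
                t_now += t_next_jump
                cur = int(rng.choice(n_hidden, p=jump_probs[cur]))
                t_next_jump = (
                    rng.exponential(1.0 / exit_rates[cur])
                    if exit_rates[cur] > 0
                    else np.inf
                )
            t_next_jump -= t_grid - t_now
            t_now = t_grid
            labels[snap] = obs[cur]
        if noise_level > 0:
            flip = rng.random(n_snapshots) < noise_level
            for i in np.flatnonzero(flip):
                others = [s for s in net.states if s != labels[i]]
                labels[i] = others[rng.integers(len(others))]
        trajs.append(
            StateTrajectory(
                trajectory_id=f"T{T:g}-{tr}", T=T, dt=dt, labels=tuple(labels)
            )
        )
    return trajs


# ---------------------------------------------------------------------------
# Enumerable toy landscapes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ToyLandscape:
    """Binary-contact-unit landscape with exact enumeration.

    Microstates are bit vectors of length n_bits; bit b contributes
    ``bit_energies[b]`` to E0 and ``bit_natives[b]`` native contacts when
    set.  ``groups`` assigns bits to substructures: a substructure is formed
    in a microstate iff all its bits are set, and a group that completes
    gains the extra (cooperative) ``group_bonus`` energy.  Moves flip a
    single bit, so the move graph is the connected hypercube.
    """

    bit_energies: tuple
    bit_natives: tuple
    groups: tuple  # tuple of tuples of bit indices, substructure order a, b, ...
    group_bonus: tuple = ()

    def __post_init__(self) -> None:
        n = len(self.bit_energies)
        if len(self.bit_natives) != n:
            raise ValueError("bit_natives must match bit_energies in length")
        if 2**n > 10_000:
            raise ValueError("landscape too large for exact enumeration")
        used = [b for g in self.groups for b in g]
        if len(used) != len(set(used)):
            raise ValueError("groups must be disjoint")
        bonus = self.group_bonus or tuple(0.0 for _ in self.groups)
        if len(bonus) != len(self.groups):
            raise ValueError("group_bonus must match groups")
        object.__setattr__(self, "group_bonus", tuple(float(x) for x in bonus))

    @property
    def n_bits(self) -> int:
        return len(self.bit_energies)

    @property
    def n_microstates(self) -> int:
        return 2**self.n_bits

    def _bits(self) -> np.ndarray:
        n = self.n_bits
        states = np.arange(2**n)
        return ((states[:, None] >> np.arange(n)[None, :]) & 1).astype(float)

    def energies(self) -> np.ndarray:
        bits = self._bits()
        e = bits @ np.asarray(self.bit_energies, dtype=float)
        for g, bonus in zip(self.groups, self.group_bonus):
            formed = bits[:, list(g)].all(axis=1)
            e = e + bonus * formed
        return e

    def natives(self) -> np.ndarray:
        return self._bits() @ np.asarray(self.bit_natives, dtype=float)

    def config_labels(self) -> List[str]:
        bits = self._bits()
        labels = []
        for row in bits:
            cfg = TopologicalConfiguration(
                tuple(int(row[list(g)].all()) for g in self.groups)
            )
            labels.append(cfg.label)
        return labels

    def reduced_potentials(self, cond: SamplingCondition) -> np.ndarray:
        return biased_energy(self.energies(), self.natives(), cond) / cond.T

    def exact_boltzmann(self, cond: SamplingCondition) -> np.ndarray:
        u = self.reduced_potentials(cond)
        w = np.exp(-(u - u.min()))
        return w / w.sum()

    def exact_free_energy(self, cond: SamplingCondition) -> float:
        """Dimensionless free energy -log sum exp(-u) of a condition."""
        u = self.reduced_potentials(cond)
        mx = -u.max()
        return float(-(mx + np.log(np.exp(-u - mx).sum())))

    def exact_coarse_probs(self, cond: SamplingCondition) -> Dict[str, float]:
        p = self.exact_boltzmann(cond)
        labels = self.config_labels()
        out: Dict[str, float] = {}
        for lab, pi in zip(labels, p):
            out[lab] = out.get(lab, 0.0) + float(pi)
        return out

    def exact_thermal_mean(self, values: np.ndarray, cond: SamplingCondition) -> float:
        return float(self.exact_boltzmann(cond) @ np.asarray(values, dtype=float))


def toy_metropolis_sample(
    landscape: ToyLandscape,
    cond: SamplingCondition,
    n_steps: int,
    seed: int = 0,
    stride: int = 10,
    trajectory_id: Optional[str] = None,
    start: int = 0,
) -> pd.DataFrame:
    """Single-flip Metropolis chain on the landscape under a biased condition.

    Acceptance is min(1, exp(-dE_biased / T)) (unit Jacobian: bit flips are
    symmetric proposals).  Emits EnsembleTable-style rows every ``stride``
    steps: (condition_id, trajectory_id, mc_step, energy, natives, config).
    """
    n_bits = landscape.n_bits
    e_biased = biased_energy(landscape.energies(), landscape.natives(), cond)
    e0 = landscape.energies()
    natives = landscape.natives()
    labels = landscape.config_labels()
    rng = np.random.default_rng(seed)
    flips = rng.integers(0, n_bits, size=n_steps)
    unif = rng.random(n_steps)
    beta = 1.0 / cond.T
    tid = trajectory_id or f"{cond.condition_id}-chain"

    rows = []
    state = start
    for step in range(n_steps):
        proposal = state ^ (1 << int(flips[step]))
        dE = e_biased[proposal] - e_biased[state]
        if dE <= 0 or unif[step] < math.exp(-beta * dE):
            state = proposal
        if step % stride == 0:
            rows.append(
                (
                    cond.condition_id,
                    tid,
                    step,
                    float(e0[state]),
                    float(natives[state]),
                    labels[state],
                )
            )
    return pd.DataFrame(
        rows,
        columns=["condition_id", "trajectory_id", "mc_step", "energy", "natives", "config"],
    )


def replica_exchange_step(
    E_m0: float,
    N_m: float,
    E_n0: float,
    N_n: float,
    cond_m: SamplingCondition,
    cond_n: SamplingCondition,
    rng: np.random.Generator,
) -> Tuple[bool, float]:
    """Attempt a configuration swap between two sampling conditions.

    Configuration m currently runs under ``cond_m`` and n under ``cond_n``.
    The acceptance probability is the exact extended-ensemble Metropolis
    ratio for exchanging the configurations, which preserves every
    condition's marginal distribution; for unbiased conditions it reduces to
    the familiar parallel-tempering form
    min(1, exp[(1/T' - 1/T)(E_m0 - E_n0)]).
    """
    u_mm = biased_energy(E_m0, N_m, cond_m) / cond_m.T
    u_nn = biased_energy(E_n0, N_n, cond_n) / cond_n.T
    u_mn = biased_energy(E_m0, N_m, cond_n) / cond_n.T
    u_nm = biased_energy(E_n0, N_n, cond_m) / cond_m.T
    log_p = float((u_mm + u_nn) - (u_mn + u_nm))
    p = min(1.0, math.exp(min(log_p, 0.0)) if log_p < 0 else 1.0)
    return bool(rng.random() < p), p


def run_replica_exchange(
    landscape: ToyLandscape,
    conditions: Sequence[SamplingCondition],
    n_steps: int,
    exchange_every: int = 500,
    n_swap_pairs: int = 1,
    seed: int = 0,
    stride: int = 10,
) -> pd.DataFrame:
    """Parallel Metropolis chains with periodic configuration exchanges.

    Every ``exchange_every`` steps, ``n_swap_pairs`` random adjacent pairs of
    conditions attempt a swap via :func:`replica_exchange_step`.  Emits
    pooled EnsembleTable rows (one trajectory per condition).
    """
    rng = np.random.default_rng(seed)
    e0 = landscape.energies()
    natives = landscape.natives()
    labels = landscape.config_labels()
    e_biased = [biased_energy(e0, natives, c) for c in conditions]
    n_bits = landscape.n_bits
    K = len(conditions)
    states = [0] * K
    rows = []
    chain_rngs = [np.random.default_rng([seed, k]) for k in range(K)]
    for step in range(n_steps):
        for k in range(K):
            r = chain_rngs[k]
            proposal = states[k] ^ (1 << int(r.integers(n_bits)))
            dE = e_biased[k][proposal] - e_biased[k][states[k]]
            if dE <= 0 or r.random() < math.exp(-dE / conditions[k].T):
                states[k] = proposal
            if step % stride == 0:
                s = states[k]
                rows.append(
                    (
                        conditions[k].condition_id,
                        f"{conditions[k].condition_id}-chain",
                        step,
                        float(e0[s]),
                        float(natives[s]),
                        labels[s],
                    )
                )
        if exchange_every and step > 0 and step % exchange_every == 0:
            for _ in range(n_swap_pairs):
                a = int(rng.integers(K - 1))
                b = a + 1
                sa, sb = states[a], states[b]
                ok, _ = replica_exchange_step(
                    e0[sa], natives[sa], e0[sb], natives[sb],
                    conditions[a], conditions[b], rng,
                )
                if ok:
                    states[a], states[b] = sb, sa
    return pd.DataFrame(
        rows,
        columns=["condition_id", "trajectory_id", "mc_step", "energy", "natives", "config"],
    )


# ---------------------------------------------------------------------------
# Toy CA structures
# ---------------------------------------------------------------------------

_STRAND_SPACING = 3.8  # A, CA-CA along a strand
_RUNG = 5.0  # A, inter-strand distance of a formed hairpin
_HAIRPIN_GAP = 30.0  # A, z offset between planted hairpins


def make_hairpin_structure(hairpin_sizes: Sequence[int]) -> NativeStructure:
    """CA trace of consecutive beta hairpins, one island per hairpin.

    Hairpin k (half-length m_k >= 2) contributes residues [o, o + 2 m_k) in
    its own z-plane: the first strand along +x at y = 0, the second folded
    back at y = 5 A.  Planes are 30 A apart, so the contact map contains
    exactly the within-hairpin islands.
    """
    coords = []
    for k, m in enumerate(hairpin_sizes):
        if m < 2:
            raise ValueError("hairpin half-length must be >= 2 (unrealizable layout)")
        z = k * _HAIRPIN_GAP
        for i in range(m):  # strand 1, left to right
            coords.append((i * _STRAND_SPACING, 0.0, z))
        for i in range(m):  # strand 2, right to left
            coords.append(((m - 1 - i) * _STRAND_SPACING, _RUNG, z))
    return NativeStructure(np.array(coords), source=f"hairpins{tuple(hairpin_sizes)}")


def _hairpin_ranges(hairpin_sizes: Sequence[int]) -> List[range]:
    out, o = [], 0
    for m in hairpin_sizes:
        out.append(range(o, o + 2 * m))
        o += 2 * m
    return out


def displace_substructure(
    structure: NativeStructure,
    decomposition: SubstructureDecomposition,
    label: str,
    scale: float,
) -> Snapshot:
    """Snapshot with one substructure's mean contact distance scaled.

    The second strand of the hairpin carrying ``label`` is moved away along
    +y until the arithmetic mean distance over the substructure's contacts
    equals ``scale`` times its native value (solved numerically); all other
    residues are untouched.
    """
    sub = next((s for s in decomposition.substructures if s.label == label), None)
    if sub is None:
        raise KeyError(f"no substructure labelled {label!r}")
    coords = structure.coords.copy()
    residues = sorted({r for pair in sub.contacts for r in pair})
    # the displaced half: residues of the hairpin's second strand (y == rung)
    strand2 = [r for r in residues if coords[r, 1] > 0]
    pairs = np.array(sorted(sub.contacts))
    target = scale * sub.d0_mean

    def mean_d(dy: float) -> float:
        c = coords.copy()
        c[strand2, 1] += dy
        d = np.linalg.norm(c[pairs[:, 0]] - c[pairs[:, 1]], axis=1)
        return float(d.mean())

    if scale < 1.0:
        raise ValueError("scale must be >= 1 (contacts cannot be closer than native)")
    if scale == 1.0:
        dy = 0.0
    else:
        hi = 10.0 * target
        dy = brentq(lambda y: mean_d(y) - target, 0.0, hi, xtol=1e-10)
    coords[strand2, 1] += dy
    return Snapshot(coords)


def plant_antiparallel_pairing(
    structure: NativeStructure,
    donor: Sequence[int],
    acceptor: Sequence[int],
    offset: float = 6.0,
) -> Snapshot:
    """Snapshot with the donor strand docked antiparallel onto the acceptor.

    Donor residue donor[k] is placed ``offset`` A above (in z) acceptor
    residue acceptor[-1-k], producing exactly the rung contacts
    (donor[k], acceptor[-1-k]); the default 6 A offset keeps diagonal
    neighbours out of a 6.5 A cutoff.
    """
    donor = list(donor)
    acceptor = list(acceptor)
    if len(donor) > len(acceptor):
        raise ValueError("donor strand longer than acceptor strand")
    coords = structure.coords.copy()
    for k, r in enumerate(donor):
        partner = acceptor[len(acceptor) - 1 - k]
        coords[r] = structure.coords[partner] + np.array([0.0, 0.0, offset])
    return Snapshot(coords)


def synthesize_toy_structures(
    hairpin_sizes: Sequence[int],
    decomposition: Optional[SubstructureDecomposition] = None,
    displacements: Optional[Dict[str, float]] = None,
    nonnative_pairings: Optional[Sequence[Tuple[Sequence[int], Sequence[int]]]] = None,
):
    """Native structure plus named perturbed snapshots.

    Returns ``(structure, decomposition, snapshots)`` where ``snapshots``
    maps a descriptive name to a Snapshot: ``native`` (identity),
    ``displaced_<label>`` per requested displacement, and ``nonnative_<k>``
    per planted antiparallel pairing.
    """
    from .contacts import ContactParams, decompose_structure

    structure = make_hairpin_structure(hairpin_sizes)
    if decomposition is None:
        decomposition = decompose_structure(structure, ContactParams())
    snaps: Dict[str, Snapshot] = {"native": Snapshot(structure.coords.copy())}
    for label, scale in (displacements or {}).items():
        snaps[f"displaced_{label}"] = displace_substructure(
            structure, decomposition, label, scale
        )
    for k, (donor, acceptor) in enumerate(nonnative_pairings or []):
        snaps[f"nonnative_{k}"] = plant_antiparallel_pairing(structure, donor, acceptor)
    return structure, decomposition, snaps
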