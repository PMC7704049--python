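"""Detailed-balance folding rates and master-equation occupancy dynamics.

Folding rates cannot be measured directly at temperatures where the native
state is stable, but unfolding rates extrapolated from high temperature can
be converted using detailed balance:

    k_fold(i -> j) = [P_eq(C_j) / P_eq(C_i)] * k_unfold(j -> i)

where the cluster equilibrium probabilities are sums of coarse-state
probabilities from the reweighted PMF.  For transitions whose exit is
hub-mediated (condition II), the same relation returns the inverse folding
mean-first-passage time rather than an exponential rate.  The assembled
cluster-level rate matrix is then a continuous-time Markov generator whose
master equation is solved by matrix exponential.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.linalg import expm

from .contacts import label_hamming
from .kinetics import ArrheniusFit, ClusterSet, extrapolate_rate
from .thermo import PMFTable

__all__ = [
    "KineticModel",
    "OccupancyTrace",
    "cluster_equilibrium_probability",
    "folding_rate_from_detailed_balance",
    "assemble_model",
    "allowed_transitions",
    "build_master_equation",
    "solve_master_equation",
    "stationary_distribution",
]


def cluster_equilibrium_probability(pmf: PMFTable, members: Sequence[str]) -> float:
    """Sum of coarse-state equilibrium probabilities over a cluster's members.

    Member states absent from the PMF (unobserved at this temperature)
    contribute zero, with a warning; a cluster with zero total probability is
    an error because detailed balance cannot be applied to it.
    """
    total = 0.0
    for state in members:
        p = pmf.probabilities.get(state)
        if p is None:
            warnings.warn(
                f"coarse state {state!r} unobserved at T = {pmf.T}; contributes 0",
                stacklevel=2,
            )
        else:
            total += p
    if total <= 0:
        raise ValueError(
            f"cluster {sorted(members)} has zero equilibrium probability at T = {pmf.T}"
        )
    return total


def folding_rate_from_detailed_balance(
    P_i: float, P_j: float, k_unfold: float
) -> float:
    """k_fold(i->j) = (P_j / P_i) * k_unfold(j->i).

    For condition-II (hub-mediated) transitions the result is the inverse
    folding MFPT rather than an exponential rate.
    """
    if P_i <= 0:
        raise ValueError("source cluster unsampled at this temperature")
    if P_j <= 0:
        raise ValueError("destination cluster unsampled at this temperature")
    if k_unfold < 0:
        raise ValueError("unfolding rate must be non-negative")
    return (P_j / P_i) * k_unfold


def allowed_transitions(
    clusters: ClusterSet, n_substructures: int
) -> List[Tuple[str, str]]:
    """Ordered cluster pairs connected by a single substructure change.

    Two clusters are adjacent when some member configuration of one differs
    from some member of the other by exactly one substructure (the Kronecker
    delta on the configuration Hamming distance).
    """
    names = clusters.names
    out = []
    for a in names:
        for b in names:
            if a == b:
                continue
            if any(
                label_hamming(x, y, n_substructures) == 1
                for x in clusters.members[a]
                for y in clusters.members[b]
            ):
                out.append((a, b))
    return out


@dataclass
class KineticModel:
    """Cluster-level rate model at one temperature.

    ``rates`` maps ordered (source, dest) pairs to rates in MC step^-1.
    Folding rates obtained by detailed balance satisfy
    k_fold / k_unfold = P_eq ratio exactly by construction; that identity is
    asserted when the model is assembled.
    """

    clusters: List[str]
    T: float
    rates: Dict[Tuple[str, str], float]
    P_eq: Dict[str, float]
    condition_ii: List[Tuple[str, str]] = field(default_factory=list)
    bootstrap_ln_k: Dict[Tuple[str, str], np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, k in self.rates.items():
            if k < 0:
                raise ValueError(f"negative rate for {key}")

    def verify_detailed_balance(self, atol: float = 1e-12) -> float:
        """Max relative violation of k_ij/k_ji = P_j/P_i over reversible pairs."""
        worst = 0.0
        for (i, j), kij in self.rates.items():
            kji = self.rates.get((j, i))
            if kji is None or kij == 0 or kji == 0:
                continue
            lhs = kij / kji
            rhs = self.P_eq[j] / self.P_eq[i]
            worst = max(worst, abs(lhs - rhs) / rhs)
        return worst


def assemble_model(
    pmf: PMFTable,
    fits: Dict[Tuple[str, str], ArrheniusFit],
    T: float,
    clusters: ClusterSet,
    n_substructures: int,
    unfolding_order: Optional[Dict[str, int]] = None,
    zero_transitions: Sequence[Tuple[str, str]] = (),
    condition_ii: Sequence[Tuple[str, str]] = (),
    bootstrap: Optional[Dict[Tuple[str, str], Dict[float, np.ndarray]]] = None,
) -> KineticModel:
    """Combine PMF and extrapolated unfolding rates into a full rate model.

    Every Arrhenius-fitted unfolding transition (j -> i) between clusters
    adjacent under the single-substructure rule is extrapolated to T; the
    reverse folding rate follows from detailed balance with the clusters'
    summed equilibrium probabilities.  ``zero_transitions`` lists ordered
    pairs deliberately removed (transitions whose rate the method cannot
    predict); both directions of a zeroed pair are dropped.  Condition-II
    transitions are included as single-exponential with a warning.
    """
    allowed = set(allowed_transitions(clusters, n_substructures))
    zeroed = set(zero_transitions) | {(b, a) for a, b in zero_transitions}
    P = {
        name: cluster_equilibrium_probability(pmf, clusters.members[name])
        for name in clusters.names
    }
    rates: Dict[Tuple[str, str], float] = {}
    cond_ii = list(condition_ii)
    for (src, dst), fit in fits.items():
        if (src, dst) not in allowed or (src, dst) in zeroed:
            continue
        k_unf = extrapolate_rate(fit, T)
        rates[(src, dst)] = k_unf
        rates[(dst, src)] = folding_rate_from_detailed_balance(P[dst], P[src], k_unf)
        if (src, dst) in cond_ii or (dst, src) in cond_ii:
            warnings.warn(
                f"transition {src}->{dst} is hub-mediated (condition II); its "
                "single-exponential treatment in the master equation is an "
                "approximation",
                stacklevel=2,
            )
    model = KineticModel(
        clusters=clusters.names,
        T=T,
        rates=rates,
        P_eq=P,
        condition_ii=cond_ii,
        bootstrap_ln_k={
            key: arrs.get(T, np.array([]))
            for key, arrs in (bootstrap or {}).items()
        },
    )
    violation = model.verify_detailed_balance()
    if violation > 1e-10:
        raise AssertionError(
            f"detailed-balance identity violated (relative error {violation:.2e})"
        )
    return model


def build_master_equation(model: KineticModel) -> Tuple[np.ndarray, List[str]]:
    """Continuous-time generator M for the cluster master equation.

    Column order follows ``model.clusters``; M[i, j] = k_{j->i} for i != j,
    diagonals make every column sum to zero exactly.
    """
    names = model.clusters
    n = len(names)
    idx = {c: i for i, c in enumerate(names)}
    M = np.zeros((n, n))
    for (src, dst), k in model.rates.items():
        if k < 0:
            raise ValueError(f"negative rate for {(src, dst)}")
        M[idx[dst], idx[src]] += k
    M[np.diag_indices(n)] -= M.sum(axis=0)
    return M, names


@dataclass
class OccupancyTrace:
    """Master-equation solution P_t(C_i) on a time grid."""

    times: np.ndarray  # MC steps
    clusters: List[str]
    P: np.ndarray  # (n_times, n_clusters)
    P0: np.ndarray

    def occupancy(self, cluster: str) -> np.ndarray:
        return self.P[:, self.clusters.index(cluster)]


def solve_master_equation(
    M: np.ndarray,
    P0: Sequence[float],
    times: Sequence[float],
    clusters: Optional[List[str]] = None,
) -> OccupancyTrace:
    """P(t) = exp(M t) P0 on the supplied grid (scaling-and-squaring expm)."""
    P0 = np.asarray(P0, dtype=float)
    if not np.isclose(P0.sum(), 1.0, atol=1e-10):
        raise ValueError("initial distribution must sum to 1")
    times = np.asarray(times, dtype=float)
    out = np.empty((len(times), len(P0)))
    for i, t in enumerate(times):
        out[i] = expm(M * t) @ P0
    names = clusters or [str(i) for i in range(len(P0))]
    return OccupancyTrace(times=times, clusters=names, P=out, P0=P0)


def stationary_distribution(M: np.ndarray) -> np.ndarray:
    """Null-space stationary vector of a generator, normalized to sum 1."""
    w, v = np.linalg.eig(M)
    i = int(np.argmin(np.abs(w)))
    p = np.real(v[:, i])
    p = np.abs(p)
    return p / p.sum()


def log_time_grid(dt: float, horizon: float, n: int = 60) -> np.ndarray:
    """Log-spaced time grid from one snapshot interval to a horizon."""
    if horizon <= dt:
        raise ValueError("horizon must exceed dt")
    return np.concatenate([[0.0], np.geomspace(dt, horizon, n)])
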