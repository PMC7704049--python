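"""From raw unfolding trajectories to extrapolated transition rates.

Pipeline stages (each a standalone operation):

1. rare-configuration filtering -- configurations carrying less than a
   fraction ``s`` of all snapshots are reassigned to their most similar
   temporal neighbour;
2. HMM denoising -- a fixed-emission hidden Markov model (probability
   ``1 - m`` that the observed configuration is the true one) is decoded by
   Viterbi to suppress transient misassignments;
3. kinetic clustering -- configurations in fast mutual exchange (pairwise
   kinetic distance below a threshold T_A) are merged into clusters;
4. rate estimation -- per-temperature cluster transition rates from
   consecutive-snapshot counts via the embedded-chain correction;
5. Arrhenius fitting and extrapolation -- ln k against 1/T (only
   temperatures with at least ``min_events`` observed transitions), giving
   the activation energy and prefactor used to extrapolate unfolding rates
   down to temperatures where the native state is stable;
6. trajectory bootstrap for error bars, performed entirely in log space.

Temperatures and energies are in simulation units with k_B = 1; times are in
MC steps.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd

from .contacts import label_hamming

__all__ = [
    "StateTrajectory",
    "ClusterSet",
    "TransitionRate",
    "ArrheniusFit",
    "SurvivalCurve",
    "filter_rare_configurations",
    "denoise_hmm",
    "kinetic_distance_matrix",
    "cluster_by_threshold",
    "map_to_clusters",
    "survival_curve",
    "estimate_transition_rates",
    "rates_by_temperature",
    "fit_arrhenius",
    "fit_all_arrhenius",
    "extrapolate_rate",
    "bootstrap_rates",
]


@dataclass(frozen=True)
class StateTrajectory:
    """A time-ordered sequence of configuration labels at fixed stride."""

    trajectory_id: str
    T: float
    dt: float  # snapshot interval, MC steps
    labels: tuple

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", tuple(self.labels))
        if self.dt <= 0:
            raise ValueError("snapshot interval dt must be positive")
        if len(self.labels) < 2:
            raise ValueError("a trajectory needs at least 2 snapshots")

    def __len__(self) -> int:
        return len(self.labels)

    def with_labels(self, labels: Sequence[str]) -> "StateTrajectory":
        return StateTrajectory(self.trajectory_id, self.T, self.dt, tuple(labels))


def _universe_size(labels) -> int:
    """Smallest substructure universe consistent with a set of labels."""
    n = 1
    for lab in labels:
        if lab in ("", "∅"):
            continue
        n = max(n, max(ord(ch) - ord("a") + 1 for ch in lab))
    return n


def filter_rare_configurations(
    trajs: Sequence[StateTrajectory],
    s: float,
    n_substructures: Optional[int] = None,
) -> List[StateTrajectory]:
    """Reassign configurations rarer than a pooled frequency ``s``.

    Each snapshot of a rare configuration is reassigned to the temporally
    preceding or following *retained* configuration in its trajectory,
    whichever is closer in Hamming distance (ties go to the preceding one).
    Applied iteratively until every retained configuration has pooled
    frequency >= s.  ``s = 0`` is the identity.
    """
    if not 0 <= s < 1:
        raise ValueError("s must be in [0, 1)")
    if s == 0:
        return list(trajs)
    all_labels = [lab for t in trajs for lab in t.labels]
    n_sub = n_substructures or _universe_size(all_labels)
    seqs = [list(t.labels) for t in trajs]
    total = sum(len(q) for q in seqs)
    while True:
        counts = Counter(lab for q in seqs for lab in q)
        rare = {lab for lab, c in counts.items() if c / total < s}
        if not rare:
            break
        retained = set(counts) - rare
        if len(retained) < 2:
            raise ValueError(
                f"s = {s} leaves fewer than 2 configurations; lower it"
            )
        for q in seqs:
            new = list(q)
            for idx, lab in enumerate(q):
                if lab not in rare:
                    continue
                prev_lab = next(
                    (q[k] for k in range(idx - 1, -1, -1) if q[k] in retained), None
                )
                next_lab = next(
                    (q[k] for k in range(idx + 1, len(q)) if q[k] in retained), None
                )
                if prev_lab is None and next_lab is None:
                    continue  # trajectory entirely rare; retry next iteration
                if prev_lab is None:
                    new[idx] = next_lab
                elif next_lab is None:
                    new[idx] = prev_lab
                else:
                    d_prev = label_hamming(lab, prev_lab, n_sub)
                    d_next = label_hamming(lab, next_lab, n_sub)
                    new[idx] = prev_lab if d_prev <= d_next else next_lab
            q[:] = new
    return [t.with_labels(q) for t, q in zip(trajs, seqs)]


def denoise_hmm(
    trajs: Sequence[StateTrajectory],
    m: float,
    pseudocount: float = 0.5,
) -> List[StateTrajectory]:
    """Viterbi-decode trajectories under a fixed-emission HMM.

    Hidden states are the observed configurations.  The emission matrix puts
    probability ``1 - m`` on correct classification and spreads ``m``
    uniformly over the other observed configurations.  The transition matrix
    is a single-pass maximum-likelihood estimate from the pooled raw
    sequences (bigram counts plus a pseudocount per cell, rows normalized);
    no iterative re-estimation is performed.  ``m = 0`` is the identity.
    """
    if not 0 <= m < 1:
        raise ValueError("m must be in [0, 1)")
    if not trajs:
        raise ValueError("need at least one trajectory")
    states = sorted({lab for t in trajs for lab in t.labels})
    K = len(states)
    if K == 1 or m == 0:
        return list(trajs)
    index = {s: i for i, s in enumerate(states)}

    counts = np.full((K, K), pseudocount)
    start = np.full(K, pseudocount)
    for t in trajs:
        seq = [index[lab] for lab in t.labels]
        start[seq[0]] += 1
        for a, b in zip(seq[:-1], seq[1:]):
            counts[a, b] += 1
    logA = np.log(counts / counts.sum(axis=1, keepdims=True))
    logpi = np.log(start / start.sum())
    logB = np.full((K, K), np.log(m / (K - 1)))
    np.fill_diagonal(logB, np.log(1 - m))

    out = []
    for t in trajs:
        obs = [index[lab] for lab in t.labels]
        n = len(obs)
        delta = np.empty((n, K))
        psi = np.empty((n, K), dtype=int)
        delta[0] = logpi + logB[:, obs[0]]
        idx_k = np.arange(K)
        for step in range(1, n):
            scores = delta[step - 1][:, None] + logA  # (K_prev, K_cur)
            best = scores.max(axis=0)
            # tie-break: prefer the self-transition (stability), else the
            # lexicographically smallest predecessor (np.argmax returns the
            # first maximum)
            arg = np.argmax(scores, axis=0)
            self_tied = np.abs(scores[idx_k, idx_k] - best) <= 1e-12
            arg = np.where(self_tied, idx_k, arg)
            psi[step] = arg
            delta[step] = best + logB[:, obs[step]]
        path = np.empty(n, dtype=int)
        path[-1] = int(np.argmax(delta[-1]))
        for step in range(n - 2, -1, -1):
            path[step] = psi[step + 1][path[step + 1]]
        out.append(t.with_labels([states[i] for i in path]))
    return out


def kinetic_distance_matrix(trajs: Sequence[StateTrajectory]) -> pd.DataFrame:
    """Pairwise kinetic distances between observed configurations.

    For each unordered pair {x, y}, passage times are collected from every
    maximal trajectory segment whose labels stay within {x, y}: the time (in
    MC steps) from the first snapshot in one member of the pair to the first
    subsequent snapshot in the other.  Passages interrupted by third states
    are excluded by construction; segments with no arrival contribute
    nothing.  The distance is the mean of all collected passage times in
    either direction, pooled over trajectories and temperatures; pairs with
    no observed passage get +inf.  The diagonal is 0.
    """
    states = sorted({lab for t in trajs for lab in t.labels})
    mat = pd.DataFrame(np.inf, index=states, columns=states)
    np.fill_diagonal(mat.values, 0.0)
    for a_i, x in enumerate(states):
        for y in states[a_i + 1:]:
            times: List[float] = []
            for t in trajs:
                labs = t.labels
                n = len(labs)
                seg_start = None
                for k in range(n + 1):
                    inside = k < n and labs[k] in (x, y)
                    if inside and seg_start is None:
                        seg_start = k
                    if not inside and seg_start is not None:
                        seg = labs[seg_start:k]
                        times.extend(_segment_passages(seg, x, y, t.dt))
                        seg_start = None
            if times:
                mat.loc[x, y] = mat.loc[y, x] = float(np.mean(times))
    return mat


def _segment_passages(seg, x: str, y: str, dt: float) -> List[float]:
    """First-passage times x->y and y->x within one {x, y}-only segment."""
    out = []
    for src, dst in ((x, y), (y, x)):
        try:
            i0 = next(i for i, lab in enumerate(seg) if lab == src)
        except StopIteration:
            continue
        try:
            i1 = next(i for i in range(i0 + 1, len(seg)) if seg[i] == dst)
        except StopIteration:
            continue
        out.append((i1 - i0) * dt)
    return out


@dataclass(frozen=True)
class ClusterSet:
    """Partition of configuration labels into kinetic clusters."""

    members: Dict[str, frozenset]  # cluster name -> configuration labels
    T_A: float
    distance_matrix: Optional[pd.DataFrame] = None

    @classmethod
    def from_components(cls, comps, T_A, matrix=None) -> "ClusterSet":
        members = {}
        for comp in comps:
            name = "+".join(sorted(comp))
            members[name] = frozenset(comp)
        return cls(members=members, T_A=T_A, distance_matrix=matrix)

    @classmethod
    def singletons(cls, labels) -> "ClusterSet":
        return cls.from_components([{lab} for lab in labels], T_A=0.0)

    def cluster_of(self, label: str) -> str:
        for name, labs in self.members.items():
            if label in labs:
                return name
        raise KeyError(f"configuration {label!r} not in any cluster")

    @property
    def names(self) -> List[str]:
        return sorted(self.members)


def cluster_by_threshold(matrix: pd.DataFrame, T_A: float) -> ClusterSet:
    """Connected components of the adjacency graph T^K < T_A."""
    if T_A <= 0:
        raise ValueError("T_A must be positive")
    states = list(matrix.index)
    g = nx.Graph()
    g.add_nodes_from(states)
    for i, x in enumerate(states):
        for y in states[i + 1:]:
            if matrix.loc[x, y] < T_A:
                g.add_edge(x, y)
    return ClusterSet.from_components(nx.connected_components(g), T_A, matrix)


def map_to_clusters(
    trajs: Sequence[StateTrajectory], clusters: ClusterSet
) -> List[StateTrajectory]:
    """Replace configuration labels by their cluster names."""
    lookup = {lab: name for name, labs in clusters.members.items() for lab in labs}
    return [t.with_labels([lookup[lab] for lab in t.labels]) for t in trajs]


@dataclass
class SurvivalCurve:
    """Empirical survival of a cluster after entry, with exponential fit."""

    cluster: str
    T: float
    times: np.ndarray  # MC steps
    survival: np.ndarray
    rate: float  # single-exponential fit, MC step^-1
    residual: float  # RMS deviation of the fit from the empirical curve
    n_entries: int


def survival_curve(
    trajs: Sequence[StateTrajectory],
    cluster: str,
    T: float,
    clusters: Optional[ClusterSet] = None,
) -> SurvivalCurve:
    """Survival probability of a cluster at temperature T.

    Entry events are transitions into the cluster from a different cluster
    (occupancy at trajectory start is not an entry).  Dwell times run until
    the first excursion out; entries still inside the cluster at trajectory
    end are right-censored.  The curve is computed only on the window
    tau_traj - max(first entry time) over trajectories that enter, so every
    reported time point is observable by all contributing trajectories.  A
    least-squares single-exponential fit of the curve provides a Markovianity
    diagnostic: clusters with hidden internal structure show visibly
    multi-exponential decay and a large fit residual.
    """
    use = [t for t in trajs if t.T == T]
    if clusters is not None:
        use = map_to_clusters(use, clusters)
    dwells = []  # (dwell_steps, censored)
    first_entries = []
    dt = None
    traj_len = 0
    for t in use:
        dt = t.dt
        traj_len = max(traj_len, len(t))
        labs = t.labels
        entered_at = None
        saw_entry = False
        for k in range(1, len(labs)):
            if labs[k] == cluster and labs[k - 1] != cluster:
                entered_at = k
                if not saw_entry:
                    first_entries.append(k)
                    saw_entry = True
            elif entered_at is not None and labs[k] != cluster:
                dwells.append((k - entered_at, False))
                entered_at = None
        if entered_at is not None:
            dwells.append((len(labs) - entered_at, True))
    if not dwells:
        raise ValueError(f"no entry events into cluster {cluster!r} at T = {T}")
    window = traj_len - max(first_entries)  # snapshots
    n_grid = max(2, window)
    grid = np.arange(n_grid)
    surv = np.empty(n_grid)
    n_at_risk = np.empty(n_grid)
    dwell_arr = np.array([d for d, _ in dwells])
    cens_arr = np.array([c for _, c in dwells])
    for i, g in enumerate(grid):
        at_risk = (dwell_arr >= g) | (~cens_arr)
        alive = dwell_arr > g
        denom = at_risk.sum()
        n_at_risk[i] = denom
        surv[i] = alive[at_risk].sum() / denom if denom else np.nan
    surv[0] = 1.0
    times = grid * (dt or 1.0)

    # single-exponential fit of log-survival, weighted by the number of
    # entries still at risk so the noisy tail does not dominate
    pos = (surv > 0) & (n_at_risk > 0)
    if pos.sum() >= 2 and times[pos].max() > 0:
        slope = np.polyfit(
            times[pos], np.log(surv[pos]), 1, w=np.sqrt(n_at_risk[pos])
        )[0]
        rate = max(0.0, -slope)
    else:
        rate = 0.0
    fit = np.exp(-rate * times)
    residual = float(np.sqrt(np.nanmean((fit - surv) ** 2)))
    return SurvivalCurve(cluster, T, times, surv, rate, residual, len(dwells))


@dataclass(frozen=True)
class TransitionRate:
    """One cluster-to-cluster rate at one temperature."""

    source: str
    dest: str
    T: float
    k: float  # MC step^-1
    n_trans: int  # Z_{Cj->Ci}
    n_occ: int  # Z_{Cj}


def estimate_transition_rates(
    trajs: Sequence[StateTrajectory],
    clusters: Optional[ClusterSet] = None,
    T: Optional[float] = None,
) -> List[TransitionRate]:
    """Cluster transition rates from consecutive-snapshot counts.

    P(C_i | C_j) = Z_{j->i} / Z_j over consecutive snapshot pairs; the rate
    applies the embedded-chain correction

        k_{j->i} = (1/dt) * log(1 / (1 - p_out)) * P(C_i|C_j) / p_out,

    with p_out the total per-interval exit probability, which removes the
    bias from multiple exits competing within one snapshot interval.
    Returned for every ordered pair with at least one observed transition;
    sources with no exits contribute k = 0 rates for no pairs.
    """
    use = [t for t in trajs if T is None or t.T == T]
    if clusters is not None:
        use = map_to_clusters(use, clusters)
    if not use:
        raise ValueError("no trajectories at the requested temperature")
    dt = use[0].dt
    trans: Counter = Counter()
    occ: Counter = Counter()
    for t in use:
        labs = t.labels
        for lab in labs:
            occ[lab] += 1
        for a, b in zip(labs[:-1], labs[1:]):
            if a != b:
                trans[(a, b)] += 1
    out: List[TransitionRate] = []
    temp = T if T is not None else use[0].T
    for j in sorted(occ):
        exits = {i: c for (a, i), c in trans.items() if a == j}
        if not exits:
            continue
        p_out = sum(exits.values()) / occ[j]
        if p_out >= 1:
            raise ValueError(
                f"every occupancy of {j!r} exits within one interval; "
                "dt too coarse for this system"
            )
        factor = math.log(1.0 / (1.0 - p_out)) / (dt * p_out)
        for i, c in sorted(exits.items()):
            p_i = c / occ[j]
            out.append(TransitionRate(j, i, temp, factor * p_i, c, occ[j]))
    return out


def rates_by_temperature(
    trajs: Sequence[StateTrajectory], clusters: Optional[ClusterSet] = None
) -> pd.DataFrame:
    """All transition rates at every temperature present, as a tidy table."""
    rows = []
    for T in sorted({t.T for t in trajs}):
        for r in estimate_transition_rates(trajs, clusters, T):
            rows.append((r.source, r.dest, r.T, r.k, r.n_trans, r.n_occ))
    return pd.DataFrame(
        rows, columns=["source", "dest", "T", "k", "n_trans", "n_occ"]
    )


@dataclass
class ArrheniusFit:
    """Least-squares Arrhenius parameters for one transition.

    ln k(T) = ln_k0 - dE / T  (k_B = 1); ``points`` holds the fitted
    (1/T, ln k, n_events) triples, ``excluded`` the temperatures dropped by
    the minimum-event rule.
    """

    source: str
    dest: str
    ln_k0: float
    dE: float  # activation energy, simulation energy units
    points: List[Tuple[float, float, int]]
    cov: np.ndarray  # 2x2 covariance of (slope, intercept)
    excluded: List[float] = field(default_factory=list)


def fit_arrhenius(
    rates: Sequence[TransitionRate], min_events: int = 5
) -> ArrheniusFit:
    """Fit ln k against 1/T for one transition across temperatures.

    Temperatures with fewer than ``min_events`` observed transitions are
    excluded (too noisy); at least two eligible temperatures are required.
    """
    srcs = {(r.source, r.dest) for r in rates}
    if len(srcs) != 1:
        raise ValueError("fit_arrhenius expects rates for a single transition")
    (src, dst), = srcs
    eligible = [r for r in rates if r.n_trans >= min_events and r.k > 0]
    excluded = sorted({r.T for r in rates} - {r.T for r in eligible})
    if len(eligible) < 2:
        raise ValueError(
            f"insufficient temperatures for extrapolation of {src}->{dst}: "
            f"{len(eligible)} eligible (need >= 2)"
        )
    x = np.array([1.0 / r.T for r in eligible])
    y = np.array([math.log(r.k) for r in eligible])
    if len(eligible) == 2:
        slope = (y[1] - y[0]) / (x[1] - x[0])
        intercept = y[0] - slope * x[0]
        cov = np.full((2, 2), np.nan)
    else:
        (slope, intercept), cov = np.polyfit(x, y, 1, cov=True)
    points = [(float(xi), float(yi), r.n_trans) for xi, yi, r in zip(x, y, eligible)]
    return ArrheniusFit(src, dst, float(intercept), float(-slope), points, cov, excluded)


def fit_all_arrhenius(
    rate_table: pd.DataFrame, min_events: int = 5
) -> Dict[Tuple[str, str], ArrheniusFit]:
    """Arrhenius fits for every transition with enough eligible temperatures."""
    fits = {}
    for (src, dst), grp in rate_table.groupby(["source", "dest"]):
        rates = [
            TransitionRate(src, dst, row.T, row.k, int(row.n_trans), int(row.n_occ))
            for row in grp.itertuples()
        ]
        try:
            fits[(src, dst)] = fit_arrhenius(rates, min_events)
        except ValueError:
            continue
    return fits


def extrapolate_rate(fit: ArrheniusFit, T_target: float) -> float:
    """k(T) = exp(ln k0 - dE / T)."""
    return math.exp(fit.ln_k0 - fit.dE / T_target)


def bootstrap_rates(
    trajs: Sequence[StateTrajectory],
    clusters: Optional[ClusterSet],
    T_targets: Sequence[float],
    B: int = 1000,
    seed: int = 0,
    min_events: int = 5,
) -> Dict[Tuple[str, str], Dict[float, np.ndarray]]:
    """Trajectory bootstrap of extrapolated rates, in log space.

    At each temperature the original number of trajectories is resampled
    with replacement; rates are recomputed, Arrhenius refit, and
    re-extrapolated to every target temperature.  Returns, per transition
    and target temperature, the array of bootstrap ln k values; iterations
    in which the transition is absent are recorded as NaN and should be
    omitted from summaries.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    use = map_to_clusters(trajs, clusters) if clusters is not None else list(trajs)
    temps = sorted({t.T for t in use})
    by_temp = {T: [t for t in use if t.T == T] for T in temps}
    names = sorted({lab for t in use for lab in t.labels})
    idx = {n: i for i, n in enumerate(names)}
    K = len(names)
    dt = use[0].dt

    # per-trajectory sufficient statistics: transition-count matrix + occupancy
    stats = {
        T: [
            _count_stats(t.labels, idx, K) for t in group
        ]
        for T, group in by_temp.items()
    }

    master = np.random.default_rng(seed)
    child_seeds = master.integers(0, 2**31 - 1, size=B)
    results: Dict[Tuple[str, str], Dict[float, List[float]]] = {}
    for b in range(B):
        rng = np.random.default_rng(child_seeds[b])
        rate_rows = []
        for T in temps:
            group = stats[T]
            pick = rng.integers(0, len(group), size=len(group))
            trans = sum(group[i][0] for i in pick)
            occ = sum(group[i][1] for i in pick)
            rate_rows.extend(_rates_from_counts(trans, occ, names, T, dt))
        table = pd.DataFrame(
            rate_rows, columns=["source", "dest", "T", "k", "n_trans", "n_occ"]
        )
        fits = fit_all_arrhenius(table, min_events)
        for key, fit in fits.items():
            store = results.setdefault(key, {Tt: [] for Tt in T_targets})
            for Tt in T_targets:
                store[Tt].append(fit.ln_k0 - fit.dE / Tt)
        for key in results:
            if key not in fits:
                for Tt in T_targets:
                    results[key][Tt].append(np.nan)
    # pad transitions first seen late
    out: Dict[Tuple[str, str], Dict[float, np.ndarray]] = {}
    for key, store in results.items():
        out[key] = {
            Tt: np.pad(
                np.asarray(vals, dtype=float),
                (B - len(vals), 0),
                constant_values=np.nan,
            )
            for Tt, vals in store.items()
        }
    return out


def _count_stats(labels, idx, K):
    trans = np.zeros((K, K), dtype=np.int64)
    occ = np.zeros(K, dtype=np.int64)
    prev = None
    for lab in labels:
        i = idx[lab]
        occ[i] += 1
        if prev is not None and prev != i:
            trans[prev, i] += 1
        prev = i
    return trans, occ


def _rates_from_counts(trans, occ, names, T, dt):
    rows = []
    for j in range(len(names)):
        if occ[j] == 0:
            continue
        total = trans[j].sum()
        if total == 0:
            continue
        p_out = total / occ[j]
        if p_out >= 1:
            raise ValueError("dt too coarse for resampled data")
        factor = math.log(1.0 / (1.0 - p_out)) / (dt * p_out)
        for i in range(len(names)):
            if trans[j, i] > 0:
                p_i = trans[j, i] / occ[j]
                rows.append(
                    (names[j], names[i], T, factor * p_i, int(trans[j, i]), int(occ[j]))
                )
    return rows
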