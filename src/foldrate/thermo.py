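"""Multistate reweighting of biased equilibrium ensembles.

Simulations are run on a grid of conditions (temperature T, umbrella setpoint
S, bias strength k_bias); every snapshot carries its unbiased energy E0 and
native-contact count N.  The biased energy is

    E = E0 + 1/2 * k_bias * (N - S)^2

and the reduced potential of snapshot n under condition k is u_k(n) = E_k(n) /
T_k (k_B = 1 throughout).  The multistate reweighting equations (MBAR) are
solved for the dimensionless per-condition free energies, after which
normalized snapshot weights can be evaluated at any target condition --
typically unbiased (k_bias = 0) conditions at the temperatures of interest.
From the weights follow coarse-state equilibrium probabilities and PMFs
(F = -log P_eq), thermal averages such as the melting curve, and a
melting-temperature estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp

__all__ = [
    "SamplingCondition",
    "EnsembleTable",
    "EquilibriumWeights",
    "PMFTable",
    "biased_energy",
    "solve_reweighting",
    "coarse_state_pmf",
    "thermal_average_curve",
    "estimate_melting_temperature",
]


@dataclass(frozen=True)
class SamplingCondition:
    """One point of the sampling grid: (T, S, k_bias) plus an identifier."""

    T: float
    S: float = 0.0
    k_bias: float = 0.0
    condition_id: str = ""

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError("temperature must be positive")
        if self.k_bias < 0:
            raise ValueError("k_bias must be >= 0")


def biased_energy(E0, N, cond: SamplingCondition):
    """Umbrella-modified energy E0 + 1/2 k_bias (N - S)^2 (vectorized)."""
    E0 = np.asarray(E0, dtype=float)
    N = np.asarray(N, dtype=float)
    return E0 + 0.5 * cond.k_bias * (N - cond.S) ** 2


@dataclass
class EnsembleTable:
    """Per-snapshot records across the condition grid.

    ``rows`` columns: condition_id, trajectory_id, mc_step, energy, natives,
    config.  ``burn_in`` is the fraction of each trajectory's steps discarded
    from the front before analysis (equilibration window).
    """

    rows: pd.DataFrame
    conditions: Dict[str, SamplingCondition]
    burn_in: float = 0.125

    REQUIRED = ("condition_id", "trajectory_id", "mc_step", "energy", "natives", "config")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.rows.columns]
        if missing:
            raise ValueError(f"EnsembleTable rows missing columns: {missing}")
        unknown = set(self.rows["condition_id"]) - set(self.conditions)
        if unknown:
            raise ValueError(f"rows reference unknown condition ids: {sorted(unknown)}")
        if not 0 <= self.burn_in < 1:
            raise ValueError("burn_in must be in [0, 1)")

    def equilibrated(self) -> pd.DataFrame:
        """Rows surviving the burn-in window, per trajectory."""
        if self.burn_in == 0:
            return self.rows.reset_index(drop=True)
        def _tail(g: pd.DataFrame) -> pd.DataFrame:
            lo = g["mc_step"].min()
            hi = g["mc_step"].max()
            cut = lo + self.burn_in * (hi - lo)
            return g[g["mc_step"] >= cut]
        out = (
            self.rows.groupby(["condition_id", "trajectory_id"], group_keys=False, sort=False)
            [list(self.rows.columns)]
            .apply(_tail)
        )
        return out.reset_index(drop=True)


@dataclass
class EquilibriumWeights:
    """Solved reweighting state.

    ``f`` maps condition id -> dimensionless free energy (first condition
    anchored at 0); ``log_denominator`` is log sum_k N_k exp(f_k - u_k(n))
    per snapshot; ``weights`` maps each requested target condition id to its
    normalized per-snapshot weight vector.  ``snapshots`` is the equilibrated
    row table the weights index into.
    """

    f: Dict[str, float]
    weights: Dict[str, np.ndarray]
    target_conditions: Dict[str, SamplingCondition]
    snapshots: pd.DataFrame
    log_denominator: np.ndarray
    residual: float

    def weights_at(self, cond: SamplingCondition) -> np.ndarray:
        """Normalized snapshot weights at an arbitrary target condition."""
        u = _reduced_potential(self.snapshots, cond)
        logw = -u - self.log_denominator
        logw -= logsumexp(logw)
        return np.exp(logw)


def _reduced_potential(rows: pd.DataFrame, cond: SamplingCondition) -> np.ndarray:
    e = biased_energy(rows["energy"].to_numpy(), rows["natives"].to_numpy(), cond)
    return e / cond.T


def _check_overlap(rows: pd.DataFrame, conditions: Sequence[SamplingCondition]) -> None:
    """Reject condition grids whose sampled native-contact ranges form
    disconnected groups (no reweighting information can flow between them)."""
    ids = [c.condition_id for c in conditions]
    ranges = {}
    for cid in ids:
        n = rows.loc[rows["condition_id"] == cid, "natives"]
        ranges[cid] = (n.min(), n.max())
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(ids)
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            lo = max(ranges[a][0], ranges[b][0])
            hi = min(ranges[a][1], ranges[b][1])
            if lo <= hi:
                g.add_edge(a, b)
    comps = list(nx.connected_components(g))
    if len(comps) > 1:
        raise ValueError(
            "sampling conditions do not overlap; disconnected groups: "
            + "; ".join(",".join(sorted(c)) for c in comps)
        )


def solve_reweighting(
    table: EnsembleTable,
    targets: Optional[Sequence[SamplingCondition]] = None,
    tol: float = 1e-12,
    max_iter: int = 2000,
) -> EquilibriumWeights:
    """Solve the multistate reweighting self-consistency equations.

    Minimizes the standard convex objective in the per-condition
    dimensionless free energies f_k,

        phi(f) = (1/n) sum_n log sum_k N_k exp(f_k - u_k(n)) - sum_k (N_k/n) f_k,

    whose stationary point satisfies the MBAR equations.  Returns normalized
    snapshot weights at each requested target condition.
    """
    rows = table.equilibrated()
    if len(rows) == 0:
        raise ValueError("no snapshots survive the burn-in window")
    sampled = [table.conditions[cid] for cid in sorted(table.conditions)]
    counts = rows["condition_id"].value_counts()
    sampled = [c for c in sampled if counts.get(c.condition_id, 0) > 0]
    if len(sampled) > 1:
        _check_overlap(rows, sampled)

    n_total = len(rows)
    K = len(sampled)
    u = np.stack([_reduced_potential(rows, c) for c in sampled])  # (K, n)
    N_k = np.array([counts[c.condition_id] for c in sampled], dtype=float)
    logN = np.log(N_k)

    if K == 1:
        f_hat = np.zeros(1)
        log_denom = logN[0] - u[0]
    else:
        def objective(theta: np.ndarray):
            f = np.concatenate([[0.0], theta])
            a = logN[:, None] + f[:, None] - u  # (K, n)
            ld = logsumexp(a, axis=0)
            val = ld.mean() - float((N_k / n_total) @ f)
            w = np.exp(a - ld[None, :])  # (K, n) mixture responsibilities
            grad_full = w.mean(axis=1) - N_k / n_total
            return val, grad_full[1:]

        res = minimize(
            objective,
            x0=np.zeros(K - 1),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": max_iter, "ftol": 1e-15, "gtol": tol},
        )
        f_hat = np.concatenate([[0.0], res.x])
        # self-consistency residual: f_k + log sum_n exp(-u_kn - log_denom)
        a = logN[:, None] + f_hat[:, None] - u
        log_denom = logsumexp(a, axis=0)
        resid_vec = f_hat + logsumexp(-u - log_denom[None, :], axis=1)
        resid_vec -= resid_vec[0]
        residual = float(np.max(np.abs(resid_vec)))
        if residual > 1e-6:
            raise RuntimeError(
                f"reweighting did not converge: self-consistency residual {residual:.2e}"
            )

    if K == 1:
        residual = 0.0

    f_map = {c.condition_id: float(f_hat[i] - f_hat[0]) for i, c in enumerate(sampled)}
    result = EquilibriumWeights(
        f=f_map,
        weights={},
        target_conditions={},
        snapshots=rows,
        log_denominator=log_denom,
        residual=residual,
    )
    for t in (targets or []):
        result.weights[t.condition_id] = result.weights_at(t)
        result.target_conditions[t.condition_id] = t
    return result


@dataclass
class PMFTable:
    """Coarse-state equilibrium probabilities and dimensionless free energies
    F = -log P_eq at one target temperature, with bootstrap uncertainties."""

    T: float
    probabilities: Dict[str, float]
    free_energies: Dict[str, float]
    errors: Dict[str, float] = field(default_factory=dict)

    def p_eq(self, state: str) -> float:
        return self.probabilities.get(state, 0.0)


def coarse_state_pmf(
    weights: EquilibriumWeights,
    target: SamplingCondition,
    n_bootstrap: int = 200,
    seed: int = 0,
    state_column: str = "config",
) -> PMFTable:
    """Coarse-state PMF at an (unbiased) target condition.

    P_eq of a coarse state is the summed weight of the snapshots assigned to
    it; F = -log P_eq.  Uncertainties come from a trajectory-level block
    bootstrap: trajectories are resampled with replacement and the state
    probabilities recomputed with the solved mixture denominator held fixed.
    Unobserved states get no entry.
    """
    rows = weights.snapshots
    w = weights.weights.get(target.condition_id)
    if w is None:
        w = weights.weights_at(target)
    labels = rows[state_column].to_numpy()
    states = sorted(set(labels))
    probs = {s: float(w[labels == s].sum()) for s in states}
    probs = {s: p for s, p in probs.items() if p > 0}
    total = sum(probs.values())
    probs = {s: p / total for s, p in probs.items()}
    fes = {s: float(-np.log(p)) for s, p in probs.items()}

    errors: Dict[str, float] = {}
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        traj_keys = rows["trajectory_id"].astype(str) + "|" + rows["condition_id"].astype(str)
        uniq = np.array(sorted(traj_keys.unique()))
        key_arr = traj_keys.to_numpy()
        u = _reduced_potential(rows, target)
        logw_un = -u - weights.log_denominator
        boot = {s: [] for s in probs}
        for _ in range(n_bootstrap):
            chosen = rng.choice(uniq, size=len(uniq), replace=True)
            idx = np.concatenate([np.flatnonzero(key_arr == k) for k in chosen])
            lw = logw_un[idx]
            lw = lw - logsumexp(lw)
            wb = np.exp(lw)
            lab = labels[idx]
            for s in probs:
                p = wb[lab == s].sum()
                boot[s].append(-np.log(p) if p > 0 else np.nan)
        for s in probs:
            vals = np.array(boot[s], dtype=float)
            vals = vals[np.isfinite(vals)]
            errors[s] = float(vals.std(ddof=1)) if len(vals) > 1 else np.nan
    return PMFTable(T=target.T, probabilities=probs, free_energies=fes, errors=errors)


def thermal_average_curve(
    weights: EquilibriumWeights,
    observable,
    T_grid: Sequence[float],
    k_bias: float = 0.0,
) -> pd.DataFrame:
    """Thermal average <X>(T) of a per-snapshot observable on a temperature
    grid, each point reweighted to the unbiased condition at that T.

    ``observable`` is either a column name of the snapshot table or a
    callable mapping the snapshot DataFrame to a per-row vector.  With
    X = fraction of native contacts this is the melting curve.
    """
    rows = weights.snapshots
    if callable(observable):
        x = np.asarray(observable(rows), dtype=float)
    else:
        x = rows[observable].to_numpy(dtype=float)
    if len(x) != len(rows):
        raise ValueError("observable must yield one value per snapshot")
    out = []
    for T in T_grid:
        cond = SamplingCondition(T=float(T), S=0.0, k_bias=k_bias, condition_id=f"target@{T}")
        w = weights.weights_at(cond)
        out.append((float(T), float((w * x).sum())))
    return pd.DataFrame(out, columns=["T", "mean"])


def estimate_melting_temperature(curve: pd.DataFrame, n_plateau: int = 3) -> float:
    """Midpoint crossing of a melting curve.

    The low-T and high-T plateaus are the means of the ``n_plateau`` extreme
    grid points each; T_M is where the curve crosses halfway between them,
    located by monotone linear interpolation on the bracketing segment.
    """
    c = curve.sort_values("T").reset_index(drop=True)
    T = c["T"].to_numpy(dtype=float)
    y = c["mean"].to_numpy(dtype=float)
    if len(T) < 2 * n_plateau:
        raise ValueError("curve too short to define plateaus")
    lo_plateau = y[:n_plateau].mean()
    hi_plateau = y[-n_plateau:].mean()
    if lo_plateau <= hi_plateau:
        raise ValueError(
            "transition not bracketed: the curve does not decrease with "
            "temperature (no cooperative melting in range)"
        )
    mid = 0.5 * (lo_plateau + hi_plateau)
    dy = y - mid
    sign = np.sign(dy)
    crossings = np.flatnonzero(sign[:-1] * sign[1:] < 0)
    exact = np.flatnonzero(sign == 0)
    if len(exact):
        return float(T[exact[0]])
    if len(crossings) == 0:
        raise ValueError("transition not bracketed by the temperature grid")
    i = crossings[0]
    frac = dy[i] / (dy[i] - dy[i + 1])
    return float(T[i] + frac * (T[i + 1] - T[i]))
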