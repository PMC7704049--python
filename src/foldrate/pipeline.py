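"""End-to-end analysis: ensembles + unfolding trajectories -> folding model.

Stages: configuration-labelled inputs are reweighted to coarse-state PMFs at
the target temperature; unfolding trajectories are rare-filtered, HMM
denoised, kinetically clustered, converted to per-temperature transition
rates, Arrhenius-fitted and extrapolated; folding rates follow from detailed
balance and the cluster master equation is solved for occupancy dynamics.
Every stage's tabular output is written as TSV next to a run manifest.
"""

from __future__ import annotations

import math
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import assembly, kinetics, thermo
from .config import AnalysisConfig
from .io import RunManifest, read_conditions, read_ensemble, read_trajectories
from .kinetics import ClusterSet, StateTrajectory

__all__ = ["PipelineResult", "run_pipeline", "analyze_trajectories"]


@dataclass
class PipelineResult:
    pmf: thermo.PMFTable
    clusters: ClusterSet
    rate_table: pd.DataFrame
    fits: Dict[Tuple[str, str], kinetics.ArrheniusFit]
    model: assembly.KineticModel
    occupancy: assembly.OccupancyTrace
    bootstrap: Dict[Tuple[str, str], Dict[float, np.ndarray]] = field(default_factory=dict)
    survival: List[kinetics.SurvivalCurve] = field(default_factory=list)
    warnings: List[str] = field(default_factory=list)


def analyze_trajectories(
    trajs: Sequence[StateTrajectory],
    cfg: AnalysisConfig,
    n_substructures: Optional[int] = None,
) -> Tuple[List[StateTrajectory], ClusterSet]:
    """Rare-configuration filter + HMM denoising + kinetic clustering."""
    filtered = kinetics.filter_rare_configurations(trajs, cfg.s, n_substructures)
    denoised = kinetics.denoise_hmm(filtered, cfg.m)
    matrix = kinetics.kinetic_distance_matrix(denoised)
    clusters = kinetics.cluster_by_threshold(matrix, cfg.T_A)
    return denoised, clusters


def run_pipeline(
    cfg: AnalysisConfig,
    ensemble_path,
    conditions_path,
    trajectories_path,
    out_dir,
    target_T: Optional[float] = None,
    n_substructures: Optional[int] = None,
    p0_cluster: Optional[str] = None,
    t_max: Optional[float] = None,
) -> PipelineResult:
    """Run the full analysis from files on disk and write all outputs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(command="pipeline", config=cfg.to_dict())
    for p in (ensemble_path, conditions_path, trajectories_path):
        manifest.add_input(p)
    caught: List[str] = []
    try:
        result = _run(
            cfg, ensemble_path, conditions_path, trajectories_path, out,
            target_T, n_substructures, p0_cluster, t_max, manifest, caught,
        )
    except Exception as exc:
        manifest.warnings.append(f"aborted: {exc}")
        manifest.write(out / "manifest.json")
        raise
    manifest.warnings.extend(caught)
    manifest.write(out / "manifest.json")
    return result


def _run(
    cfg, ensemble_path, conditions_path, trajectories_path, out,
    target_T, n_substructures, p0_cluster, t_max, manifest, caught,
) -> PipelineResult:
    t0 = time.time()
    conditions = read_conditions(conditions_path)
    table = read_ensemble(ensemble_path, conditions, burn_in=cfg.burn_in)
    trajs = read_trajectories(trajectories_path)
    if not trajs:
        raise ValueError("empty trajectory input")
    T = target_T if target_T is not None else cfg.target_T
    if T is None:
        raise ValueError("target temperature required (config target_T or argument)")
    manifest.timings["read"] = time.time() - t0

    # step 2: thermodynamics
    t0 = time.time()
    target = thermo.SamplingCondition(T=T, S=0.0, k_bias=0.0, condition_id="target")
    weights = thermo.solve_reweighting(table, targets=[target])
    pmf = thermo.coarse_state_pmf(
        weights, target, n_bootstrap=cfg.pmf_bootstrap, seed=cfg.seed
    )
    manifest.timings["thermodynamics"] = time.time() - t0

    # step 4: unfolding kinetics
    t0 = time.time()
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        denoised, clusters = analyze_trajectories(trajs, cfg, n_substructures)
        if cfg.s > 0:
            _warn_if_pathway_erased(trajs, denoised, caught)
        rate_table = kinetics.rates_by_temperature(denoised, clusters)
        caught.extend(str(w.message) for w in wlist)
    survival = []
    for name in clusters.names:
        for temp in sorted({t.T for t in denoised}):
            try:
                survival.append(kinetics.survival_curve(denoised, name, temp, clusters))
            except ValueError:
                continue
    manifest.timings["kinetics"] = time.time() - t0

    # step 5: Arrhenius + bootstrap
    t0 = time.time()
    fits = kinetics.fit_all_arrhenius(rate_table, cfg.min_events)
    boot = kinetics.bootstrap_rates(
        denoised, clusters, T_targets=[T], B=cfg.bootstrap,
        seed=cfg.seed, min_events=cfg.min_events,
    )
    manifest.timings["arrhenius"] = time.time() - t0

    # step 6: detailed balance + master equation
    t0 = time.time()
    n_sub = n_substructures or _infer_universe(trajs)
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        model = assembly.assemble_model(
            pmf, fits, T, clusters, n_sub,
            zero_transitions=cfg.zero_transitions,
            condition_ii=cfg.condition_ii,
            bootstrap=boot,
        )
        caught.extend(str(w.message) for w in wlist)
    M, names = assembly.build_master_equation(model)
    start = p0_cluster or min(
        clusters.names, key=lambda n: min(len(x.replace("∅", "")) for x in clusters.members[n])
    )
    P0 = np.zeros(len(names))
    P0[names.index(start)] = 1.0
    dt = trajs[0].dt
    horizon = t_max or dt * 1e6
    grid = assembly.log_time_grid(dt, horizon)
    occupancy = assembly.solve_master_equation(M, P0, grid, names)
    manifest.timings["assembly"] = time.time() - t0

    _write_outputs(out, pmf, clusters, rate_table, fits, model, occupancy, cfg)
    if cfg.make_plots:
        _write_plots(out, pmf, rate_table, fits, survival, occupancy)
    return PipelineResult(
        pmf=pmf, clusters=clusters, rate_table=rate_table, fits=fits,
        model=model, occupancy=occupancy, bootstrap=boot,
        survival=survival, warnings=caught,
    )


def _infer_universe(trajs) -> int:
    from .kinetics import _universe_size

    return _universe_size([lab for t in trajs for lab in t.labels])


def _warn_if_pathway_erased(raw, filtered, caught: List[str]) -> None:
    before = {lab for t in raw for lab in t.labels}
    after = {lab for t in filtered for lab in t.labels}
    erased = before - after
    if erased:
        caught.append(
            f"rare-configuration filter erased {sorted(erased)}; if any belongs "
            "to a dominant pathway, lower s"
        )


def _write_outputs(out, pmf, clusters, rate_table, fits, model, occupancy, cfg) -> None:
    pd.DataFrame(
        [
            (s, pmf.probabilities[s], pmf.free_energies[s], pmf.errors.get(s, np.nan))
            for s in sorted(pmf.probabilities)
        ],
        columns=["config", "P_eq", "F", "F_err"],
    ).to_csv(out / "pmf.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(name, ",".join(sorted(m))) for name, m in sorted(clusters.members.items())],
        columns=["cluster", "members"],
    ).to_csv(out / "clusters.tsv", sep="\t", index=False)
    rate_table.rename(
        columns={"source": "from", "dest": "to", "n_trans": "Z_trans", "n_occ": "Z_occ"}
    ).to_csv(out / "rates.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            (f.source, f.dest, f.ln_k0, f.dE, len(f.points), ",".join(f"{t:g}" for t in f.excluded))
            for f in fits.values()
        ],
        columns=["from", "to", "ln_k0", "dE_activation", "n_points", "excluded_T"],
    ).to_csv(out / "arrhenius.tsv", sep="\t", index=False)
    rows = []
    for (src, dst), k in sorted(model.rates.items()):
        lo = hi = np.nan
        arr = model.bootstrap_ln_k.get((src, dst))
        if arr is not None and np.isfinite(arr).sum() > 1:
            ok = arr[np.isfinite(arr)]
            sd = ok.std(ddof=1)
            lo, hi = math.exp(np.mean(ok) - sd), math.exp(np.mean(ok) + sd)
        direction = "unfold" if (src, dst) in model.bootstrap_ln_k else "fold"
        rows.append((src, dst, direction, k, lo, hi))
    pd.DataFrame(
        rows, columns=["from_cluster", "to_cluster", "direction", "rate", "lo", "hi"]
    ).to_csv(out / "model.tsv", sep="\t", index=False)
    occ_rows = [
        (t, c, occupancy.P[i, j])
        for i, t in enumerate(occupancy.times)
        for j, c in enumerate(occupancy.clusters)
    ]
    pd.DataFrame(occ_rows, columns=["time", "cluster", "probability"]).to_csv(
        out / "occupancy.tsv", sep="\t", index=False
    )


def _write_plots(out, pmf, rate_table, fits, survival, occupancy) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots()
    for s, F in sorted(pmf.free_energies.items()):
        x = 0 if s == "∅" else len(s)
        ax.errorbar([x], [F], yerr=[pmf.errors.get(s, 0.0)], fmt="o", color="C0")
        ax.annotate(s, (x, F), textcoords="offset points", xytext=(4, 4))
    ax.set_xlabel("formed substructures")
    ax.set_ylabel("F = -log P_eq")
    fig.savefig(out / "pmf.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots()
    for (src, dst), fit in fits.items():
        x = [p[0] for p in fit.points]
        y = [p[1] for p in fit.points]
        (line,) = ax.plot(x, y, "o", label=f"{src}→{dst}")
        xs = np.linspace(min(x), max(x), 20)
        ax.plot(xs, fit.ln_k0 - fit.dE * xs, "-", color=line.get_color())
    ax.set_xlabel("1 / T")
    ax.set_ylabel("ln k")
    ax.legend(fontsize=7)
    fig.savefig(out / "arrhenius.png", dpi=120)
    plt.close(fig)

    if survival:
        fig, ax = plt.subplots()
        for sc in survival:
            ax.plot(sc.times, sc.survival, ".-", label=f"{sc.cluster} T={sc.T:g}", alpha=0.6)
        ax.set_xlabel("MC steps")
        ax.set_ylabel("survival probability")
        ax.set_yscale("log")
        ax.legend(fontsize=6)
        fig.savefig(out / "survival.png", dpi=120)
        plt.close(fig)

    fig, ax = plt.subplots()
    for j, c in enumerate(occupancy.clusters):
        ax.plot(occupancy.times, occupancy.P[:, j], label=c)
    ax.set_xscale("log")
    ax.set_xlabel("MC steps")
    ax.set_ylabel("occupancy")
    ax.legend(fontsize=7)
    fig.savefig(out / "occupancy.png", dpi=120)
    plt.close(fig)
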