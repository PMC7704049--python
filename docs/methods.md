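# Methods

`foldrate` infers protein folding pathways and transition rates without ever
simulating folding directly.  It combines two kinds of simulation output that
*are* tractable — biased equilibrium sampling around physiological
temperatures, and unfolding trajectories at high temperature — through the
principle of detailed balance.  This note records the model, the estimators,
the numerical choices, and what the built-in synthetic benchmarks do and do
not demonstrate.

## Coarse-graining the folding landscape

The native CA contact map (pairs with distance < `d_c`, sequence separation
≥ `min_sep`) is decomposed into **substructures**: islands of contacts of at
least `c` members, connected by Manhattan hops of at most `h` on the
half-map (i < j).  Islands are labelled `a, b, c, …` by ascending minimum
residue index; contacts in no surviving island are retained as
"unassigned" but play no role downstream.  Substructures are expected to
form and break cooperatively, because the first contacts of an island
require closing a loop whose entropic cost is only repaid as the remaining
contacts zip up.

A snapshot's **topological configuration** is the subset of substructures
formed: substructure *s* is formed when the mean CA distance over its
contacts satisfies ⟨d⟩ ≤ f·⟨d₀⟩, with ⟨d₀⟩ the same mean in the native
structure.  ⟨d⟩ is the arithmetic mean (the natural reading of "average
distance"; geometric alternatives differ negligibly at f ≈ 1.7).  A
**coarse state** S_i collects every microstate — including ones with
nonnative contacts — consistent with configuration *i*.

Default parameters follow the beta-sheet presets: `d_c` = 6.5 Å /
`min_sep` = 3 for the substructure map, 6 Å / `min_sep` = 8 for the native
contact *count* used as the umbrella coordinate, `c` = 7, `h` = 5,
`f` = 1.7.  Larger `d_c` and `f` values suit helical proteins whose contacts
run through side chains.  Predictions are insensitive to `f` within roughly
[1.6, 1.8]; far outside that window the substructure-formed calls (and hence
the clusters) change qualitatively.

## Equilibrium thermodynamics

Equilibrium ensembles are generated under a grid of conditions
(T, S, k_bias) with the umbrella energy E = E⁰ + ½·k_bias·(N − S)², N being
the native-contact count (`k_bias` = 0.02 simulation units is the
production default).  All conditions are pooled and reweighted with the
multistate reweighting (MBAR) equations over reduced potentials
u_k(x) = E_k(x)/T_k (k_B ≡ 1).  The solver minimizes the standard convex
objective in the per-condition dimensionless free energies with an
analytic gradient (L-BFGS-B, log-sum-exp throughout, first condition
anchored at zero) and verifies the self-consistency residual (< 1e−6)
before use.  The implementation is validated against exact partition sums
on enumerable toy landscapes.

From the solved weights follow, at any unbiased target temperature:
coarse-state probabilities P_eq and the dimensionless PMF F = −log P_eq;
thermal averages ⟨X⟩(T), in particular the melting curve with X = fraction
of native contacts; and the melting temperature T_M, defined here
operationally as the midpoint crossing between the low-T and high-T
plateaus (means of the three extreme grid points each, monotone linear
interpolation on the bracketing segment).  Curves that do not decrease with
temperature raise an error rather than return a meaningless midpoint.

Statistical uncertainty on PMF entries comes from a trajectory-level block
bootstrap (200 resamples by default) with the solved mixture denominator
held fixed — an assumption-light substitute for asymptotic covariance
formulas that is also what the equilibrium-probability errors downstream
would need anyway.  Analysis uses only steps past a burn-in window
(default: the final 87.5% of each trajectory is kept), and a convergence
report (sliding-window mean energy, RMS deviation of N from the setpoint)
is available as an advisory diagnostic.

Replica-exchange swaps in the toy sampler use the exact extended-ensemble
Metropolis ratio for exchanging configurations between two conditions.
This choice preserves every condition's marginal distribution exactly —
the property the enumeration-oracle tests check — and reduces to the
familiar parallel-tempering acceptance exp[(1/T′ − 1/T)(E_m⁰ − E_n⁰)] when
the umbrella terms vanish.

## Unfolding kinetics

Unfolding trajectories (no bias, no exchange) at several temperatures above
T_M are converted to configuration sequences and processed in five steps:

1. **Rare-configuration filter** (`s`, default 0): configurations carrying
   less than a pooled fraction `s` of snapshots are reassigned, snapshot by
   snapshot, to the nearer (Hamming) of the preceding/following retained
   configuration in that trajectory; ties go to the preceding one
   (preserves entry-time causality).  Applied iteratively until all
   retained configurations clear the threshold.  `s` must stay below the
   prevalence of any configuration on a dominant pathway — the pipeline
   warns when the filter erases a configuration entirely.
2. **HMM denoising** (`m`, default 0.1): hidden states are the observed
   configurations; emissions put probability 1 − m on correct
   classification, m spread uniformly over the others; the transition
   matrix is a single-pass count estimate from the pooled raw sequences
   (pseudocount 0.5 per cell) — no Baum–Welch iteration.  Viterbi decoding
   with ties broken toward the self-transition, then the smallest label.
   Decoding corrects isolated misassignments but cannot distinguish a
   genuine one-snapshot excursion from noise; this removes a small fraction
   of real transitions and biases rates slightly low (visible as ≈ 0.1
   log10 in the end-to-end benchmark, well inside its tolerance).
3. **Kinetic clustering**: the kinetic distance between configurations i, j
   is the mean first-passage time between them pooled over all segments of
   all trajectories whose labels stay within {i, j} (passages interrupted
   by third states are excluded by construction; each segment contributes
   at most one passage per direction, timed from the first snapshot in the
   source member).  Configurations with distance below `T_A` are merged
   into clusters (connected components).  `T_A` must sit inside a clear
   timescale gap; for the synthetic linear networks, which plant no fast
   pairs, any `T_A` below the fastest genuine exchange yields singleton
   clusters.
4. **Rates**: with P(C_i|C_j) = Z_{j→i}/Z_j from consecutive snapshot
   pairs, the rate applies the embedded-chain correction
   k_{j→i} = (1/Δt)·log(1/(1−p_out))·P(C_i|C_j)/p_out, which reduces to
   Z_{j→i}/(Z_j·Δt) when p_out ≪ 1.  Transitions completing and reversing
   within one Δt are invisible — an inherent resolution limit, which is why
   the benchmarks keep k·Δt ≲ 0.2.
5. **Arrhenius extrapolation**: ln k against 1/T by ordinary least squares,
   slope −ΔE‡ and intercept ln k₀, using only temperatures with at least
   `min_events` = 5 observed transitions; at least two eligible
   temperatures are required.  Extrapolated unfolding rates at target
   temperature T are exp(ln k₀ − ΔE‡/T).

**Survival diagnostics.**  For each cluster and temperature, an empirical
survival curve is built over entry events (transitions into the cluster;
occupancy at trajectory start is not an entry), right-censored at
trajectory end and truncated to the window every contributing trajectory
can observe.  A single-exponential fit (log-linear least squares weighted
by the number at risk) provides the Markovianity check: clusters whose exit
is gated by a hidden sub-state ("hub") show multi-exponential decay and a
visibly larger fit residual.  For such transitions the rate estimator above
still returns a good approximation to the inverse mean first-passage time,
which is the quantity detailed balance needs; the master equation then
treats the transition as single-exponential, a documented approximation.

**Bootstrap errors.**  At each temperature the original number of
trajectories is resampled with replacement; rates are recomputed from the
resampled sufficient statistics, Arrhenius refit, and re-extrapolated.  The
whole analysis runs in log space, so the reported intervals
exp(mean ± SD of ln k) are symmetric on a log scale.  Iterations in which a
transition is absent are recorded as missing and omitted from its summary.
PMF uncertainty is deliberately *not* propagated into folding-rate error
bars; they reflect kinetic sampling noise only.

## Detailed balance and the master equation

For clusters i (less folded) and j (more folded) in a model whose allowed
transitions connect configurations differing by exactly one substructure:

    k_fold(i→j) = [P_eq(C_j) / P_eq(C_i)] · k_unfold(j→i),

with cluster probabilities summed over member coarse states.  The identity
k_fold/k_unfold = P_eq ratio holds to machine precision by construction and
is asserted on every assembled model.  Transitions the method cannot
predict (neither Markovian nor hub-mediated) are removed explicitly via the
configuration's `zero_transitions` list; nothing is zeroed silently.

The cluster generator M (off-diagonal k_{j→i}, diagonals the negative
column sums, columns summing to zero exactly) is propagated as
P(t) = exp(Mt)·P₀ by scaling-and-squaring matrix exponential on a
log-spaced grid; the implementation is held to the eigendecomposition
oracle at 1e−8 on well-conditioned problems, conserves probability to
1e−10, and relaxes to the Boltzmann stationary vector.

## Nonnative-state analysis

Snapshot contacts absent from the native map, and (by default) at Manhattan
distance ≥ 2 from every native contact so register-shifted native pairs are
not miscalled, form per-snapshot nonnative maps.  A per-cluster `relaxed`
flag disables the buffer for clusters where near-native mispairings are
themselves the object of interest; the flag is configuration-driven because
that judgement cannot be automated.  Maps are clustered into recurrent
classes (adjacent when the symmetric difference of contact sets is below
10), and each class's frequency-averaged map is thresholded at 10% before
island detection with `c` = 7, `h` = 3.  The sampling temperature window
for equilibrium nonnative maps is a configuration parameter (default
0.80–0.90 T_M).

## Synthetic benchmarks: what they emulate, and what they don't

The generators are first-class, tested code and define the study
conditions:

* `SyntheticNetwork` — a reversible CTMC over configurations with exact
  Arrhenius unfolding laws and free energies G(T) = E − T·S_conf, so
  folding rates follow from detailed balance *by construction*.  The
  default linear 4-substructure network uses ΔE = ΔS = 3 per formed
  substructure (T_M = 1), unfolding prefactors of 1.2–2.5 × 10⁻⁶ and
  activation energies 2.5–3.5, giving dwell times of order 10⁷ MC steps at
  the simulated temperatures 1.15–1.55 T_M with Δt = 5×10⁵ — trajectory
  lengths of 10⁸ steps (200 snapshots) match a realistic unfolding-run
  budget.  Exact Gillespie simulation discretized at Δt; optional uniform
  misassignment noise; per-trajectory RNG streams derived from
  (seed, trajectory index).  An optional hub/trap split of one state
  (exchange rates 2×10⁻⁷ / 5×10⁻⁸, hub occupancy 0.2) plants
  condition-II-style multi-exponential exits with a closed-form true
  inverse MFPT, π_hub·k_exit.
* `ToyLandscape` — binary contact units with per-bit energies, cooperative
  group bonuses, and a single-flip move graph; everything is enumerable,
  so Boltzmann probabilities, free energies and thermal averages are exact
  oracles for the sampler and the reweighting solver.  The 64-microstate
  default (6 bits, two 3-bit substructures, bonuses −2 and −2.5) is sampled
  at 3 temperatures × 4 setpoints with k_bias = 0.4 for 2×10⁵ steps per
  condition.
* Toy structures — multi-hairpin CA traces (strand spacing 3.8 Å, rung
  5 Å, hairpins 30 Å apart) whose contact maps contain exactly the planted
  islands; perturbations scale a substructure's ⟨d⟩ by an exact factor
  (solved numerically) or dock a strand antiparallel onto another at 6 Å,
  which plants precisely the rung contacts.

Because the generative model embodies the same kinetic assumptions the
analysis makes, end-to-end recovery tests are well-posed parameter-recovery
exercises — they validate the estimators and the plumbing, not the physics.
They say nothing about force-field accuracy, about whether real proteins'
coarse states are Markovian, or about the adequacy of the Arrhenius form
for a particular system; those must be checked per protein with the
survival and Arrhenius-linearity diagnostics.  Sampling noise levels, on
the other hand, are realistic for the stated budgets, and the benchmark
tolerances (e.g. 0.3 log10 units on recovered folding rates at 0.8 T_M
from 100 trajectories × 5 temperatures) reflect them.

## Numerical choices and degenerate inputs

* Strict inequality d < d_c for contacts; 0-based contiguous residue
  indexing after PDB parsing (insertion codes and gaps renumbered).
* Reweighting requires overlapping sampled native-contact ranges; solver
  failure or disconnected condition groups raise with diagnostics rather
  than returning garbage.  Unobserved coarse states get no PMF entry, and
  detailed balance refuses clusters with zero equilibrium probability.
* Rates are reported only for ordered pairs with ≥ 1 observed transition;
  a source whose every occupancy exits within one interval is an error
  ("Δt too coarse").
* More than 26 islands exhausts the single-letter label space and raises.
* All tabular I/O is TSV with headers; re-running any stage with identical
  inputs and seeds is byte-identical.

## Known limitations

* Rates are in Monte-Carlo units; only relative rates are meaningful
  unless calibrated externally.
* The Δt-resolution blind spot and the HMM's erasure of one-snapshot
  excursions both bias rates mildly downward at high temperature.
* Condition-II transitions are propagated as single-exponential in the
  master equation.
* The unfolding pathway is assumed to be the reverse of the folding
  pathway over the extrapolation range.
* One reweighting backend, 1-D umbrella coordinate, no 2-D PMFs.
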