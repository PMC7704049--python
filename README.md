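# foldrate

Folding pathways and rates for proteins whose folding is too slow to
simulate directly.

Many proteins — especially large, misfolding-prone ones — take so long to
fold in atomistic Monte-Carlo or MD simulation that a direct folding run is
hopeless.  Two other kinds of simulation *are* affordable: equilibrium
sampling with umbrella biasing and replica exchange (which yields free
energies of intermediates at physiological temperatures), and unfolding
runs at high temperature (which yield unfolding rates).  `foldrate` joins
the two through detailed balance: for coarse states *i* (less folded) and
*j* (more folded),

```
k_fold(i→j) = [P_eq(C_j) / P_eq(C_i)] · k_unfold(j→i)
```

where the equilibrium probabilities come from multistate (MBAR) reweighting
of the biased ensembles and the unfolding rate is extrapolated down in
temperature with the Arrhenius law k(T) = k₀·exp(−ΔE‡/k_B T).  The
resulting cluster-level rate matrix is propagated with the master equation
dP_t/dt = M·P_t to predict how the populations of folding intermediates
evolve.

The coarse states themselves are *topological configurations*: subsets of
native-contact "substructures" (islands on the CA contact map) currently
formed in a snapshot — e.g. `abcd` for fully folded, `bc` for a partially
folded intermediate, `∅` for unfolded.  Configurations in fast kinetic
exchange are merged into clusters before rates are estimated.  The package
covers the full pipeline: contact-map and substructure analysis, snapshot
assignment, MBAR reweighting and PMFs, melting curves, trajectory
denoising (rare-state filter + HMM/Viterbi), kinetic clustering, survival
diagnostics, rate estimation, Arrhenius extrapolation with trajectory
bootstrap, detailed-balance assembly, master-equation dynamics, and
recurrent nonnative-state analysis — plus synthetic generators (kinetic
networks, enumerable toy landscapes, toy structures) that provide exact
ground truth for every stage.

It is aimed at structural/computational biophysicists analyzing
Monte-Carlo folding simulations; rates are in MC-step units, so relative
rates between transitions (and between protein variants) are the meaningful
output.

## Worked example

Recover folding rates on a synthetic 4-substructure folding pathway with
known ground truth — the linear network `∅ ↔ a ↔ ab ↔ abc ↔ abcd` with
exact Arrhenius unfolding laws and prescribed free energies:

```python
import math
from foldrate import (
    linear_unfolding_network, simulate_kinetic_network,
    denoise_hmm, kinetic_distance_matrix, cluster_by_threshold,
    folding_rate_from_detailed_balance, extrapolate_rate,
)
from foldrate.kinetics import rates_by_temperature, fit_all_arrhenius

net = linear_unfolding_network()          # ∅ <-> a <-> ab <-> abc <-> abcd
T_M = net.melting_temperature()

# 100 unfolding trajectories at each of 5 temperatures above T_M,
# 200 snapshots at dt = 5e5 MC steps, with 10% misassignment noise
trajs = []
for i, T in enumerate((1.15, 1.25, 1.35, 1.45, 1.55)):
    trajs += simulate_kinetic_network(net, T, n_traj=100, n_snapshots=200,
                                      dt=5e5, seed=100 + i, noise=0.10)

denoised = denoise_hmm(trajs, m=0.1)
clusters = cluster_by_threshold(kinetic_distance_matrix(denoised), T_A=1e6)
fits = fit_all_arrhenius(rates_by_temperature(denoised, clusters), min_events=5)

T = 0.8 * T_M
p_eq = net.p_eq(T)                        # exact equilibrium probabilities
print(f"folding rates at T = {T:.2f} (= 0.8 T_M), MC step^-1")
for (src, dst), fit in sorted(fits.items()):
    if (src, dst) not in net.unfold_edges:
        continue
    k_unf = extrapolate_rate(fit, T)
    k_fold = folding_rate_from_detailed_balance(p_eq[dst], p_eq[src], k_unf)
    truth = net.folding_rate(dst, src, T)
    print(f"  {dst:>4} -> {src:<4}  predicted {k_fold:.2e}   true {truth:.2e}"
          f"   log10 error {abs(math.log10(k_fold / truth)):.2f}")
```

Output:

```
folding rates at T = 0.80 (= 0.8 T_M), MC step^-1
     ∅ -> a     predicted 9.95e-08   true 9.69e-08   log10 error 0.01
     a -> ab    predicted 9.47e-08   true 1.12e-07   log10 error 0.07
    ab -> abc   predicted 5.32e-08   true 4.00e-08   log10 error 0.12
   abc -> abcd  predicted 7.45e-08   true 9.96e-08   log10 error 0.13
```

Every folding step — a quantity never simulated directly — is recovered
within ~0.13 log10 units (a factor of 1.4) from high-temperature unfolding
data alone.  The folding direction was inferred from unfolding rates
measured at 1.15–1.55 T_M and the exact state free energies; with real
data the free energies would come from `foldrate.thermo` reweighting of
umbrella/replica-exchange ensembles instead.

## Command line

The same stages are exposed as a thin CLI:

```
foldrate contacts --pdb native.pdb --dc 6.5 --min-sep 3
foldrate substructures --map contacts.tsv -c 7 --hop 5
foldrate pmf --ensemble ensemble.tsv --conditions conditions.yaml --target-t 0.83
foldrate rates --trajs trajs.tsv --m 0.1 --ta 1e8 --out rates.tsv
foldrate arrhenius --rates rates.tsv --extrapolate-t 0.80,0.85,0.90
foldrate pipeline --ensemble ... --conditions ... --trajs ... --target-t 0.83
```

Every invocation writes a JSON manifest (input hashes, parameters,
timings) alongside its outputs.  `foldrate simulate` generates synthetic
trajectory bundles from a network specification file.

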