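# Methods

`ephysfit` fits multi-compartment, conductance-based neuron models to
current-clamp recordings by minimizing a feature-based fitness function
with the covariance matrix adaptation evolution strategy (CMA-ES), and
then asks whether the fitted parameters discriminate neuron subtypes.
This note records the models, the numerical choices, and what the
synthetic benchmarks do and do not establish.

## Biophysical model

A neuron is a tree of cylindrical compartments with an optional spherical
soma. Each compartment carries a leak conductance (`1/RM` per area),
membrane capacitance (`CM` per area), and Hodgkin–Huxley-style channels
with maximal conductance densities in S/m². Gating variables follow
`dx/dt = (x_inf − x)/τ_x`; channel current is `ḡ·Πx_i^{p_i}·(V − E)`.
Rate and steady-state functions use the five-parameter form
`(A + B·V)/(C + exp((V + D)/F))`, which expresses constants, linoids,
exponentials and Boltzmann sigmoids — the parameterization used by the
GENESIS/MOOSE channel libraries. Where the denominator has a removable
zero, the value is linearly interpolated from V ± 10 µV; this guard is
validated against 40-digit arithmetic in the tests.

Calcium, when enabled (`calYN`), is a per-compartment single-exponential
pool: `d[Ca]/dt = −([Ca] − Ca_rest)/τ_Ca + B_Ca·(−I_Ca)`, with `B_Ca`
(mM·A⁻¹·s⁻¹) folding shell volume and the Faraday constant into one
constant. Calcium-channel reversal potentials may follow the Nernst
potential of the pool (external calcium fixed at 2 mM, T = 305 K).
BK-type channels use a Hill function of [Ca] as their activation.
Explicit spines and synaptic channels are out of scope (`spineYN` must be
False).

Units are SI throughout (V, s, A, S/m², F/m², Ω·m², Ω·m; mM for
calcium). Morphology files (GENESIS `.p`, SWC) use µm and are converted
at parse time. Conductance densities are assigned per region: region 0 is
the soma, region 1 the dendrite out to a configurable path distance
(default 60 µm, measured along the tree from the soma center to the
segment midpoint), region 2 beyond. Membrane areas are `π·d²` for the
spherical soma and `π·d·L` for cylinders.

## Integration scheme

The cable equation on the tree is advanced by backward Euler with channel
conductances frozen at the current gate states. The symmetric
tree-structured system is solved exactly each step by Hines-ordered
elimination (children eliminated into parents), so arbitrary branching
morphologies cost O(n) per step. Gates then advance analytically,
`x ← x_inf + (x − x_inf)·exp(−dt/τ)`, at the freshly solved voltages, and
the calcium pool updates by the same exponential rule. The inner loop is
compiled with numba.

Defaults: `dt = 10 µs`, `record_dt = 100 µs`. The scheme is first-order
but stiffly stable; the tests verify (i) exact agreement (1e−9 V) of the
tree solve with a dense matrix solve on random passive trees, (ii) the
analytic RC charging curve within 1%, (iii) sub-0.1 mV sensitivity of
passive responses to halving dt, and (iv) spike counts of the shipped
spiking models unchanged between dt and dt/16. Spike *times* in a
first-order scheme shift slightly with dt, so sample-wise voltage
comparisons across step sizes are only meaningful for subthreshold
segments; tests are written accordingly.

## Features and fitness

Features per trace: pre- and post-injection baselines, steady-state
voltage response, rectification (sag: steady-state minus minimum
deflection, hyperpolarizing traces only), falling-curve time constant
(least-squares single-exponential from injection onset to the voltage
minimum), first-spike latency, spike count and times, per-spike width
(full width at half height, linearly interpolated) and height (peak minus
threshold), AHP depth and shape, a charging curve, and a
membrane-potential occupancy histogram.

Spike threshold is the point on the upstroke where dV/dt first exceeds 5%
of its maximum; the derivative is taken by central differences and the
maximum per spike over its upstroke (per-spike rather than per-trace,
since the defining maximum is ambiguous for mixed spike sizes). The AHP
window runs from the peak to the next upward threshold crossing, capped
at the next spike or 20 ms. AHP shape and charging curve are resampled to
20 points so traces of different durations compare point-wise. The
histogram feature is defined here as the occupancy histogram of Vm during
injection, 64 bins over [−100, +50] mV, normalized to sum 1 — the name
appears in the feature roster we reproduce without a published
definition, so this definition is a documented stand-in isolated behind
the feature interface. Undefined features (no spikes, wrong polarity) are
flagged and skipped, never zero-filled.

Each feature difference is normalized to a unitless number,
`f = |m − d| / (|m| + |d|)` (vector features: mean of point-wise
normalized differences; histograms: half the L1 distance). Absolute
values are used in the denominator because membrane potentials are
negative. Per-feature values are averaged over the traces where both
sides define the feature; per-spike features pair the first
min(n_sim, n_data) spikes.

The combined fitness is a weighted root-mean-square,
`total = sqrt(Σ w_i f_i² / N)` over the N features with positive weight.
RMS was chosen over a plain weighted sum because it reproduces all six
published striatal combined totals from the published per-feature means
to within ±0.005 (the package's worked examples, recomputed by
`scripts/acceptance.py`); a literal weighted sum does not. The published
pallidal totals agree within about 1.5–4%; the residual is consistent
with the totals being averages of per-model combined values while the
feature rows are averages of per-feature values (Jensen's inequality
makes the recombined value a slight underestimate), and two of the seven
pallidal columns therefore sit just outside a ±0.01 reproduction band.
Tabulated per-feature values are treated as already weight-scaled
(√w·f); raw features are weight-scaled inside the combination. Shipped
weight presets: striatal fits weight the AHP curve 4× and ignore
rectification and spike time; pallidal fits weight rectification 2×,
halve spike time and height, and ignore the pre-injection baseline and
latency.

## CMA-ES

The optimizer is a self-contained implementation of standard
(μ/μ_w, λ)-CMA-ES — log-decreasing recombination weights over the best
μ = ⌊λ/2⌋ candidates, cumulative step-size adaptation, rank-one plus
rank-μ covariance updates — with the published default strategy
constants. Population size defaults to 8. Parameters are affinely mapped
to the unit box by their bounds; `sigma0` defaults to 0.3 in scaled
space, a deliberately broad initial search. Out-of-box samples are
repaired by projection and charged a quadratic penalty on the repair
distance at ranking time (recombination uses the unrepaired samples, the
standard treatment). Ranking ties break by candidate index; NaN fitness
is ranked worst with a warning. Sampling draws one
`standard_normal((λ, n))` block per generation from
`default_rng((seed, generation))`, making ask/tell trajectories exactly
reproducible. Termination diagnoses: evaluation budget, covariance
condition number > 1e14, or σ·√λ_max below 1e−12. Tests pin the
per-generation mean/σ/C trajectories to an independently written
reference implementation (1e−6 relative over 20 generations) and check
the usual sphere/Rosenbrock benchmarks.

## Fit orchestration

Each generation's candidates are simulated under the recorded protocols
and scored; results are written to the storage directory (params.yaml,
fitness.yaml, optionally the trace CSVs) before being reported, keyed by
a canonical 12-significant-digit serialization of the parameter map.
Re-encountered parameter vectors — duplicates within a population or a
re-run over the same directory — are served from this cache, which also
makes interrupted runs resumable. Evaluation may fan out over a
single-machine process pool, one simulation per worker; results are
independent of the degree of parallelism. A failed simulation scores +∞
and the run continues.

Convergence follows a plateau rule on the per-generation mean fitness:
over a 25-generation window, |least-squares slope| < 0.002 per generation
and standard deviation < 0.06. The slope is taken in magnitude: a run
still improving steeply has not converged (the sign convention is
ambiguous in the source material; magnitude is the conservative reading).
For post-hoc analysis, the best-model subset is the 50 lowest-fitness
evaluations when more than 2,000 were performed, else the lowest 2.5%
(rounded up, at least one).

## Subtype analysis

Pooled best-model parameter matrices are z-scored per column (ddof 1,
mirroring SAS STDIZE). Variable selection is a stepwise linear
discriminant: forward entry by largest partial F of the Wilks' lambda
reduction with p < 0.15, backward removal at p > 0.15 (SAS STEPDISC
defaults; the thresholds were not stated in the source material). Note
the statistical behavior these thresholds imply: with several noise
columns, the best spurious candidate clears p < 0.15 in roughly half of
null datasets, so selection of *extra* columns alongside a truly
informative one is expected, and the tests assert what the procedure
guarantees — a strongly separating column is always selected, and first.
The number of clusters is chosen by Ward-linkage hierarchical clustering
scored with the Calinski–Harabasz pseudo-F over k = 2…6 (the source
procedure's criterion is unnamed; pseudo-F is the common default), and
the disjoint clustering is k-means with fixed-seed k-means++ seeding,
yielding centroids, centroid distances and a cluster × subtype confusion
matrix. On instances small enough to enumerate, the k-means inertia
equals the exhaustive optimum in the tests.

## Synthetic study conditions

Two ground-truth reference neurons (4 compartments: 16 µm spherical soma
plus three 100 µm × 4 µm dendritic segments; RM = 1 Ω·m², CM = 0.01 F/m²,
RA = 1 Ω·m) stand in for the recordings, which live in external archives:

- **spiker** (striatal-projection-like): E_leak = −80 mV; NaF (m³h), KDr
  (n²) and a slowly inactivating A-type current KA (a²b, inactivation
  τ = 50 ms). Somatic densities 3500/600/300 S/m² (dendritic 120/60,
  60/30, 100/50 proximal/distal). Silent at rest, rheobase ≈ 0.1 nA,
  first-spike latency falling from ~180 ms to ~50 ms as injection rises —
  the hallmark delayed-firing phenotype.
- **pauser** (pallidal-like): E_leak = −45 mV drives tonic ~15 Hz firing
  at zero current; adds an HVA calcium channel (Nernst reversal, feeds
  the pool) and a calcium-dependent BK current shaping the AHP; silenced
  by hyperpolarizing steps.

Recording emulation: the spiker protocol family is one hyperpolarizing
(−100 pA), one subthreshold (+80 pA) and two suprathreshold (+180, +220
pA) 400 ms steps in 500 ms traces; the pauser family is two
hyperpolarizing 1 s steps (−200, −100 pA) plus a zero-current trace.
Additive Gaussian noise (default sd 0.5 mV, a typical whole-cell noise
floor) is seeded, so every artifact is reproducible from (kind, seed).
Measurement windows derive from the protocol timing.

The standard recovery experiment frees the somatic NaF, KDr and KA
densities and RM (truth strictly inside bounds, initial values displaced
from truth), fits 50 generations × population 8 against noiseless
recordings for three seeds, and reports the median best fitness (< 0.05
in the acceptance test; observed ≈ 0.01) and median per-parameter
recovery errors (RM within 10%, spiking densities within 30%; observed
≤ ~6%). These problem sizes — 400 evaluations per seed, four 0.5 s
traces — are deliberately small compared to a real fitting campaign
(thousands of evaluations against multi-second recordings) and were
chosen so the full benchmark is a routine desk run.

What the synthetic benchmark does **not** show: real recordings carry
electrode and series-resistance artifacts, trial-to-trial variability,
channel kinetics that differ from the model family being fitted, and
morphologies far richer than four compartments. Passing recovery
demonstrates the machinery (simulator, features, fitness, optimizer) is
correct and well-coupled, not that any particular biological model class
is identifiable from current-clamp data.

## Known limitations

- Channel half-activations and time constants are not tunable parameters
  (only densities and passive properties), matching the scope of the
  reproduced workflow.
- First-order time stepping: spike times shift by O(dt); dt = 10 µs keeps
  this below one recording sample for the shipped models.
- The stepwise discriminant admits spurious variables at its default
  thresholds by construction (see above); treat selected-variable lists
  as candidates, not certificates.
- Igor binary traces, NeuroML export, explicit spines, synaptic input,
  and multi-machine scheduling are out of scope.
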