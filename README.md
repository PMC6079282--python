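# ephysfit

Automatic parameter optimization of multi-compartment, conductance-based
neuron models against current-clamp recordings — and statistical analysis
of the fitted parameters to discriminate neuron subtypes.

Building a biophysically realistic single-neuron model means choosing
dozens of maximal conductance densities whose nonlinear interactions make
hand-tuning impractical, and whose degeneracy (inward and outward
currents can compensate each other) means many parameter sets produce the
same physiology. `ephysfit` is for electrophysiologists and modelers who
have current-clamp data — voltage responses to hyperpolarizing and
depolarizing steps, or spontaneous firing — and want (1) a population of
well-fitting models rather than a single brittle one, and (2) to know
which parameters differ systematically between cell types (e.g.
arkypallidal vs. prototypical pallidal neurons, D1 vs. D2 striatal
projection neurons).

## What it does

- **Declarative models** — channel kinetics in the five-parameter rate
  form `(A + B·V)/(C + exp((V + D)/F))` with gating
  `dx/dt = (x_inf − x)/τ_x`; GENESIS `.p` or SWC morphologies;
  per-region conductance densities in S/m² (suffix `_0`/`_1`/`_2` for
  soma / proximal / distal); passive properties; optional
  single-time-constant calcium pool with Nernst calcium reversal and
  BK-type calcium-dependent channels.
- **Simulator** — backward-Euler cable integration with an exact Hines
  tree solve per step and exponential gate updates, compiled with numba.
- **Fitness** — spiking features (threshold at 5% of maximal dV/dt,
  height, full-width-at-half-height, count, times, latency, AHP depth
  and shape) and subthreshold features (baselines, steady-state
  response, sag, falling-curve τ, charging curve, Vm histogram); each
  normalized as `|m − d|/(|m| + |d|)` and combined as a weighted RMS.
- **Optimizer** — a self-contained bounded CMA-ES (ask/tell/stop,
  population 8 by default), with per-evaluation disk persistence,
  caching, resumability, parallel population evaluation, a
  plateau-based convergence detector (|slope| < 0.002 and sd < 0.06 of
  the mean fitness over 25 generations) and best-model selection (the
  2.5% best, or the 50 best past 2,000 evaluations).
- **Analysis** — standardization, Pearson correlation screens, stepwise
  discriminant variable selection, Ward + pseudo-F cluster-count choice,
  and k-means clustering with centroid distances and a confusion matrix.
- **Synthetic ground truth** — two shipped reference neurons (a silent,
  long-latency "spiker" and a tonically firing "pauser") generate
  noisy recordings from known parameters so the entire pipeline is
  testable end-to-end, including parameter-recovery experiments.

## Worked example

Generate synthetic recordings from the spiker ground truth, then recover
its somatic sodium density and membrane resistance:

```python
from ephysfit import (
    ParamDef, ParamSet, SPN_WEIGHTS, do_fit,
    make_reference_neuron, generate_recordings, reference_protocols,
)

neuron = make_reference_neuron("spiker")        # truth: NaF_0=3500, RM=1.0
data = generate_recordings(neuron, reference_protocols("spiker"),
                           noise_sd=0.0, seed=0)
params = ParamSet([
    ParamDef("NaF_0", initial=2000.0, min=200.0, max=6000.0),
    ParamDef("RM",    initial=2.0,    min=0.2,   max=4.0),
])
history = do_fit(neuron, data, params, SPN_WEIGHTS,
                 generations=20, popsize=8, seed=0, store_dir="fit-out")
best = history.best
print(f"best fitness {best.fitness:.4f}")
print({k: round(float(v), 1) for k, v in best.params.items()})
```

Output from this exact run:

```
best fitness 0.0067
{'NaF_0': 3494.7, 'RM': 1.0}
```

The best fitness is the weighted RMS of normalized feature differences
across the four traces (0 would be a perfect match; the truth parameters
score exactly 0), and the recovered sodium density is within 0.2% of the
3500 S/m² ground truth. The same loop, run from the command line:

```sh
ephysfit synth --kind spiker --seed 0 --out rec/
ephysfit fit --model model.yaml --data rec/ --params params.yaml \
             --generations 50 --popsize 8 --seed 0 --out fit-out/
ephysfit analyze --best-models best.csv --out report.json
```

## Scope

MOOSE/NEURON integration, NeuroML export, explicit spines and synaptic
channels, Igor binary traces, tunable channel kinetics (half-activations
and time constants), and multi-machine scheduling are out of scope. See
`docs/methods.md` for the model equations, numerical choices and known
limitations.
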