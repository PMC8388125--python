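# slpkinetics

Kinetic and equilibrium analysis of self-labeling protein tags (HaloTag7,
SNAP-tag, CLIP-tag) from fluorescence polarization (FP) and anisotropy
measurements.

Self-labeling tags react covalently with synthetic substrates
(chloroalkanes, benzylguanines, benzylcytosines), and the labeling rate —
spanning more than six orders of magnitude across substrates — decides
which tag/substrate pair is usable in a live-cell experiment. This
package is for biochemists and assay developers who record labeling
kinetics by stopped-flow anisotropy or plate-reader FP and need the rate
and affinity constants, with honest uncertainties, out of those traces.

## What it computes

**Mechanisms** (molar/second units throughout; `slpkinetics.mechanisms`):

* one-step labeling P + S → PS with apparent second-order constant
  k_app (closed-form integrated rate law);
* two-step labeling P + S ⇌ PS\* → PS (k₁, k₋₁, k₂) with derived
  K_d = k₋₁/k₁ and k_app = k₁k₂/(k₋₁+k₂);
* labeling followed by slow conjugate conversion (k₃);
* kinetic competition of a fluorescent probe and a dark competitor.

**Fitting** (`GlobalKineticModel` → `KineticFitResults`): global
nonlinear least squares across all concentration conditions at once,
log-scale rate parameters, multi-start, parametric Monte Carlo
confidence intervals (N = 1000, worst 5% of refits discarded), model
comparison (AICc + runs test), stopped-flow dead-time estimation, and
the log–log regression of k_app against binding affinity.

**Equilibrium** (`slpkinetics.equilibrium`): single-site FP isotherms
(with the fully-reacted-dye anchor-point trick for weak binders),
four-parameter logistic competition curves, exact depletion-corrected
I50 → K_d conversion (two-ligand one-site mass action solved to
root-finder precision; Cheng–Prusoff only as a cross-check), and
ΔG = RT ln K_d.

**Synthetic data** (`slpkinetics.synthdata`): generators that emulate the
stopped-flow, plate-reader and titration assay designs with additive
Gaussian noise and full seed determinism, used by the test suite and the
recovery studies in place of non-redistributable instrument traces.

## Worked example

Simulate a plate-reader labeling experiment (protein series at fixed
50 nM substrate) and refit it:

```python
import numpy as np
from slpkinetics import (FitSpec, GlobalKineticModel, plate_reader_design,
                         generate_kinetic_dataset)

design = plate_reader_design(
    {"kapp": 2.57e4},                       # generating truth, M^-1 s^-1
    protein_concentrations=[0.2e-6, 1e-6, 5e-6, 25e-6],
    substrate_total=50e-9, seed=3,
)
traces, truth = generate_kinetic_dataset(design)

model = GlobalKineticModel(traces, spec=FitSpec("model1", design.response))
result = model.fit(seed=0).monte_carlo_ci(n_iterations=200, seed=0)
print(result.summary())
```

which prints (exact output of the code above):

```
Global kinetic fit — mechanism model1
traces: 12   observations: 732   RSS: 0.0183139   residual SD: 0.005009
------------------------------------------------------------------------
   parameter     estimate         sd                     95% CI
        kapp        25749        231 [      25314,       26177]
     r_bound       0.2503   0.000216 [    0.24991,     0.25074]
uncertainties: Monte Carlo (190 retained fits)
```

The fitted k_app (25 749 M⁻¹ s⁻¹, 95% CI 25 314–26 177) recovers the
generating constant 25 700 M⁻¹ s⁻¹ well within its interval; `r_bound`
is the fitted FP of the fully labeled substrate (the free-dye baseline
0.05 is held fixed). For stopped-flow data fitted with the two-step
mechanism, `result.derived` additionally reports the dissociation
constant k₋₁/k₁ and the apparent second-order constant k₁k₂/(k₋₁+k₂).

A command-line interface wraps the same pipeline:

```
slpkin simulate --config design.json --out bundle/
slpkin fit --bundle bundle/ --mechanism model2 --mc-iterations 1000 --out fit/
slpkin fit-isotherm --data titration.csv --probe-total 5e-8 --out iso.json
slpkin recover --config design.json --n-seeds 20 --out recovery.tsv
```

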