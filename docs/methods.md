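# Methods

## Scope and model

`slpkinetics` analyzes the covalent labeling kinetics and equilibrium
binding of self-labeling protein tags (HaloTag7, SNAP-tag, CLIP-tag and
variants) as observed by fluorescence polarization (FP) or anisotropy.
All internal arithmetic is in molar and seconds; FP and anisotropy are
dimensionless fractions, with millipolarization (mP = 1000 × FP) accepted
and emitted only at the I/O boundary.

### Reaction mechanisms

Four mass-action mechanisms cover the regimes met in practice:

1. **One-step labeling** (`model1`): P + S → PS with apparent second-order
   rate constant k_app (M⁻¹ s⁻¹). Valid when reactant concentrations are
   far below the dissociation constant of the non-covalent encounter
   complex, so the binding site is unsaturated and the rate is linear in
   both concentrations. The integrated rate law is closed-form:
   for P₀ ≠ S₀,

   PS(t) = P₀S₀ (e^{(P₀−S₀)kt} − 1) / (P₀ e^{(P₀−S₀)kt} − S₀),

   evaluated in an overflow-safe form with the exponent kept negative and
   `expm1` for short-time precision; the equal-concentration branch
   PS(t) = ktC₀²/(1 + ktC₀) is selected when the totals differ by less
   than 1e-9 relative, avoiding catastrophic cancellation.

2. **Two-step (bind-then-react)** (`model2`): P + S ⇌ PS* → PS with k₁
   (M⁻¹ s⁻¹), k₋₁ (s⁻¹), k₂ (s⁻¹). Derived constants:
   K_d = k₋₁/k₁ and k_app = k₁k₂/(k₋₁ + k₂), the low-concentration limit
   of the mechanism (bounded above by k₁, the diffusion-limited ceiling).
   This mechanism produces the biphasic anisotropy traces seen for fast
   rhodamine substrates in stopped flow: a fast binding phase whose rate
   scales with concentration, and a slower covalent phase whose amplitude
   reflects the residual unbound fraction at the binding pre-equilibrium.

3. **Labeling with conjugate aging** (`aging`): P + S → PSa → PSb with
   k_app and a slow first-order conversion k₃ (typically 10⁻³–10⁻² s⁻¹),
   for plate-reader data with a slow second signal phase.

4. **Kinetic competition** (`competition`): two parallel irreversible
   reactions P + S → PS and P + I → PI sharing the protein, used to
   measure rate constants of non-fluorescent substrates (I) against a
   fluorescent probe (S). The competitor carries no signal.

ODE-based mechanisms are reduced to two state variables via conservation
laws and integrated with LSODA at rtol 1e-8 and atol 1e-13 applied to the
state scaled by the largest reactant total (so the tolerance means the
same thing from nM to mM inputs), with analytic Jacobians supplied — k₁
up to 10⁸ M⁻¹ s⁻¹ against nanomolar concentrations makes the system
stiff, and the analytic Jacobian keeps the BDF path cheap even for the
pathological parameter sets a multi-start optimizer visits.

Known approximation limits, verified by the property tests: the one-step
description of two-step data holds to <1% only past ~100× the complex
relaxation time 1/(k₋₁+k₂) and at concentrations a few hundredfold below
K_d; with both reactants at K_d/100 the saturation correction
k₁(P+S)/(k₋₁+k₂) is already ~2%.

### Signal model

FP = (I∥ − G·I⊥)/(I∥ + G·I⊥) with the instrument grating factor G as a
multiplicative correction on the perpendicular channel; anisotropy
r = (I∥ − G·I⊥)/(I∥ + 2G·I⊥), interconvertible via r = 2FP/(3 − FP).
A trace is projected from species concentrations by mole-fraction
weighting: signal = r_free·[S]/S_tot + r_bound·(bound)/S_tot + offset,
where the encounter complex and the covalent conjugate share r_bound
(both rotate with the protein) and fluorescence intensity changes on
binding are taken as negligible, so no intensity weighting is applied by
default (per-species weights are available for assays where brightness
does change). Instrument dead time removes (does not interpolate) early
points; a fixed mixing delay shifts the recorded clock.

## Fitting

`GlobalKineticModel.fit()` minimizes the summed squared residuals over
all traces simultaneously with `scipy.optimize.least_squares` (bounded
trust-region reflective). Rate constants are encoded as log10 values —
positivity by construction and sane conditioning across the >6 decades
the constants span; the shared bound-state response r_bound is fitted
linearly alongside, while the free-dye baseline r_free stays fixed (it is
measured separately in the real assays). An optional shared substrate
concentration scale factor absorbs dye quantification errors; it is
identifiable only when the design includes protein-limiting conditions.

Multi-start (default 5): start 1 uses heuristics (k_app from the
half-rise time under pseudo-first-order excess; the two-step start seeded
from that one-step estimate with K_d placed near the lowest assayed
concentration), the rest draw rate constants log-uniformly within bounds.
Exploratory starts run with a reduced evaluation budget (150 vs 400
function evaluations) and the winner is re-polished at full budget if an
exploratory start won; ties break to the first convergence. Default
bounds: k_app ∈ [1, 10¹⁰], k₁ ∈ [10², 10¹¹], k₋₁ ∈ [10⁻⁵, 10⁶],
k₂ ∈ [10⁻⁴, 10⁴], k₃ ∈ [10⁻⁶, 10²] (M⁻¹ s⁻¹ or s⁻¹ as appropriate).

Uncertainties: by default from the covariance s²(JᵀJ)⁻¹ with a
central-difference Jacobian at step 10⁻⁴ in log10 space — wide enough
that ODE solver noise does not masquerade as curvature in degenerate
directions, which is exactly what the identifiability diagnostic needs.
A warning flags covariance condition numbers above 10⁶ (e.g. two-step
fits with all traces far below K_d, where k₁ and k₋₁ only enter through
their ratio). The primary uncertainty route is the parametric Monte
Carlo bootstrap (`monte_carlo_ci`): simulate N replicate datasets from
the fitted model with i.i.d. Gaussian noise at each trace's residual SD,
refit each from the point estimate, discard the 5% of refits with the
highest RSS, and report per-parameter SDs and percentile 95% intervals
(derived quantities included). Defaults N = 1000, 5% discarded;
deterministic under a single integer seed fanned out to per-iteration
child seeds. The property suite checks empirical CI coverage of 90–99%
at reduced N = 200 over 200 repetitions.

Dead-time estimation fits A·e^{−kt} to a pseudo-first-order calibration
decay and returns ln(A_expected/A_fitted)/k; without the independently
known initial amplitude the offset is unidentifiable and the function
refuses. Model comparison reports the RSS ratio, the small-sample
corrected AIC difference (advisory threshold 2) and a Wald–Wolfowitz
runs test on the simpler model's residuals, which exposes the long
same-sign runs a biphasic misfit leaves.

## Equilibrium analysis

Direct titrations use the single-site hyperbola
FP = FP_min + (FP_max − FP_min)[P]/(K_d + [P]) fitted by least squares
(log10 K_d internally); an optional anchor pseudo-point — the FP of the
fully reacted dye placed at a very high nominal protein concentration —
pins the upper plateau of weak-affinity titrations and is weighted like a
real observation. Competition titrations are fitted with a 4-parameter
logistic (midpoint I50, free Hill slope, lower plateau fixable to the
free-dye FP). I50 → competitor K_d conversion solves the exact
two-ligand one-site equilibrium: free protein is the bracketed root of
P_f + S_tot·P_f/(K_dS+P_f) + I_tot·P_f/(K_dI+P_f) = P_tot on
[0, P_tot] (Brent, rtol 1e-14), and K_dI is root-found (on log K_d) so
that the bound probe fraction at I = I50 is half its no-competitor
value. All depletion effects are therefore exact; the classical
Cheng–Prusoff correction I50/(1 + [S]/K_dS) is provided only as a
cross-check and agrees in the negligible-depletion limit. Free energies:
ΔG = RT ln(K_d/1 M), default T = 310.15 K (the 37 °C assay temperature),
configurable.

## Synthetic data

The generator emulates three assay families with additive i.i.d.
Gaussian noise on the signal only (never on times or concentrations),
triplicates by default, and full determinism under a seed:

* **Stopped-flow anisotropy**: protein:substrate 1:1 at 0.125–1 μM,
  log-spaced time grid to 10 s (200 points), dead time 2 ms, anisotropy
  noise SD 0.002, r_free 0.05 / r_bound 0.20.
* **Plate-reader FP kinetics**: fixed substrate (20–50 nM) against a
  protein series (15 nM–256 μM span available), linear time grid,
  FP noise SD 0.005 (5 mP), r_free 0.05 / r_bound 0.25; competition
  layout adds a competitor series at fixed protein and probe.
* **Equilibrium titrations**: isotherms (probe 10–50 nM, protein
  0–250 μM, noise SD 2 mP, optional anchor at 5 mM–0.1 M) and
  competition curves (protein 5 μM, probe 50 nM, competitor 80 μM–10 mM,
  noise SD 3 mP) from the exact models.

The noise magnitudes are declared assumptions chosen to match the
scatter regime such assays produce, not measured instrument constants.
Not modeled: drift, photobleaching, mixing transients, fluorogenic
brightness changes, photon-count statistics. Passing recovery tests
therefore demonstrate the correctness and statistical calibration of the
pipeline under ideal Gaussian noise, not robustness to every real
instrument artifact.

Fixture bundles are plain text (CSV traces + JSON sidecars + manifest)
and round-trip losslessly, including the mP unit flag.

## Recovery experiments and problem sizes

Because raw instrument traces for the published experiments are not
redistributable, published constants serve as generating truth and
recovery of those constants validates the chain end to end
(`run_recovery`, `scripts/acceptance.py`). Reported values are medians
over 20 independently seeded datasets; the two-step stopped-flow
experiment fixes k₂ = 10 s⁻¹ and reconstructs k₁ = k_app·k₂/(k₂ −
k_app·K_d), k₋₁ = K_d·k₁ from the published (K_d, k_app) pair, so both
derived constants — not the individual rates, which trade off — are the
scored quantities. Recovery fits use 2 optimizer starts (the heuristic
start converges on these well-posed designs; the extra starts are
insurance) and the plate-reader designs use 61–121 time points per
trace, sizes chosen to resolve the fastest trace in each series.

## Known limitations

* Single-site binding only; no cooperativity, no multi-site models.
* The two-step mechanism's individual rates k₁, k₋₁ are not separable
  from data recorded entirely below K_d (flagged, not prevented).
* The exponential dead-time estimator requires an independently known
  initial amplitude.
* No diffusion-limited rate theory: k₁ near 10⁹ M⁻¹ s⁻¹ is accepted
  arithmetically, not physically vetted.
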