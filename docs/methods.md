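# Methods

This note documents the models behind each `covscreen` module, the defaults
and numerical choices, what the synthetic generators do and do not emulate,
and the known limitations.

## Plate normalization (`plate_core`)

Raw signals are rescaled affinely against on-plate controls:
`viability% = 100·(s − mean_kill)/(mean_vehicle − mean_kill)`. Being affine,
normalization preserves the within-plate ranking of signals. Two deliberate
choices:

- **No clamping before fitting.** Noise pushes wells past 100% or below 0%;
  those values are retained so curve fits see unbiased data. Clamp only at
  report time if needed.
- **Kill-floor fallback.** Plates without a kill control use 0 signal as the
  0% anchor, keeping the operation total. Toxicity normalization analogously
  anchors 100% at a maximum-lysis control when present, otherwise at the
  plate maximum of the baseline-subtracted signal (the assay protocol does
  not always include a lysis anchor, so both modes exist).
- Concentrations are stored in molar; all logs are base 10. Replicates are
  averaged after normalization, per concentration.

## Dose–response and DSS (`dose_response`)

The 4PL ("log inhibitor vs response, variable slope") model is fitted by
bounded nonlinear least squares (`scipy.optimize.curve_fit`, TRF) with three
midpoint starts at the quartiles of the log-dose range; the best RSS wins,
deterministically for a given input. Default bounds are percent-scale
(bottom ∈ [−10, 50], top ∈ [0, 120], |h| ∈ [0.2, 10], midpoint within the
data range ± 2 decades); an `auto` mode derives bottom/top bounds from the
data span for non-percent scales (anisotropy). Descending curves are
represented canonically as top ≥ bottom with a negative Hill slope; both
directions are tried and the better fit kept. Poor fits are returned flagged
`inconclusive` (convergence failure or < 4 distinct doses) rather than
raising — screening tables report such compounds as "inconclusive", and a
converged fit may still be classified that way in context (top below the
activity threshold, or midpoint beyond the top screened dose).

The AUC of the logistic is exact:
∫ y dx = bottom·Δx + (top−bottom)·[x + softplus(ln10·h·(m−x))/(h·ln10)],
evaluated with `logaddexp` so steep slopes cannot overflow. DSS1/2/3 follow
the formulas in the README; the printed formulas produce values on a 0–1
scale, reported here ×100 to match the conventional 0–100 DSS display. The
threshold crossing x₁ is found by analytic inversion of the 4PL at
response = t, clamped to the window; a is clamped to [t, 100] before the
log so DSS2 stays finite and the ordering 0 ≤ DSS3 ≤ DSS2 ≤ DSS1 ≤ 100
holds whenever a ≤ 100.

## FP binding (`fp_binding`)

Anisotropy uses the standard definition r = (I∥ − G·I⊥)/(I∥ + 2G·I⊥) with a
default G factor of 1.0 (configurable; the instrument calibration is not part
of this package's scope).

The competitive equilibrium E+P⇌EP, E+I⇌EI is solved exactly by bracketed
root finding (Brent) on free protein in [0, E_t]; the protein balance is
strictly increasing in free E, so the root is unique. Mass balance holds to
better than 1e−9 relative across the tested parameter space.

The IC50 → K_d conversion derives every intermediate from mass balance and
the probe equilibrium alone: [EP]₀ from the single-site quadratic, then at
50% displacement [EP]₅₀ = [EP]₀/2, [P]₅₀, [E]₅₀, [EI]₅₀, [I]₅₀ = IC50 −
[EI]₅₀, and finally K_d = [I]₅₀/(1 + [P]₅₀/K_D,probe + [E]₀/K_D,probe).
Cross-checked against the equilibrium solver, the conversion is exact to
machine precision at the half-displacement point; the ~0.2% residual error
in full round trips comes from approximating the (slightly non-logistic)
displacement curve with a 4PL. When IC50 ≤ [EI]₅₀ (tight binding) the
correction has no positive solution; K_d is then reported as the upper bound
IC50/denominator with a flag, and a Morrison-type tight-binding fit is out
of scope. Time-resolved affinities (covalent inhibitors tighten over hours)
are handled by running the same static conversion independently per
incubation time point; kinetic coupling belongs to `covalent_kinetics`.

## Covalent kinetics (`covalent_kinetics`)

The two-step scheme E+I ⇌ E·I → E−I is assumed irreversible (k₋₂ = 0). Each
time course is fitted with an unconstrained-plateau one-phase decay
y(t) = plateau + span·e^(−kobs·t) (flat signals return kobs = 0, flagged);
the kobs-vs-[I] hyperbola is then fitted with inverse-variance weights from
the per-dose standard errors when available. If the fitted K_i exceeds 10×
the largest probed dose, saturation is declared undetectable: K_i and k₂ are
reported unresolved and only the initial slope — the second-order constant
k₂/K_i — is returned, since that is all the data identify in the linear
regime. Time is in hours throughout. `round_second_order` reproduces the
reporting convention of kinetics summary tables: multiples of 10³ M⁻¹h⁻¹,
two significant figures at ≥ 10×10³ and one below. Under that convention
rate constants recomputed from *rounded* table inputs can differ by one unit
in the last digit from values computed from unrounded fits.

## BRET (`bret`)

The raw ratio is 515 nm emission over 410 nm emission (RLU); subtracting the
donor-only raw ratio removes bleed-through. The background is taken per
plate (per replicate group) — whether it should be per experiment instead is
configurable by how wells are grouped before `titration_points`. Saturation
fits use y = BRETmax·x/(BRET50 + x) on pooled biological repeats with
technical replicates pre-averaged; titrations without curvature (fitted
BRET50 beyond 10× the covered expression range) return only the initial
slope, flagged.

"The A/D ratio at which the BRET ratio changes most linearly" is
operationalized as: the tested plasmid ratio whose mean relative expression
is closest to BRET50/2, tie-breaking toward the lower ratio. Rationale: the
saturation curve's curvature is small well below BRET50 while signal remains
measurable; above saturation the readout no longer responds to clustering
changes. Time-course treatments reuse the same % inhibition conversion per
time point; no kinetic model is fitted to BRET traces.

## Composite score (`scoring`)

score = DSS_t²/DSS_o · tox_o/tox_t · K_d⁻¹ with K_d pinned to µM. The score
is a dimensionally heterogeneous ranking heuristic by construction; no
uncertainty propagation is attempted (inputs are point estimates). Compounds
with a zero denominator are excluded with the reason recorded by the caller.
Ranking is by descending score, ties to lower K_d, then compound id; the
default selection keeps the top 3 per chemical series (how many to advance
is a judgment call — the parameter is exposed).

## Synthetic data (`synthetic`)

Generators emulate the *statistical* structure of each assay — signal levels
anchored by controls, multiplicative noise with an additive floor
(default CV 2%, floor 0.2% of the signal scale, as typical plate-reader
behaviour), technical replicates — not the underlying cell biology
(no nanoclustering physics, trafficking, or compound transport). Passing
recovery tests therefore demonstrates correctness of the *analysis* under
the model the analysis assumes, plus robustness to measurement noise; it
does not validate the model against real cells.

Specific choices:

- Dose–response plates: vehicle 10 000, kill 500 signal units; default dose
  window 0.6–40 µM (half-log, 10 points), the typical screening range.
- FP displacement: anisotropy interpolates in the bound-probe fraction from
  the exact equilibrium solver between r_free = 0.05 and r_bound = 0.25; the
  threefold dilution series is centred automatically on the predicted IC50
  (found by root-finding), because under depletion the IC50 for a weak
  binder can exceed its K_d by nearly two orders of magnitude and a fixed
  window would miss the transition. The exact displacement curve is not a
  4PL; the fitted-midpoint approximation contributes the sub-1% round-trip
  error reported by the acceptance script.
- FP time courses: 7 doses (5–320 µM, twofold), 9 time points over 24 h
  (dense early sampling plus an overnight point), signal 0.30 → 0.20;
  "1% noise" means additive Gaussian noise with σ = 1% of the decay span.
  The default generator is exactly exponential (model-consistent); real
  re-equilibration of a displaced probe is only approximately so.
- BRET titrations: relative expression spans 0.05–4 × BRET50 (12 points),
  donor channel fixed at 10⁵ RLU, donor-only background ratio 0.08; noise on
  the acceptor channel and RFU.

Problem sizes in the acceptance script (200 simulation replicates for the
kinetics and BRET recoveries, 1000 random draws for the AUC audit) were
chosen as the smallest sizes at which the reported medians are stable to
well within the quoted tolerances.

## Limitations

- No 5PL/biphasic dose–response models, no synergy scoring, no edge-effect
  or plate-layout correction.
- No Morrison tight-binding IC50 fitting; the tight-binding branch only
  bounds K_d.
- No full progress-curve kinetics (pseudo-first-order assumed), no substrate
  competition correction.
- No spectral unmixing or luciferase-decay correction in BRET.
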