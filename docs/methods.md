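# Methods

## The transport/utilization model

The model treats peak oxygen uptake as the simultaneous solution of five
coupled relations linking six parameters (V̇a, D_L, Q̇, Hb, D_M, Vmax):

1. **Alveolar mass balance.** PAO₂ = PIO₂ − 863·(V̇O₂/1000)/V̇a with
   PIO₂ = FiO₂·(P_b − 47). This is the single-gas O₂ form; the
   respiratory-quotient correction term of the full alveolar gas equation is
   deliberately omitted (at peak exercise RER ≈ 1.1 the difference in PAO₂
   is a few mmHg and is absorbed by D_L, which is estimated against the same
   PAO₂ in the inverse stage).
2. **Lung Bohr integration.** Mixed-venous blood enters the pulmonary
   capillary and takes up O₂ along normalized transit time τ ∈ [0, 1] under
   Fick's law of diffusion, dC/dτ = D_L·(PAO₂ − P(C))/(10·Q̇), through the
   nonlinear dissociation curve. End-capillary PO₂ is equated to arterial
   PO₂ — shunt and V̇/Q̇ heterogeneity are ignored (a documented
   approximation; see *Limitations*).
3. **Fick principle.** V̇O₂ = 10·Q̇·(CaO₂ − CvO₂) (contents mL/dL, the
   factor 10 is the dL→L bridge and appears nowhere else).
4. **Muscle Bohr integration.** Arterial blood releases O₂ against a
   uniform mitochondrial pressure P_mito: dC/dτ = D_M·(P_mito − P(C))/(10·Q̇).
5. **Mitochondrial demand.** Michaelis–Menten: V̇O₂ = Vmax·P_mito/(P_mito + P50_mito).

Blood O₂ is carried as `content = 1.34·Hb·S(P) + 0.003·P` (Hüfner constant
and solubility both configurable) with the Severinghaus standard curve
S = (P³+150P)/(P³+150P+23400), P50 = 26.86 mmHg. Saturations are fractions
internally; percent only at I/O boundaries. An optional Bohr-effect shift
rescales the curve's P50 from pH (measured, or Henderson–Hasselbalch from
PaCO₂); the default pipeline uses the unshifted curve because peak-exercise
acid–base state is not modelled.

## Numerics

**Capillary integration.** The content ODE is integrated in PO₂ space via
the chain rule (dP/dτ = flux / (dC/dP)), which follows the identical
trajectory while avoiding a curve inversion per step. Classical fixed-step
RK4 with `n_integration_steps = 200` (deterministic and
grid-refinement-testable; refining 200 → 2000 steps moves end-capillary
content by < 1e-3 mL/dL across the tested (D, Q̇, gradient) grid). Explicit
RK4 is unstable where the local rate constant k = D/(10·Q̇·dC/dP) gives
k·h ≫ 1 — the near-equilibrated, flat-curve region at large D — so each
fixed step is subdivided until k·h ≲ 0.4, with k bounded using the flattest
curve slope reachable within the step (the high-PO₂ end of the
entry/driving range). Without this safeguard the integrator produces
arbitrary end values at the diffusion search bracket's upper end.

**Inverse stage.** D_L and D_M are found by bisection on log₁₀D over
[0.05, 5000] mL/min/mmHg (the end PO₂ is monotone in D), to 1e-4 mmHg on
the end-capillary PO₂. D_M is matched on venous PO₂; since measured blood
points are held curve-consistent, this is equivalent to matching venous
content. Degenerate records (no arteriovenous gradient) return D = 0 with a
flag; a measured arterial PO₂ at or above the computed alveolar PO₂ makes
D_L unresolvable (reported at the bracket maximum, flagged) rather than
aborting the subject. V̇a uses V̇e·(1 − Vd/Vt), falling back to
863·V̇CO₂/PaCO₂ when Vd/Vt is missing. Vmax uses the closure
Vmax = V̇O₂peak·(P_mito,peak + P50_mito)/P_mito,peak.

**Forward solver.** For a candidate V̇O₂, relation 5 fixes P_mito and
relation 1 fixes PAO₂; the venous PO₂ fixed point of the composite
lung→muscle map closes relations 2+4 (secant iteration with a damped
fallback and warm starts; the map is a strong contraction because the lung
leg nearly saturates). The outer mismatch between circulatory transport and
the candidate V̇O₂ is strictly decreasing in V̇O₂ — transport falls and
demand back-pressure rises — so Brent root finding on (0, Vmax) gives the
unique operating point, to 1e-4 mL/min. At convergence all relations agree
to < 1e-3 relative; non-convergence raises with the residuals attached.
V̇O₂ < Vmax always (the Michaelis–Menten factor is < 1), and the solution
is nondecreasing in every parameter (verified over 0.25–4× sweeps).

## Mitochondrial closure: what Vmax does and does not mean

P_mito at peak exercise is not measurable by iCPET. The estimation stage
adopts the conventional closure P_mito,peak = 1.0 mmHg, P50_mito = 0.3 mmHg
(both exposed in `EstimationSettings`; every estimate carries a flag naming
the assumption). The forward model, however, lets P_mito float via the
Michaelis–Menten relation. The two views coincide only when the operating
P_mito equals the assumed value, which yields an exact identity for the
closure error of the recovered Vmax:

    Vmax_est / Vmax_true = (1 + P50_mito/P_mito,peak) · V̇O₂/Vmax_true.

At the default closure this is 1.3·r with r = V̇O₂/Vmax_true, exact at
r = 1/1.3 and drifting proportionally with r. For synthetic subjects whose
parameters scatter lognormally (spread 0.10) around group profiles, the
log-scatter of r is at most spread·√2 ≈ 0.14, so the median |error| is
bounded by ~10 % a priori — and the tests assert that bound, not the < 1 %
that holds for the directly identified parameters (V̇a, D_L, Q̇, Hb, D_M at
zero noise). The same mechanism injects a few-percent driving-pressure bias
into D_M for subjects whose operating P_mito differs from the assumed peak
value; it stays below 1 % at the cohort median. Real-world Vmax estimates
carry the same caveat: they are conditional on the closure, not measured.

## Predicted-normal values (reference table)

Predicted V̇O₂peak uses the base Hansen/Wasserman cycle-ergometry
equations — male: W·(50.72 − 0.372·age); female: (W + 43)·(22.78 − 0.17·age)
— without the over/under-weight branching (available behind a flag). The
published regression coefficients mapping predicted V̇O₂ to normal pathway
parameters are not publicly tabulated, so the shipped default table is
constructed from this package's own forward model: with Hb held at a
constant 14.9 g/dL (an intensive quantity), the model is homogeneous of
degree one in the five extensive parameters, so slope-through-origin models
calibrated at one anchor are *exactly* self-consistent — the forward model
on `normals(v)` returns `v` for every predicted V̇O₂ in the physiological
range (the suite checks 1000–4000 mL/min). The anchor is a
healthy-control-like median set (V̇a 51, D_L 41.5, Q̇ 19.3, D_M 49.8), with
the anchor Vmax closed so the anchor's operating P_mito equals the
estimation closure (hence the normal-Vmax slope is exactly 1.3 mL per mL of
predicted V̇O₂). The table's provenance string travels into every report;
user tables load from JSON and are validated (non-negative slopes).
`validate_reference_models` refits the per-parameter regressions on any
control cohort and reports deviations from the active table.

Predicted cardiac output (needed for the ≥ 80 %-predicted eligibility
criterion) assumes a normal peak arteriovenous difference of 13 mL/dL; this
is a declared assumption surfaced in the classifier's failure reasons.

## Synthetic cohorts

The generator emulates the study conditions: three groups (11 control /
15 PASC-like / 11 CFS-like by default), demographics drawn per group
around published medians (age, sex ratio, BMI), predicted V̇O₂ → normals →
true parameters = normals × lognormal(profile factor, spread 0.10). The
default profiles are group-to-control ratios of published peak-exercise
medians: PASC-like (V̇a 0.65, D_L 0.52, Q̇ 0.78, Hb 0.97, D_M 0.71,
Vmax 0.66), CFS-like (0.59, 0.38, 0.65, 0.95, 0.52, 0.54). The noiseless
record is derived from the forward operating point (so Fick holds exactly);
V̇e comes from true V̇a and a per-group Vd/Vt draw (medians 0.28/0.41/0.32,
sd 0.06, truncated to [0.05, 0.6]); control RER draws stay above the
eligibility threshold. Measurement noise is multiplicative lognormal per
channel (defaults: V̇O₂ and V̇e 3 %, blood gases 2 %, direct-Fick CO 5 %,
chosen on repeatability grounds); blood-gas noise perturbs the PO₂s and
recomputes saturations from the curve, so each measured blood point remains
internally consistent (analyzer-style error). Parameters are independent
across subjects by default; an optional shared-severity latent factor
(loading configurable) correlates the log-factors for tests that probe
multi-system involvement.

What the generator does *not* emulate: V̇/Q̇ heterogeneity and shunt (so
alveolar–arterial gradients are purely diffusive and much smaller than
clinical ones at normal D_L), acid–base and temperature effects on the
dissociation curve, rest-to-peak stage trajectories, lactate kinetics, and
any correlation between demographics and impairment severity. Passing tests
therefore demonstrate internal consistency of the pipeline under the stated
model, not agreement with any patient population.

## VDR conventions

Normalization is one-sided: only sub-normal parameters are raised (lowering
a supra-normal value would conflate benefit with harm); parameters at or
above normal score 0. The denominator is the Wasserman-predicted deficit,
not the all-normal forward V̇O₂. Values are reported raw — a single
normalization can overshoot the deficit and exceed 100 % (flagged, not
clamped) — and subjects without a deficit are flagged not-applicable with
all VDR undefined. On noisy records the forward model at the estimated
parameters no longer reproduces the measured V̇O₂ exactly, so small
negative VDR values can occur; they are honest outputs, not clamped.
Cohort summaries report per-group medians with seeded percentile-bootstrap
95 % CIs (2000 resamples). Joint multi-parameter normalization is out of
scope (interactions are real and are not assumed subadditive).

## Statistics

Kruskal–Wallis with tie correction (chi-square reference, k − 1 df);
for total n ≤ 10 an exact permutation p (full enumeration of group
assignments) is reported alongside. "Bonferroni post hoc" is read as
pairwise two-sided Mann–Whitney rank-sum tests with p multiplied by the
number of pairs; Dunn's rank-based z-test is available behind
`method="dunn"`. Percentiles use linear interpolation between order
statistics (a convention that must be pinned for reproducibility). Tests
are two-sided at α = 0.05.

## Problem sizes

The suite and the acceptance script use cohorts of 24–200 subjects: 200 for
distributional checks (profile reproduction, recovery under noise), 100 for
per-subject inverse–forward consistency, and the study-sized 37-subject
cohort (plus a 200-subject variant) for the VDR ranking. These sizes give
stable medians while keeping any single check within seconds on one CPU.

## Known limitations

- **D_L is ill-conditioned near lung equilibration.** At normal parameters
  the modelled pulmonary capillary equilibrates to within < 0.1 mmHg of
  alveolar PO₂, so arterial PO₂ carries almost no information about D_L;
  with realistic PO₂ measurement error, healthy-range D_L estimates are
  poorly determined (and a noisy PaO₂ above the computed PAO₂ is flagged
  unresolvable). Disease-range D_L (larger gradients) is well determined.
  This is a property of the shunt-free diffusion model, not of the solver;
  clinical A–a gradients are dominated by V̇/Q̇ heterogeneity the model
  excludes.
- Vmax (and mildly D_M) are conditional on the mitochondrial closure (see
  above).
- The control-group extraction-ratio analogue computed from group-median
  inputs (0.62) need not match a published median of per-subject ratios
  (0.6): the median of ratios is not the ratio of medians. The package
  computes per-subject values; median-input arithmetic is only used in
  worked examples.
- Cardiac output is taken as the measured direct-Fick value; no
  recalculation variant is provided.
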