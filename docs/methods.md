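# Methods

This note records the models implemented in `pk2dose`, the numerical
choices behind them, what the synthetic-data generator does and does not
emulate, and the known limitations. Units are fixed at the I/O boundary:
hours post-injection, kBq for activity, kBq/mL for concentration, g for
sample masses, kg for organ-mass tables, mGy/(MBq·h) for S-values.

## Decay arithmetic and %ID/g

All curves use injection time as t = 0. Physical decay is handled
explicitly: `decay_correct` multiplies by e^{λt} (back to injection time),
`decay_apply` by e^{−λt}, with λ = ln 2/T½ derived from the nuclide's
half-life so the pair can never drift apart (⁸⁹Zr: T½ = 78.4 h, bundled as
`ZR89`; every operation takes the nuclide as a parameter so other isotopes
work unchanged). %ID/g subtracts background *before* decay correction —
the background is a property of the counting geometry, not of the decaying
sample — and clamps negative net counts to zero with a warning rather than
reporting a negative concentration, since near-background samples are
dominated by counting noise.

## Non-compartmental analysis

AUC uses the log-linear trapezoidal rule: a logarithmic trapezoid
(t₂−t₁)(C₁−C₂)/ln(C₁/C₂) on strictly decreasing positive segments, a linear
trapezoid otherwise. Zero concentrations are never log-interpolated; they
force the linear rule on adjacent segments. AUMC uses the matching
first-moment forms (closed form (t₁C₁−t₂C₂)/k + (C₁−C₂)/k² on log
segments).

The terminal rate λz is a log-linear regression over a suffix of the
positive post-peak points; the suffix is chosen by maximising adjusted R²
over all suffixes with at least three points, ties broken toward more
points. This is the standard automatic rule; note that data-driven suffix
selection biases individual λz estimates slightly (the selected subset fits
"too well"), which is why the tests assess λz accuracy against truth over
replicates rather than against the selected subset's in-sample standard
error.

The extrapolated tail is monoexponential: AUC tail C_last/λz, AUMC tail
C_last·t_last/λz + C_last/λz². Derived parameters follow the bolus
identities CL = dose/AUC₀→∞, Vz = CL/λz, MRT = AUMC/AUC, Vss = CL·MRT.
Both AUC₀→t_last and AUC₀→∞ are reported; the chain's summary clearance is
dose over the full AUC.

Sparsely sampled organs can peak late (bone, with slow uptake of released
⁸⁹Zr, peaks near 67 h under the nominal schedule) and leave fewer than
three post-peak samples. Cohort-level NCA therefore degrades gracefully:
such curves keep their observed-span AUC/AUMC and report NaN for the
extrapolated quantities instead of failing the region
(`on_not_estimable="partial"`); a strict mode raises.

## Compartmental models and fitting

Blood: two-compartment bolus model in clearance parameterisation
(CL, V1, V2, Q), evaluated through the standard macro-constant conversion
(hybrid rates α > β from the micro rates k10 = CL/V1, k12 = Q/V1,
k21 = Q/V2). q = 0 is allowed and collapses to the one-compartment bolus.
Organs: one-compartment model with first-order uptake ka, elimination ke
and volume V. The organ model is phenomenological — it captures the
radioactivity concentration in the organ, not antibody disposition — so
dose enters with implicit availability 1.

The 1-CMT curve is invariant under the exchange
(ka, ke, V) → (ke, ka, V·ke/ka) (the classic flip-flop ambiguity). Fits are
reported in the canonical labelling ka ≥ ke; every integral quantity the
dosimetry consumes is unaffected by the choice.

Fitting is per-subject maximum likelihood with Gaussian residuals and
SD = a + b·C_pred (constant: b = 0; proportional: a = 0; combined: both
free). Optimisation runs in log-parameter space (positivity for free,
better conditioning) with Nelder-Mead from a heuristic centre plus
Latin-hypercube starts spread ±2 natural-log units (default 10 starts),
log-parameters bounded to ±25, objective tolerance 1e-10, ties resolved by
lower objective then smaller parameter norm. A residual-SD floor of 1e-10
keeps the likelihood finite on noiseless data; optima that exhaust the
iteration budget are restarted from the incumbent and accepted once the
objective stops improving (relative 1e-6). RSE% per parameter comes from
the inverse observed information (finite-difference Hessian of the log
likelihood in log space, so the log-scale SE approximates the natural-scale
CV); it is reported only for converged fits.

Population analysis is deliberately two-stage — per-subject ML fits, then
geometric-mean typical values and a lognormal IIV CV from the spread of the
log estimates — rather than full nonlinear mixed effects. At the data
richness this design provides (every subject observed at every time point,
low shrinkage), two-stage estimates are close to NLME ones, and the
procedure is deterministic and dependency-free. SAEM/FOCE estimation is out
of scope.

The visual predictive check simulates replicate cohorts from the population
summary (lognormal parameter draws, residual noise per the error model) at
the nominal sampling times — which are the bins; no binning heuristics —
and reports per-bin 5/50/95 percentiles plus the fraction of observations
inside the 90% band. Negative simulated concentrations are truncated at 0,
mirroring the generator.

Model adequacy against NCA uses
RMSE% = 100·sqrt(mean((AUC_CA − AUC_NCA)²))/mean(AUC_NCA) on paired
per-subject AUC₀₋₁₆₈ values; a per-pair normalisation is available as an
option. On noisy 7-subject cohorts at the default conditions this lands in
the 5–10% range across organs.

## Cumulated activity, residence times and allometric scaling

For dosimetry the physical decay stays in the integrand:
Ã = ∫₀^∞ C(t)·e^{−λ_phys t} dt·V_organ in closed form (the ka = ke limit is
1/(k+λ)²), reducing to the biological AUC₀→∞ at λ = 0 and strictly
decreasing in λ. Concentration converts to organ amount through the organ
mass at tissue density 1 g/mL (configurable per region). Residence time
τ = Ã/A₀ (h per unit injected activity) is the quantity the dose engine
consumes.

Whole-body residence time assumes complete retention of the antibody over
the ⁸⁹Zr time scale — renal filtration of an intact IgG is negligible — so
τ_WB = 1/λ_phys (113.1 h for ⁸⁹Zr), with a retained-fraction knob for
tracers with measurable excretion. Rest-of-body τ is whole body minus the
quantified organs; a negative remainder signals inconsistent organ
quantification and is an error, not a silent clamp.

Mouse→human scaling multiplies each organ's cumulated activity by
(m_WB,animal/m_WB,human)·(m_org,human/m_org,animal). The rest-of-body entry
uses whole-body masses on both sides, so its factor is exactly 1. Reference
masses ship as an editable CSV (nominal C57BL/6 mouse, 25 g, and an
ICRP-adult-male-style human, 73 kg); using the bundled mouse organ masses
instead of measured ones logs a provenance warning.

## Absorbed and effective dose

D(T) = Σ_S τ_S·S(T←S) over an S-value matrix read from a long-format CSV;
S-values are always input data (phantom Monte-Carlo transport is a
non-goal), and a synthetic fixture matrix with diagonally dominant
(self-dose > cross-dose) structure supports testing. Region names resolve
case-insensitively through an explicit alias map, since dose-target naming
conventions ("Endosteum (bone surface)") differ from source naming
("bone"). Effective dose is Σ_T w_T·D_T with radiation weighting 1 for
photons and electrons, so mGy/MBq sums numerically to mSv/MBq. The ICRP-103
weighting factors ship as an editable CSV whose Σw = 1 invariant is
enforced at load; remainder tissues are pooled into a single target by
default. Cohort summaries report arithmetic means and CV% with the sample
(n−1) standard deviation; a single subject yields a mean with CV flagged
unavailable.

How rest-of-body activity is distributed among phantom source regions is a
genuine modelling choice; the engine keeps it explicit — the residence
table carries a `rest_of_body` entry and the S-matrix (or alias map) says
which source column it feeds.

## Partial-method image quantification

VOI boxes are axis-aligned cubes snapped to the voxel grid (1 mm at 251 μm
voxels rasterises to 4 voxels per edge). Placement is seeded rejection
sampling over the low corners whose entire box lies inside the organ
label; a candidate is accepted if it overlaps no accepted box and the
Euclidean gap between nearest faces is at least the minimum distance
(default 1 mm — "minimum distance between VOIs" is read as face
separation, not centre distance). The attempt budget bounds the search;
exhausting it raises an infeasibility error naming the region. Defaults:
5 VOIs per organ, 3 for bone; tumours take a user-chosen count since the
sensible number depends on tumour size. Organ statistics are the mean and
CV over all voxels of all VOIs; the whole-organ contour statistics serve
as the reference method. Volumes are raw float32 plus a JSON sidecar
(shape, voxel size; 0-based indices, mm = index·voxel size at voxel
centres), with NIfTI read/write available when nibabel is importable.

## In vitro QC

Specific binding is total minus nonspecific, subtracted point-wise (no
linear-NSB co-fit), fitted to B = Bmax·[L]/(Kd+[L]) by bounded least
squares; a Kd estimate far beyond the covered ligand range (>100× the top
concentration) is flagged non-identifiable rather than reported. The
Lindmo immunoreactive fraction is 1/intercept of an unweighted OLS fit of
applied/bound against 1/cells, clipped into (0, 1] with a warning when the
intercept falls below 1. Duplicate assay rows are averaged as replicates.

## Synthetic-data generator

The generator is the package's stand-in for an animal study and defines
the conditions every closure test runs under: groups of 7 subjects,
~25 g body mass (2.8% CV), ~742.3 kBq injected (5.1% CV), sampling at 1,
3, 24, 48, 72, 168 h, lognormal IIV on every PK parameter (5% blood, 10%
organs by default) and residual noise with SD a + b·C (default constant,
a = 2 kBq/mL). Typical blood parameters are back-calculated from the
cohort summary the chain is meant to reproduce — CL = 742.3/6935.9
≈ 0.107 mL/h, Vss = CL·MRT ≈ 3.93 mL split as V1 = 2.0 mL and
V2 = 1.93 mL, Q = 0.225 mL/h solved so the terminal half-life is 28.7 h —
which also lands the late blood concentration near 2.3 kBq/mL at 168 h.
Organ one-compartment typicals fix plausible rate pairs (fast uptake
ka = 0.3/h for vascular organs; slow ka = 0.05/h, ke = 0.002/h for the
accumulating bone compartment) and solve each volume so the model AUC₀₋₁₆₈
matches the per-organ estimates (heart 1160, lung 365, kidney 837, liver
2026, bone 12619 kBq·h/mL at the nominal dose). When
`apply_physical_decay` is set, curves are multiplied by e^{−λt} and
flagged as not decay-corrected, exercising the correction path.

What the generator does *not* emulate: tumour-sink kinetics (the more
variable tumoural group is approximated only by a larger IIV CV),
target-mediated disposition, PET reconstruction noise, partial-volume
effects, or inter-organ correlation of parameters. Passing closure tests
therefore demonstrate the *chain's* correctness under its stated model, not
robustness to model misspecification in real data.

Phantoms are piecewise-constant ellipsoids with multiplicative Gaussian
voxel noise; S-value and weight fixtures are positive, diagonally dominant
and deterministic under seed.

## Pipeline and reproducibility

Stages run core → NCA → compartmental → allometry → dosimetry; each writes
its artifact (nca.csv, fits.csv, rmse.csv, residence_human.csv,
report.json) and any stage error aborts naming the stage and record. All
randomness derives from one seed fanned out by fixed per-subject/per-region
offsets; report.json carries provenance (config digest excluding the
output path, seed, package version), and reruns with the same inputs are
bit-stable. The CLI (`simulate`, `nca`, `fit`, `vpc`, `quant`, `scale`,
`dose`, `invitro`, `run`) is a thin layer over these functions with exit
codes 2/3/4 for config, data and numerical failures.

Problem sizes used by the test suite and the acceptance script — cohorts
of 2–20 subjects, 3–10 optimiser starts, 20 replicate studies for the
recovery experiment, 100 phantom seeds for the VOI validation — were
chosen as the smallest sizes at which the Monte-Carlo checks are stable.

## Known limitations

* Two-stage population estimates understate nothing only when data are
  rich per subject; with sparse or unbalanced designs NLME would differ.
* The λz suffix-selection rule shares the small-sample bias of all
  automatic terminal-phase selectors.
* Human dose numbers are only as good as the supplied S-values and organ
  masses; the bundled tables are nominal reference values, not
  subject-specific.
* Allometric mass-ratio scaling ignores species differences in
  biotransformation and any nonlinear PK.
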