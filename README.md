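# pk2dose

Preclinical PET pharmacokinetics to human dosimetry for long-lived
radiolabelled antibodies (⁸⁹Zr immunoPET and similar).

When a new radiopharmaceutical — say a ⁸⁹Zr-labelled antibody against a
tumour antigen — is characterised in mice before first-in-human use, the
same analysis chain recurs: gamma-counter and PET time–activity curves are
decay-corrected and normalised (%ID/g), blood and organ kinetics are
summarised non-compartmentally and fitted with compartmental models, the
decay-weighted cumulated activity in each organ is extrapolated from mouse
to human by mass-ratio (allometric) scaling, and organ absorbed doses plus
the ICRP-103 effective dose are obtained from phantom S-value tables.
`pk2dose` implements that chain as a tested, scriptable library with a
synthetic-data generator that reproduces the statistical structure of such
a study (7 subjects per group, sampling at 1, 3, 24, 48, 72 and 168 h,
two-compartment blood and one-compartment organ kinetics, lognormal
inter-individual variability, constant/proportional/combined residual
error), so the whole pipeline can be exercised and validated without any
animal data.

## The models and quantities

**Decay arithmetic.** Measured activity is corrected to injection time by
A·e^{λt} with λ = ln 2 / T½ (T½ = 78.4 h for ⁸⁹Zr); %ID/g is the
background-subtracted, decay-corrected sample activity per gram, as a
percentage of the injected activity.

**NCA.** AUC and AUMC by the log-linear trapezoidal rule (linear trapezoids
on rising or zero-touching segments, logarithmic on strictly decreasing
positive ones); terminal slope λz by log-linear regression with the suffix
chosen by adjusted R²; then CL = dose/AUC₀→∞, Vz = CL/λz, MRT = AUMC/AUC,
Vss = CL·MRT.

**Compartmental models.** Blood: two-compartment bolus model (CL, V1, V2,
Q) with biexponential solution C(t) = A·e^{−αt} + B·e^{−βt}. Organs:
one-compartment model with first-order uptake and elimination,
C(t) = D·ka/(V(ka−ke))·(e^{−ke t} − e^{−ka t}). Per-subject maximum
likelihood with observation SD a + b·C, multi-start optimisation in
log-parameter space; population summary by the two-stage approach
(geometric-mean typicals, lognormal IIV), checked by a visual predictive
check.

**Dosimetry.** Cumulated activity Ã = ∫ C(t)·e^{−λ_phys t} dt·V_organ in
closed form; residence time τ = Ã/A₀; rest of body = whole-body τ minus the
quantified organs; mouse→human scaling
Ã_human = (m_WB,mouse/m_WB,human)·(m_org,human/m_org,mouse)·Ã_mouse;
absorbed dose D(T) = Σ_S τ_S·S(T←S) over a pluggable S-value matrix;
effective dose E = Σ_T w_T·D_T with the ICRP-103 tissue weighting factors
(bundled, editable). S-values are input data — the package never performs
radiation transport.

**Image quantification.** The "partial method": a few (default 5; 3 for
bone) non-overlapping 1 mm³ cubic VOIs per organ with ≥ 1 mm face gap,
sampled reproducibly inside a label mask, versus whole-organ contour
statistics; plus remainder-body activity and tumour-to-lung SNR.

**Radiolabel QC.** One-site saturation binding (Kd, Bmax) and the Lindmo
extrapolation of the immunoreactive fraction.

## Worked example

```python
import pk2dose as pk

# a synthetic healthy cohort at the default study conditions
cohort = pk.simulate_cohort(pk.SimulationConfig(seed=1))
df = pk.nca_cohort(cohort, "blood")
mean = df[df.subject_id == "__mean__"].iloc[0]
cv = df[df.subject_id == "__cv_percent__"].iloc[0]
print(f"blood NCA (n=7): AUC0-inf {mean.auc_0_inf:.0f} kBq.h/mL (CV {cv.auc_0_inf:.1f}%)")
print(f"  CL {mean.cl:.3f} mL/h (CV {cv.cl:.1f}%), t1/2 {mean.t_half:.1f} h, MRT {mean.mrt:.1f} h")
```

prints

```
blood NCA (n=7): AUC0-inf 6928 kBq.h/mL (CV 7.7%)
  CL 0.106 mL/h (CV 5.9%), t1/2 27.7 h, MRT 36.1 h
```

i.e. the non-compartmental estimates recover the clearance (≈0.107 mL/h),
terminal half-life (≈28.7 h) and mean residence time (≈36.7 h) that the
generator's typical parameters encode, with cohort CVs of a few percent
driven by the configured inter-individual variability and injected-activity
spread.

The same cohort can be pushed through the whole chain from the shell:

```bash
pk2dose simulate --out-dir fixtures/ --seed 1
pk2dose nca --tacs fixtures/tacs.csv --subjects fixtures/subjects.csv \
        --region blood --out nca.csv
pk2dose run --config pipeline.yaml --out-dir results/
```

`run` writes `nca.csv`, `fits.csv`, `rmse.csv` (compartmental-vs-NCA AUC
agreement per organ), `residence_human.csv` and `report.json` (per-target
absorbed doses in mGy/MBq, effective dose in mSv/MBq, cohort CV%, and
provenance).

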