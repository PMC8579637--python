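# Methods

## Signal models and units

All four forward models operate per voxel. Diffusivities are in mm²/s,
pharmacokinetic rate constants in 1/min, times on the DCE axis in seconds.
Reported maps use the conventional clinical scales (reported = physical /
scale): ADC, MD, D_slow ×10⁻⁶ mm²/s; D_fast and the perfusion fraction f
×10⁻⁴; MK, K^trans, K_ep and V_e ×10⁻³. The scale is carried on every
`ParameterMap` and round-trips exactly through the NIfTI writer (scale
recorded in the header description and a JSON sidecar).

The kurtosis signal S₀·exp(−b·D + ⅙b²D²K) is a truncated cumulant
expansion: it is a decreasing function of b only for b < 3/(D·K). Forward
evaluation is unrestricted, but the fitting bounds (D ≤ 4×10⁻³ mm²/s,
K ≤ 3) keep fitted decays monotone over clinical b ranges.

The IVIM model is the standard bi-exponential with the perfusion pool
decaying at D_slow + D_fast, i.e. pseudo-diffusion adds to tissue
diffusion; this is the form consistent with the parameter names and the
IVIM literature.

The Tofts convolution is evaluated exactly for a piecewise-linear plasma
curve on a grid refined 20-fold relative to the frame spacing, using a
linear-recurrence solve; against the closed-form step-AIF solution the
error is below 10⁻⁶ on a 1 s grid. A trapezoid series replaces the exact
interval integral when k·h < 10⁻⁶ to avoid catastrophic cancellation on
the near-duplicate grid points created by merging frame times into the
refined grid. Two AIFs are provided: a constant step (for closed-form
testing) and the Parker population AIF with onset at the first
post-baseline frame. No signal-to-concentration conversion is modelled;
the pipeline operates on concentration curves directly, and no plasma-
volume (extended-Tofts) term is included.

## Fitting

* **ADC** — ordinary least squares of log-signal on b (exactly the
  two-point log-ratio when only b = 0 and one diffusion weighting exist).
* **DKI** — bounded trust-region nonlinear least squares over (S₀, D, K)
  with an analytic Jacobian, seeded by the log-quadratic estimate, which
  is exact on noise-free data.
* **IVIM** — segmented: (1) mono-exponential OLS on b ≥ b_threshold
  (default 200 s/mm², the common choice) gives D_slow and intercept
  A = S₀(1−f); (2) f = 1 − A/S(0), clipped to [0,1] with a flag; (3) a
  bounded scalar fit of D_fast ∈ [max(D_slow, 10⁻³), 0.5] mm²/s on the
  full curve. Voxels with f ≈ 0 keep D_slow but have the perfusion
  parameters flagged unfit. A joint four-parameter bounded fit, seeded
  from the segmented result, serves as an independent cross-check; on
  noise-free data the two agree within 1%.
* **Tofts** — bounded least squares over K^trans ∈ [0, 5]/min and
  K_ep ∈ [10⁻³, 10]/min, initialised by a closed-form K^trans estimate at
  a small set of candidate K_ep values; V_e = K^trans/K_ep, flagged when
  above 1.

Loss is unweighted least squares throughout. Voxels with non-positive
signals, too few samples or non-convergent fits are excluded from the
fitted mask rather than imputed, and masked-out voxels never influence
fitted ones. All fits are deterministic.

## ROI metrics and response labels

Parameter statistics are taken over the largest axial lesion slice (the
standard single-slice convention); volume uses all slices via the
slice-stack formula, per-slice area × (slice thickness + gap), summed.
Quartiles use linear interpolation between order statistics, the common
statistical-software default — recorded because IQR values depend on the
convention. RECIST 1.1 on a single target lesion: PR at ≥30% diameter
decrease (boundary inclusive), CR at disappearance, PD at ≥20% increase
that is also ≥5 mm absolute (the absolute guard is enforced whenever the
pre-treatment diameter is available), SD otherwise; responders = CR/PR.

## Statistics layer

Paired and unpaired location comparisons are gated on Shapiro–Wilk
normality at α = 0.05 (no test is named in common clinical practice
descriptions, so the most widely used one is chosen), with Levene's test
additionally gating the pooled-variance Student t; the rank alternatives
are Wilcoxon signed-rank and two-sided Mann–Whitney U. Categorical tables
use plain chi-square when every expected count is ≥5 and (for 2×2) the
total is ≥40, the Yates continuity correction when an expected count falls
in [1,5), and Fisher's exact test for small or sparse 2×2 tables. No
multiple-testing correction is applied (single-study descriptive use,
α = 0.05 throughout).

The logistic combination fits an unpenalised maximum-likelihood model with
all features entered simultaneously; features are centred internally so a
constant column keeps a zero coefficient. Complete separation (detected as
strictly separated fitted scores, under which the MLE diverges) is flagged
and the model refitted with a 10⁻⁶ ridge penalty so a usable score is
still produced.

ROC analysis uses the empirical curve: the AUC is the trapezoidal area,
identical to the Mann–Whitney U/(n₁n₂) with ties counted ½ (verified
against exhaustive pair counting). The marker orientation (whether high or
low values predict response) is chosen so AUC ≥ 0.5 and reported
explicitly rather than hidden in a sign flip. The operating point
maximises Youden's J over all empirical thresholds; cutoffs are placed
midway between adjacent observed values and ties resolve to the smallest
cutoff on the original marker scale, so reported cutoffs are deterministic
achievable operating points. Confidence intervals use the DeLong
structural-components variance; predictive values are computed from
integer confusion counts reconstructed at the cohort prevalence
(TP = round(sens·n₊), etc.), the convention of clinical ROC software.
Correlated AUCs are compared with the paired DeLong test; its type-I error
calibrates to the nominal 5% level in simulation.

## Synthetic cohort

The generator emulates a 56-patient pre/post induction-chemotherapy cohort
(36 responders / 20 non-responders by default; the counts are exact, not
expected values). Per-patient pre-treatment markers are drawn from
group-specific distributions: truncated normals where a mean ± SD is the
natural summary (ADC, MK, D_slow, D_fast, K^trans), log-normals matched to
median and IQR where the summary is median (IQR) (MD, f, K_ep) — the
log-normal choice encodes positivity and right skew. Markers without a
reported group difference share one distribution across groups. A single
latent "aggressiveness" factor with loading 0.5 induces within-patient
cross-marker correlation (aggressive, chemo-sensitive tumors: low
ADC/MD/D_slow, high MK); without it a multi-marker score would be
trivially additive. K^trans/K_ep pairs are resampled until V_e < 1.

Post-treatment values are pre × (1 + Δ%/100) with group-specific normal Δ%
distributions, using reported group changes where available and the
overall pre-to-post shift with a nominal 15-point spread otherwise. Tumor
diameter changes are drawn from truncated normals over the RECIST region
of the intended group (responders in (−85, −30]%, non-responders simulated
as stable disease in (−30, +20)%), with the location solved numerically so
the truncated mean equals the configured group mean — plain truncation
would bias the realised means. Labels are then assigned through the same
RECIST classifier the analysis uses, so labels, diameters and categories
are mutually consistent by construction.

Lesions are ellipsoids on a 15×15×7 voxel grid at 3×3×4 mm. The
post-treatment cross-axes are sized so the discretised voxel count matches
the drawn volume change (an order-statistic solve on normalized radii),
and recorded volumes come from the discretised masks — the slice-stack
volume formula therefore round-trips exactly against the rendered masks.
Rendering gives lesion voxels the patient's parameters with 5% log-normal
within-tumor variability over a homogeneous quiescent background, then
applies Rician noise at SNR 50 (S₀/σ) to the diffusion series — magnitude
reconstruction — and Gaussian noise (σ = 0.02 mM) to the concentration
curves, which are derived quantities. Noise is seeded per patient and
timepoint: reruns are byte-identical, different patients independent.

What the generator does **not** emulate: scanner physics (coil profiles,
EPI distortion, motion), registration error between timepoints (pre/post
are perfectly co-registered), irregular lesion shapes, intra-tumor
substructure beyond i.i.d. log-normal jitter, and the unknown true
inter-parameter correlation structure (the latent-factor loading is a
declared knob, not an inference). Passing tests therefore demonstrate
correctness of the estimators and statistics under the declared data
model, not robustness to real-world acquisition artefacts.

## Default acquisitions

DWI b = {0, 600}; DKI b = {0, 500, 1000, 1500, 2000}; IVIM b = {0, 10, 20,
30, 50, 80, 100, 150, 200, 400, 600, 800} s/mm²; DCE 35 frames at 8.1 s
(4 baseline + 31 enhanced, ≈4:44 total). All are configurable through
`CohortConfig` / the YAML config.

## Pipeline and problem sizes

The CLI exposes three stages — `simulate`, `fit`, `stats` — with ROI
summarisation folded into `fit` (maps and ROI tables are produced
together) and the report emitted by `stats`; each stage is deterministic
given (config, seed) and `simulate` writes a manifest with the seed and a
config hash. Cohort-level analyses fit only within the analysis ROI, since
that is all the downstream statistics consume.

Default problem sizes keep the suite fast on one CPU: lesions of ~100
voxels (single-slice ROIs of ~30), 56-patient cohorts, 10 replicate
cohorts in the acceptance script's AUC averages, 40 replicates in the
marker-direction check, 500 replicates in the DeLong calibration. The
choice of a coarse grid trades per-patient map resolution for cohort-level
replication, which is where the statistical claims live.

## Known limitations

* The segmented IVIM fit assumes the perfusion pool is fully decayed
  above the b threshold; for D_fast below ~20×10⁻³ mm²/s its residual
  contaminates the D_slow estimate by more than the stated tolerances.
* Rician noise biases the fitted kurtosis slightly downward, more so for
  high-diffusivity tissue whose high-b signal sits closer to the noise
  floor; at SNR 50 this attenuates the fitted between-group MK difference
  by roughly 10 units (×10⁻³) relative to ground truth. No noise-floor
  correction is applied, matching the plain least-squares convention.
* Predictive values depend on the cohort prevalence and the integer
  rounding convention; they are not transportable to other prevalences.
* The DeLong confidence interval is a normal approximation; no bootstrap
  alternative is provided.
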