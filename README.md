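# qmripred

Quantitative-MRI parameter mapping and treatment-response prediction for
solid tumors, built end-to-end: voxel-wise fitting of four functional-MRI
signal models, ROI/RECIST response metrics, and the diagnostic-statistics
layer used to compare imaging biomarkers — together with a seeded synthetic
cohort generator so the whole pipeline runs and is testable without any
patient data.

The motivating use case is nasopharyngeal carcinoma treated with induction
chemotherapy: can pre-treatment diffusion and perfusion parameters separate
patients who will respond (RECIST 1.1 CR/PR) from those who will not
(SD/PD)?

## Models

For each voxel with baseline signal S₀ and diffusion weighting b (s/mm²):

* **ADC (mono-exponential DWI)** — S(b) = S₀·exp(−b·ADC), fitted by linear
  least squares on log-signal.
* **DKI (diffusion kurtosis)** — S(b) = S₀·exp(−b·D + ⅙·b²·D²·K), bounded
  nonlinear least squares for mean diffusivity MD = D and mean kurtosis
  MK = K.
* **IVIM (bi-exponential)** — S(b)/S₀ = (1−f)·exp(−b·D_slow) +
  f·exp(−b·(D_slow+D_fast)), segmented fit: D_slow from the high-b
  mono-exponential (b ≥ 200 s/mm² by default), perfusion fraction f from the
  intercept deficit, then a bounded one-parameter fit of D_fast; a joint
  four-parameter fit is provided as an independent cross-check.
* **Tofts (DCE two-compartment)** — C_t(t) = K^trans·∫₀ᵗ C_p(τ)·
  exp(−K_ep·(t−τ)) dτ with V_e = K^trans/K_ep, fitted on concentration
  curves against a step or Parker population arterial input function.

Maps are reported in the conventional scales (ADC/MD/D_slow ×10⁻⁶ mm²/s,
D_fast and f ×10⁻⁴, MK and the DCE parameters ×10⁻³).

On top of the maps: single-slice ROI summaries, Δ and Δ% change metrics,
the slice-stack tumor volume (area × (thickness + gap), summed over
slices), RECIST 1.1 labelling, normality-gated paired/unpaired group tests,
chi-square/Fisher categorical tests, a logistic combination of markers into
a predicted-probability score (PRE), and full ROC analysis: AUC with DeLong
confidence intervals, the Youden-optimal cutoff, likelihood ratios and
predictive values at the cohort prevalence, and the paired DeLong test for
comparing correlated ROC curves.

## Worked example

Recompute a pooled two-sample t statistic from published group summaries
(volume change %: −64.98 ± 17.77 in 36 responders vs −30.35 ± 14.94 in 20
non-responders):

```python
>>> from qmripred import t_from_summary
>>> t_from_summary(-64.98, 17.77, 36, -30.35, 14.94, 20)
7.378641315053702
```

Generate the default 56-patient synthetic cohort, render and fit the DWI
images, and ask how well pre-treatment ADC separates responders:

```python
from qmripred import CohortConfig, generate_cohort, roc_analysis
from qmripred.pipeline import fitted_cohort_frame

cfg = CohortConfig(seed=42)                      # 36 responders, 20 non-responders
records = generate_cohort(cfg)
frame = fitted_cohort_frame(records, cfg, models=("adc",), timepoints=("pre",))
wide = frame.pivot_table(index=["patient_id", "group"],
                         columns="parameter", values="mean")
responder = wide.index.get_level_values("group") == "RG"
r = roc_analysis(wide["ADC"].to_numpy(), responder, marker="ADC-pre")
print(f"AUC={r.auc:.3f} ({r.orientation} predicts response), "
      f"cutoff={r.cutoff:.0f}, sens={r.sensitivity:.2f}, spec={r.specificity:.2f}")
```

which prints

```
AUC=0.865 (lower predicts response), cutoff=1252, sens=0.69, spec=0.90
```

i.e. tumors with low pre-treatment ADC (below ≈1250 ×10⁻⁶ mm²/s here) tend
to respond — low ADC reflects high cellularity and little necrosis, which
favors chemotherapy delivery. The AUC of 0.87 means a randomly chosen
responder has lower fitted ADC than a randomly chosen non-responder 87% of
the time.

A shell interface wraps the stages:

```
qmripred simulate --seed 42 --out cohort/
qmripred fit --in cohort/ --out maps/ --model all
qmripred stats --cohort maps/cohort_fitted.csv --out report/
```

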