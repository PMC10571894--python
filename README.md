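# mtsurv — multitask 3D survival networks

`mtsurv` is a research package for image-based outcome prediction of cancer
patients under right censoring.  It targets the setting of tumor-centered 3D
volumes (CT, optionally PET) with delineated gross tumor volume (GTV) masks
and censored endpoints such as loco-regional control or progression-free
survival, where cohorts are small and direct deep-learning training is
fragile.  Its core idea is multitask learning: one shared image backbone is
jointly optimized for two complementary survival objectives and an auxiliary
tumor-segmentation objective, so that outcome predictions are anchored to
tumor location and shape.

## The model

A 3D UNet (or a UNETR-style vision transformer) maps a 48×64×64 crop around
the tumor center of mass to

- a voxelwise sigmoid **segmentation map** trained with
  `L_seg = 0.5·L_Dice + L_BCE`,
- a tanh-bounded **Cox log-hazard** `γ(x) ∈ (−1, 1)` for the
  proportional-hazards model `h(t,x) = h₀(t)·exp(γ(x))`, trained with the
  batchwise negative partial log-likelihood
  `L_Cox = −Σᵢ δᵢ [γᵢ − ln Σ_{t_j ≥ t_i} exp(γⱼ)]`, and
- a **discrete-time head**: conditional survival probabilities for ten
  intervals over 0–120 months, trained with a masked binary cross-entropy;
  cumulative products give the survival curve, read out at 24 months for
  evaluation.

In the multi-outcome setting the losses are added,
`L = L_Cox + L_GH (+ L_seg)`.  The protocol is 5-fold cross-validation
stratified by event status, repeated 3 times; the 15 resulting models are
ensembled (15 models for independent-validation patients, 12/3 for the
training/internal-test views of exploratory patients).  Evaluation uses the
concordance index with Noether-type confidence intervals (hazard
predictions score *below* 0.5 when informative; survival probabilities
above), Kaplan–Meier curves, and median-threshold log-rank stratification.

Everything runs on a small, fully tested numpy autodiff engine inside the
package — no GPU framework is required — with desk-scale presets (16³
volumes) that make the complete protocol, training included, feasible on a
single CPU.  A synthetic phantom generator provides cohorts with known
ground-truth hazards for end-to-end validation.

## Worked example

Train the desk-scale multitask CNN on 200 synthetic phantoms whose only
prognostic factor is tumor volume (β = 1.5), with the full 3×5
cross-validation ensemble (about 10 minutes on one CPU core):

```python
import numpy as np
from mtsurv import (
    tiny_phantom_spec, generate_cohort, oracle_cindex, normalize_sample,
    tiny_cnn_config, tiny_schedule, run_cross_validation, ensemble_report,
)

spec = tiny_phantom_spec(cohort_size=200, true_effect=1.5, seed=11)
samples, truths = generate_cohort(spec)
records = [s.record for s in samples]
print("event fraction", np.mean([r.event for r in records]),
      "oracle C-index", oracle_cindex(truths, records))

samples = [normalize_sample(s) for s in samples]
table, per_model, assignment, history = run_cross_validation(
    samples, tiny_cnn_config(), tiny_schedule(), n_folds=5, n_repetitions=3, seed=7,
)
print(ensemble_report(table, {s.patient_id: s.record for s in samples}).to_string())
```

One run of this prints:

```
event frac 0.56 oracle c 0.2044049459041731
  head           role  n_patients   c_index    ci_low   ci_high  logrank_statistic     logrank_p
0  cox       training         200  0.305023  0.259062  0.350985          35.638308  2.375695e-09
1  cox  internal_test         200  0.407032  0.352431  0.461634          11.947615  5.471738e-04
2   gh       training         200  0.618779  0.567513  0.670045           7.877191  5.006218e-03
3   gh  internal_test         200  0.517543  0.459940  0.575145           0.552475  4.573083e-01
```

Reading this: the true log-hazard itself scores C = 0.204 (hazard reading —
lower is better), the ceiling for this cohort.  The trained Cox-head
ensemble reaches C = 0.41 (CI 0.35–0.46) on patients it never trained on,
clearly better than random (0.5), and its median split separates survival
curves at log-rank p ≈ 5×10⁻⁴; the training-ensemble C of 0.31 shows the
usual optimism gap.  (Exact third decimals can drift between BLAS builds;
the internal-test Cox C-index stays near 0.40.)

The same workflow is scriptable from the shell:

```bash
mtsurv simulate cohort --cohort-size 200 --effect 1.5 --seed 11
mtsurv train cohort/manifest.csv run --preset tiny-cnn --repetitions 3 --folds 5 --seed 7
mtsurv evaluate run/ensemble_table.csv cohort/manifest.csv
mtsurv report run/ensemble_table.csv cohort/manifest.csv run/km
mtsurv audit --preset paper-cnn
```

`mtsurv audit` prints the parameter accounting of the full-scale
architectures, e.g. 356,004 trainable parameters (0.36 M) for the
multitask CNN without the DenseNet branch and 1.47 M with it.

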