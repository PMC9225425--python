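# qmri

Quantitative analysis pipeline for preclinical contrast-enhanced MRI studies
of traumatic brain injury, built around the question: *does a head injury
open the meningeal blood barriers, and for how long?*  The package is aimed
at imaging scientists who quantify dynamic contrast-enhanced (DCE) MRI and
T2 relaxometry in small-animal cohorts scanned repeatedly (before injury,
the day of injury, and a week later) and who need the whole chain — image
synthesis, map fitting, enhancement quantification, exclusion rules, and
repeated-measures statistics — to be reproducible and testable without
animal data.

## What it computes

- **T2 relaxometry** — voxelwise fits of S(TE) = S0 exp(-TE/T2) from
  multi-echo stacks (TE = 10…110 ms), by weighted log-linear least squares
  or batched nonlinear least squares; ROI summaries over successfully
  fitted voxels.
- **DCE enhancement AUC** — relative enhancement
  (S(t) − S_base)/S_base against the pre-injection baseline, integrated
  over the post-injection window (trapezoid on frame midpoints), and
  normalized to the same session's bilateral muscle ROI:
  AUC_norm = AUC_roi / AUC_muscle.
- **Exclusion rules** — sessions with poor contrast uptake (muscle AUC
  below threshold) and ROIs shrunken by the median ± 4·MAD voxel-outlier
  rule are flagged with reasons, never silently dropped.
- **Group statistics** — repeated-measures linear mixed models
  (Injury × Sex × Day, or Region × Injury × Sex × Day) with a per-animal
  random intercept and Type III omnibus F tests; Bonferroni-corrected
  pairwise comparisons; Kruskal–Wallis with tie correction; exact
  (full-enumeration, tie-safe) and asymptotic Mann–Whitney U; Hedges' g
  with the small-sample correction J = 1 − 3/(4(n1+n2−2) − 1).
- **Histology** — percent area stained of thresholded
  immunohistochemistry images, averaged over ≥3 sections per animal.
- **Digital phantom** — a cohort simulator (2×2×3 design, Rician noise,
  lognormal between-animal and injection variance components, known
  ground-truth enhancement and T2 per tissue) that makes every stage
  verifiable against closed forms.

## Worked example

Simulate a cohort of 40 animals (10 per Injury × Sex cell) in which injury
doubles meningeal enhancement on Day 1, run the image pipeline, and fit the
three-factor mixed model on the muscle-normalized meningeal AUC:

```python
from qmri import phantom, pipeline, roistats
from qmri.groupstats import fit_mixed_model
from qmri.pipeline import group_effect_size

acq = phantom.AcquisitionSpec(matrix=(18, 18, 6))
tissues = [t for t in phantom.default_tissues()
           if t.label in ("meninges", "cortex", "muscle")]
design = phantom.DesignSpec(n_per_cell=10,
                            injury_effects={("meninges", "Day1"): 2.0},
                            seed=42)

table = pipeline.run_cohort(design, acq, tissues, metrics=("auc_norm",))
men = roistats.require_clean(table).query("roi == 'meninges'")
print(fit_mixed_model(men).summary())
print(f"Injured-vs-sham Day1 Hedges g: "
      f"{group_effect_size(table, roi='meninges', day='Day1'):.2f}")
```

Output:

```
Mixed-model ANOVA: value ~ injury x sex x day  (random intercept: animal_id, n=40 subjects, 120 observations)
-------------------------------------------------------------------------------------------------------------
term                         num df   den df         F         p
injury                            1     36.0     4.797    0.0351
sex                               1     36.0     1.875    0.1794
day                               2     72.0   221.650    0.0000
injury x sex                      1     36.0     0.884    0.3533
injury x day                      2     72.0   222.637    0.0000
sex x day                         2     72.0     2.553    0.0849
injury x sex x day                2     72.0     2.400    0.0980
Between-subject variance: 0.07079; residual variance: 0.006747

Injured-vs-sham Day1 Hedges g: 1.76
```

The strong Injury × Day interaction is the injected Day-1-only doubling;
the Hedges' g of 1.76 is the pipeline's estimate of the injured-vs-sham
standardized difference on Day 1 (the generator's analytic expectation for
this configuration is 1.49; individual cohorts scatter around it).

The same pipeline is available from the shell:

```bash
qmri run --config cohort.yaml --out results/
qmri fit-t2 --stack me.nii.gz --echoes 10,30,50,70,90,110 --method nlls \
     --rois labels.nii.gz --out t2/
qmri dce-auc --series dce.nii.gz --rois labels.nii.gz \
     --roi-names meninges,cortex,muscle --out auc/
qmri histo-quant --images sections/ --threshold 128 --out stains.csv
```

`qmri run` writes NIfTI volumes, the long-format measurement table, the
statistics tables and a JSON manifest with per-file SHA-256 hashes;
identical config + seed reproduces identical bytes.

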