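# Methods

## Overview

`qmri` re-creates, in a fully testable form, the analysis chain of a
preclinical contrast-enhanced MRI study of traumatic meningeal enhancement:
mice receive closed-head impacts (CHIMERA) or sham treatment and are scanned
at three visits — one week before injury (Baseline), immediately after the
final injury (Day 1), and one week post-injury (Day 7).  Each scan session
produces a multi-echo T2-weighted stack and an 11-minute, 11-frame dynamic
contrast-enhanced (DCE) FLASH series with contrast injection commencing
2 minutes into the acquisition.  Because no animal data ship with the
package, a digital phantom generates cohorts with known ground truth; every
downstream claim the test suite makes is a claim about quantities the
phantom controls exactly.

## Digital phantom

**Geometry.** The label volume places a bilateral extracranial muscle slab
(the normalization reference), a one-voxel-thick dorsal meninges shell, a
cortex band beneath it, and blocks for the deep ROIs (brainstem, cerebellum,
corpus callosum, dorsal hippocampus, optic tract, LGN, superior colliculus).
Default matrices are 92 x 92 x 25 at 150 x 150 x 1000 um (a 500 um slice
variant is configurable).  The geometry is schematic by design: ROIs are
generated in register, so no registration or skull stripping exists in the
pipeline (deliberately out of scope).

**T2-weighted signal.** Each tissue carries a proton-density amplitude S0
and a transverse relaxation time T2; the noiseless multi-echo signal is
S(TE) = S0 exp(-TE/T2) at TE = 10, 30, 50, 70, 90, 110 ms.  Default T2
values sit in the physiologic 30–80 ms range for mouse brain at 7 T; they
are configurable inputs, not claims about any particular dataset.

**Noise.** Magnitude images carry Rician noise, sqrt((mu+e1)^2 + e2^2) with
e1, e2 ~ N(0, sigma^2) — the standard magnitude-MRI model.  The default
sigma (3.3 signal units against brain S0 ~ 100) corresponds to SNR ~ 30.
Pure-noise background voxels are Rayleigh with mean sigma sqrt(pi/2), which
the relaxometry stage exploits to estimate the noise floor.

**Contrast uptake.** Relative enhancement follows a delayed saturating
mono-exponential, E(t) = A (1 - exp(-k (t - t0))) for t >= t0 (t0 = 2 min),
evaluated at frame midpoints (11 one-minute frames).  This is the simplest
shape with an analytic AUC, which gives the quadrature tests an exact
oracle.  No pharmacokinetic (Tofts-type) model is fitted anywhere — the AUC
metric is deliberately model-free.

**Variance components.** The 2 x 2 x 3 design (Injury x Sex x Day) draws,
per animal, a lognormal multiplier exp(N(0, tau^2)) on the enhancement
amplitude of all intracranial tissues (biological between-animal
variability; default tau = 0.4, giving a cohort coefficient of variation of
~40%, typical of DCE measures, and an expected injured-vs-sham effect size
comparable to large published meningeal effects), and, per session, a
lognormal injection-efficiency multiplier (default sd 0.2) applied to
*every* tissue including muscle.  The injection multiplier cancels exactly
under muscle normalization — which is the point of the reference ROI — and
the tests assert this.  Injury and sex effects are multiplicative shifts on
amplitude keyed by (ROI, day); the default injury signature doubles
meningeal enhancement on Day 1.

**Histology.** Binary stained/unstained images place an exact
round(f * n_pixels) count of stained pixels by thresholding a smoothed
Gaussian random field, so staining is spatially clumped rather than
salt-and-pepper.

**What the phantom does not emulate.** No k-space effects (B0/B1
inhomogeneity, motion, partial volume), no inter-session ROI drawing error,
no physiologic drift within a session, and enhancement kinetics far simpler
than real tissue.  Passing tests therefore validate the *analysis*
machinery — fitting, integration, normalization, exclusion, statistics —
not the biological fidelity of any simulated number.

## Relaxometry

T2 maps are fitted voxelwise from the multi-echo stack under the
mono-exponential model, either by weighted log-linear least squares
(weights S^2, the standard de-biasing of the log transform) or by nonlinear
least squares initialized from the log-linear solution.  The NLLS path is a
batched Levenberg–Marquardt on the two-parameter problem, vectorized over
all voxels (closed-form 2x2 normal equations, per-voxel damping), so a full
92 x 92 x 25 volume fits in about a second per method.  Guards: voxels with
any non-positive sample are unfittable by the log-linear path; fits with
T2 outside (0, 2000 ms] are rejected (CSF/artifact guard); voxels whose
first-echo signal falls below 3x the Rayleigh-estimated background noise
are skipped.  ROI summaries (mean, median, voxel counts) use successfully
fitted voxels only, and a fully excluded ROI is reported as missing, never
as zero.  ROI values are computed voxelwise-then-averaged; fitting the
ROI-mean signal instead is possible through the same API (fit the averaged
curve with `T2Decay`) but is not the default.

## DCE AUC

Signal is converted to relative enhancement (S(t) - S_base)/S_base against
the mean of the pre-injection frames (default 2 frames: with one-minute
frames and injection at 2 min, exactly frames 1–2 precede injection; a
baseline window reaching into the injection is a validation error).  The
AUC integrates relative enhancement over the post-injection window (default
2–11 min) by a trapezoid rule on frame midpoints with rectangle extension
to the window edges — exact for constant and linear curves, and for the
saturating phantom curve accurate to the classical trapezoid bound
(T Δ²/12) max|f''| plus an edge term.  Per-ROI values are means over
voxelwise AUCs after dropping non-evaluable voxels and robust outliers
(median ± 4 MAD, configurable).  Session normalization divides every ROI's
raw AUC by the pooled bilateral muscle ROI's raw AUC; a session whose
muscle AUC is at or below threshold is flagged for exclusion rather than
divided.  Relative (rather than raw-signal) AUC is the default metric; the
raw AUC is also reported per ROI.

## Exclusion rules and table assembly

The long-format measurement table has one row per (animal, day, ROI,
metric) with design factors attached.  Exclusions are flags with reasons —
`poor_uptake` (session muscle AUC below threshold, default 0.01),
`roi_too_small` (fewer than 5 surviving voxels), `missing_value` — never
silent deletion; flagging is idempotent, and the statistics layer refuses
tables whose flagged rows have not been filtered.  Missing visits are
simply absent rows; the mixed model tolerates them.  The numeric defaults
are deliberately conservative and configurable.

## Group statistics

**Mixed model.** The repeated-measures analysis is a linear mixed model
with a per-animal random intercept, fixed effects for all main effects and
interactions of the design factors (Injury x Sex x Day; optionally
Region x Injury x Sex x Day with region as a second within factor), fitted
by REML (statsmodels MixedLM).  Factors are sum-to-zero coded so that each
term's Wald block test is the Type III omnibus test; with treatment coding
it would be a simple effect at the reference levels.  Omnibus F statistics
are Wald chi-square / numerator df.  Denominator df use the classical
between-within scheme: between-subject terms get n_subjects - n_cells;
terms involving within factors multiply that by prod(levels - 1) over the
within factors in the term.  Satterthwaite df would be the other natural
choice but is not exposed by the fitting backend; for the balanced phantom
designs the two coincide, and the test suite cross-checks the F statistics
against an independent REML implementation (R lme4/lmerTest) to 2%.
Type-I calibration is verified by simulation: 200 null-phantom cohorts give
an Injury x Day rejection rate statistically consistent with the nominal
5%.

**Post hocs.** Pairwise comparisons are explicitly enumerated families of
two-sided pooled-variance t tests with Bonferroni adjustment
p_adj = min(1, m p); the family and its size m are always recorded.

**Rank tests.** Kruskal–Wallis uses the standard H with the tie correction
1 - sum(t^3 - t)/(N^3 - N) and a chi-square reference on k-1 df; an
all-identical sample returns H = 0, p = 1.  The Mann–Whitney U test reports
U = min(U1, U2); the exact mode enumerates all C(n1+n2, n1) assignments of
the pooled mid-ranks (a permutation test, hence exact under ties) with
p = P(min(U1, U2) <= U_obs), used by default when both samples have at most
10 observations; otherwise the normal approximation with tie and continuity
corrections is used.  scipy's implementations serve as independent oracles
in the tests, not as the implementation, because scipy's exact mode does
not handle ties.

**Effect size.** Hedges' g = J (mean_x - mean_y)/s_pooled with the
small-sample correction J = 1 - 3/(4(n1+n2-2) - 1); zero pooled SD yields
NaN with a warning.  Separate analyses per injury regimen (single vs
repetitive impact) are supported by the `regimen` column; effect sizes are
the cross-regimen comparable quantity since absolute AUC depends on slice
geometry.

## Orchestration and reproducibility

`qmri run --config cohort.yaml --out DIR` executes simulate → fit-t2 →
dce-auc → roi-stats → group-stats; any failure aborts naming the stage
(exit code 3; config schema errors exit 2).  All randomness derives from a
single root seed through named substreams (one per animal-visit image), so
identical config + seed reproduces byte-identical tables; the run manifest
records the config snapshot, seed, package version and SHA-256 of every
output file.

## Problem sizes in the validation studies

The statistical simulation studies run the *full image pipeline* at a
reduced matrix (18 x 18 x 6, meninges/cortex/muscle tissue set) so that
hundreds of cohorts fit in a desk-scale run: type-I calibration uses 200
null cohorts at n = 4 animals per Injury x Sex cell; effect-size recovery
uses 50 cohorts at n = 10 per cell, against an analytic expectation that
propagates both the lognormal animal variance and the Rician measurement
noise of ROI-mean AUCs (delta method through the muscle ratio).  Relaxometry
accuracy is validated at the full 92 x 92 x 25 matrix.  These sizes are the
package's validation defaults; all are parameters.

## Known limitations

- The between-within denominator df is approximate under missing data
  (unbalanced designs); fractional Satterthwaite df are not computed.
- The exact Mann–Whitney enumeration is O(C(n1+n2, n1)) and is capped by
  default at n1, n2 <= 10.
- The phantom's enhancement kinetics and geometry are schematic (see
  above); absolute simulated AUC/T2 values carry no biological meaning
  beyond their configured ground truth.
- Histology quantification assumes single-channel intensity images; no
  color deconvolution or cell counting is attempted.
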