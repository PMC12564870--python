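# Methods

This note records how `braintraj` defines its statistics, what the
synthetic generator does and does not emulate, and the numerical and
design choices made where convention alone did not settle the question.

## Region taxonomy

The catalogue holds 95 structures: 45 bilateral pairs (aseg-style
subcortical labels such as `Left-Hippocampus`, DKT cortical labels such
as `ctx-lh-parstriangularis`) and 5 midline structures (3rd and 4th
ventricles, brain stem, CSF, WM hypointensities). The exact 95-name
roster is a reconstruction from the published region lists and summary
tables — no machine-readable roster was distributed with the source
study — and is therefore versioned here as data (`taxonomy.py`), with
aliases for common FreeSurfer spelling variants (`Left-Thalamus-Proper`
etc.).

Lobe grouping follows neuroanatomical convention with three deliberate
placements that differ from naive reading: the insula is grouped with
the temporal lobe, the lateral and inferior lateral ventricles go to
"other" (not subcortical), and the choroid plexus and ventral
diencephalon go to "subcortical". A separate, coarser six-group layout
(frontal, parietal, temporal, occipital, limbic, cerebellum) exists only
for the inter-pipeline agreement report; its "limbic" membership
(hippocampus, amygdala, entorhinal, parahippocampal, four cingulate
regions) is likewise a documented reconstruction.

Bilateral combination is done per subject as left + right, then
averaged across subjects. Summing per subject first is what makes the
per-bin SDs (and hence CIs) well defined; for the bin means it is
algebraically identical to summing the two hemisphere means.

## Confound correction

Per region, `V = β₀ + β₁·Sex + β₂·Age + Σγₖ·1{cohort k} + ε` is fitted
by OLS (sex: male = 1; reference cohort: lexicographically first unless
configured — the choice shifts corrected volumes by a constant that
cancels in every change statistic). Correction subtracts only the
fitted sex and cohort terms. Assumptions: additive, homoscedastic,
region-independent effects; age enters linearly in the correction model
(curvature is deliberately left in the residual so the trajectory stage
can see it).

**Verification includes age.** The verification refit tests the
residual sex and cohort coefficients *conditional on age*. With cohorts
that occupy different age ranges (one cohort contributes nothing under
51), a marginal cohort contrast on corrected volumes would simply
re-detect the preserved age trend and declare every cohort different —
a false alarm, not a failed correction. Conditioning on age makes the
verification test exactly the thing correction claims to have removed.
`verify_correction(include_age=False)` provides the marginal variant.

Multiplicity: one BH family per coefficient type — all regions' sex
tests in one family, all regions × cohort levels in another.

Effect sizes are pooled-SD Cohen's d (not Hedges g). Preservation
diagnostics: squared correlation of corrected volume with age
("age partial r²", marginal, not partialled for sex/cohort — the
corrected volumes have those removed already), and ICC(2,1) between raw
and corrected volumes across subjects.

## Age bins and change statistics

Seven inclusive integer bins, 21–30 … 81–90. Ages under 21 fold into
the youngest bin with a warning (source cohorts include a few
20-year-olds); ages over 90 are excluded with a warning. Bin summaries
exclude zero volumes (a zero from a segmenter means a failed structure,
not an empty one) and report mean ± SD with a 1.96·SEM 95% CI.

All change statistics use the symmetric percent change
`100·(b − a)/((a + b)/2)`: antisymmetric, scale-invariant, bounded in
(−200, 200). By construction the range change dominates both the
absolute endpoint change and the max consecutive change on every
series; this is asserted as a property test. Nonpositive volumes are a
signalled error, not a NaN.

## Trajectory shape classification

Linear and cubic polynomials are fitted by least squares to the seven
bin means against bin-midpoint ages (25.5, 35.5, …, 85.5). Midpoints
preserve year units for the coefficients; note that both R² values are
invariant to any affine re-coding of age (the spanned function space is
the same), so the R² improvement — cubic minus linear — does not depend
on this choice at all. The improvement is clipped at 0 (the models are
nested; small negative values are roundoff).

A region is non-monotonic only if (a) the improvement exceeds 0.2
(default, configurable) and (b) the cubic's derivative has a real root
strictly inside the open interval (first midpoint, last midpoint). A
local minimum ⇒ U-shaped, local maximum ⇒ inverted-U. When both
derivative roots are interior, the extremum whose fitted value deviates
more from the chord joining the curve's endpoints wins — the other
"extremum" of a cubic is always the shallow one created by the tail.
With fewer than four bins only the linear model is fitted.

Applied to the bundled reference bin means, this procedure labels
exactly seven of the fifty regions non-monotonic (caudate, pallidum,
insula U-shaped; entorhinal, hippocampus, amygdala, brain stem
inverted-U) with R² improvements from 0.231 to 0.766, and the
regenerated change columns agree with the published tables to one
decimal for 49 of 50 regions (the inferior lateral ventricle
recomputes to 116.5 against a printed 116.8 — a print inconsistency in
the source table).

## Agreement metrics

Paired pipelines are compared after bilateral combination by stacking
(subject, structure) observations within each lobe group:

* **ICC(2,1)** — two-way random effects, single measurement, absolute
  agreement (the method-comparison convention; computed via pingouin,
  cross-checked in tests against explicit ANOVA mean squares to 1e−10).
  Zero between-target variance is a signalled error.
* **CoV** — 100 · SD/mean over the pooled values of both pipelines.
* **D** — mean difference over the pooled between-observation SD.
* **RC** — Bland–Altman reproducibility coefficient, 1.96·SD of the
  paired differences.
* **R²** — squared Pearson correlation of the paired vectors.

Stacking heterogeneous structures inflates between-target variance, so
ICC and R² mostly index ranking/scale agreement across the pooled lobe,
and CoV is dominated by between-structure spread; RC and D remain
per-observation and are the sensitive quantities. This pooling is the
only one consistent with the intended per-observation RC behaviour
(pipeline noise σ ⇒ RC = 1.96σ).

## Synthetic generator

Each region: `V = f(age) + sex_delta·1{male} + cohort_offset +
N(0, noise_sd)`, volumes clipped at zero with a warning count. Defaults
(the "study-shaped" spec):

| parameter | default | rationale |
|---|---|---|
| cell counts | published cohort × bin × sex table (1832 subjects) | reproduces the design, incl. no ADNI-like subjects under 51 |
| f(age) | cubic LS fit of each region's published bin means | realistic trajectory shapes per region |
| noise_sd | region's published 21–30 bin SD (mm³) | realistic within-bin spread |
| cohort offsets | +0.5·noise_sd (IXI-like), −0.5·noise_sd (ADNI-like), 0 (reference) | pure mean shifts, the additive-γ model |
| sex_delta | calibrated per region for marginal Cohen's d = 0.427 | matches the reported pooled sex effect |

The sex calibration is closed-form: the pooled within-sex SD is
computed analytically from the demographic cells (uniform integer ages
per bin) as √(noise² + trajectory/cohort variance), and the small
male–female difference in age mix is netted out so the *marginal* d
hits the target. Ages are integers; bins are inclusive.

What the generator does **not** emulate: heteroscedasticity (real bin
SDs grow with age in ventricular regions; one SD per region is used),
between-region correlation (regions are sampled independently),
scanner/site effects beyond a mean shift, non-Gaussian tails, and any
longitudinal structure. Passing tests therefore demonstrate that the
*estimators* behave correctly under the design's sampling structure,
not that real data meet these assumptions.

Two empirical consequences, both computed by the test suite and the
acceptance script: (1) in the full synthetic study the dual correction
eliminates every cohort effect (0/50 regions at FDR < 0.05) and cuts
the mean |d| by ~80%; the residual post-correction sex effect is real,
not a bug — females in the design are on average 3.5 years older, so an
age-composition component (~0.05 d) plus a sampling floor (~0.04 d at
n ≈ 1830) survives any correct sex-coefficient removal. (2) the nominal
95% bin CIs cover at ~94.4%, not 95% — the z = 1.96 multiplier with a
sample SD at n = 50 per bin is exactly t-underscoverage
(2·F_t49(1.96) − 1 = 0.9443). The coverage simulation uses 10
independent regions × 7 bins × 1000 seeds so its Monte-Carlo SE
(≈0.09 pp) is well below the deviation being measured.

## Numerical choices

* Table-comparison rounding: half away from zero, matching printed
  display precision (`round_half_away`).
* Polynomial fits: `numpy.polynomial` (ascending coefficients);
  verified against explicit normal equations to 1e−8 in tests.
* BH-FDR: statsmodels step-up; verified against a brute-force
  sort-based oracle to 1e−12.
* Degenerate inputs raise typed errors (`DegenerateDataError`) rather
  than returning NaN: zero pooled SD, nonpositive volumes in percent
  changes, constant series in R², single-sex Cohen's d.
* CSV round-trips are exact: floats written at repr precision and read
  with `float_precision="round_trip"`.
* Rank-deficient confound designs (e.g. cohort perfectly confounded
  with sex) are a named error, not a silently dropped column.

## Limitations

* Cross-sectional summaries: bin-mean trajectories conflate age and
  generation effects; nothing here estimates within-person change.
* The 0.2 R²-improvement threshold is a convention; regions near it
  (cerebellar white matter reaches 0.199 on the reference table) can
  flip with small perturbations of the bin means.
* The agreement module quantifies pipeline interchangeability on
  tabular outputs only; it cannot diagnose *why* two segmenters
  disagree.
* Exact reproduction of the source study's pipeline-agreement table and
  demographics is out of scope: it requires the original MRI sample and
  both segmentation pipelines.
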