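# braintraj

Normative regional brain-volume trajectories across adulthood.

Cross-sectional volumetric MRI studies summarize how the ~95 structures of a
FreeSurfer/FastSurfer-style segmentation (DKT cortical parcels plus aseg
subcortical structures) change between young adulthood and old age. Doing
that honestly across several cohorts requires (1) removing sex and
scanner/cohort confounds without removing the age signal, (2) summarizing
bilateral volumes in decade age bins, (3) quantifying change with statistics
that are symmetric and scale-free, and (4) recognizing that some structures
do not change monotonically at all. `braintraj` packages that whole analysis
for anyone working with regional volume tables: neuroimaging researchers
building normative references, and methodologists who want the pieces
(confound residualization, symmetric percent change, ICC-based pipeline
agreement) as tested functions.

## The model

For each region, observed volume is modelled by OLS as

    V_i = β₀ + β₁·Sex_i + β₂·Age_i + Σₖ γₖ·1{Cohort_i = k} + ε_i

(sex coded male = 1, female = 0; one indicator per non-reference cohort) and
the *dual-corrected* volume subtracts only the fitted confound terms,

    V_i^corr = V_i − [β₁·Sex_i + Σₖ γₖ·1{Cohort_i = k}],

preserving the age trend and individual differences. A verification refit
tests the residual sex/cohort coefficients with Benjamini–Hochberg FDR
across regions.

Bilateral volumes (left + right) are summarized per decade bin (21–30 …
81–90; mean ± SD after excluding zero values, 95% CI from the SEM), and each
region's seven bin means V₁…V₇ yield three symmetric percent-change
statistics:

* endpoint change  = 100·(V₇ − V₁)/((V₇ + V₁)/2)
* max consecutive  = maxᵢ |100·(Vᵢ₊₁ − Vᵢ)/((Vᵢ₊₁ + Vᵢ)/2)|
* range change     = 100·(V_max − V_min)/((V_max + V_min)/2)

Linear and cubic polynomials are fitted to the bin means against bin-midpoint
age; a region is **U-shaped** (interior minimum) or **inverted-U** (interior
maximum) when the cubic improves R² over the line by more than 0.2 and its
derivative has a real root strictly inside the age range, else **linear**.

A separate module computes inter-pipeline segmentation agreement — ICC(2,1),
CoV, Cohen's D, Bland–Altman reproducibility coefficient and R² — pooled
within coarse lobe groups, for validating one segmenter against another.

Because the source cohorts cannot be redistributed, the package ships a
synthetic multi-cohort generator that reproduces the study design: three
cohorts with the published age-bin × sex cell counts (the ADNI-like cohort
has no subjects under 51), per-region trajectories and noise scales seeded
from the published bin statistics, additive cohort offsets, and a sex offset
calibrated to a marginal Cohen's d of 0.427.

## Worked example

```python
from braintraj.datasets import reference_bin_means
from braintraj.trajectories import change_metrics

metrics = change_metrics(reference_bin_means())
cols = ["endpoint_change", "range_change", "max_consecutive_change",
        "r2_improvement", "pattern"]
print(metrics.loc[["Caudate", "Hippocampus", "Thalamus",
                   "WM Hypointensities"], cols].round(3).to_string())
```

```
                    endpoint_change  range_change  max_consecutive_change  r2_improvement     pattern
region
Caudate                       6.643        10.443                   7.799           0.766    U-shaped
Hippocampus                 -11.280        12.735                   7.871           0.471  inverted-U
Thalamus                    -18.893        18.893                   5.656           0.042      linear
WM Hypointensities          122.589       122.589                  44.716           0.177      linear
```

Reading the rows: the caudate *grows* 6.6% endpoint-to-endpoint but swings
10.4% across bins with a mid-life minimum (U-shaped; the cubic fit explains
77 percentage points more variance than a line). The hippocampus loses 11.3%
young-to-old but follows an inverted-U with a mid-50s peak. The thalamus
declines 18.9% essentially linearly, and white-matter hypointensities — a
cerebrovascular-burden proxy — more than double (+122.6%), monotonically, so
their large R² gain is irrelevant (no interior extremum at the threshold).

The same pipeline runs end to end on any volume table (or a simulated one):

```bash
braintraj run --out results/ --seed 0          # simulate → correct → classify
braintraj regen-tables --out tables/           # tables from the bundled bin means
braintraj agree --a fs_volumes.csv --b cnn_volumes.csv --out agreement.tsv
```

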