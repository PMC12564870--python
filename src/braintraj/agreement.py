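"""Paired-method agreement metrics between two segmentation pipelines.

Given two volume tables for the same subjects (e.g. one from a CNN
segmenter and one from FreeSurfer), structures are combined bilaterally
and pooled within coarse anatomical groups; each group's paired
(subject, structure) volume vectors are compared with:

* ICC(2,1) - two-way random-effects, single-rater, absolute-agreement
  intraclass correlation (the method-comparison convention)
* CoV      - between-observation SD over the grand mean of the pooled
  values, as a percent
* D        - mean difference over the pooled between-observation SD
* RC       - Bland-Altman reproducibility coefficient, 1.96 * SD of the
  paired differences
* R^2      - squared Pearson correlation of the paired vectors
"""
from __future__ import annotations

import numpy as np
import pandas as pd
import pingouin as pg

from .core import DegenerateDataError, ValidationError, VolumeMatrix
from .io import combine_bilateral
from .taxonomy import RegionTaxonomy, VALIDATION_GROUPING, default_taxonomy

CI_Z = 1.96


def icc_paired(values_a, values_b) -> float:
    """ICC(2,1): two-way random, single rater/measurement, absolute agreement."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("paired vectors must be 1-D and equal length")
    n = a.size
    if n < 3:
        raise ValidationError("ICC needs at least 3 paired observations")
    if np.var((a + b) / 2, ddof=1) < 1e-12 * max(1.0, np.mean(np.abs(a)) ** 2):
        raise DegenerateDataError("zero between-target variance: ICC undefined")
    long = pd.DataFrame(
        {
            "target": np.tile(np.arange(n), 2),
            "rater": np.repeat(["A", "B"], n),
            "rating": np.concatenate([a, b]),
        }
    )
    table = pg.intraclass_corr(data=long, targets="target", raters="rater", ratings="rating")
    table = table.set_index("Type")
    # pingouin labels ICC(2,1) "ICC2" or "ICC(A,1)" depending on version
    key = "ICC(A,1)" if "ICC(A,1)" in table.index else "ICC2"
    return float(table.loc[key, "ICC"])


def cov_between_subject(values) -> float:
    """Coefficient of variation: 100 * SD / mean, sample SD."""
    v = np.asarray(values, dtype=float)
    mean = float(np.mean(v))
    if mean <= 0:
        raise DegenerateDataError("CoV undefined for non-positive mean")
    return float(100.0 * np.std(v, ddof=1) / mean)


def effect_size_d(values_a, values_b) -> float:
    """Cohen's D between paired sets with pooled between-subject SD."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    sa, sb = np.var(a, ddof=1), np.var(b, ddof=1)
    pooled = np.sqrt(((a.size - 1) * sa + (b.size - 1) * sb) / (a.size + b.size - 2))
    if pooled == 0:
        raise DegenerateDataError("zero pooled SD: effect size undefined")
    return float((np.mean(a) - np.mean(b)) / pooled)


def reproducibility_coefficient(differences) -> float:
    """Bland-Altman RC = 1.96 * SD of the paired differences."""
    d = np.asarray(differences, dtype=float)
    if d.size < 2:
        raise DegenerateDataError("RC needs at least 2 differences")
    return float(CI_Z * np.std(d, ddof=1))


def agreement_report(
    matrix_a: VolumeMatrix,
    matrix_b: VolumeMatrix,
    taxonomy: RegionTaxonomy | None = None,
    grouping: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Per-group agreement metrics between two pipelines' volume tables.

    Both matrices must cover the same subjects and regions. The default
    grouping is the six-group validation layout (frontal, parietal,
    temporal, occipital, limbic, cerebellum); pass any
    ``{group: [bilateral names]}`` mapping to override. A "Mean" row
    averages the metric columns across groups.
    """
    taxonomy = taxonomy or default_taxonomy()
    grouping = grouping or VALIDATION_GROUPING
    if set(matrix_a.subject_ids) != set(matrix_b.subject_ids):
        only_a = sorted(set(matrix_a.subject_ids) - set(matrix_b.subject_ids))
        only_b = sorted(set(matrix_b.subject_ids) - set(matrix_a.subject_ids))
        raise ValidationError(f"subject mismatch: only in A {only_a[:5]}, only in B {only_b[:5]}")
    bil_a = combine_bilateral(matrix_a, taxonomy)
    bil_b = combine_bilateral(matrix_b, taxonomy)
    bil_b = bil_b.with_volumes(bil_b.volumes.loc[bil_a.volumes.index])

    rows = []
    for group, names in grouping.items():
        names = [n for n in names if n in bil_a.region_set and n in bil_b.region_set]
        if not names:
            continue
        a = bil_a.volumes[names].to_numpy(dtype=float).ravel()
        b = bil_b.volumes[names].to_numpy(dtype=float).ravel()
        keep = ~(np.isnan(a) | np.isnan(b))
        a, b = a[keep], b[keep]
        diffs = a - b
        r = np.corrcoef(a, b)[0, 1]
        rows.append(
            dict(
                group=group,
                mean_a_mm3=float(np.mean(a)),
                mean_b_mm3=float(np.mean(b)),
                sd_diff_mm3=float(np.std(diffs, ddof=1)),
                icc=icc_paired(a, b),
                cov_percent=cov_between_subject(np.concatenate([a, b])),
                effect_size_d=effect_size_d(a, b),
                reproducibility_coefficient_mm3=reproducibility_coefficient(diffs),
                r_squared=float(r ** 2),
            )
        )
    report = pd.DataFrame(rows).set_index("group")
    mean_row = report.mean(numeric_only=True)
    mean_row.name = "Mean"
    return pd.concat([report, mean_row.to_frame().T])
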