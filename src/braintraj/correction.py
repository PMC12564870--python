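"""Regression-based dual correction of volumes for sex and cohort.

Each region's observed volume is modelled by ordinary least squares as

    V_i = b0 + b1 * Sex_i + b2 * Age_i + sum_k g_k * 1{Cohort_i = k} + e_i

with sex coded male=1 / female=0 and one indicator per non-reference
cohort. The corrected volume subtracts only the fitted sex and cohort
contributions,

    V_corrected_i = V_i - [b1 * Sex_i + sum_k g_k * 1{Cohort_i = k}],

leaving the age trend and individual residual untouched. Verification
refits the confound model on the corrected volumes and tests the
residual sex and cohort coefficients, with Benjamini-Hochberg FDR
adjustment across the region family (one family per coefficient type;
cohort levels are pooled into one family).

Note on the verification model: the residual cohort test is performed
conditional on age (age stays in the verification design). The three
cohorts have deliberately different age ranges, so a marginal cohort
contrast on corrected volumes would re-discover the age trend itself
rather than any uncorrected cohort effect.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .core import DegenerateDataError, ValidationError, VolumeMatrix


@dataclass
class CorrectionFit:
    """Fitted confound model for one region."""

    region: str
    beta0: float
    beta_sex: float
    beta_age: float
    gamma: dict[str, float]          # non-reference cohort -> offset (mm^3)
    residual_sd: float
    n_used: int
    reference_cohort: str
    p_sex: float = np.nan
    p_gamma: dict[str, float] = field(default_factory=dict)
    p_age: float = np.nan
    se_sex: float = np.nan
    se_age: float = np.nan
    se_gamma: dict[str, float] = field(default_factory=dict)


def _design(matrix: VolumeMatrix, reference_cohort: str | None, include_age: bool = True):
    sex = matrix.sex_indicator()
    age = matrix.meta["age"].to_numpy(dtype=float)
    cohorts = matrix.meta["cohort"]
    levels = sorted(cohorts.unique())
    reference = reference_cohort if reference_cohort is not None else levels[0]
    if reference not in levels:
        raise ValidationError(f"reference cohort {reference!r} not present (levels: {levels})")
    others = [c for c in levels if c != reference]
    cols = {"const": np.ones_like(sex), "sex": sex}
    if include_age:
        cols["age"] = age
    for c in others:
        cols[f"cohort[{c}]"] = (cohorts == c).astype(float).to_numpy()
    X = pd.DataFrame(cols, index=matrix.volumes.index)
    return X, reference, others


def fit_confound_model(
    matrix: VolumeMatrix, region: str, reference_cohort: str | None = None
) -> CorrectionFit:
    """OLS fit of one region's volume on sex, age and cohort indicators.

    The reference cohort (default: first in lexicographic order) gets no
    indicator; its fitted cohort contribution is zero by construction.
    """
    if region not in matrix.region_set:
        raise ValidationError(f"region {region!r} not in matrix")
    y = matrix.volumes[region]
    X, reference, others = _design(matrix, reference_cohort)
    keep = y.notna()
    y, X = y[keep], X[keep]
    if len(y) < X.shape[1]:
        raise ValidationError(f"{region}: fewer observations ({len(y)}) than parameters")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise ValidationError(
            f"{region}: design is rank deficient ({rank} < {X.shape[1]}); "
            "a confound is collinear (e.g. cohort confounded with sex or constant age)"
        )
    res = sm.OLS(y.to_numpy(), X.to_numpy()).fit()
    params = pd.Series(res.params, index=X.columns)
    pvals = pd.Series(res.pvalues, index=X.columns)
    bse = pd.Series(res.bse, index=X.columns)
    return CorrectionFit(
        region=region,
        beta0=float(params["const"]),
        beta_sex=float(params["sex"]),
        beta_age=float(params["age"]),
        gamma={c: float(params[f"cohort[{c}]"]) for c in others},
        residual_sd=float(np.sqrt(res.scale)),
        n_used=int(res.nobs),
        reference_cohort=reference,
        p_sex=float(pvals["sex"]),
        p_gamma={c: float(pvals[f"cohort[{c}]"]) for c in others},
        p_age=float(pvals["age"]),
        se_sex=float(bse["sex"]),
        se_age=float(bse["age"]),
        se_gamma={c: float(bse[f"cohort[{c}]"]) for c in others},
    )


def fit_all_regions(matrix: VolumeMatrix, reference_cohort: str | None = None) -> dict[str, CorrectionFit]:
    return {r: fit_confound_model(matrix, r, reference_cohort) for r in matrix.region_set}


def apply_correction(fits, matrix: VolumeMatrix) -> VolumeMatrix:
    """Subtract fitted sex and cohort contributions from each region.

    ``fits`` is one :class:`CorrectionFit` or a ``{region: fit}`` map.
    Regions without a fit pass through unchanged. Corrected volumes over
    reference-cohort females equal the raw values by construction.
    """
    if isinstance(fits, CorrectionFit):
        fits = {fits.region: fits}
    sex = matrix.sex_indicator()
    cohorts = matrix.meta["cohort"]
    corrected = matrix.volumes.copy()
    for region, fit in fits.items():
        if region not in corrected.columns:
            raise ValidationError(f"fit for unknown region {region!r}")
        known = set(fit.gamma) | {fit.reference_cohort}
        unknown = sorted(set(cohorts.unique()) - known)
        if unknown:
            raise ValidationError(f"{region}: cohort(s) {unknown} absent from fit")
        offsets = cohorts.map(lambda c: fit.gamma.get(c, 0.0)).to_numpy(dtype=float)
        corrected[region] = corrected[region] - (fit.beta_sex * sex + offsets)
    return matrix.with_volumes(corrected, provenance="corrected")


def correct_matrix(
    matrix: VolumeMatrix, reference_cohort: str | None = None
) -> tuple[VolumeMatrix, dict[str, CorrectionFit]]:
    """Fit and apply the dual correction to every region."""
    fits = fit_all_regions(matrix, reference_cohort)
    return apply_correction(fits, matrix), fits


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values for one family of tests."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def verify_correction(
    corrected: VolumeMatrix,
    reference_cohort: str | None = None,
    include_age: bool = True,
) -> pd.DataFrame:
    """Re-test sex and cohort effects on corrected volumes.

    Returns a long table with one row per (region, term); terms are
    ``sex`` and ``cohort[<name>]``. q-values are BH-adjusted within two
    families: all sex tests, and all cohort tests pooled across levels.
    """
    rows = []
    for region in corrected.region_set:
        y = corrected.volumes[region]
        X, reference, others = _design(corrected, reference_cohort, include_age=include_age)
        keep = y.notna()
        res = sm.OLS(y[keep].to_numpy(), X[keep].to_numpy()).fit()
        params = pd.Series(res.params, index=X.columns)
        pvals = pd.Series(res.pvalues, index=X.columns)
        rows.append(dict(region=region, term="sex", estimate=float(params["sex"]),
                         p_value=float(pvals["sex"])))
        for c in others:
            rows.append(dict(region=region, term=f"cohort[{c}]",
                             estimate=float(params[f"cohort[{c}]"]),
                             p_value=float(pvals[f"cohort[{c}]"])))
    table = pd.DataFrame(rows)
    table["q_value"] = np.nan
    for fam, mask in (
        ("sex", table["term"] == "sex"),
        ("cohort", table["term"].str.startswith("cohort")),
    ):
        if mask.any():
            table.loc[mask, "q_value"] = bh_fdr(table.loc[mask, "p_value"].to_numpy())
    return table


def sex_effect_d(matrix: VolumeMatrix, region: str) -> float:
    """Cohen's d (pooled-SD) of male minus female volumes for one region."""
    y = matrix.volumes[region]
    male = y[(matrix.meta["sex"] == "M") & y.notna()].to_numpy(dtype=float)
    female = y[(matrix.meta["sex"] == "F") & y.notna()].to_numpy(dtype=float)
    if male.size < 2 or female.size < 2:
        raise DegenerateDataError(f"{region}: both sexes needed for Cohen's d")
    pooled = np.sqrt(
        ((male.size - 1) * np.var(male, ddof=1) + (female.size - 1) * np.var(female, ddof=1))
        / (male.size + female.size - 2)
    )
    if pooled == 0:
        raise DegenerateDataError(f"{region}: zero pooled SD")
    return float((np.mean(male) - np.mean(female)) / pooled)


def preservation_metrics(raw: VolumeMatrix, corrected: VolumeMatrix) -> pd.DataFrame:
    """Per-region check that correction kept the biology.

    * ``age_partial_r2``: squared correlation of corrected volume with age
    * ``individual_icc``: ICC(2,1) between raw and corrected volumes
    """
    from .agreement import icc_paired  # local import avoids a cycle

    if set(raw.subject_ids) != set(corrected.subject_ids):
        raise ValidationError("raw and corrected matrices must share subjects")
    age = raw.meta["age"].to_numpy(dtype=float)
    rows = []
    for region in raw.region_set:
        a = raw.volumes[region].to_numpy(dtype=float)
        c = corrected.volumes.loc[raw.volumes.index, region].to_numpy(dtype=float)
        keep = ~(np.isnan(a) | np.isnan(c))
        if np.var(c[keep]) == 0:
            raise DegenerateDataError(f"{region}: constant corrected volumes")
        r = np.corrcoef(c[keep], age[keep])[0, 1]
        rows.append(dict(region=region, age_partial_r2=float(r ** 2),
                         individual_icc=icc_paired(a[keep], c[keep])))
    return pd.DataFrame(rows).set_index("region")
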