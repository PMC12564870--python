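"""Confound model fitting, residualization, verification and BH-FDR."""
import numpy as np
import pandas as pd
import pytest

from braintraj.core import DegenerateDataError, ValidationError, VolumeMatrix
from braintraj.correction import (
    CorrectionFit,
    apply_correction,
    bh_fdr,
    correct_matrix,
    fit_all_regions,
    fit_confound_model,
    preservation_metrics,
    sex_effect_d,
    verify_correction,
)
from braintraj.synthetic import RegionParams, SyntheticSpec, generate_volumes


def bh_oracle(p):
    """Step-up q-values straight from the sorting definition."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    running_min = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running_min = min(running_min, p[idx] * m / rank)
        q[idx] = running_min
    return q


def two_cohort_matrix(n=3000, beta_sex=200.0, gamma_ixi=-300.0, slope=-20.0,
                      noise=150.0, seed=0):
    rng = np.random.default_rng(seed)
    cohort = rng.choice(["Korean", "IXI"], n)
    sex = rng.choice(["M", "F"], n)
    age = rng.integers(21, 91, n).astype(float)
    v = (
        20000.0
        + beta_sex * (sex == "M")
        + slope * age
        + gamma_ixi * (cohort == "IXI")
        + rng.normal(0, noise, n)
    )
    meta = pd.DataFrame(
        {"cohort": cohort, "age": age, "sex": sex},
        index=pd.Index([f"s{i}" for i in range(n)], name="subject_id"),
    )
    return VolumeMatrix(pd.DataFrame({"R": v}, index=meta.index), meta)


class TestFit:
    def test_parameter_recovery_within_3se(self):
        matrix = two_cohort_matrix()
        fit = fit_confound_model(matrix, "R", reference_cohort="Korean")
        assert abs(fit.beta_sex - 200.0) < 3 * fit.se_sex
        assert abs(fit.beta_age - (-20.0)) < 3 * fit.se_age
        assert abs(fit.gamma["IXI"] - (-300.0)) < 3 * fit.se_gamma["IXI"]
        assert fit.n_used == 3000

    def test_noiseless_single_cohort_is_exact(self):
        age = np.arange(21, 41, dtype=float)
        meta = pd.DataFrame(
            {"cohort": "K", "age": age, "sex": ["M", "F"] * 10},
            index=pd.Index([f"s{i}" for i in range(20)], name="subject_id"),
        )
        v = 5000.0 - 12.5 * age  # pure linear age trend, no sex effect
        matrix = VolumeMatrix(pd.DataFrame({"R": v}, index=meta.index), meta)
        fit = fit_confound_model(matrix, "R")
        assert fit.beta_sex == pytest.approx(0.0, abs=1e-9)
        assert fit.beta_age == pytest.approx(-12.5, abs=1e-9)
        assert fit.gamma == {}

    def test_subject_order_invariance(self):
        matrix = two_cohort_matrix(n=400, seed=4)
        shuffled = VolumeMatrix(
            matrix.volumes.iloc[::-1].copy(), matrix.meta.iloc[::-1].copy()
        )
        f1 = fit_confound_model(matrix, "R", "Korean")
        f2 = fit_confound_model(shuffled, "R", "Korean")
        assert f1.beta_sex == pytest.approx(f2.beta_sex, rel=1e-10)
        assert f1.gamma["IXI"] == pytest.approx(f2.gamma["IXI"], rel=1e-10)

    def test_collinear_design_is_named(self):
        # cohort perfectly confounded with sex
        meta = pd.DataFrame(
            {"cohort": ["A"] * 5 + ["B"] * 5, "age": np.arange(30, 40, dtype=float),
             "sex": ["M"] * 5 + ["F"] * 5},
            index=pd.Index([f"s{i}" for i in range(10)], name="subject_id"),
        )
        matrix = VolumeMatrix(
            pd.DataFrame({"R": np.linspace(1000, 2000, 10)}, index=meta.index), meta
        )
        with pytest.raises(ValidationError, match="rank deficient"):
            fit_confound_model(matrix, "R")


class TestApply:
    def _manual_fit(self):
        return CorrectionFit(
            region="R", beta0=0.0, beta_sex=200.0, beta_age=0.0,
            gamma={"k": -300.0}, residual_sd=1.0, n_used=10, reference_cohort="ref",
        )

    def test_forced_arithmetic(self):
        fit = self._manual_fit()
        meta = pd.DataFrame(
            {"cohort": ["ref", "k"], "age": [40, 40], "sex": ["M", "M"]},
            index=pd.Index(["a", "b"], name="subject_id"),
        )
        matrix = VolumeMatrix(
            pd.DataFrame({"R": [10000.0, 10000.0]}, index=meta.index), meta
        )
        out = apply_correction(fit, matrix)
        assert out.volumes.loc["a", "R"] == pytest.approx(9800.0)   # - beta_sex
        assert out.volumes.loc["b", "R"] == pytest.approx(10100.0)  # - (200 - 300)
        assert out.provenance == "corrected"

    def test_reference_cohort_females_unchanged(self):
        fit = self._manual_fit()
        meta = pd.DataFrame(
            {"cohort": ["ref", "ref"], "age": [30, 60], "sex": ["F", "F"]},
            index=pd.Index(["a", "b"], name="subject_id"),
        )
        matrix = VolumeMatrix(
            pd.DataFrame({"R": [5000.0, 4000.0]}, index=meta.index), meta
        )
        out = apply_correction(fit, matrix)
        assert out.volumes["R"].tolist() == [5000.0, 4000.0]

    def test_unknown_cohort_rejected(self):
        fit = self._manual_fit()
        meta = pd.DataFrame(
            {"cohort": ["mystery"], "age": [40], "sex": ["F"]},
            index=pd.Index(["a"], name="subject_id"),
        )
        matrix = VolumeMatrix(pd.DataFrame({"R": [1.0]}, index=meta.index), meta)
        with pytest.raises(ValidationError, match="mystery"):
            apply_correction(fit, matrix)

    def test_cohort_gap_removed(self):
        matrix = two_cohort_matrix(seed=2)
        corrected, fits = correct_matrix(matrix, "Korean")
        ver = verify_correction(corrected, "Korean")
        cohort_rows = ver[ver["term"].str.startswith("cohort")]
        assert np.allclose(cohort_rows["estimate"], 0.0, atol=1e-8)
        assert (ver["q_value"] > 0.9).all()

    def test_idempotent_on_corrected_data(self):
        matrix = two_cohort_matrix(seed=6)
        corrected, _ = correct_matrix(matrix, "Korean")
        fit2 = fit_confound_model(corrected, "R", "Korean")
        assert abs(fit2.beta_sex) < 3 * fit2.se_sex
        assert abs(fit2.gamma["IXI"]) < 3 * fit2.se_gamma["IXI"]
        twice, _ = correct_matrix(corrected, "Korean")
        assert np.allclose(twice.volumes["R"], corrected.volumes["R"], atol=1e-6)

    def test_noiseless_residual_sex_effect_exactly_zero(self):
        age = np.tile(np.arange(21, 31, dtype=float), 2)
        meta = pd.DataFrame(
            {"cohort": "K", "age": age, "sex": ["M"] * 10 + ["F"] * 10},
            index=pd.Index([f"s{i}" for i in range(20)], name="subject_id"),
        )
        v = 1000.0 + 200.0 * (meta["sex"] == "M") + 5.0 * age
        matrix = VolumeMatrix(pd.DataFrame({"R": v}, index=meta.index), meta)
        true_fit = CorrectionFit(
            region="R", beta0=1000.0, beta_sex=200.0, beta_age=5.0,
            gamma={}, residual_sd=0.0, n_used=20, reference_cohort="K",
        )
        corrected = apply_correction(true_fit, matrix)
        delta = fit_confound_model(corrected, "R", "K").beta_sex
        assert delta == pytest.approx(0.0, abs=1e-9)


class TestBH:
    def test_forced_vector(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04, 1.0])
        np.testing.assert_allclose(q, [0.05, 0.05, 0.05, 0.05, 1.0], atol=1e-12)

    def test_degenerate_vectors(self):
        np.testing.assert_array_equal(bh_fdr([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])
        assert bh_fdr([0.37]) == pytest.approx([0.37])
        with pytest.raises(ValidationError):
            bh_fdr([0.5, 1.5])

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(123)
        for _ in range(100):
            p = rng.uniform(0, 1, rng.integers(1, 40))
            np.testing.assert_allclose(bh_fdr(p), bh_oracle(p), atol=1e-12)


class TestEffectSizeAndPreservation:
    def test_sex_effect_d_cases(self):
        meta = pd.DataFrame(
            {"cohort": "K", "age": 30.0, "sex": ["M"] * 4 + ["F"] * 4},
            index=pd.Index([f"s{i}" for i in range(8)], name="subject_id"),
        )
        base = np.array([1.0, 2.0, 3.0, 4.0])
        equal = VolumeMatrix(
            pd.DataFrame({"R": np.concatenate([base, base])}, index=meta.index), meta
        )
        assert sex_effect_d(equal, "R") == 0.0
        sd = np.std(base, ddof=1)
        shifted = VolumeMatrix(
            pd.DataFrame({"R": np.concatenate([base + sd, base])}, index=meta.index), meta
        )
        assert sex_effect_d(shifted, "R") == pytest.approx(1.0)

    def test_sex_effect_d_simulation(self):
        rng = np.random.default_rng(9)
        n = 100_000
        meta = pd.DataFrame(
            {"cohort": "K", "age": 30.0, "sex": ["M"] * n + ["F"] * n},
            index=pd.Index([f"s{i}" for i in range(2 * n)], name="subject_id"),
        )
        v = 100.0 + np.concatenate([rng.normal(0.427, 1.0, n), rng.normal(0.0, 1.0, n)])
        matrix = VolumeMatrix(pd.DataFrame({"R": v}, index=meta.index), meta)
        assert sex_effect_d(matrix, "R") == pytest.approx(0.427, abs=0.02)

    def test_one_sex_absent_signalled(self, tiny_matrix):
        with pytest.raises(DegenerateDataError):
            sex_effect_d(tiny_matrix, "Hippocampus")

    def test_preservation_identity_and_pure_age(self):
        age = np.arange(21, 91, dtype=float)
        meta = pd.DataFrame(
            {"cohort": "K", "age": age, "sex": ["M", "F"] * 35},
            index=pd.Index([f"s{i}" for i in range(70)], name="subject_id"),
        )
        v = 9000.0 - 15.0 * age  # noiseless pure-age signal
        matrix = VolumeMatrix(pd.DataFrame({"R": v}, index=meta.index), meta)
        metrics = preservation_metrics(matrix, matrix)
        assert metrics.loc["R", "individual_icc"] == pytest.approx(1.0, abs=1e-9)
        assert metrics.loc["R", "age_partial_r2"] == pytest.approx(1.0, abs=1e-12)

    def test_preservation_known_age_variance_share(self):
        rng = np.random.default_rng(31)
        n = 5000
        age = rng.integers(21, 91, n).astype(float)
        signal = 10.0 * age
        # choose noise so age explains ~30% of total variance
        noise_sd = np.sqrt(np.var(signal) * 0.7 / 0.3)
        meta = pd.DataFrame(
            {"cohort": "K", "age": age, "sex": rng.choice(["M", "F"], n)},
            index=pd.Index([f"s{i}" for i in range(n)], name="subject_id"),
        )
        v = 50000.0 + signal + rng.normal(0, noise_sd, n)
        matrix = VolumeMatrix(pd.DataFrame({"R": v}, index=meta.index), meta)
        metrics = preservation_metrics(matrix, matrix)
        assert metrics.loc["R", "age_partial_r2"] == pytest.approx(0.3, abs=0.03)
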