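"""Synthetic multi-cohort volume data with the structure the analysis assumes.

Each subject's volume for a region is

    V = f(age) + sex_delta * 1{male} + cohort_offset + N(0, noise_sd)

with ``f`` a linear or cubic polynomial in age (years). Demographics are
drawn per (cohort, age-bin, sex) cell with fixed counts; ages are
integers uniform within the bin. The default specification mirrors the
three-cohort study design: cell counts follow the published demographic
table (the ADNI cohort contributes nothing below the 51-60 bin), each
region's age polynomial and noise scale are seeded from the published
per-bin means/SDs, cohort offsets are +/- half a noise SD, and the sex
offset is calibrated so the marginal Cohen's d between sexes is 0.427.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import datasets
from .core import DataQualityWarning, ValidationError, VolumeMatrix
from .datasets import AGE_BINS, BIN_RANGES

DEFAULT_SEX_D = 0.427
DEFAULT_COHORT_OFFSET_SCALE = 0.5
DEFAULT_REFERENCE_COHORT = "Korean"


@dataclass
class RegionParams:
    """Generative parameters for one bilateral region."""

    name: str
    coeffs: tuple                  # polynomial in age, ascending powers; len 2 (linear) or 4 (cubic)
    noise_sd: float
    sex_delta: float = 0.0         # mm^3 added for males
    cohort_offsets: dict[str, float] = field(default_factory=dict)

    def trajectory(self, age) -> np.ndarray:
        return np.polynomial.polynomial.polyval(np.asarray(age, dtype=float), np.asarray(self.coeffs))


@dataclass
class SyntheticSpec:
    """Full recipe for one synthetic dataset."""

    cells: pd.DataFrame            # cohort, age_bin, n_male, n_female
    regions: dict[str, RegionParams]
    reference_cohort: str = DEFAULT_REFERENCE_COHORT
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self) -> "SyntheticSpec":
        required = {"cohort", "age_bin", "n_male", "n_female"}
        if not required.issubset(self.cells.columns):
            raise ValidationError(f"cells table needs columns {sorted(required)}")
        bad_bins = set(self.cells["age_bin"]) - set(AGE_BINS)
        if bad_bins:
            raise ValidationError(f"unknown age bin(s): {sorted(bad_bins)}")
        if int(self.cells[["n_male", "n_female"]].to_numpy().sum()) == 0:
            raise ValidationError("spec describes zero subjects")
        if not self.regions:
            raise ValidationError("spec has no regions")
        for p in self.regions.values():
            if p.noise_sd <= 0:
                raise ValidationError(f"{p.name}: noise_sd must be > 0")
            if len(p.coeffs) not in (2, 4):
                raise ValidationError(f"{p.name}: trajectory must be linear (2) or cubic (4) coefficients")
            if p.cohort_offsets.get(self.reference_cohort, 0.0) != 0.0:
                raise ValidationError(f"{p.name}: reference cohort offset must be 0")
        return self

    # -- (de)serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return dict(
            reference_cohort=self.reference_cohort,
            seed=int(self.seed),
            cells=self.cells.to_dict(orient="records"),
            regions={
                n: dict(coeffs=[float(c) for c in p.coeffs], noise_sd=float(p.noise_sd),
                        sex_delta=float(p.sex_delta),
                        cohort_offsets={k: float(v) for k, v in p.cohort_offsets.items()})
                for n, p in self.regions.items()
            },
        )

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticSpec":
        regions = {
            n: RegionParams(name=n, coeffs=tuple(rp["coeffs"]), noise_sd=rp["noise_sd"],
                            sex_delta=rp.get("sex_delta", 0.0),
                            cohort_offsets=dict(rp.get("cohort_offsets", {})))
            for n, rp in d["regions"].items()
        }
        return cls(cells=pd.DataFrame(d["cells"]), regions=regions,
                   reference_cohort=d.get("reference_cohort", DEFAULT_REFERENCE_COHORT),
                   seed=int(d.get("seed", 0)))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def sample_demographics(spec: SyntheticSpec, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw (cohort, age, sex) for every subject described by the cells.

    Ages are integers uniform in the bin's inclusive range; counts per
    (cohort, bin, sex) cell are exact. Deterministic under a seeded rng.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    rows = []
    counter = 0
    for rec in spec.cells.sort_values(["cohort", "age_bin"]).itertuples():
        lo, hi = BIN_RANGES[rec.age_bin]
        for sex, n in (("M", int(rec.n_male)), ("F", int(rec.n_female))):
            ages = rng.integers(lo, hi + 1, size=n)
            for a in ages:
                rows.append((f"{rec.cohort}-{counter:05d}", rec.cohort, int(a), sex))
                counter += 1
    if not rows:
        raise ValidationError("spec describes zero subjects")
    return pd.DataFrame(rows, columns=["subject_id", "cohort", "age", "sex"]).set_index("subject_id")


def generate_volumes(spec: SyntheticSpec, seed: int | None = None) -> VolumeMatrix:
    """Generate a full synthetic :class:`VolumeMatrix` (provenance "synthetic")."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    meta = sample_demographics(spec, rng)
    male = (meta["sex"] == "M").to_numpy(dtype=float)
    age = meta["age"].to_numpy(dtype=float)
    cohort = meta["cohort"]
    volumes = {}
    n_clipped = 0
    for name, p in spec.regions.items():
        offsets = cohort.map(lambda c: p.cohort_offsets.get(c, 0.0)).to_numpy(dtype=float)
        v = p.trajectory(age) + p.sex_delta * male + offsets + rng.normal(0.0, p.noise_sd, size=len(meta))
        clipped = v < 0
        n_clipped += int(clipped.sum())
        v[clipped] = 0.0
        volumes[name] = v
    if n_clipped:
        warnings.warn(f"{n_clipped} negative volume(s) clipped to 0", DataQualityWarning, stacklevel=2)
    vol_df = pd.DataFrame(volumes, index=meta.index)
    return VolumeMatrix(vol_df, meta, provenance="synthetic")


def write_fixture(matrix: VolumeMatrix, path) -> None:
    """Write a generated matrix as a delimited fixture (lossless round-trip)."""
    from .io import write_volume_table  # local import: io depends on core only

    write_volume_table(matrix, path)


# ---------------------------------------------------------------------------
# default three-cohort specification
# ---------------------------------------------------------------------------

def _expected_demographic_moments(cells: pd.DataFrame, params: RegionParams):
    """Per-sex expectation and variance of the deterministic volume part.

    Treats age as uniform over each bin's integers and weights by the
    exact cell counts, so the calibration needs no sampling.
    """
    stats = {}
    for sex_col, sex in (("n_male", "M"), ("n_female", "F")):
        total_w = 0.0
        ex = 0.0
        ex2 = 0.0
        for rec in cells.itertuples():
            n = float(getattr(rec, sex_col))
            if n == 0:
                continue
            lo, hi = BIN_RANGES[rec.age_bin]
            ages = np.arange(lo, hi + 1, dtype=float)
            g = params.trajectory(ages) + params.cohort_offsets.get(rec.cohort, 0.0)
            total_w += n
            ex += n * g.mean()
            ex2 += n * (g ** 2).mean()
        mean = ex / total_w
        var = ex2 / total_w - mean ** 2
        stats[sex] = (total_w, mean, var)
    return stats


def calibrate_sex_delta(cells: pd.DataFrame, params: RegionParams, target_d: float = DEFAULT_SEX_D) -> float:
    """Sex offset (mm^3) giving the requested marginal Cohen's d.

    The pooled within-sex SD combines trajectory/cohort variance (from
    the demographic mix) with the noise SD; the male and female age
    mixes differ slightly, so their trajectory means are netted out.
    """
    stats = _expected_demographic_moments(cells, params)
    (n_m, mu_m, var_m), (n_f, mu_f, var_f) = stats["M"], stats["F"]
    pooled = np.sqrt(
        ((n_m - 1) * (var_m + params.noise_sd ** 2) + (n_f - 1) * (var_f + params.noise_sd ** 2))
        / (n_m + n_f - 2)
    )
    return float(target_d * pooled - (mu_m - mu_f))


def default_spec(
    seed: int = 0,
    target_sex_d: float = DEFAULT_SEX_D,
    cohort_offset_scale: float = DEFAULT_COHORT_OFFSET_SCALE,
    n_scale: float = 1.0,
) -> SyntheticSpec:
    """The study-shaped default: 50 regions, 3 cohorts, ~1830 subjects.

    Region trajectories are the cubic least-squares fits of the
    published bin means (midpoint age encoding); noise SDs are the
    published 21-30 bin SDs; cohort offsets are ``+scale*noise_sd`` for
    IXI and ``-scale*noise_sd`` for ADNI relative to the Korean
    reference; sex offsets are calibrated per region for the target
    marginal d. ``n_scale`` multiplies every cell count (rounded).
    """
    cells = datasets.cohort_cell_counts().copy()
    if n_scale != 1.0:
        cells["n_male"] = np.rint(cells["n_male"] * n_scale).astype(int)
        cells["n_female"] = np.rint(cells["n_female"] * n_scale).astype(int)
    means = datasets.reference_bin_means()
    sds = datasets.reference_bin_sds()
    x = datasets.bin_midpoint_array()
    regions = {}
    for name in means.columns:
        y = means[name].to_numpy(dtype=float)
        coeffs = tuple(float(c) for c in np.polynomial.polynomial.polyfit(x, y, 3))
        noise_sd = float(sds[name].iloc[0])
        params = RegionParams(
            name=name,
            coeffs=coeffs,
            noise_sd=noise_sd,
            cohort_offsets={
                "IXI": cohort_offset_scale * noise_sd,
                "ADNI": -cohort_offset_scale * noise_sd,
            },
        )
        params.sex_delta = calibrate_sex_delta(cells, params, target_sex_d)
        regions[name] = params
    return SyntheticSpec(cells=cells, regions=regions,
                         reference_cohort=DEFAULT_REFERENCE_COHORT, seed=seed)
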