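"""Bundled reference tables and the study's age-bin layout.

Two small CSVs ship with the package:

* ``reference_bin_stats.csv`` - published per-age-bin mean and SD of the
  50 bilateral/midline structure volumes (mm^3), the analysis-ready
  summary the trajectory stage consumes.
* ``cohort_cell_counts.csv`` - male/female counts per (cohort, age bin)
  for the three source cohorts (Korean, IXI, ADNI; the ADNI cohort
  contributes no subjects below the 51-60 bin). These counts drive the
  synthetic generator's demographics.

Ages are grouped into seven decade bins, 21-30 through 81-90.
"""
from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

AGE_BINS = ("21-30", "31-40", "41-50", "51-60", "61-70", "71-80", "81-90")
BIN_RANGES = {b: (int(b[:2]), int(b[-2:])) for b in AGE_BINS}
# Midpoint of the integer-age bin, used as the abscissa for polynomial fits.
BIN_MIDPOINTS = {b: (lo + hi) / 2 for b, (lo, hi) in BIN_RANGES.items()}


def _read_packaged(name: str) -> pd.DataFrame:
    with resources.files("braintraj.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def reference_bin_stats() -> pd.DataFrame:
    """Long table: region, age_bin, mean_mm3, sd_mm3 (50 x 7 rows)."""
    return _read_packaged("reference_bin_stats.csv")


def reference_bin_means() -> pd.DataFrame:
    """Wide table of published bin means: index age_bin, one column per region."""
    long = reference_bin_stats()
    wide = long.pivot(index="age_bin", columns="region", values="mean_mm3")
    return wide.loc[list(AGE_BINS)]


def reference_bin_sds() -> pd.DataFrame:
    """Wide table of published bin SDs, same layout as the means."""
    long = reference_bin_stats()
    wide = long.pivot(index="age_bin", columns="region", values="sd_mm3")
    return wide.loc[list(AGE_BINS)]


def cohort_cell_counts() -> pd.DataFrame:
    """Long table: cohort, age_bin, n_male, n_female."""
    return _read_packaged("cohort_cell_counts.csv")


def bin_midpoint_array() -> np.ndarray:
    return np.array([BIN_MIDPOINTS[b] for b in AGE_BINS])
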