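"""Core containers and exceptions.

The pipeline's universal currency is the :class:`VolumeMatrix`: a
subjects x regions table of structure volumes (mm^3) together with
per-subject metadata (cohort label, age in years, sex).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

META_COLUMNS = ("cohort", "age", "sex")

SEX_ALIASES = {
    "m": "M", "male": "M", "1": "M",
    "f": "F", "female": "F", "0": "F",
}


class BrainTrajError(Exception):
    """Base class for all package errors."""


class FormatError(BrainTrajError):
    """A file did not match the expected dialect or layout."""


class ValidationError(BrainTrajError):
    """Input data violated a contract (bad metadata, bad volumes...)."""


class DegenerateDataError(BrainTrajError):
    """A statistic is undefined on the given data (zero variance etc.)."""


class DataQualityWarning(UserWarning):
    """Recoverable data issues: excluded rows, clipped values, empty bins."""


def normalize_sex(value) -> str:
    s = str(value).strip()
    if s in ("M", "F"):
        return s
    key = s.lower()
    if key in SEX_ALIASES:
        return SEX_ALIASES[key]
    raise ValidationError(f"unknown sex code: {value!r} (expected M/F)")


@dataclass
class VolumeMatrix:
    """Subjects x regions volume table with subject metadata.

    Parameters
    ----------
    volumes:
        DataFrame indexed by unique ``subject_id`` with one float column
        per region (mm^3, >= 0; NaN marks a missing region).
    meta:
        DataFrame on the same index with columns ``cohort`` (str),
        ``age`` (years, in [0, 120]) and ``sex`` ("M"/"F").
    provenance:
        Free-text origin tag: ``raw``, ``corrected`` or ``synthetic``.
    """

    volumes: pd.DataFrame
    meta: pd.DataFrame
    provenance: str = "raw"
    _validated: bool = field(default=False, repr=False, compare=False)

    def __post_init__(self):
        self.validate()

    # -- contracts ---------------------------------------------------------
    def validate(self) -> "VolumeMatrix":
        if not self.volumes.index.is_unique:
            dupes = self.volumes.index[self.volumes.index.duplicated()].unique()
            raise ValidationError(f"duplicate subject_ids: {list(dupes)[:5]}")
        if not self.volumes.index.equals(self.meta.index):
            raise ValidationError("volumes and meta must share the same subject index")
        missing = [c for c in META_COLUMNS if c not in self.meta.columns]
        if missing:
            raise ValidationError(f"metadata columns missing: {missing}")
        ages = pd.to_numeric(self.meta["age"], errors="coerce")
        if ages.isna().any():
            bad = self.meta.index[ages.isna()][:5]
            raise ValidationError(f"non-numeric ages for subjects {list(bad)}")
        if ((ages < 0) | (ages > 120)).any():
            bad = self.meta.index[(ages < 0) | (ages > 120)][:5]
            raise ValidationError(f"ages outside [0, 120] for subjects {list(bad)}")
        self.meta = self.meta.assign(
            age=ages, sex=self.meta["sex"].map(normalize_sex), cohort=self.meta["cohort"].astype(str)
        )
        vols = self.volumes.apply(pd.to_numeric, errors="coerce")
        newly_bad = vols.isna() & self.volumes.notna()
        if newly_bad.any().any():
            subj = self.volumes.index[newly_bad.any(axis=1)][0]
            raise ValidationError(f"non-numeric volume cell(s), first in subject {subj!r}")
        # residualized (corrected) volumes may legitimately go negative
        if self.provenance != "corrected" and (vols < 0).any().any():
            subj = vols.index[(vols < 0).any(axis=1)][0]
            raise ValidationError(f"negative volume(s), first in subject {subj!r}")
        self.volumes = vols.astype(float)
        if self.volumes.isna().any().any():
            n = int(self.volumes.isna().sum().sum())
            warnings.warn(f"{n} missing region value(s) flagged as NaN", DataQualityWarning, stacklevel=2)
        self._validated = True
        return self

    # -- conveniences ------------------------------------------------------
    @property
    def subject_ids(self) -> list:
        return list(self.volumes.index)

    @property
    def region_set(self) -> list:
        return list(self.volumes.columns)

    @property
    def n_subjects(self) -> int:
        return len(self.volumes)

    def region(self, name: str) -> pd.Series:
        return self.volumes[name]

    def with_volumes(self, volumes: pd.DataFrame, provenance: str | None = None) -> "VolumeMatrix":
        return VolumeMatrix(volumes, self.meta.copy(), provenance or self.provenance)

    def equals(self, other: "VolumeMatrix") -> bool:
        return (
            self.volumes.equals(other.volumes)
            and self.meta[list(META_COLUMNS)].equals(other.meta[list(META_COLUMNS)])
        )

    def to_frame(self) -> pd.DataFrame:
        """Single flat table: subject_id index, metadata then region columns."""
        return pd.concat([self.meta[list(META_COLUMNS)], self.volumes], axis=1)

    def sex_indicator(self) -> np.ndarray:
        """Sex coded male=1, female=0, as used by the confound models."""
        return (self.meta["sex"].to_numpy() == "M").astype(float)
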