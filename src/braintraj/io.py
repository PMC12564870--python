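"""Reading and writing regional volume data.

Two whitespace-column "stats" dialects are supported, matching the
per-subject summary files emitted by FreeSurfer-family segmenters:

* ``aseg``  - subcortical table; volume in the ``Volume_mm3`` column,
  structure label in ``StructName``.
* ``aparc`` - cortical parcellation table; gray-matter volume in the
  ``GrayVol`` column, label in ``StructName``.

Both start with ``#``-prefixed header lines; the ``# ColHeaders`` line
names the data columns. Cohort-level data travels as a delimited table
with columns ``subject_id, cohort, age, sex, <region...>``.
"""
from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .core import DataQualityWarning, FormatError, ValidationError, VolumeMatrix, META_COLUMNS
from .taxonomy import RegionTaxonomy, default_taxonomy

_DIALECT_VOLUME_COLUMN = {"aseg": "Volume_mm3", "aparc": "GrayVol"}
_LABEL_COLUMN = "StructName"


def _as_text_stream(source):
    if hasattr(source, "read"):
        return source
    return open(source, "r")


def parse_stats_file(source, dialect: str = "aseg") -> dict[str, float]:
    """Parse one stats file into a ``{structure: volume mm^3}`` map.

    Unparseable data rows are reported via :class:`DataQualityWarning`,
    never silently dropped. Duplicate structure labels raise.
    """
    if dialect not in _DIALECT_VOLUME_COLUMN:
        raise FormatError(f"unknown stats dialect {dialect!r} (expected aseg or aparc)")
    volume_col = _DIALECT_VOLUME_COLUMN[dialect]

    columns: list[str] | None = None
    volumes: dict[str, float] = {}
    bad_rows: list[str] = []
    n_data = 0
    stream = _as_text_stream(source)
    try:
        for line in stream:
            line = line.rstrip("\n")
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.startswith("ColHeaders"):
                    columns = body.split()[1:]
                continue
            if not line.strip():
                continue
            n_data += 1
            if columns is None:
                bad_rows.append(line)
                continue
            tokens = line.split()
            if len(tokens) != len(columns):
                bad_rows.append(line)
                continue
            row = dict(zip(columns, tokens))
            if volume_col not in row or _LABEL_COLUMN not in row:
                raise FormatError(
                    f"{dialect} dialect requires columns {_LABEL_COLUMN} and {volume_col}; "
                    f"file has {columns}"
                )
            label = row[_LABEL_COLUMN]
            try:
                vol = float(row[volume_col])
            except ValueError:
                bad_rows.append(line)
                continue
            if label in volumes:
                raise FormatError(f"duplicate structure label {label!r} in {dialect} table")
            volumes[label] = vol
    finally:
        if not hasattr(source, "read"):
            stream.close()

    if n_data and columns is None:
        raise FormatError(f"{dialect} table has data rows but no '# ColHeaders' line")
    if n_data == 0:
        warnings.warn(f"{dialect} table contains no data rows", DataQualityWarning, stacklevel=2)
    if bad_rows:
        warnings.warn(
            f"{len(bad_rows)} unparseable row(s) in {dialect} table, first: {bad_rows[0]!r}",
            DataQualityWarning,
            stacklevel=2,
        )
    return volumes


def write_stats_file(volumes: dict[str, float], path, dialect: str = "aseg") -> None:
    """Write a ``{structure: volume}`` map as a minimal stats-dialect table.

    The float formatting round-trips exactly through
    :func:`parse_stats_file` (``repr`` precision).
    """
    if dialect not in _DIALECT_VOLUME_COLUMN:
        raise FormatError(f"unknown stats dialect {dialect!r}")
    volume_col = _DIALECT_VOLUME_COLUMN[dialect]
    lines = ["# Title synthetic stats table", f"# ColHeaders Index {_LABEL_COLUMN} {volume_col}"]
    for i, (label, vol) in enumerate(volumes.items(), start=1):
        lines.append(f"{i} {label} {float(vol)!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_volume_table(source, sep: str = ",") -> VolumeMatrix:
    """Load a delimited volume table into a validated :class:`VolumeMatrix`.

    Expects columns ``subject_id, cohort, age, sex``; every remaining
    column is treated as a region volume in mm^3.
    """
    df = pd.read_csv(source, sep=sep, float_precision="round_trip")
    required = ["subject_id", *META_COLUMNS]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"required column(s) missing: {missing}")
    df = df.set_index("subject_id")
    region_cols = [c for c in df.columns if c not in META_COLUMNS]
    if not region_cols:
        raise ValidationError("table contains no region volume columns")
    return VolumeMatrix(df[region_cols], df[list(META_COLUMNS)])


def write_volume_table(matrix: VolumeMatrix, path, sep: str = ",") -> None:
    """Write a :class:`VolumeMatrix` so it round-trips losslessly."""
    matrix.to_frame().to_csv(path, sep=sep, index_label="subject_id")


def combine_bilateral(matrix: VolumeMatrix, taxonomy: RegionTaxonomy | None = None) -> VolumeMatrix:
    """Combine left+right hemisphere volumes into 50 bilateral measures.

    Per subject, the bilateral volume is the sum of the two hemisphere
    volumes; midline structures pass through unchanged. A subject with
    only one hemisphere present gets NaN for that bilateral region (the
    region is flagged, the subject is kept).
    """
    taxonomy = taxonomy or default_taxonomy()
    present = set(matrix.region_set)
    out = {}
    for bname in taxonomy.bilateral_names:
        sides = taxonomy.pair(bname)
        if "midline" in sides:
            canonical = sides["midline"]
            if canonical in present:
                out[bname] = matrix.volumes[canonical]
        else:
            left, right = sides.get("left"), sides.get("right")
            have = [s for s in (left, right) if s in present]
            if not have:
                continue
            if len(have) == 1:
                warnings.warn(
                    f"{bname}: only one hemisphere present; region flagged missing",
                    DataQualityWarning,
                    stacklevel=2,
                )
                out[bname] = pd.Series(np.nan, index=matrix.volumes.index)
            else:
                out[bname] = matrix.volumes[left] + matrix.volumes[right]
    if not out:
        raise ValidationError("no taxonomy regions found in matrix")
    combined = pd.DataFrame(out, index=matrix.volumes.index)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", DataQualityWarning)
        return matrix.with_volumes(combined)


def lateralized_from_stats(
    aseg: dict[str, float],
    aparc_lh: dict[str, float] | None = None,
    aparc_rh: dict[str, float] | None = None,
    taxonomy: RegionTaxonomy | None = None,
) -> dict[str, float]:
    """Merge per-subject stats maps into one canonical-name volume map.

    Cortical parcellation labels arrive unprefixed (e.g.
    ``parstriangularis``) and are mapped to ``ctx-lh-...``/``ctx-rh-...``;
    labels outside the 95-structure roster are ignored.
    """
    taxonomy = taxonomy or default_taxonomy()
    merged: dict[str, float] = {}
    for label, vol in aseg.items():
        if label in taxonomy:
            merged[taxonomy.normalize(label)] = vol
    for hemi, table in (("lh", aparc_lh), ("rh", aparc_rh)):
        for label, vol in (table or {}).items():
            name = f"ctx-{hemi}-{label}"
            if name in taxonomy:
                merged[taxonomy.normalize(name)] = vol
    return merged
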