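"""End-to-end orchestration: simulate/load -> correct -> summarize -> classify.

Every emitted table is TSV with a ``#``-comment provenance header
(package version, config, input digest) so runs are diff-able and
reproducible byte-for-byte under a fixed seed.
"""
from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .core import ValidationError, VolumeMatrix
from .correction import correct_matrix, verify_correction
from .io import combine_bilateral, load_volume_table, write_volume_table
from .synthetic import default_spec, generate_volumes
from .taxonomy import default_taxonomy, LOBES
from .trajectories import change_metrics, summarize_bins, round_half_away
from .datasets import AGE_BINS


@dataclass
class PipelineConfig:
    """Knobs of the full analysis run."""

    input_csv: str | None = None      # None -> simulate the default synthetic study
    outdir: str = "braintraj-out"
    reference_cohort: str | None = None
    fdr_level: float = 0.05
    r2_threshold: float = 0.2         # cubic-over-linear R^2 gain for non-monotonic calls
    ci_multiplier: float = 1.96
    rounding: int = 1
    seed: int = 0
    skip_correction: bool = False     # for summary-only inputs (one row per bin)
    make_plots: bool = False

    def __post_init__(self):
        if not (0.0 < self.fdr_level < 1.0):
            raise ValidationError("fdr_level must be in (0, 1)")
        if self.r2_threshold < 0:
            raise ValidationError("r2_threshold must be >= 0")


def _digest(df: pd.DataFrame) -> str:
    return hashlib.sha256(df.to_csv().encode()).hexdigest()[:16]


def _write_tsv(df: pd.DataFrame, path: Path, header_lines: list[str], index=True) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=index)


def build_change_table(metrics: pd.DataFrame, taxonomy=None, rounding: int = 1) -> pd.DataFrame:
    """Change statistics grouped by lobe, in the conventional table order."""
    taxonomy = taxonomy or default_taxonomy()
    unknown = [r for r in metrics.index if r not in taxonomy._pairs]
    if unknown:
        raise ValidationError(f"unknown region(s) in metrics: {unknown}")
    rows = []
    for lobe in LOBES:
        for region in taxonomy.bilateral_names:
            if taxonomy.lobe_of(region) != lobe or region not in metrics.index:
                continue
            m = metrics.loc[region]
            rows.append(
                dict(
                    lobe=lobe,
                    region=region,
                    endpoint_change=round_half_away(m["endpoint_change"], rounding),
                    range_change=round_half_away(m["range_change"], rounding),
                    max_consecutive_change=round_half_away(m["max_consecutive_change"], rounding),
                    pattern=m["pattern"],
                    r2_improvement=round_half_away(m["r2_improvement"], 3),
                )
            )
    return pd.DataFrame(rows, columns=["lobe", "region", "endpoint_change", "range_change",
                                       "max_consecutive_change", "pattern", "r2_improvement"])


def _plot_lobe_trajectories(summaries: pd.DataFrame, outdir: Path, taxonomy) -> list[Path]:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    paths = []
    for lobe in LOBES:
        regions = [r for r in summaries["region"].unique() if taxonomy.lobe_of(r) == lobe]
        if not regions:
            continue
        fig, ax = plt.subplots(figsize=(7, 4.5))
        for region in regions:
            sub = summaries[summaries["region"] == region].set_index("age_bin").reindex(AGE_BINS)
            ax.plot(range(len(AGE_BINS)), sub["mean_mm3"], marker="o", label=region)
        ax.set_xticks(range(len(AGE_BINS)), AGE_BINS, rotation=45)
        ax.set_xlabel("age bin (years)")
        ax.set_ylabel("mean bilateral volume (mm$^3$)")
        ax.set_title(f"{lobe} structures")
        ax.legend(fontsize=6, ncol=2)
        fig.tight_layout()
        path = outdir / f"trajectories_{lobe}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        paths.append(path)
    return paths


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run the full analysis; returns a name -> path map of artifacts.

    Artifacts: corrected volume table, verification report, per-bin
    summaries, change-statistics table, pattern table, and a log of
    every exclusion/warning with its reason.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    taxonomy = default_taxonomy()
    log: list[str] = []

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")

        if config.input_csv is None:
            spec = default_spec(seed=config.seed)
            matrix = generate_volumes(spec)
            log.append(f"stage=input source=synthetic seed={config.seed} n={matrix.n_subjects}")
        else:
            matrix = load_volume_table(config.input_csv)
            log.append(f"stage=input source={config.input_csv} n={matrix.n_subjects}")
        input_hash = _digest(matrix.to_frame())

        lateralized = all(name in taxonomy for name in matrix.region_set)
        if lateralized:
            matrix = combine_bilateral(matrix, taxonomy)
            log.append(f"stage=combine_bilateral regions={len(matrix.region_set)}")

        if config.skip_correction:
            corrected, verification = matrix, pd.DataFrame()
            log.append("stage=correction skipped (summary-only input)")
        else:
            corrected, fits = correct_matrix(matrix, config.reference_cohort)
            reference = next(iter(fits.values())).reference_cohort
            verification = verify_correction(corrected, reference)
            n_sig = int((verification["q_value"] < config.fdr_level).sum())
            log.append(f"stage=correction reference={reference} residual_significant={n_sig}")

        summaries = summarize_bins(corrected, config.ci_multiplier)
        bin_means = summaries.pivot(index="age_bin", columns="region", values="mean_mm3")
        bin_means = bin_means.reindex([b for b in AGE_BINS if b in bin_means.index])
        metrics = change_metrics(bin_means, config.r2_threshold)
        change_table = build_change_table(metrics, taxonomy, config.rounding)

        if _digest(matrix.to_frame()) != input_hash and config.input_csv is None:
            raise RuntimeError("internal: a stage mutated its input table")

        for w in caught:
            log.append(f"warning={w.category.__name__} message={w.message}")

    header = [
        f"braintraj {__version__}",
        f"input_digest={input_hash}",
        f"config: seed={config.seed} reference_cohort={config.reference_cohort} "
        f"fdr={config.fdr_level} r2_threshold={config.r2_threshold} "
        f"ci={config.ci_multiplier} rounding={config.rounding}",
    ]
    artifacts: dict[str, Path] = {}
    artifacts["corrected"] = outdir / "corrected_volumes.csv"
    write_volume_table(corrected, artifacts["corrected"])
    artifacts["verification"] = outdir / "verification.tsv"
    _write_tsv(verification, artifacts["verification"], header, index=False)
    artifacts["bin_summaries"] = outdir / "bin_summaries.tsv"
    _write_tsv(summaries, artifacts["bin_summaries"], header, index=False)
    artifacts["changes"] = outdir / "change_table.tsv"
    _write_tsv(change_table, artifacts["changes"], header, index=False)
    artifacts["patterns"] = outdir / "patterns.tsv"
    patterns = metrics[["pattern", "r2_improvement", "extremum_age"]]
    _write_tsv(patterns, artifacts["patterns"], header)
    artifacts["log"] = outdir / "run.log"
    artifacts["log"].write_text("\n".join(log) + "\n")

    if config.make_plots:
        for p in _plot_lobe_trajectories(summaries, outdir, taxonomy):
            artifacts[p.stem] = p
    return artifacts


def regenerate_reference_tables(outdir, r2_threshold: float = 0.2, rounding: int = 1) -> dict[str, Path]:
    """Recompute the change and pattern tables from the bundled bin means."""
    from . import datasets

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    means = datasets.reference_bin_means()
    metrics = change_metrics(means, r2_threshold)
    table = build_change_table(metrics, rounding=rounding)
    header = [f"braintraj {__version__}", "source=bundled reference bin means"]
    paths = {
        "changes": outdir / "reference_change_table.tsv",
        "patterns": outdir / "reference_patterns.tsv",
    }
    _write_tsv(table, paths["changes"], header, index=False)
    _write_tsv(metrics[["pattern", "r2_improvement", "extremum_age"]], paths["patterns"], header)
    return paths
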