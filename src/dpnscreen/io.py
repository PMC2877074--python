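"""Reading and writing the pipeline's tabular artifacts.

Everything is plain tab-delimited text: expression and call matrices
(probes as rows, chips as columns), the chip manifest
(``chip_id, tissue, genotype, day``), truth tables, probe-level results
and run-length summaries. The analysis configuration is a YAML file whose
unknown keys are errors, so a config fully and exactly describes a run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from .model import (
    ExpressionDataset,
    FilterParams,
    RunLengthSummary,
    ValidationError,
    WindowCall,
)

MATRIX_FILE = "matrix.tsv"
CALLS_FILE = "calls.tsv"
MANIFEST_FILE = "manifest.tsv"
TRUTH_FILE = "truth.tsv"
RESULTS_FILE = "window_calls.tsv"
SUMMARY_FILE = "run_length_summary.tsv"


def read_dataset(
    matrix_path: str | Path,
    calls_path: str | Path,
    manifest_path: str | Path,
) -> ExpressionDataset:
    """Read and validate an expression dataset from three TSV files."""
    raw = pd.read_csv(matrix_path, sep="\t", index_col=0)
    calls = pd.read_csv(calls_path, sep="\t", index_col=0, dtype=str)
    manifest = pd.read_csv(manifest_path, sep="\t", index_col=0)
    raw.index = raw.index.astype(str)
    calls.index = calls.index.astype(str)
    manifest.index = manifest.index.astype(str)
    if "day" in manifest.columns:
        manifest["day"] = manifest["day"].astype(int)
    return ExpressionDataset(raw=raw, calls=calls, manifest=manifest)


def write_dataset(
    dataset: ExpressionDataset,
    out_dir: str | Path,
    truth: pd.DataFrame | None = None,
) -> dict[str, Path]:
    """Write a dataset (and optional truth table) as TSV; return file manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out_dir / MATRIX_FILE,
        "calls": out_dir / CALLS_FILE,
        "manifest": out_dir / MANIFEST_FILE,
    }
    dataset.raw.to_csv(paths["matrix"], sep="\t", index_label="probe_id")
    dataset.calls.to_csv(paths["calls"], sep="\t", index_label="probe_id")
    dataset.manifest.to_csv(paths["manifest"], sep="\t", index_label="chip_id")
    if truth is not None:
        paths["truth"] = out_dir / TRUTH_FILE
        truth.to_csv(paths["truth"], sep="\t", index_label="probe_id")
    return paths


def read_truth(path: str | Path) -> pd.DataFrame:
    truth = pd.read_csv(path, sep="\t", index_col=0)
    truth.index = truth.index.astype(str)
    return truth.fillna({"direction": ""})


def calls_to_frame(calls: Iterable[WindowCall], days: Sequence[int] | None = None) -> pd.DataFrame:
    """Probe-level results table with deterministic row order.

    Rows are ordered by run length descending, then probe id. Window
    endpoints are reported both as time-point indices and, when the day
    grid is given, as postnatal days.
    """
    rows = []
    for c in calls:
        row = {
            "probe_id": c.probe_id,
            "direction": c.direction,
            "win_start": c.start,
            "win_end": c.end,
            "run_length": c.run_length,
            "low_expressor": c.low_expressor,
            "max_fold": c.max_fold,
        }
        if days is not None:
            row["start_day"] = int(days[c.start])
            row["end_day"] = int(days[c.end])
        rows.append(row)
    columns = ["probe_id", "direction", "win_start", "win_end", "run_length", "low_expressor", "max_fold"]
    if days is not None:
        columns += ["start_day", "end_day"]
    frame = pd.DataFrame(rows, columns=columns)
    return frame.sort_values(
        ["run_length", "probe_id"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)


def write_results(
    calls: list[WindowCall],
    summary: RunLengthSummary,
    out_dir: str | Path,
    days: Sequence[int] | None = None,
) -> dict[str, Path]:
    """Write probe-level window calls and the run-length summary as TSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "results": out_dir / RESULTS_FILE,
        "summary": out_dir / SUMMARY_FILE,
    }
    calls_to_frame(calls, days).to_csv(paths["results"], sep="\t", index=False)
    summary_table = summary.table.copy()
    summary_table.insert(0, "tissue", summary.tissue)
    summary_table.to_csv(paths["summary"], sep="\t", index=False)
    return paths


# ---------------------------------------------------------------------------
# Analysis configuration
# ---------------------------------------------------------------------------

_CONFIG_KEYS = {
    "matrix",
    "calls",
    "manifest",
    "tissue",
    "normalization",
    "auto_qc",
    "exclude_chips",
    "out_dir",
    "seed",
    "filter",
}


@dataclass
class AnalysisConfig:
    """A complete description of one pipeline run."""

    matrix: str
    calls: str
    manifest: str
    tissue: str
    out_dir: str
    normalization: str = "quantile"
    auto_qc: bool = True
    exclude_chips: tuple[str, ...] = ()
    seed: int = 0
    filter: FilterParams = field(default_factory=FilterParams)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValidationError("config must be a mapping")
        unknown = set(data) - _CONFIG_KEYS
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        filt = data.pop("filter", {}) or {}
        unknown_f = set(filt) - set(FilterParams.field_names())
        if unknown_f:
            raise ValidationError(f"unknown filter keys: {sorted(unknown_f)}")
        data["filter"] = FilterParams(**filt)
        if "exclude_chips" in data:
            data["exclude_chips"] = tuple(data["exclude_chips"] or ())
        missing = {"matrix", "calls", "manifest", "tissue", "out_dir"} - set(data)
        if missing:
            raise ValidationError(f"config missing required keys: {sorted(missing)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        from dataclasses import asdict

        data = asdict(self)
        data["exclude_chips"] = list(self.exclude_chips)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)
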