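"""Core data model shared by every pipeline stage.

The universal substrate is :class:`ExpressionDataset`: a probe x chip raw
intensity matrix, a matching detection-call matrix (tokens ``A``/``M``/``P``
for absent/marginal/present) and a chip manifest giving each chip's tissue,
genotype (``Akita`` diabetic vs ``WT`` control) and postnatal day.

All filter thresholds live in :class:`FilterParams` so that a run is fully
described by one parameter object plus the input data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Sequence

import numpy as np
import pandas as pd

CALL_ABSENT = "A"
CALL_MARGINAL = "M"
CALL_PRESENT = "P"
VALID_CALLS = frozenset({CALL_ABSENT, CALL_MARGINAL, CALL_PRESENT})

GENOTYPE_AFFECTED = "Akita"
GENOTYPE_CONTROL = "WT"
GENOTYPES = (GENOTYPE_AFFECTED, GENOTYPE_CONTROL)

#: Postnatal days of the standard eight-time-point design (P20..P56).
DEFAULT_DAYS: tuple[int, ...] = (20, 24, 28, 32, 36, 40, 48, 56)

MANIFEST_COLUMNS = ("tissue", "genotype", "day")


def day_label(day: int) -> str:
    """Display label for a postnatal day, e.g. 20 -> 'P20'."""
    return f"P{int(day)}"


class ValidationError(ValueError):
    """Raised when an input violates the data-model invariants."""


@dataclass(frozen=True)
class FilterParams:
    """All thresholds of the screening procedure.

    Parameters
    ----------
    fold_threshold
        Genotype-ratio exceedance threshold (> 1). The study design uses
        1.5 (lenient) and 3 (stringent).
    escape_threshold
        Out-of-window ratios must stay strictly inside the open band
        ``(1/escape_threshold, escape_threshold)``.
    min_run
        Minimum number of consecutive exceeding time-points (>= 2).
    intensity_floor
        Raw intensities below this are raised to it before ratios are
        formed (floor 10 ties the floor to the absent-call level).
    low_expressor_cutoff
        Probes whose summary raw intensity is strictly below this are
        flagged as low expressors (unreliable at 100 raw units).
    min_present_run
        Detection filter: a probe must be called present in at least this
        many consecutive time-points to be retained.
    require_uniform_direction
        Whether an exceedance run must be direction-uniform (a contiguous
        block mixing up and down counts as two runs).
    present_rule
        ``"either"``: presence run in either genotype retains the probe;
        ``"both"``: required in both genotypes.
    mask_rule
        ``"break"``: a QC-masked time-point terminates consecutive runs;
        ``"bridge"``: its neighbours are treated as adjacent.
    strict_exceedance
        Exceedance is strict (``r > t`` / ``r < 1/t``); the closed variant
        is provided for replication experiments.
    down_threshold
        Down-regulation threshold; ``None`` means the exact reciprocal
        ``1/fold_threshold``. Set to e.g. 0.66 to mimic a rounded display
        value.
    low_expressor_stat
        Summary statistic over the tissue's retained chips used against
        ``low_expressor_cutoff``: ``"median"`` or ``"mean"``.
    """

    fold_threshold: float = 1.5
    escape_threshold: float = 1.5
    min_run: int = 2
    intensity_floor: float = 10.0
    low_expressor_cutoff: float = 100.0
    min_present_run: int = 2
    require_uniform_direction: bool = True
    present_rule: str = "either"
    mask_rule: str = "break"
    strict_exceedance: bool = True
    down_threshold: float | None = None
    low_expressor_stat: str = "median"

    def __post_init__(self) -> None:
        if not self.fold_threshold > 1:
            raise ValidationError(f"fold_threshold must be > 1, got {self.fold_threshold}")
        if not self.escape_threshold > 1:
            raise ValidationError(f"escape_threshold must be > 1, got {self.escape_threshold}")
        if self.fold_threshold < self.escape_threshold:
            raise ValidationError(
                "fold_threshold must be >= escape_threshold "
                f"({self.fold_threshold} < {self.escape_threshold})"
            )
        if self.min_run < 2:
            raise ValidationError(f"min_run must be >= 2, got {self.min_run}")
        if self.min_present_run < 2:
            raise ValidationError(f"min_present_run must be >= 2, got {self.min_present_run}")
        if self.intensity_floor < 0:
            raise ValidationError(f"intensity_floor must be >= 0, got {self.intensity_floor}")
        if not self.intensity_floor < self.low_expressor_cutoff:
            raise ValidationError("intensity_floor must be < low_expressor_cutoff")
        if self.present_rule not in ("either", "both"):
            raise ValidationError(f"present_rule must be 'either' or 'both', got {self.present_rule!r}")
        if self.mask_rule not in ("break", "bridge"):
            raise ValidationError(f"mask_rule must be 'break' or 'bridge', got {self.mask_rule!r}")
        if self.low_expressor_stat not in ("median", "mean"):
            raise ValidationError("low_expressor_stat must be 'median' or 'mean'")

    @property
    def down_cutoff(self) -> float:
        """Effective down-regulation threshold (reciprocal unless overridden)."""
        return 1.0 / self.fold_threshold if self.down_threshold is None else self.down_threshold

    @property
    def escape_down_cutoff(self) -> float:
        return 1.0 / self.escape_threshold

    def with_(self, **kwargs) -> "FilterParams":
        return replace(self, **kwargs)

    @classmethod
    def field_names(cls) -> tuple[str, ...]:
        return tuple(f.name for f in fields(cls))


@dataclass
class ExpressionDataset:
    """Probe x chip intensities, detection calls and chip manifest.

    ``raw`` and ``calls`` are probe x chip DataFrames with identical axis
    labels; ``manifest`` is indexed by chip id with columns
    ``tissue, genotype, day``.
    """

    raw: pd.DataFrame
    calls: pd.DataFrame
    manifest: pd.DataFrame

    def __post_init__(self) -> None:
        for frame in (self.raw, self.calls):
            frame.index.name = "probe_id"
            frame.columns.name = None
        self.manifest.index.name = "chip_id"
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        raw, calls, manifest = self.raw, self.calls, self.manifest
        if raw.shape != calls.shape:
            raise ValidationError(
                f"raw matrix shape {raw.shape} differs from calls shape {calls.shape}"
            )
        if not raw.index.equals(calls.index) or not raw.columns.equals(calls.columns):
            raise ValidationError("raw and calls must share identical probe/chip labels")
        if raw.index.has_duplicates:
            raise ValidationError("duplicate probe ids")
        if raw.columns.has_duplicates:
            raise ValidationError("duplicate chip ids")
        if (raw.to_numpy() < 0).any():
            bad = raw.stack()
            bad = bad[bad < 0]
            probe, chip = bad.index[0]
            raise ValidationError(f"negative intensity at probe {probe!r}, chip {chip!r}")
        call_values = calls.to_numpy()
        ok = np.isin(call_values, list(VALID_CALLS))
        if not ok.all():
            i, j = np.argwhere(~ok)[0]
            raise ValidationError(
                f"unknown call token {call_values[i, j]!r} at probe "
                f"{calls.index[i]!r}, chip {calls.columns[j]!r}"
            )
        missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
        if missing:
            raise ValidationError(f"manifest missing columns: {missing}")
        if set(manifest.index) != set(raw.columns):
            raise ValidationError("manifest chips do not match matrix chips exactly")
        if manifest.index.has_duplicates:
            raise ValidationError("manifest lists a chip more than once")
        bad_geno = set(manifest["genotype"]) - set(GENOTYPES)
        if bad_geno:
            raise ValidationError(f"unknown genotypes in manifest: {sorted(bad_geno)}")
        if (manifest["day"].astype(int) <= 0).any():
            raise ValidationError("postnatal days must be positive integers")
        dup = manifest.groupby(["tissue", "genotype", "day"]).size()
        dup = dup[dup > 1]
        if len(dup):
            t, g, d = dup.index[0]
            raise ValidationError(
                f"duplicate chip for (tissue={t!r}, genotype={g!r}, day=P{d}): "
                "each (tissue, genotype, day) maps to at most one chip"
            )

    # -- convenience -----------------------------------------------------
    @property
    def probe_ids(self) -> pd.Index:
        return self.raw.index

    @property
    def chip_ids(self) -> pd.Index:
        return self.raw.columns

    @property
    def tissues(self) -> list[str]:
        return sorted(self.manifest["tissue"].unique())

    def days(self, tissue: str | None = None) -> list[int]:
        m = self.manifest if tissue is None else self.manifest[self.manifest["tissue"] == tissue]
        return sorted(int(d) for d in m["day"].unique())

    def chips_for(self, tissue: str | None = None, genotype: str | None = None) -> list[str]:
        m = self.manifest
        if tissue is not None:
            m = m[m["tissue"] == tissue]
        if genotype is not None:
            m = m[m["genotype"] == genotype]
        return list(m.index)

    def chip_at(self, tissue: str, genotype: str, day: int) -> str | None:
        m = self.manifest
        hit = m[(m["tissue"] == tissue) & (m["genotype"] == genotype) & (m["day"] == day)]
        return None if hit.empty else hit.index[0]

    def drop_chips(self, chip_ids: Sequence[str]) -> "ExpressionDataset":
        """Dataset without the given chips (QC exclusion)."""
        chip_ids = [c for c in chip_ids if c in self.raw.columns]
        keep = [c for c in self.raw.columns if c not in set(chip_ids)]
        return ExpressionDataset(
            raw=self.raw[keep].copy(),
            calls=self.calls[keep].copy(),
            manifest=self.manifest.loc[keep].copy(),
        )

    def subset_tissue(self, tissue: str) -> "ExpressionDataset":
        if tissue not in set(self.manifest["tissue"]):
            raise ValidationError(f"tissue {tissue!r} not in manifest")
        chips = self.chips_for(tissue)
        return ExpressionDataset(
            raw=self.raw[chips].copy(),
            calls=self.calls[chips].copy(),
            manifest=self.manifest.loc[chips].copy(),
        )

    def equals(self, other: "ExpressionDataset") -> bool:
        return (
            self.raw.equals(other.raw)
            and self.calls.equals(other.calls)
            and self.manifest.equals(other.manifest)
        )


@dataclass
class FoldChangeSeries:
    """Per-probe ordered Akita/WT ratio series across time-points.

    ``mask[t]`` is True where either genotype's chip is missing (QC
    exclusion); masked ratios carry NaN and take no part in selection.
    """

    probe_id: str
    ratios: np.ndarray
    mask: np.ndarray
    days: tuple[int, ...]
    tissue: str = ""

    def __post_init__(self) -> None:
        self.ratios = np.asarray(self.ratios, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.ratios.shape != self.mask.shape:
            raise ValidationError("ratios and mask must have equal length")
        unmasked = self.ratios[~self.mask]
        if not np.all(np.isfinite(unmasked)) or np.any(unmasked <= 0):
            raise ValidationError(
                f"probe {self.probe_id!r}: unmasked ratios must be finite and > 0"
            )

    def __len__(self) -> int:
        return len(self.ratios)


@dataclass(frozen=True)
class WindowCall:
    """An accepted probe: direction, window, run length, low-expressor flag."""

    probe_id: str
    direction: str  # "up" | "down"
    start: int  # inclusive time-point index
    end: int  # inclusive
    run_length: int
    low_expressor: bool = False
    max_fold: float = float("nan")  # max ratio magnitude in window (fold units)

    @property
    def accepted(self) -> bool:
        return True


@dataclass(frozen=True)
class Rejection:
    """A rejected probe with the clause that failed."""

    probe_id: str
    reason: str

    @property
    def accepted(self) -> bool:
        return False


@dataclass
class RunLengthSummary:
    """Counts of accepted probes by minimum consecutive run length.

    ``table`` has one row per run length k with the number of accepted
    probes at run length >= k (cumulative mode) or == k (exact mode), and
    the low-expressor sub-count.
    """

    tissue: str
    table: pd.DataFrame  # columns: k, n_probes, n_low_expressor
    platform_size: int
    eliminated_by_detection: int
    mode: str = "cumulative"

    def count_at(self, k: int) -> int:
        row = self.table[self.table["k"] == k]
        return 0 if row.empty else int(row["n_probes"].iloc[0])


@dataclass
class GenePanel:
    """A named list of gene symbols with probe mappings.

    ``mapping`` maps a gene symbol to the probe ids measuring it; symbols
    without probes are reported as unmapped, never dropped silently.
    """

    name: str
    genes: tuple[str, ...]
    mapping: dict[str, tuple[str, ...]] = field(default_factory=dict)

    @property
    def unmapped(self) -> tuple[str, ...]:
        return tuple(g for g in self.genes if not self.mapping.get(g))
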