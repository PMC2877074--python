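"""Shared fixtures and helpers for the dpnscreen test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from dpnscreen import ExpressionDataset, FilterParams, FoldChangeSeries, SimulationParams

DAYS = (20, 24, 28, 32, 36, 40, 48, 56)


def make_series(ratios, mask=None, probe_id="probe", days=None) -> FoldChangeSeries:
    ratios = np.asarray(ratios, dtype=float)
    mask = np.zeros(len(ratios), dtype=bool) if mask is None else np.asarray(mask, dtype=bool)
    days = tuple(days) if days is not None else tuple(range(len(ratios)))
    r = ratios.copy()
    r[mask] = np.nan
    return FoldChangeSeries(probe_id=probe_id, ratios=r, mask=mask, days=days)


def make_dataset(
    raw: dict[str, list[float]],
    calls: dict[str, list[str]] | None = None,
    manifest_rows: list[tuple[str, str, str, int]] | None = None,
    probe_ids: list[str] | None = None,
) -> ExpressionDataset:
    """Small hand-built dataset. ``raw`` maps chip_id -> per-probe values;
    ``manifest_rows`` are (chip_id, tissue, genotype, day)."""
    raw_df = pd.DataFrame(raw, index=probe_ids or [f"p{i}" for i in range(len(next(iter(raw.values()))))])
    raw_df.index = raw_df.index.astype(str)
    if calls is None:
        calls_df = pd.DataFrame("P", index=raw_df.index, columns=raw_df.columns)
    else:
        calls_df = pd.DataFrame(calls, index=raw_df.index)
    if manifest_rows is None:
        manifest_rows = []
        for chip in raw_df.columns:
            tissue, genotype, day = chip.split("_")
            manifest_rows.append((chip, tissue, genotype, int(day.lstrip("P"))))
    manifest = pd.DataFrame(
        manifest_rows, columns=["chip_id", "tissue", "genotype", "day"]
    ).set_index("chip_id")
    return ExpressionDataset(raw=raw_df, calls=calls_df, manifest=manifest)


def two_genotype_dataset(
    akita: np.ndarray, wt: np.ndarray, tissue: str = "DRG", days=DAYS
) -> ExpressionDataset:
    """Dataset from probe x day intensity arrays, one chip per (genotype, day)."""
    akita, wt = np.atleast_2d(akita), np.atleast_2d(wt)
    raw, rows = {}, []
    for t, day in enumerate(days[: akita.shape[1]]):
        for genotype, mat in (("Akita", akita), ("WT", wt)):
            chip = f"{tissue}_{genotype}_P{day}"
            raw[chip] = mat[:, t]
            rows.append((chip, tissue, genotype, day))
    return make_dataset(raw, manifest_rows=rows, probe_ids=[f"p{i}" for i in range(akita.shape[0])])


def zero_noise_params(**overrides) -> SimulationParams:
    """Generator settings with all stochastic dispersion switched off."""
    defaults = dict(noise_cv=0.0, chip_scale_spread=0.0, seed=0)
    defaults.update(overrides)
    return SimulationParams(**defaults)


@pytest.fixture
def default_params() -> FilterParams:
    return FilterParams()


@pytest.fixture
def tiny_dataset() -> ExpressionDataset:
    """3 probes x 4 chips, one tissue, two genotypes, two days."""
    return make_dataset(
        {
            "DRG_Akita_P20": [100.0, 300.0, 5.0],
            "DRG_WT_P20": [100.0, 150.0, 5.0],
            "DRG_Akita_P24": [110.0, 290.0, 8.0],
            "DRG_WT_P24": [105.0, 145.0, 12.0],
        },
        calls={
            "DRG_Akita_P20": ["P", "P", "A"],
            "DRG_WT_P20": ["P", "P", "A"],
            "DRG_Akita_P24": ["P", "P", "M"],
            "DRG_WT_P24": ["P", "P", "P"],
        },
    )


def random_series(rng: np.random.Generator, length: int, with_mask: bool) -> FoldChangeSeries:
    """Random log-uniform ratio series, occasionally masked, for oracle checks.

    Ratios concentrate around the decision boundaries (band edges at
    1/1.5, 1.5 and 3) so the enumeration exercises every clause.
    """
    log_r = rng.uniform(np.log(1 / 4.5), np.log(4.5), size=length)
    # snap ~30% of points near a boundary to stress edge behaviour
    near = rng.random(length) < 0.3
    boundary = rng.choice([1 / 3, 1 / 1.5, 1.0, 1.5, 3.0], size=length)
    jitter = np.exp(rng.normal(0.0, 0.05, size=length))
    ratios = np.where(near, boundary * jitter, np.exp(log_r))
    mask = np.zeros(length, dtype=bool)
    if with_mask:
        mask = rng.random(length) < 0.2
        if mask.all():
            mask[rng.integers(length)] = False
    ratios = ratios.copy()
    ratios[mask] = np.nan
    return FoldChangeSeries(
        probe_id="r", ratios=ratios, mask=mask, days=tuple(range(length))
    )
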