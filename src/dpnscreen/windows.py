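"""Consecutive-window fold-change selection — the analysis core.

For each probe a genotype ratio series ``r_t = floored(Akita_t) /
floored(WT_t)`` is formed over the ordered time-points (raw values below
the intensity floor are raised to it, so ratios are always finite and
positive). A probe is *accepted* when its ratios exceed the fold threshold
in one direction over a single block of at least ``min_run`` consecutive
time-points, and every time-point outside that block stays strictly inside
the escape band ``(1/escape_threshold, escape_threshold)``. Probes whose
profile also excurses outside the window — the "zigzagging" profiles typical
of low expressors — are thereby rejected.

Time-points whose chip was eliminated by QC are masked: a masked point
breaks a run (or bridges, by configuration) and is exempt from the escape
constraint.

`brute_force_oracle` re-derives the decision by literal enumeration of
every contiguous window and is kept deliberately independent of
`classify_probe` for verification.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .model import (
    ExpressionDataset,
    FilterParams,
    FoldChangeSeries,
    GENOTYPE_AFFECTED,
    GENOTYPE_CONTROL,
    Rejection,
    ValidationError,
    WindowCall,
)

# Rejection reasons enumerate the clause that failed.
REASON_NO_RUN = "no_exceedance_run"
REASON_MULTIPLE_RUNS = "multiple_exceedance_runs"
REASON_RUN_TOO_SHORT = "run_shorter_than_min_run"
REASON_ESCAPE = "escape_band_violation_outside_window"
REASON_ALL_MASKED = "all_time_points_masked"


def floor_intensities(raw: pd.DataFrame | np.ndarray, intensity_floor: float):
    """Raise every intensity below the floor to the floor.

    The floor (default 10 raw units, the absent-call level) guarantees
    ratios stay finite and keeps near-background probes at ratio 1.
    """
    if intensity_floor < 0:
        raise ValidationError(f"intensity floor must be >= 0, got {intensity_floor}")
    if isinstance(raw, pd.DataFrame):
        return raw.clip(lower=intensity_floor)
    return np.maximum(np.asarray(raw, dtype=float), intensity_floor)


def compute_fold_changes(
    dataset: ExpressionDataset,
    tissue: str,
    params: FilterParams,
    probe_ids: Sequence[str] | None = None,
) -> list[FoldChangeSeries]:
    """Per-probe Akita/WT ratio series over the tissue's ordered days.

    A day lacking either genotype's chip (QC exclusion) is masked; its
    ratio is NaN. Intensities are floored before division.
    """
    if tissue not in set(dataset.manifest["tissue"]):
        raise ValidationError(f"tissue {tissue!r} not in manifest")
    days = tuple(dataset.days(tissue))
    probe_ids = list(dataset.probe_ids if probe_ids is None else probe_ids)

    akita_cols, wt_cols, mask = [], [], []
    for day in days:
        a = dataset.chip_at(tissue, GENOTYPE_AFFECTED, day)
        w = dataset.chip_at(tissue, GENOTYPE_CONTROL, day)
        akita_cols.append(a)
        wt_cols.append(w)
        mask.append(a is None or w is None)
    mask = np.array(mask, dtype=bool)

    floored = floor_intensities(dataset.raw.loc[probe_ids], params.intensity_floor)
    n = len(probe_ids)
    ratios = np.full((n, len(days)), np.nan)
    for t, (a, w) in enumerate(zip(akita_cols, wt_cols)):
        if not mask[t]:
            ratios[:, t] = floored[a].to_numpy() / floored[w].to_numpy()

    return [
        FoldChangeSeries(probe_id=p, ratios=ratios[i], mask=mask.copy(), days=days, tissue=tissue)
        for i, p in enumerate(probe_ids)
    ]


def _direction(r: float, params: FilterParams) -> int:
    """+1 up-exceedance, -1 down-exceedance, 0 in between."""
    up, down = params.fold_threshold, params.down_cutoff
    if params.strict_exceedance:
        if r > up:
            return 1
        if r < down:
            return -1
    else:
        if r >= up:
            return 1
        if r <= down:
            return -1
    return 0


def _in_escape_band(r: float, params: FilterParams) -> bool:
    """Strictly inside the open band (1/escape, escape)."""
    return (r < params.escape_threshold) and (r > params.escape_down_cutoff)


def find_exceedance_runs(
    series: FoldChangeSeries, params: FilterParams
) -> list[tuple[str, int, int]]:
    """Maximal direction-uniform runs of threshold exceedance.

    Returns ``(direction, start, end)`` with inclusive time-point indices.
    A masked time-point terminates a run under ``mask_rule='break'`` and is
    transparent under ``'bridge'``. With ``require_uniform_direction`` a
    direction flip always starts a new run.
    """
    runs: list[tuple[str, int, int]] = []
    cur_dir = 0
    cur_start = -1
    prev_idx = -1  # last unmasked index seen

    def close(end: int) -> None:
        nonlocal cur_dir, cur_start
        if cur_dir != 0:
            runs.append(("up" if cur_dir > 0 else "down", cur_start, end))
        cur_dir, cur_start = 0, -1

    for t in range(len(series)):
        if series.mask[t]:
            if params.mask_rule == "break":
                close(prev_idx)
            continue
        d = _direction(series.ratios[t], params)
        if d == 0:
            close(prev_idx)
        elif d == cur_dir:
            pass  # run continues
        else:
            if cur_dir != 0 and not params.require_uniform_direction and d != 0:
                # mixed-direction runs allowed: keep extending
                pass
            else:
                close(prev_idx)
                cur_dir, cur_start = d, t
        prev_idx = t
    close(prev_idx)
    return runs


def _run_length(series: FoldChangeSeries, start: int, end: int) -> int:
    """Number of unmasked time-points in the inclusive window."""
    return int((~series.mask[start : end + 1]).sum())


def classify_probe(
    series: FoldChangeSeries, params: FilterParams
) -> WindowCall | Rejection:
    """Accept or reject a probe's fold-change series.

    Accept iff exactly one exceedance run exists at the fold threshold,
    its (unmasked) length is >= ``min_run``, and every unmasked ratio
    outside the run lies strictly within the escape band. With the
    1.5/1.5 setting this reduces to: the out-of-band time-points form a
    single direction-uniform contiguous block of length >= ``min_run``.
    """
    if series.mask.all():
        return Rejection(series.probe_id, REASON_ALL_MASKED)
    runs = find_exceedance_runs(series, params)
    if not runs:
        return Rejection(series.probe_id, REASON_NO_RUN)
    if len(runs) > 1:
        return Rejection(series.probe_id, REASON_MULTIPLE_RUNS)
    direction, start, end = runs[0]
    run_len = _run_length(series, start, end)
    if run_len < params.min_run:
        return Rejection(series.probe_id, REASON_RUN_TOO_SHORT)
    for t in range(len(series)):
        if series.mask[t] or start <= t <= end:
            continue
        if not _in_escape_band(series.ratios[t], params):
            return Rejection(series.probe_id, REASON_ESCAPE)
    in_window = series.ratios[start : end + 1][~series.mask[start : end + 1]]
    max_fold = float(in_window.max() if direction == "up" else 1.0 / in_window.min())
    return WindowCall(
        probe_id=series.probe_id,
        direction=direction,
        start=start,
        end=end,
        run_length=run_len,
        max_fold=max_fold,
    )


def flag_low_expressor(
    probe_raw: np.ndarray | pd.Series,
    call: WindowCall,
    cutoff: float,
    stat: str = "median",
) -> WindowCall:
    """Attach the low-expressor flag to an accepted call.

    A probe is a low expressor when its summary raw intensity over the
    tissue's retained chips is strictly below the cutoff (100 raw units).
    """
    values = np.asarray(probe_raw, dtype=float)
    summary = float(np.median(values) if stat == "median" else np.mean(values))
    from dataclasses import replace

    return replace(call, low_expressor=bool(summary < cutoff))


def brute_force_oracle(
    series: FoldChangeSeries, params: FilterParams
) -> WindowCall | Rejection:
    """Decide acceptance by literal enumeration of every contiguous window.

    Independent of :func:`classify_probe`; used for verification only.
    A window qualifies when every unmasked in-window ratio exceeds the fold
    threshold in one direction, its unmasked length is >= min_run, its
    endpoints are unmasked exceedances, and every unmasked out-of-window
    ratio sits strictly inside the escape band. Under ``mask_rule='break'``
    a window may not straddle a masked time-point. Acceptance requires
    exactly one qualifying window.
    """
    n = len(series)
    if n > 16:
        raise ValidationError("oracle enumeration limited to series of length <= 16")
    qualifying: list[tuple[str, int, int, int]] = []
    for s in range(n):
        for e in range(s, n):
            win = list(range(s, e + 1))
            unmasked_in = [t for t in win if not series.mask[t]]
            if not unmasked_in:
                continue
            if series.mask[s] or series.mask[e]:
                continue  # canonical windows have unmasked endpoints
            if params.mask_rule == "break" and any(series.mask[t] for t in win):
                continue
            dirs = {_direction(series.ratios[t], params) for t in unmasked_in}
            if params.require_uniform_direction:
                if dirs != {1} and dirs != {-1}:
                    continue
            else:
                if 0 in dirs:
                    continue
            if len(unmasked_in) < params.min_run:
                continue
            outside_ok = all(
                _in_escape_band(series.ratios[t], params)
                for t in range(n)
                if t not in win and not series.mask[t]
            )
            if not outside_ok:
                continue
            d = 1 if 1 in dirs else -1
            qualifying.append(("up" if d == 1 else "down", s, e, len(unmasked_in)))
    if len(qualifying) != 1:
        reason = REASON_NO_RUN if not qualifying else REASON_MULTIPLE_RUNS
        return Rejection(series.probe_id, reason)
    direction, s, e, run_len = qualifying[0]
    vals = [series.ratios[t] for t in range(s, e + 1) if not series.mask[t]]
    max_fold = float(max(vals) if direction == "up" else 1.0 / min(vals))
    return WindowCall(
        probe_id=series.probe_id,
        direction=direction,
        start=s,
        end=e,
        run_length=run_len,
        max_fold=max_fold,
    )


def classify_dataset(
    dataset: ExpressionDataset,
    tissue: str,
    params: FilterParams,
    probe_ids: Sequence[str] | None = None,
) -> tuple[list[WindowCall], list[Rejection]]:
    """Classify every (retained) probe of a tissue; attach low-expressor flags."""
    series_list = compute_fold_changes(dataset, tissue, params, probe_ids)
    tissue_chips = dataset.chips_for(tissue)
    accepted: list[WindowCall] = []
    rejected: list[Rejection] = []
    for series in series_list:
        result = classify_probe(series, params)
        if isinstance(result, WindowCall):
            result = flag_low_expressor(
                dataset.raw.loc[series.probe_id, tissue_chips],
                result,
                params.low_expressor_cutoff,
                params.low_expressor_stat,
            )
            accepted.append(result)
        else:
            rejected.append(result)
    return accepted, rejected


def rejection_histogram(rejections: Iterable[Rejection]) -> dict[str, int]:
    hist: dict[str, int] = {}
    for r in rejections:
        hist[r.reason] = hist.get(r.reason, 0) + 1
    return dict(sorted(hist.items()))
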