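"""Detection-call consecutive filtering.

With closely spaced time-points, a probe called "present" at only one
developmental stage is treated as an artifact. The filter retains a probe
only if some genotype's call series contains at least ``min_present_run``
consecutive "present" calls ("marginal" does not count as present).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .model import (
    CALL_PRESENT,
    ExpressionDataset,
    FilterParams,
    GENOTYPES,
    ValidationError,
)


def presence_series(
    dataset: ExpressionDataset, tissue: str, genotype: str
) -> tuple[pd.DataFrame, np.ndarray]:
    """Probe x day boolean presence matrix for one genotype.

    Returns ``(present, mask)`` where ``mask[t]`` is True for days whose
    chip is missing (QC-excluded); masked columns carry False placeholders
    that must be interpreted through the mask.
    """
    days = dataset.days(tissue)
    cols: dict[int, pd.Series | bool] = {}
    mask = np.zeros(len(days), dtype=bool)
    for t, day in enumerate(days):
        chip = dataset.chip_at(tissue, genotype, day)
        if chip is None:
            mask[t] = True
            cols[day] = False
        else:
            cols[day] = dataset.calls[chip] == CALL_PRESENT
    present = pd.DataFrame(cols, index=dataset.probe_ids)
    return present, mask


def _max_consecutive_true(present: np.ndarray) -> np.ndarray:
    """Row-wise longest run of True in a 2-D boolean array."""
    if present.shape[1] == 0:
        return np.zeros(present.shape[0], dtype=int)
    run = np.zeros(present.shape[0], dtype=int)
    best = np.zeros(present.shape[0], dtype=int)
    for t in range(present.shape[1]):
        run = np.where(present[:, t], run + 1, 0)
        best = np.maximum(best, run)
    return best


def _longest_present_run(
    present: np.ndarray, mask: np.ndarray, mask_rule: str
) -> np.ndarray:
    """Longest consecutive-present run per probe under the mask rule.

    'break': a masked day terminates a run (no call evidence there);
    'bridge': masked days are removed so their neighbours become adjacent.
    """
    if mask_rule == "bridge":
        present = present[:, ~mask]
    else:
        present = present.copy()
        present[:, mask] = False
    return _max_consecutive_true(present)


def consecutive_present_filter(
    dataset: ExpressionDataset, tissue: str, params: FilterParams
) -> tuple[pd.Index, int]:
    """Retain probes with >= min_present_run consecutive present calls.

    Under ``present_rule='either'`` a qualifying run in either genotype's
    series retains the probe; ``'both'`` requires one in each. Returns the
    retained probe index and the number eliminated.
    """
    days = dataset.days(tissue)
    if params.min_present_run > len(days):
        raise ValidationError(
            f"min_present_run={params.min_present_run} exceeds the "
            f"{len(days)} time-points of tissue {tissue!r}"
        )
    per_genotype = []
    for genotype in GENOTYPES:
        present, mask = presence_series(dataset, tissue, genotype)
        longest = _longest_present_run(present.to_numpy(), mask, params.mask_rule)
        per_genotype.append(longest >= params.min_present_run)
    if params.present_rule == "either":
        keep = per_genotype[0] | per_genotype[1]
    else:
        keep = per_genotype[0] & per_genotype[1]
    retained = dataset.probe_ids[keep]
    return retained, int((~keep).sum())
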