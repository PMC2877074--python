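"""Fold-change window selection: floor, ratios, runs, classification, oracle."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dpnscreen import (
    FilterParams,
    brute_force_oracle,
    classify_probe,
    compute_fold_changes,
    find_exceedance_runs,
    flag_low_expressor,
    floor_intensities,
    GOLDEN_PATTERNS,
)
from dpnscreen.model import Rejection, ValidationError, WindowCall
from dpnscreen.windows import (
    REASON_ESCAPE,
    REASON_MULTIPLE_RUNS,
    REASON_NO_RUN,
    REASON_RUN_TOO_SHORT,
)

from conftest import make_series, two_genotype_dataset


# -- floor -------------------------------------------------------------------


@pytest.mark.parametrize(
    "value,expected",
    [(5.0, 10.0), (10.0, 10.0), (9.999, 10.0), (10.001, 10.001), (40000.0, 40000.0), (0.0, 10.0)],
)
def test_floor_replaces_subthreshold_values(value, expected):
    out = floor_intensities(np.array([value]), 10.0)
    assert out[0] == expected


def test_floor_rejects_negative_floor():
    with pytest.raises(ValidationError):
        floor_intensities(np.array([1.0]), -1.0)


def test_floor_on_dataframe_preserves_labels():
    df = pd.DataFrame({"c1": [5.0, 50.0]}, index=["a", "b"])
    out = floor_intensities(df, 10.0)
    assert list(out.index) == ["a", "b"] and out.loc["a", "c1"] == 10.0


# -- fold-change series ------------------------------------------------------


def test_ratio_direct_division_and_floored_identity(default_params):
    # Akita 300 vs WT 150 -> 2.0; both below floor -> 10/10 = 1.0
    ds = two_genotype_dataset(np.array([[300.0, 5.0]]), np.array([[150.0, 5.0]]))
    (series,) = compute_fold_changes(ds, "DRG", default_params)
    assert series.ratios[0] == pytest.approx(2.0)
    assert series.ratios[1] == pytest.approx(1.0)


def test_missing_chip_masks_time_point(default_params):
    # endoneurium-like series: P36 Akita chip excluded -> 7 usable ratios
    akita = np.ones((1, 8)) * 200.0
    wt = np.ones((1, 8)) * 100.0
    ds = two_genotype_dataset(akita, wt, tissue="endoneurium")
    ds = ds.drop_chips(["endoneurium_Akita_P36"])
    (series,) = compute_fold_changes(ds, "endoneurium", default_params)
    assert series.mask.sum() == 1
    assert series.mask[list(series.days).index(36)]
    assert (~series.mask).sum() == 7
    assert np.isnan(series.ratios[series.mask]).all()


def test_unknown_tissue_rejected(default_params):
    ds = two_genotype_dataset(np.ones((1, 2)) * 100, np.ones((1, 2)) * 100)
    with pytest.raises(ValidationError):
        compute_fold_changes(ds, "liver", default_params)


# -- exceedance runs ---------------------------------------------------------


def test_single_up_run_detected(default_params):
    series = make_series([1.0, 1.0, 1.8, 1.8, 1.0, 1.0, 1.0, 1.0])
    assert find_exceedance_runs(series, default_params) == [("up", 2, 3)]


def test_no_runs_on_flat_series(default_params):
    series = make_series([1.0] * 8)
    assert find_exceedance_runs(series, default_params) == []


def test_down_run_and_isolated_up(default_params):
    series = make_series([0.5, 0.5, 0.5, 1.0, 1.0, 1.0, 1.0, 1.6])
    assert find_exceedance_runs(series, default_params) == [("down", 0, 2), ("up", 7, 7)]


def test_adjacent_direction_flip_splits_runs(default_params):
    series = make_series([1.8, 1.8, 0.5, 0.5])
    runs = find_exceedance_runs(series, default_params)
    assert runs == [("up", 0, 1), ("down", 2, 3)]


def test_masked_point_breaks_run_by_default():
    params = FilterParams(mask_rule="break")
    series = make_series([1.8, 1.8, 1.8], mask=[False, True, False])
    assert find_exceedance_runs(series, params) == [("up", 0, 0), ("up", 2, 2)]


def test_masked_point_bridges_when_configured():
    params = FilterParams(mask_rule="bridge")
    series = make_series([1.8, 1.8, 1.8], mask=[False, True, False])
    assert find_exceedance_runs(series, params) == [("up", 0, 2)]


# -- classification: golden selection patterns -------------------------------


@pytest.mark.parametrize("panel", sorted(GOLDEN_PATTERNS))
def test_golden_patterns_classified_as_expected(panel, default_params):
    spec = GOLDEN_PATTERNS[panel]
    result = classify_probe(make_series(spec["ratios"], probe_id=panel), default_params)
    if spec["expected"] == "selected":
        assert isinstance(result, WindowCall)
        assert result.direction == spec["direction"]
        assert result.run_length == spec["run_length"]
    else:
        assert isinstance(result, Rejection)


def test_rejection_reasons_enumerate_failing_clause(default_params):
    assert classify_probe(make_series([1.0] * 8), default_params).reason == REASON_NO_RUN
    assert (
        classify_probe(make_series([1.8, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0]), default_params).reason
        == REASON_RUN_TOO_SHORT
    )
    assert (
        classify_probe(make_series([1.8, 1.8, 1.0, 1.0, 0.5, 0.5, 1.0, 1.0]), default_params).reason
        == REASON_MULTIPLE_RUNS
    )
    # stringent threshold: sub-threshold excursion outside the window
    stringent = FilterParams(fold_threshold=3.0, escape_threshold=1.5)
    assert (
        classify_probe(make_series([3.5, 3.5, 1.0, 2.0, 1.0, 1.0, 1.0, 1.0]), stringent).reason
        == REASON_ESCAPE
    )


def test_escape_band_is_open_at_the_boundary(default_params):
    # out-of-window ratio exactly at 1.5 is outside the open band -> reject
    result = classify_probe(make_series([1.8, 1.8, 1.5, 1.0, 1.0, 1.0, 1.0, 1.0]), default_params)
    assert isinstance(result, Rejection)
    # strictly inside the band -> accept
    result = classify_probe(make_series([1.8, 1.8, 1.49, 1.0, 1.0, 1.0, 1.0, 1.0]), default_params)
    assert isinstance(result, WindowCall)


def test_masked_points_exempt_from_escape_constraint(default_params):
    # excursion at a masked time-point must not reject the probe
    ratios = [1.0, 1.0, 1.8, 1.8, 9.9, 1.0, 1.0, 1.0]
    mask = [False, False, False, False, True, False, False, False]
    result = classify_probe(make_series(ratios, mask=mask), default_params)
    assert isinstance(result, WindowCall)
    assert (result.start, result.end, result.run_length) == (2, 3, 2)


def test_all_masked_series_rejected(default_params):
    result = classify_probe(make_series([1.0, 1.0], mask=[True, True]), default_params)
    assert isinstance(result, Rejection)


# -- low-expressor flag ------------------------------------------------------


@pytest.mark.parametrize(
    "values,expected",
    [([50.0] * 4, True), ([100.0] * 4, False), ([40000.0] * 4, False), ([99.0, 99.0, 101.0, 101.0], False)],
)
def test_low_expressor_median_strictly_under_cutoff(values, expected):
    call = WindowCall("p", "up", 2, 3, 2)
    flagged = flag_low_expressor(np.array(values), call, cutoff=100.0)
    assert flagged.low_expressor is expected


# -- invariants (property tests) ---------------------------------------------


@settings(max_examples=300, derandomize=True, deadline=None)
@given(
    ratios=st.lists(
        st.floats(min_value=0.1, max_value=10.0, allow_nan=False), min_size=4, max_size=12
    )
)
def test_reciprocal_symmetry_flips_direction(ratios):
    params = FilterParams()
    fwd = classify_probe(make_series(ratios), params)
    rev = classify_probe(make_series([1.0 / r for r in ratios]), params)
    assert isinstance(fwd, WindowCall) == isinstance(rev, WindowCall)
    if isinstance(fwd, WindowCall):
        assert {fwd.direction, rev.direction} == {"up", "down"} or (
            fwd.direction == rev.direction  # symmetric profile edge case
        )
        assert (fwd.start, fwd.end) == (rev.start, rev.end)


@settings(max_examples=300, derandomize=True, deadline=None)
@given(
    ratios=st.lists(
        st.floats(min_value=0.1, max_value=10.0, allow_nan=False), min_size=4, max_size=10
    ),
    thresholds=st.tuples(st.floats(min_value=1.5, max_value=2.0), st.floats(min_value=2.5, max_value=4.0)),
)
def test_raising_fold_threshold_never_rescues_a_reject(ratios, thresholds):
    lo, hi = thresholds
    series = make_series(ratios)
    low = classify_probe(series, FilterParams(fold_threshold=lo, escape_threshold=1.5))
    high = classify_probe(series, FilterParams(fold_threshold=hi, escape_threshold=1.5))
    if isinstance(high, WindowCall):
        assert isinstance(low, WindowCall)


@settings(max_examples=300, derandomize=True, deadline=None)
@given(
    ratios=st.lists(
        st.floats(min_value=0.1, max_value=10.0, allow_nan=False), min_size=4, max_size=10
    ),
    k=st.integers(min_value=2, max_value=5),
)
def test_accepted_sets_nest_in_min_run(ratios, k):
    series = make_series(ratios)
    at_k1 = classify_probe(series, FilterParams(min_run=k + 1))
    if isinstance(at_k1, WindowCall):
        at_k = classify_probe(series, FilterParams(min_run=k))
        assert isinstance(at_k, WindowCall)


# -- oracle equivalence ------------------------------------------------------


def _assert_same_decision(series, params):
    got = classify_probe(series, params)
    want = brute_force_oracle(series, params)
    assert isinstance(got, WindowCall) == isinstance(want, WindowCall), (
        f"ratios={series.ratios} mask={series.mask} params={params}: "
        f"classify={got} oracle={want}"
    )
    if isinstance(got, WindowCall):
        assert (got.direction, got.start, got.end, got.run_length) == (
            want.direction,
            want.start,
            want.end,
            want.run_length,
        )


def test_oracle_agrees_on_golden_patterns(default_params):
    for panel, spec in GOLDEN_PATTERNS.items():
        _assert_same_decision(make_series(spec["ratios"], probe_id=panel), default_params)
    # down-regulation in 3 consecutive time-points accepted by the oracle
    result = brute_force_oracle(
        make_series(GOLDEN_PATTERNS["B"]["ratios"]), default_params
    )
    assert isinstance(result, WindowCall)
    assert (result.direction, result.run_length) == ("down", 3)


def test_oracle_rejects_single_point_exceedance(default_params):
    result = brute_force_oracle(make_series([1.0, 1.8, 1.0, 1.0]), default_params)
    assert isinstance(result, Rejection)


def test_oracle_equivalence_on_random_series():
    """classify_probe must match literal window enumeration on random data."""
    from conftest import random_series

    rng = np.random.default_rng(2024)
    param_grid = [
        FilterParams(fold_threshold=1.5, escape_threshold=1.5),
        FilterParams(fold_threshold=3.0, escape_threshold=1.5),
        FilterParams(fold_threshold=1.5, escape_threshold=1.5, mask_rule="bridge"),
    ]
    n = 0
    for _ in range(1500):
        length = int(rng.integers(4, 13))
        with_mask = bool(rng.random() < 0.5)
        series = random_series(rng, length, with_mask)
        for params in param_grid:
            _assert_same_decision(series, params)
            n += 1
    assert n >= 4000
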