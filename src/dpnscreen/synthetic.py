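"""Synthetic two-genotype bead-array time-course generator.

Emulates the data regime of an eight-time-point (P20..P56) expression
screen on a diabetic (Akita) vs control (WT) design: raw intensities of
present probes spanning roughly 10-40,000, low expressors under 100 raw
units, absent probes, planted consecutive-window differential profiles,
"zigzagging" noisy low-level profiles, and an optional corrupted chip that
emulates a tissue swap for the clustering QC. Every probe carries a ground
truth row so each downstream stage can be tested for exact recovery.

Probe classes
-------------
stable
    Constant genotype ratio of 1; baseline anywhere in the present range.
developmental_trend
    Smooth monotone intensity trend shared by both genotypes (ratio 1):
    developmentally regulated but not genotype-differential.
planted_window
    Genotype ratio equal to the planted fold over a contiguous window of
    time-points and 1 elsewhere — the profiles the window filter must find.
zigzag_low
    Baseline below the low-expressor cutoff with a sign-alternating ratio
    (above threshold, below reciprocal, ...): the noisy low-level profiles
    the escape constraint is designed to eliminate.
absent
    Baseline below the absent-call level; called absent at all but at most
    one time-point, hence eliminated by the detection filter.

The intensity model is log-uniform per-probe baselines inside the present
range with multiplicative log-normal measurement noise (coefficient of
variation ``noise_cv``) and per-chip log-normal scale factors
(``chip_scale_spread``). Tissues differ by per-probe log-normal factors so
chips of a tissue correlate more with each other than across tissues.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model import (
    CALL_ABSENT,
    CALL_MARGINAL,
    CALL_PRESENT,
    DEFAULT_DAYS,
    ExpressionDataset,
    GENOTYPE_AFFECTED,
    GENOTYPE_CONTROL,
    GENOTYPES,
    ValidationError,
    day_label,
)

CLASS_STABLE = "stable"
CLASS_TREND = "developmental_trend"
CLASS_PLANTED = "planted_window"
CLASS_ZIGZAG = "zigzag_low"
CLASS_ABSENT = "absent"
CLASSES = (CLASS_STABLE, CLASS_TREND, CLASS_PLANTED, CLASS_ZIGZAG, CLASS_ABSENT)

#: Call thresholds on the true (noise-free) expression level.
ABSENT_BELOW = 10.0
MARGINAL_BELOW = 20.0

DEFAULT_FRACTIONS = {
    CLASS_STABLE: 0.55,
    CLASS_TREND: 0.15,
    CLASS_PLANTED: 0.05,
    CLASS_ZIGZAG: 0.10,
    CLASS_ABSENT: 0.15,
}

DEFAULT_PLANTED = ((("up"), 2, 2.0), (("down"), 3, 2.0), (("up"), 4, 1.8))


@dataclass
class SimulationParams:
    """Generator settings; defaults describe the reference study conditions."""

    n_probes: int = 400
    time_points: tuple[str, ...] = tuple(day_label(d) for d in DEFAULT_DAYS)
    tissues: tuple[str, ...] = ("DRG", "endoneurium")
    class_fractions: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_FRACTIONS))
    planted_spec: tuple[tuple[str, int, float], ...] = DEFAULT_PLANTED
    intensity_range: tuple[float, float] = (10.0, 40000.0)
    noise_cv: float = 0.1
    chip_scale_spread: float = 0.05
    zigzag_fold: float = 1.7
    escape_threshold: float = 1.5
    outlier_chip: tuple[str, str, int] | None = None  # (tissue, genotype, day)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_probes <= 0:
            raise ValidationError(f"n_probes must be positive, got {self.n_probes}")
        total = sum(self.class_fractions.values())
        if not math.isclose(total, 1.0, abs_tol=1e-6):
            raise ValidationError(f"class_fractions must sum to 1, got {total}")
        unknown = set(self.class_fractions) - set(CLASSES)
        if unknown:
            raise ValidationError(f"unknown probe classes: {sorted(unknown)}")
        low, high = self.intensity_range
        if not (0 < low < high):
            raise ValidationError("intensity bounds must be positive with low < high")
        n_tp = len(self.time_points)
        for direction, run, fold in self.planted_spec:
            if direction not in ("up", "down"):
                raise ValidationError(f"planted direction must be up/down, got {direction!r}")
            if not 2 <= run <= n_tp:
                raise ValidationError(
                    f"planted run length {run} must be in [2, {n_tp}]"
                )
            if not fold > self.escape_threshold:
                raise ValidationError(
                    f"planted fold {fold} must exceed the escape threshold "
                    f"{self.escape_threshold}"
                )

    @property
    def days(self) -> tuple[int, ...]:
        return tuple(int(tp.lstrip("P")) for tp in self.time_points)


def _class_counts(params: SimulationParams) -> dict[str, int]:
    """Deterministic largest-remainder apportionment of probes to classes."""
    n = params.n_probes
    raw = {c: params.class_fractions.get(c, 0.0) * n for c in CLASSES}
    counts = {c: int(math.floor(v)) for c, v in raw.items()}
    short = n - sum(counts.values())
    by_remainder = sorted(CLASSES, key=lambda c: (-(raw[c] - counts[c]), c))
    for c in by_remainder[:short]:
        counts[c] += 1
    return counts


def _chip_id(tissue: str, genotype: str, day: int) -> str:
    return f"{tissue}_{genotype}_{day_label(day)}"


def generate_dataset(params: SimulationParams) -> tuple[ExpressionDataset, pd.DataFrame]:
    """Generate a dataset and its truth table.

    Returns ``(dataset, truth)`` where ``truth`` is a probe-indexed frame
    with columns ``class, direction, win_start, win_end, fold,
    low_expressor``. Identical params (including seed) give identical
    output. All chips are always emitted; the optional outlier chip is
    corrupted in place, to be found (and only then removed) by QC.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_probes
    n_tp = len(params.time_points)
    days = params.days
    low, high = params.intensity_range
    counts = _class_counts(params)

    classes = np.array([c for c in CLASSES for _ in range(counts[c])])
    probe_ids = np.array([f"probe_{i:05d}" for i in range(n)])

    # Per-probe baselines by class. Tissue factors are bounded in [0.5, 2],
    # so present-range baselines in [210, high/(2.2*max_fold)] keep every
    # noise-free value above the low-expressor cutoff after the smallest
    # factor, above the intensity floor after the largest down-fold, and
    # below the range ceiling after the largest up-fold: at zero noise no
    # clipping or flooring ever distorts a planted ratio.
    max_fold = max([f for _, _, f in params.planted_spec], default=2.0)
    baseline = np.empty(n)
    zig_hi = max(MARGINAL_BELOW * 1.15, 95.0 / (2.0 * params.zigzag_fold))
    for i, cls in enumerate(classes):
        if cls == CLASS_ABSENT:
            baseline[i] = rng.uniform(1.0, 0.8 * ABSENT_BELOW)
        elif cls == CLASS_ZIGZAG:
            # low expressor: present but under the cutoff even at factor 2
            baseline[i] = np.exp(
                rng.uniform(np.log(MARGINAL_BELOW * 1.1), np.log(zig_hi))
            )
        else:
            lo = 2.1 * 100.0
            hi = max(high / (2.2 * max_fold), lo * 1.5)
            baseline[i] = np.exp(rng.uniform(np.log(lo), np.log(hi)))

    # Trend factors (shared by both genotypes; ratio unaffected).
    trend = np.ones((n, n_tp))
    for i, cls in enumerate(classes):
        if cls == CLASS_TREND:
            slope = rng.uniform(-1.0, 1.0)  # log2-fold over the full course
            trend[i] = 2.0 ** (slope * np.linspace(-0.5, 0.5, n_tp))

    # Genotype ratio profiles (Akita multiplier) + truth bookkeeping.
    ratio = np.ones((n, n_tp))
    truth = pd.DataFrame(
        {
            "class": classes,
            "direction": "",
            "win_start": -1,
            "win_end": -1,
            "fold": np.nan,
            "low_expressor": False,
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    planted_idx = np.where(classes == CLASS_PLANTED)[0]
    for j, i in enumerate(planted_idx):
        direction, run, fold = params.planted_spec[j % len(params.planted_spec)]
        start = int(rng.integers(0, n_tp - run + 1))
        factor = fold if direction == "up" else 1.0 / fold
        ratio[i, start : start + run] = factor
        truth.loc[probe_ids[i], ["direction", "win_start", "win_end", "fold"]] = (
            direction,
            start,
            start + run - 1,
            fold,
        )
    zig_idx = np.where(classes == CLASS_ZIGZAG)[0]
    for i in zig_idx:
        phase = int(rng.integers(0, 2))
        zig = np.array(
            [params.zigzag_fold if (t + phase) % 2 == 0 else 1.0 / params.zigzag_fold for t in range(n_tp)]
        )
        ratio[i] = zig
    truth.loc[probe_ids[zig_idx], "low_expressor"] = True

    # Tissue-specific per-probe factors: chips of a tissue share a profile.
    # Bounded in [0.5, 2] so class intensity designs cannot clip (see above).
    def draw_tissue_factor() -> np.ndarray:
        return np.exp(rng.uniform(np.log(0.5), np.log(2.0), size=n))

    tissue_factor = {tissue: draw_tissue_factor() for tissue in params.tissues}

    sigma_noise = math.sqrt(math.log(1.0 + params.noise_cv**2)) if params.noise_cv > 0 else 0.0
    sigma_chip = params.chip_scale_spread

    chip_ids, manifest_rows = [], []
    raw_cols: dict[str, np.ndarray] = {}
    call_cols: dict[str, np.ndarray] = {}

    # Absent probes: one optional "present" artifact call per probe.
    absent_idx = np.where(classes == CLASS_ABSENT)[0]
    artifact_tp = {i: int(rng.integers(0, n_tp)) for i in absent_idx}
    artifact_geno = {i: GENOTYPES[int(rng.integers(0, 2))] for i in absent_idx}

    for tissue in params.tissues:
        for genotype in GENOTYPES:
            for t, day in enumerate(days):
                chip = _chip_id(tissue, genotype, day)
                level = baseline * trend[:, t]
                if genotype == GENOTYPE_AFFECTED:
                    level = level * ratio[:, t]
                # detection calls from the true level (ratio applied, tissue
                # factor and noise excluded: calls mimic an intensity gate)
                call = np.where(
                    level < ABSENT_BELOW,
                    CALL_ABSENT,
                    np.where(level < MARGINAL_BELOW, CALL_MARGINAL, CALL_PRESENT),
                )
                for i in absent_idx:
                    if artifact_tp[i] == t and artifact_geno[i] == genotype:
                        call[i] = CALL_PRESENT
                    else:
                        call[i] = CALL_ABSENT

                values = level * tissue_factor[tissue]
                if sigma_noise > 0:
                    values = values * np.exp(rng.normal(0.0, sigma_noise, size=n))
                scale = np.exp(rng.normal(0.0, sigma_chip)) if sigma_chip > 0 else 1.0
                values = values * scale
                # keep present-class probes inside the stated intensity range
                present_like = classes != CLASS_ABSENT
                values[present_like] = np.clip(values[present_like], low, high)

                chip_ids.append(chip)
                raw_cols[chip] = values
                call_cols[chip] = call
                manifest_rows.append({"chip_id": chip, "tissue": tissue, "genotype": genotype, "day": day})

    if params.outlier_chip is not None:
        tissue, genotype, day = params.outlier_chip
        chip = _chip_id(tissue, genotype, day)
        if chip not in raw_cols:
            raise ValidationError(f"outlier chip {chip!r} not in the design")
        # tissue swap: redraw the chip from another tissue's profile
        others = [t for t in params.tissues if t != tissue]
        swap_factor = tissue_factor[others[0]] if others else draw_tissue_factor()
        t_idx = days.index(day)
        level = baseline * trend[:, t_idx] * swap_factor
        noise = np.exp(rng.normal(0.0, max(sigma_noise, 0.05), size=n))
        values = level * noise
        present_like = classes != CLASS_ABSENT
        values[present_like] = np.clip(values[present_like], low, high)
        raw_cols[chip] = values

    raw = pd.DataFrame(raw_cols, index=probe_ids)
    calls = pd.DataFrame(call_cols, index=probe_ids)
    manifest = pd.DataFrame(manifest_rows).set_index("chip_id")
    dataset = ExpressionDataset(raw=raw, calls=calls, manifest=manifest)
    return dataset, truth


# ---------------------------------------------------------------------------
# Canonical per-probe fold-change fixtures (selection-rule golden patterns)
# ---------------------------------------------------------------------------

#: Four canonical ratio profiles over P20..P56 with their expected decision:
#: A - up-regulation in 2 consecutive time-points               -> selected
#: B - down-regulation in 3 consecutive time-points             -> selected
#: C - up in 2 consecutive plus an isolated later up-excursion  -> eliminated
#: D - down in 3 consecutive followed by a later up-excursion   -> eliminated
GOLDEN_PATTERNS: dict[str, dict] = {
    "A": {
        "ratios": (1.0, 1.0, 1.8, 1.8, 1.0, 1.0, 1.0, 1.0),
        "expected": "selected",
        "direction": "up",
        "run_length": 2,
    },
    "B": {
        "ratios": (1.0, 1.0, 0.55, 0.55, 0.55, 1.0, 1.0, 1.0),
        "expected": "selected",
        "direction": "down",
        "run_length": 3,
    },
    "C": {
        # up at P28-P32, back in band at P36-P40, isolated up at P48
        "ratios": (1.0, 1.0, 1.8, 1.8, 1.0, 1.0, 1.8, 1.0),
        "expected": "eliminated",
        "direction": None,
        "run_length": None,
    },
    "D": {
        # down at P28-P36, later up-excursion at P56
        "ratios": (1.0, 1.0, 0.55, 0.55, 0.55, 1.0, 1.0, 1.8),
        "expected": "eliminated",
        "direction": None,
        "run_length": None,
    },
}


def write_fixture_suite(out_dir: str | Path) -> dict[str, Path]:
    """Write the four golden fold-change fixtures and expected decisions.

    Emits one TSV per panel (columns ``day, fold_change``) plus
    ``expected_decisions.tsv``; returns a name -> path manifest.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Path] = {}
    decisions = []
    for panel, spec in GOLDEN_PATTERNS.items():
        path = out_dir / f"pattern_{panel}.tsv"
        pd.DataFrame(
            {"day": list(DEFAULT_DAYS), "fold_change": list(spec["ratios"])}
        ).to_csv(path, sep="\t", index=False)
        manifest[f"pattern_{panel}"] = path
        decisions.append({"panel": panel, "expected": spec["expected"]})
    dec_path = out_dir / "expected_decisions.tsv"
    pd.DataFrame(decisions).to_csv(dec_path, sep="\t", index=False)
    manifest["expected_decisions"] = dec_path
    return manifest
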