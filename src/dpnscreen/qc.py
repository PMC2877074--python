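"""Chip-level quality control and per-tissue normalization.

QC follows the bead-array practice of summarizing each chip (mean
intensity, fraction of present calls) and clustering chips on the
correlation of their log-intensities: a chip whose cluster is dominated by
another tissue is flagged for elimination — the scenario in which a
mislabeled or swapped endoneurium chip lands inside the DRG cluster.

Normalization is applied strictly within each tissue. Quantile
normalization (rank-based distribution matching) stands in for the bead
scanner's cubic-spline option; both equalize intensity distributions
across chips and the choice is recorded in the run log.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .model import CALL_PRESENT, ExpressionDataset, ValidationError

logger = logging.getLogger("dpnscreen")

REASON_TISSUE_MISMATCH = "clustered_with_majority_tissue:{majority}"
REASON_TIE = "ambiguous_cluster_tie:{tissues}"
REASON_DEGENERATE = "constant_chip_undefined_correlation"


@dataclass
class ChipQCReport:
    """Per-chip QC table: summary stats, cluster label, outlier flag + reason."""

    table: pd.DataFrame  # index chip_id; columns mean_intensity, fraction_present,
    #                       tissue, cluster, outlier, reason

    @property
    def flagged(self) -> list[str]:
        return list(self.table.index[self.table["outlier"]])


def chip_summary(dataset: ExpressionDataset) -> pd.DataFrame:
    """Mean raw intensity and fraction of present calls per chip."""
    if dataset.raw.empty:
        raise ValidationError("empty dataset")
    mean_intensity = dataset.raw.mean(axis=0)
    fraction_present = (dataset.calls == CALL_PRESENT).mean(axis=0)
    out = pd.DataFrame(
        {
            "mean_intensity": mean_intensity,
            "fraction_present": fraction_present,
            "tissue": dataset.manifest.loc[dataset.chip_ids, "tissue"],
        }
    )
    out.index.name = "chip_id"
    return out


def cluster_outliers(
    dataset: ExpressionDataset,
    n_clusters: int | None = None,
    method: str = "average",
) -> ChipQCReport:
    """Flag chips clustering with the wrong tissue.

    Chips are clustered by average-linkage hierarchical clustering on
    ``1 - Pearson correlation`` of ``log2(raw + 1)`` and cut into
    ``n_clusters`` groups (default: number of tissues). A chip is flagged
    when the majority tissue of its cluster differs from its manifest
    tissue; a cluster whose tissue vote ties flags all its chips rather
    than passing silently. Constant chips (undefined correlation) are
    flagged as degenerate and left out of the clustering.
    """
    if dataset.raw.shape[1] < 3:
        raise ValidationError("clustering QC needs at least 3 chips")
    report = chip_summary(dataset)
    report["cluster"] = -1
    report["outlier"] = False
    report["reason"] = ""

    log_x = np.log2(dataset.raw.to_numpy(dtype=float) + 1.0)
    stds = log_x.std(axis=0)
    degenerate = stds < 1e-12  # constant chip: correlation undefined
    for chip in dataset.chip_ids[degenerate]:
        report.loc[chip, ["outlier", "reason"]] = True, REASON_DEGENERATE
    usable = ~degenerate
    chips = dataset.chip_ids[usable]
    if len(chips) < 3:
        return ChipQCReport(report)

    corr = np.corrcoef(log_x[:, usable], rowvar=False)
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method=method)
    k = n_clusters if n_clusters is not None else len(dataset.tissues)
    k = min(k, len(chips))
    labels = fcluster(z, t=k, criterion="maxclust")
    report.loc[chips, "cluster"] = labels
    logger.info("QC clustering: %d chips into %d clusters (%s linkage)", len(chips), k, method)

    tissues = dataset.manifest.loc[chips, "tissue"]
    for label in np.unique(labels):
        members = chips[labels == label]
        counts = tissues.loc[members].value_counts()
        top = counts[counts == counts.max()]
        if len(top) > 1:
            reason = REASON_TIE.format(tissues=",".join(sorted(top.index)))
            report.loc[members, "outlier"] = True
            report.loc[members, "reason"] = reason
            continue
        majority = top.index[0]
        for chip in members:
            if tissues.loc[chip] != majority:
                report.loc[chip, "outlier"] = True
                report.loc[chip, "reason"] = REASON_TISSUE_MISMATCH.format(majority=majority)
    for chip in report.index[report["outlier"]]:
        logger.info("QC flagged chip %s: %s", chip, report.loc[chip, "reason"])
    return ChipQCReport(report)


def _quantile_normalize(x: np.ndarray) -> np.ndarray:
    """Classic quantile normalization: every column gets the mean sorted profile."""
    order = np.argsort(x, axis=0, kind="stable")
    sorted_x = np.take_along_axis(x, order, axis=0)
    mean_profile = sorted_x.mean(axis=1)
    out = np.empty_like(x, dtype=float)
    ranks = np.empty_like(order)
    rows = np.arange(x.shape[0])[:, None]
    np.put_along_axis(ranks, order, np.broadcast_to(rows, x.shape).copy(), axis=0)
    out = mean_profile[ranks]
    return out


def normalize_per_tissue(
    dataset: ExpressionDataset, method: str = "quantile"
) -> ExpressionDataset:
    """Normalize intensities within each tissue independently.

    ``"quantile"`` equalizes within-tissue intensity distributions (every
    chip of a tissue ends with the identical value multiset); ``"none"``
    is the identity. Detection calls are never touched. A tissue with a
    single chip is passed through with a warning (quantile undefined).
    """
    if method not in ("quantile", "none"):
        raise ValidationError(f"unknown normalization method {method!r}")
    if method == "none":
        return ExpressionDataset(
            raw=dataset.raw.copy(), calls=dataset.calls.copy(), manifest=dataset.manifest.copy()
        )
    raw = dataset.raw.copy()
    for tissue in dataset.tissues:
        chips = dataset.chips_for(tissue)
        if len(chips) < 2:
            warnings.warn(
                f"tissue {tissue!r} has a single chip; quantile normalization skipped",
                stacklevel=2,
            )
            continue
        raw.loc[:, chips] = _quantile_normalize(raw[chips].to_numpy(dtype=float))
    return ExpressionDataset(raw=raw, calls=dataset.calls.copy(), manifest=dataset.manifest.copy())


def median_profile(
    dataset: ExpressionDataset,
    probe_ids: list[str],
    tissue: str | None = None,
) -> pd.DataFrame:
    """Per-probe time profiles scaled by the probe's median intensity.

    Each probe's intensities are divided by that probe's median across all
    retained chips (of the tissue, when given), yielding the
    median-normalized profiles used for candidate-gene plots. Returns a
    tidy frame ``(probe_id, day, genotype, value)``; probes with median 0
    are reported with NaN values rather than dividing by zero.
    """
    chips = dataset.chips_for(tissue)
    if tissue is not None and not chips:
        raise ValidationError(f"tissue {tissue!r} not in manifest")
    missing = [p for p in probe_ids if p not in dataset.probe_ids]
    if missing:
        raise ValidationError(f"unknown probes: {missing}")
    rows = []
    manifest = dataset.manifest.loc[chips]
    for probe in probe_ids:
        values = dataset.raw.loc[probe, chips].to_numpy(dtype=float)
        med = float(np.median(values)) if len(values) else 0.0
        for chip, value in zip(chips, values):
            rows.append(
                {
                    "probe_id": probe,
                    "day": int(manifest.loc[chip, "day"]),
                    "genotype": manifest.loc[chip, "genotype"],
                    "value": value / med if med > 0 else np.nan,
                }
            )
    out = pd.DataFrame(rows, columns=["probe_id", "day", "genotype", "value"])
    return out.sort_values(["probe_id", "day", "genotype"], kind="stable").reset_index(drop=True)
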