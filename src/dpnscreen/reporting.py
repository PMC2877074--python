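"""Run-length summaries, candidate-gene panel profiles and the full pipeline.

`summarize` turns a list of accepted window calls into the run-length
summary table: for each minimum run length k in {2..6}, how many probes
were differentially expressed in at least k consecutive time-points, and
how many of those are low expressors. `run_pipeline` chains
QC -> chip exclusion -> per-tissue normalization -> detection filter ->
fold-change window selection -> summary, writing every artifact and a log
that records each parameter and each excluded chip.
"""

from __future__ import annotations

import logging
from dataclasses import asdict
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from . import io as dio
from .detection import consecutive_present_filter
from .model import (
    ExpressionDataset,
    FilterParams,
    GenePanel,
    Rejection,
    RunLengthSummary,
    ValidationError,
    WindowCall,
)
from .qc import ChipQCReport, chip_summary, cluster_outliers, median_profile, normalize_per_tissue
from .windows import classify_dataset, classify_probe, compute_fold_changes, rejection_histogram

logger = logging.getLogger("dpnscreen")

RUN_LENGTHS = (2, 3, 4, 5, 6)


def summarize(
    calls: Iterable[WindowCall],
    tissue: str = "",
    platform_size: int = 0,
    eliminated: int = 0,
    ks: Sequence[int] = RUN_LENGTHS,
    mode: str = "cumulative",
) -> RunLengthSummary:
    """Count accepted probes by minimum consecutive run length.

    ``mode='cumulative'`` counts calls with run length >= k (so the k=2 row
    includes every accepted probe); ``'exact'`` counts run length == k.
    """
    if mode not in ("cumulative", "exact"):
        raise ValidationError(f"unknown summary mode {mode!r}")
    calls = list(calls)
    rows = []
    for k in ks:
        if mode == "cumulative":
            hits = [c for c in calls if c.run_length >= k]
        else:
            hits = [c for c in calls if c.run_length == k]
        rows.append(
            {
                "k": k,
                "n_probes": len(hits),
                "n_low_expressor": sum(c.low_expressor for c in hits),
            }
        )
    table = pd.DataFrame(rows, columns=["k", "n_probes", "n_low_expressor"])
    return RunLengthSummary(
        tissue=tissue,
        table=table,
        platform_size=platform_size,
        eliminated_by_detection=eliminated,
        mode=mode,
    )


# ---------------------------------------------------------------------------
# Candidate-gene panels
# ---------------------------------------------------------------------------


def load_default_panels() -> dict[str, GenePanel]:
    """The three packaged candidate-gene panels (symbols only).

    Probe mappings are platform-annotation data and are supplied by the
    caller (see :func:`attach_probe_mapping`).
    """
    with resources.files("dpnscreen.data").joinpath("panels.tsv").open() as fh:
        table = pd.read_csv(fh, sep="\t")
    panels: dict[str, GenePanel] = {}
    for name, group in table.groupby("panel", sort=True):
        panels[name] = GenePanel(name=name, genes=tuple(group["gene"]))
    return panels


def attach_probe_mapping(panel: GenePanel, mapping: pd.DataFrame) -> GenePanel:
    """Attach a gene->probe mapping table (columns ``gene, probe_id``)."""
    lookup: dict[str, tuple[str, ...]] = {}
    for gene in panel.genes:
        probes = mapping.loc[mapping["gene"] == gene, "probe_id"]
        lookup[gene] = tuple(probes)
    return GenePanel(name=panel.name, genes=panel.genes, mapping=lookup)


def panel_profiles(
    dataset: ExpressionDataset,
    panel: GenePanel,
    tissue: str,
    params: FilterParams | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Median-normalized profiles and filter flags for a gene panel.

    Returns ``(profiles, flags)``: ``profiles`` is a tidy table
    ``(gene, probe_id, day, genotype, value)`` of per-probe intensities
    scaled by the probe's median across the tissue's retained chips;
    ``flags`` reports per gene whether any of its probes passes the
    window filter (and lists unmapped symbols with no verdict).
    """
    params = params or FilterParams()
    mapped = {g: ps for g, ps in panel.mapping.items() if ps}
    probe_ids = [p for ps in mapped.values() for p in ps]
    profiles = median_profile(dataset, probe_ids, tissue)
    gene_of = {p: g for g, ps in mapped.items() for p in ps}
    if not profiles.empty:
        profiles.insert(0, "gene", profiles["probe_id"].map(gene_of))
    else:
        profiles["gene"] = pd.Series(dtype=str)

    series_by_probe = {
        s.probe_id: s for s in compute_fold_changes(dataset, tissue, params, probe_ids)
    }
    flag_rows = []
    for gene in panel.genes:
        probes = panel.mapping.get(gene, ())
        if not probes:
            flag_rows.append({"gene": gene, "mapped": False, "passes_filter": None})
            continue
        passes = any(
            classify_probe(series_by_probe[p], params).accepted for p in probes
        )
        flag_rows.append({"gene": gene, "mapped": True, "passes_filter": passes})
    flags = pd.DataFrame(flag_rows, columns=["gene", "mapped", "passes_filter"])
    return profiles, flags


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------


def run_pipeline(config: dio.AnalysisConfig) -> dict[str, Path]:
    """Execute the complete screen described by a config; return file manifest.

    Stages: read -> chip QC (clustering outlier elimination plus manual
    exclusions) -> per-tissue normalization -> detection-call filter ->
    floored fold-change window selection -> run-length summary. Re-running
    with identical config and inputs is bit-identical.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / "pipeline.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        logger.info("filter parameters: %s", asdict(config.filter))
        logger.info("normalization: %s; auto_qc: %s", config.normalization, config.auto_qc)
        dataset = dio.read_dataset(config.matrix, config.calls, config.manifest)
        platform_size = len(dataset.probe_ids)

        excluded: list[str] = list(config.exclude_chips)
        for chip in excluded:
            logger.info("excluded chip %s: manual exclusion list", chip)
        qc_report: ChipQCReport | None = None
        if config.auto_qc and dataset.raw.shape[1] >= 3:
            qc_report = cluster_outliers(dataset)
            excluded += [c for c in qc_report.flagged if c not in excluded]
        else:
            summary_only = chip_summary(dataset)
            qc_report = ChipQCReport(
                summary_only.assign(cluster=-1, outlier=False, reason="")
            )
        qc_path = out_dir / "chip_qc.tsv"
        qc_report.table.to_csv(qc_path, sep="\t", index_label="chip_id")
        dataset = dataset.drop_chips(excluded)
        logger.info("retained %d chips after QC", dataset.raw.shape[1])

        dataset = normalize_per_tissue(dataset, config.normalization)

        tissue = config.tissue
        retained, eliminated = consecutive_present_filter(dataset, tissue, config.filter)
        logger.info(
            "detection filter (%s): retained %d probes, eliminated %d of %d",
            tissue,
            len(retained),
            eliminated,
            platform_size,
        )

        accepted, rejected = classify_dataset(dataset, tissue, config.filter, list(retained))
        logger.info("window filter accepted %d probes", len(accepted))
        logger.info("rejection histogram: %s", rejection_histogram(rejected))

        summary = summarize(
            accepted, tissue=tissue, platform_size=platform_size, eliminated=eliminated
        )
        days = dataset.days(tissue)
        paths = dio.write_results(accepted, summary, out_dir, days=days)
        paths["qc"] = qc_path
        paths["log"] = log_path
        return paths
    finally:
        logger.removeHandler(handler)
        handler.close()
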