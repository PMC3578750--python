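"""End-to-end genome-wide analysis: simulate/ingest -> promoters ->
enrichment calls -> activity classes -> timing comparisons.

Defaults follow the genome-wide protocol: 2 kb uniqueness window, 1 kb
promoters, >= 10 contained probes per promoter, two-component Gaussian
mixture fit genome-wide with the 80% promoter rule, bootstrap depth 10^4
with alpha = 0.025 per tail, and a two-sided Wilcoxon rank-sum test.  The
run is deterministic given its seed and produces a machine-readable report
plus intermediate TSVs when an output directory is given.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as rio
from .activity import classify_activity
from .comparison import compare_timing_groups
from .enrichment import call_enrichment_track
from .promoters import (
    find_unique_tss,
    make_promoter_windows,
    summarize_promoter_timing,
)
from .synthetic_data import SimulationConfig, SyntheticDataset, simulate_dataset

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_genomewide_analysis", "analyze_dataset"]


@dataclass
class RunConfig:
    """Configuration of a full genome-wide run on synthetic data."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    feature: str = "H3K27me3"
    min_probes: int = 10
    enrichment_threshold: float = 0.8
    n_resamples: int = 10_000
    alpha: float = 0.025
    zero_threshold: float = 0.0
    weighted: bool = True
    seed: int = 0
    outdir: str | Path | None = None

    def validate(self) -> None:
        if self.min_probes < 1:
            raise ValueError("min_probes must be >= 1")
        if not 0 < self.enrichment_threshold <= 1:
            raise ValueError("enrichment_threshold must be in (0, 1]")
        if not 0 < self.alpha < 0.5:
            raise ValueError("alpha must be in (0, 0.5)")
        if self.n_resamples < 1:
            raise ValueError("n_resamples must be >= 1")


def analyze_dataset(
    dataset: SyntheticDataset | dict,
    config: RunConfig,
) -> dict:
    """Run the analysis stages on an in-memory dataset; returns the report.

    ``dataset`` needs annotation, chip_track, timing_track and expression
    tables (a dict with those keys is accepted for ingested data).
    """
    config.validate()
    if isinstance(dataset, dict):
        annotation = dataset["annotation"]
        chip_track = dataset["chip_track"]
        timing_track = dataset["timing_track"]
        expression = dataset["expression"]
    else:
        annotation = dataset.annotation
        chip_track = dataset.chip_track
        timing_track = dataset.timing_track
        expression = dataset.expression

    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    logger.info("stage 1/5: unique TSS selection (%d TSSs in)", len(annotation))
    unique = find_unique_tss(annotation)
    windows = make_promoter_windows(unique)
    promoters = summarize_promoter_timing(
        windows, timing_track, min_probes=config.min_probes
    )
    n_kept = int((~promoters["discarded"]).sum())
    logger.info(
        "stage 2/5: %d promoters (%d kept, %d discarded)",
        len(promoters),
        n_kept,
        len(promoters) - n_kept,
    )

    logger.info("stage 3/5: mixture fit and enrichment calls")
    calls, gmm = call_enrichment_track(
        promoters,
        chip_track,
        threshold=config.enrichment_threshold,
        feature=config.feature,
        seed=config.seed,
    )
    n_enriched = int(calls["enriched"].sum())
    logger.info("%d promoters enriched for %s", n_enriched, config.feature)

    logger.info("stage 4/5: activity classes")
    activity = classify_activity(expression, zero_threshold=config.zero_threshold)

    report: dict = {
        "software": "replitime",
        "seed": config.seed,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "feature": config.feature,
        "counts": {
            "tss_in": int(len(annotation)),
            "unique_tss": int(len(unique)),
            "promoter_windows": int(len(windows)),
            "promoters_kept": n_kept,
            "promoters_discarded": int(len(promoters)) - n_kept,
            "enriched": n_enriched,
            "non_enriched": int(len(calls)) - n_enriched,
        },
        "gmm": gmm.to_dict(),
        "parameters": {
            "min_probes": config.min_probes,
            "enrichment_threshold": config.enrichment_threshold,
            "n_resamples": config.n_resamples,
            "alpha": config.alpha,
            "weighted": config.weighted,
        },
    }

    logger.info("stage 5/5: timing comparison")
    membership = pd.Series(
        pd.Categorical.from_codes(
            calls["enriched"].astype(int), categories=["non-enriched", "enriched"]
        ).astype(str),
        index=calls["promoter_id"],
        name="group",
    )
    kept_ids = promoters.loc[~promoters["discarded"], "promoter_id"]
    group_sizes = membership.reindex(kept_ids).value_counts()
    if group_sizes.get("enriched", 0) == 0 or group_sizes.get("non-enriched", 0) == 0:
        logger.warning(
            "a comparison group is empty (sizes: %s); comparison skipped",
            dict(group_sizes),
        )
        report["comparison"] = None
        report["comparison_weighted"] = None
    else:
        statuses = activity.set_index("promoter_id")["status"]
        unweighted = compare_timing_groups(
            promoters,
            membership,
            statuses=None,
            n_resamples=config.n_resamples,
            alpha=config.alpha,
            seed=config.seed,
        )
        report["comparison"] = unweighted.to_dict()
        if config.weighted:
            weighted = compare_timing_groups(
                promoters,
                membership,
                statuses=statuses,
                n_resamples=config.n_resamples,
                alpha=config.alpha,
                seed=config.seed,
            )
            report["comparison_weighted"] = weighted.to_dict()
        else:
            report["comparison_weighted"] = None

    if outdir:
        rio.write_table(promoters, outdir / "promoters.tsv")
        rio.write_table(calls, outdir / "calls.tsv")
        rio.write_table(activity, outdir / "activity.tsv")
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2)
    return report


def run_genomewide_analysis(config: RunConfig) -> dict:
    """Simulate a dataset and run the full analysis; returns the report."""
    config.validate()
    sim_config = dataclasses.replace(config.simulation, seed=config.seed)
    logger.info("stage 0/5: simulating dataset (seed %d)", config.seed)
    dataset = simulate_dataset(sim_config)
    if config.outdir:
        dataset.write(Path(config.outdir) / "data")
    return analyze_dataset(dataset, config)
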