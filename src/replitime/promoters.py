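"""Unique-TSS selection, promoter windows, and per-promoter timing summaries.

A TSS is *unique* when no other annotated TSS lies within a 2 kb window
centered on it, i.e. no neighbor at distance <= 1000 bp on the same
chromosome (the boundary distance of exactly 1000 bp disqualifies, and two
transcripts annotated at the same base disqualify each other).  The promoter
of a unique TSS is the 1 kb window centered on it, [tss-500, tss+500) in
0-based half-open coordinates.  Promoter replication timing is the median
score of the probes mapping *entirely* within the window; promoters with
fewer than ``min_probes`` (default 10) such probes are flagged discarded.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "find_unique_tss",
    "make_promoter_windows",
    "probes_in_promoter",
    "summarize_promoter_timing",
    "contained_probe_indices",
]

ANNOTATION_COLUMNS = ["gene_id", "chrom", "strand", "tss"]


def _validate_annotation(annotation: pd.DataFrame) -> None:
    missing = [c for c in ANNOTATION_COLUMNS if c not in annotation.columns]
    if missing:
        raise ValueError(f"annotation is missing columns: {missing}")
    if len(annotation) == 0:
        return
    if (annotation["tss"] < 0).any():
        raise ValueError("TSS positions must be non-negative")
    bad = set(annotation["strand"]) - {"+", "-"}
    if bad:
        raise ValueError(f"invalid strand values: {sorted(bad)}")


def find_unique_tss(
    annotation: pd.DataFrame, max_neighbor_distance: int = 1000
) -> pd.DataFrame:
    """Return the TSSs with no other TSS within ``max_neighbor_distance`` bp.

    The distance rule is inclusive: a neighbor at exactly the maximum
    distance disqualifies both TSSs.  Output is sorted by (chrom, tss,
    gene_id) and is independent of the input row order.
    """
    _validate_annotation(annotation)
    if len(annotation) == 0:
        return annotation.copy()
    out = annotation.sort_values(
        ["chrom", "tss", "gene_id"], kind="mergesort"
    ).reset_index(drop=True)
    keep = np.ones(len(out), dtype=bool)
    for _, idx in out.groupby("chrom", sort=False).groups.items():
        pos = out.loc[idx, "tss"].to_numpy()
        gaps = np.diff(pos)
        close = gaps <= max_neighbor_distance
        chrom_keep = np.ones(len(pos), dtype=bool)
        chrom_keep[:-1] &= ~close
        chrom_keep[1:] &= ~close
        keep[np.asarray(idx)] = chrom_keep
    return out[keep].reset_index(drop=True)


def make_promoter_windows(
    unique_tss: pd.DataFrame, window_size: int = 1000
) -> pd.DataFrame:
    """Build the ``window_size`` bp promoter window centered on each TSS.

    Windows are [tss - w/2, tss + w/2) regardless of strand.  TSSs closer
    than half a window to the chromosome start would leave the coordinate
    space and are skipped with a warning.
    """
    _validate_annotation(unique_tss)
    half = window_size // 2
    ok = unique_tss["tss"] >= half
    n_skipped = int((~ok).sum())
    if n_skipped:
        logger.warning(
            "skipping %d promoter(s) whose window would extend past "
            "position 0",
            n_skipped,
        )
    kept = unique_tss[ok]
    return pd.DataFrame(
        {
            "promoter_id": kept["gene_id"].to_numpy(),
            "chrom": kept["chrom"].to_numpy(),
            "start": kept["tss"].to_numpy() - half,
            "end": kept["tss"].to_numpy() - half + window_size,
            "strand": kept["strand"].to_numpy(),
            "tss": kept["tss"].to_numpy(),
        }
    )


def probes_in_promoter(promoter, track: pd.DataFrame) -> pd.DataFrame:
    """Probes of ``track`` entirely contained in one promoter window.

    ``promoter`` is a mapping/Series with chrom, start and end.  A probe is
    contained when probe.start >= start and probe.end <= end on the same
    chromosome; partial overlaps are excluded.
    """
    mask = (
        (track["chrom"] == promoter["chrom"])
        & (track["start"] >= promoter["start"])
        & (track["end"] <= promoter["end"])
    )
    return track[mask]


def contained_probe_indices(
    promoters: pd.DataFrame, track: pd.DataFrame
):
    """Yield ``(promoter_id, index_array)`` of contained probes per promoter.

    Index arrays refer to positional rows of ``track``.  Probes with
    non-finite values are dropped first (they count toward nothing).
    """
    track = track.reset_index(drop=True)
    finite = np.isfinite(track["value"].to_numpy())
    track = track[finite]
    by_chrom = {}
    for chrom, sub in track.groupby("chrom", sort=False):
        sub = sub.sort_values("start", kind="mergesort")
        by_chrom[chrom] = (
            sub["start"].to_numpy(),
            sub["end"].to_numpy(),
            sub.index.to_numpy(),
        )
    for row in promoters.itertuples(index=False):
        entry = by_chrom.get(row.chrom)
        if entry is None:
            yield row.promoter_id, np.empty(0, dtype=np.int64)
            continue
        starts, ends, orig = entry
        i0 = np.searchsorted(starts, row.start, side="left")
        i1 = np.searchsorted(starts, row.end, side="left")
        sel = ends[i0:i1] <= row.end
        yield row.promoter_id, orig[i0:i1][sel]


def summarize_promoter_timing(
    promoters: pd.DataFrame, timing_track: pd.DataFrame, min_probes: int = 10
) -> pd.DataFrame:
    """Attach n_probes, median replication timing and the discarded flag.

    ``replication_timing`` is the median value of probes entirely contained
    in the promoter window (even counts average the two central values); it
    is NaN — and the promoter flagged ``discarded`` — when fewer than
    ``min_probes`` probes map inside.
    """
    if min_probes < 1:
        raise ValueError("min_probes must be >= 1")
    values = timing_track["value"].to_numpy()
    n_probes = np.zeros(len(promoters), dtype=np.int64)
    timing = np.full(len(promoters), np.nan)
    for i, (_, idx) in enumerate(
        contained_probe_indices(promoters, timing_track)
    ):
        n_probes[i] = len(idx)
        if len(idx) >= min_probes:
            timing[i] = float(np.median(values[idx]))
    out = promoters.copy()
    out["n_probes"] = n_probes
    out["replication_timing"] = timing
    out["discarded"] = n_probes < min_probes
    n_disc = int(out["discarded"].sum())
    if n_disc:
        logger.info(
            "discarded %d promoter(s) with fewer than %d mapping probes",
            n_disc,
            min_probes,
        )
    return out
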