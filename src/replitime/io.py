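"""Plain-text readers and writers for the formats the pipeline exchanges.

All genomic coordinates are 0-based, half-open (BED convention).  Annotations
travel as BED6 where each record is a 1 bp interval at the strand-aware
transcription start site; probe-level signal travels as 4-column bedGraph;
tabular data (expression, truth labels, promoter summaries, enrichment
calls, activity classes, qPCR Ct tables) travels as TSV with a header line.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]
BEDGRAPH_COLUMNS = ["chrom", "start", "end", "value"]
CT_COLUMNS = ["sample", "target", "fraction", "replicate", "ct"]


def write_annotation_bed6(annotation: pd.DataFrame, path: str | Path) -> None:
    """Write a TSS annotation (gene_id, chrom, strand, tss) as BED6.

    Each TSS becomes a 1 bp interval [tss, tss+1) named by its gene id.
    """
    bed = pd.DataFrame(
        {
            "chrom": annotation["chrom"],
            "start": annotation["tss"].astype(int),
            "end": annotation["tss"].astype(int) + 1,
            "name": annotation["gene_id"],
            "score": 0,
            "strand": annotation["strand"],
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)


def read_annotation_bed6(path: str | Path) -> pd.DataFrame:
    """Read a BED6 file into a TSS annotation table.

    The strand-aware transcript start is used as the TSS: the interval start
    for + strand records, ``end - 1`` for - strand records.
    """
    bed = pd.read_csv(path, sep="\t", header=None, names=BED6_COLUMNS, comment="#")
    tss = bed["start"].where(bed["strand"] == "+", bed["end"] - 1)
    return pd.DataFrame(
        {
            "gene_id": bed["name"].astype(str),
            "chrom": bed["chrom"].astype(str),
            "strand": bed["strand"].astype(str),
            "tss": tss.astype(int),
        }
    )


def write_bedgraph(track: pd.DataFrame, path: str | Path) -> None:
    track[BEDGRAPH_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    track = pd.read_csv(
        path, sep="\t", header=None, names=BEDGRAPH_COLUMNS, comment="#"
    )
    track["chrom"] = track["chrom"].astype(str)
    return track


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_ct_table(path: str | Path) -> pd.DataFrame:
    """Read a qPCR Ct table and validate its schema."""
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in CT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"Ct table is missing required columns: {missing}")
    return table
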