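"""Readers/writers for the plain-text formats the pipeline exchanges.

All tables are TSV; copy number uses the standard SEG columns (sample, chrom,
start, end, num_mark, seg_mean) with 0-based half-open intervals; islands use
a BED-like table (chrom, start, end, cgi_id).
"""
from __future__ import annotations

from pathlib import Path

import pandas as pd

FLOAT_FMT = "%.10g"


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Probe x sample or gene x sample matrix with ids in the first column."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"probe_id", "chrom", "pos", "cgi_id", "region"}
    if not need <= set(df.columns):
        raise ValueError(f"manifest must have columns {sorted(need)}")
    return df


def read_islands(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "cgi_id" not in df.columns:  # headerless BED
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["chrom", "start", "end", "cgi_id"])
    return df


def read_annotation(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"gene_id", "chrom", "tss", "strand", "cgi_ids"}
    if not need <= set(df.columns):
        raise ValueError(f"annotation must have columns {sorted(need)}")
    return df


def read_seg(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"sample", "chrom", "start", "end", "seg_mean"}
    if not need <= set(df.columns):
        raise ValueError(f"SEG file must have columns {sorted(need)}")
    return df


def read_clinical(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    need = {"time", "event"}
    if not need <= set(df.columns):
        raise ValueError(f"clinical table must have columns {sorted(need)}")
    return df


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> str:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT, index=index)
    return str(path)
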