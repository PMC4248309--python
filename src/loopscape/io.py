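"""Readers/writers for the plain-text formats the pipeline exchanges.

BED and BEDPE are consumed and produced as headerless TSV with 0-based
half-open coordinates; tables with named columns use headered TSV.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

BEDPE_COLS = ["chrom1", "start1", "end1", "chrom2", "start2", "end2",
              "name", "score", "strand1", "strand2"]
BED_COLS = ["chrom", "start", "end", "name"]


def read_bed(path, names=None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    names = list(names or BED_COLS)
    if df.shape[1] > len(names):
        names = names + [f"col{i}" for i in range(len(names), df.shape[1])]
    df.columns = names[: df.shape[1]]
    return df


def write_bed(df: pd.DataFrame, path, cols=None) -> None:
    cols = cols or [c for c in BED_COLS if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bedpe(path) -> pd.DataFrame:
    """Read a BEDPE file of PETs; validates coordinates line by line."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 6:
        raise ValueError(f"{path}: BEDPE needs >= 6 columns, found {df.shape[1]}")
    df.columns = BEDPE_COLS[: df.shape[1]]
    bad = (df["start1"] >= df["end1"]) | (df["start2"] >= df["end2"])
    if bad.any():
        lineno = int(bad.idxmax()) + 1
        raise ValueError(f"{path}: malformed interval at line {lineno} (start >= end)")
    return df


def write_bedpe(df: pd.DataFrame, path) -> None:
    """Write a full 10-column BEDPE (missing name/score/strand filled in)."""
    df = df.copy()
    if "name" not in df:
        df["name"] = [f"pair{i}" for i in range(len(df))]
    if "score" not in df:
        df["score"] = 0
    for col in ("strand1", "strand2"):
        if col not in df:
            df[col] = "."
    df[BEDPE_COLS].to_csv(path, sep="\t", header=False, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
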