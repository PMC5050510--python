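"""Readers and writers for the pipeline's on-disk formats.

Canonical format is TSV (UTF-8, '.' decimal separator, empty field for
missing values); a ``sep`` argument accepts a CSV dialect.  Every writer's
output is re-readable by the corresponding reader.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .responders import validate_phenotypes

__all__ = [
    "read_phenotypes", "write_phenotypes",
    "read_counts", "write_counts",
    "read_groups", "write_groups",
    "read_annotation", "write_annotation",
    "read_gene_list", "write_json_report",
]


def read_phenotypes(path, sep: str = "\t") -> pd.DataFrame:
    """Read and validate a long-format phenotype table.

    Expected columns: fish_id, family_id, occasion, cortisol.  Raises on
    missing columns, duplicate (fish, occasion) records, non-numeric or
    negative cortisol; rows with an empty cortisol field are dropped
    (missing observation).
    """
    df = pd.read_csv(path, sep=sep, dtype={"fish_id": str, "family_id": str})
    required = ["fish_id", "family_id", "occasion", "cortisol"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    df["cortisol"] = pd.to_numeric(df["cortisol"], errors="raise")
    df = df.dropna(subset=["cortisol"]).reset_index(drop=True)
    df["occasion"] = df["occasion"].astype(int)
    return validate_phenotypes(df[required + [c for c in df.columns
                                              if c not in required]])


def write_phenotypes(data: pd.DataFrame, path, sep: str = "\t") -> None:
    cols = ["fish_id", "family_id", "occasion", "cortisol"]
    data[cols].to_csv(path, sep=sep, index=False)


def read_counts(path, sep: str = "\t") -> pd.DataFrame:
    """Read a transcript × sample count matrix (first column transcript_id)."""
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index.name = "transcript_id"
    if df.index.duplicated().any():
        raise ValueError(f"{path}: duplicate transcript ids")
    if (df.to_numpy() < 0).any():
        raise ValueError(f"{path}: negative counts")
    return df


def write_counts(counts: pd.DataFrame, path, sep: str = "\t") -> None:
    counts.to_csv(path, sep=sep, index_label="transcript_id")


def read_groups(path, sep: str = "\t") -> pd.Series:
    """Read a sample → group map (columns sample_id, group)."""
    df = pd.read_csv(path, sep=sep, dtype=str)
    if not {"sample_id", "group"} <= set(df.columns):
        raise ValueError(f"{path}: needs columns sample_id, group")
    if df["sample_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample ids")
    return df.set_index("sample_id")["group"]


def write_groups(groups: pd.Series, path, sep: str = "\t") -> None:
    groups.rename_axis("sample_id").rename("group").reset_index().to_csv(
        path, sep=sep, index=False)


def read_annotation(path, sep: str = "\t") -> pd.DataFrame:
    """Read a gene → GO-term table.

    Accepts either a two-column header table (gene_id, go_id) or a
    GAF 2.x file (comment lines starting with '!'; gene symbol in column 2,
    GO id in column 5).
    """
    with open(path, "rt", encoding="utf-8") as fh:
        first = fh.readline()
    if first.startswith("!") or (first.count("\t") >= 4
                                 and "gene_id" not in first):
        df = pd.read_csv(path, sep="\t", comment="!", header=None, dtype=str)
        ann = df.iloc[:, [1, 4]]
        ann.columns = ["gene_id", "go_id"]
    else:
        ann = pd.read_csv(path, sep=sep, dtype=str)
        if not {"gene_id", "go_id"} <= set(ann.columns):
            raise ValueError(f"{path}: needs columns gene_id, go_id")
        ann = ann[["gene_id", "go_id"]]
    return ann.drop_duplicates().reset_index(drop=True)


def write_annotation(annotation: pd.DataFrame, path, sep: str = "\t") -> None:
    annotation[["gene_id", "go_id"]].to_csv(path, sep=sep, index=False)


def read_gene_list(path) -> list[str]:
    """One gene id per line; blank lines and '#' comments ignored."""
    genes = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            genes.append(line)
    return genes


def write_json_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n",
                          encoding="utf-8")
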