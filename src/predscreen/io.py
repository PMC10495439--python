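"""Tabular and gene-set file I/O.

All tables are UTF-8, tab-separated with one header row, '.' decimals and
``NA`` for missing values.  Gene sets use the standard GMT layout
(name, description, then member genes, tab-separated).
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Sequence

import pandas as pd

from .stats import ValidationError
from .tme import GeneSet

__all__ = ["read_tsv", "write_tsv", "read_panel", "read_gmt", "write_gmt",
           "file_digest"]

NA = "NA"


def read_tsv(path, required: Sequence[str] | None = None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"{path}: file not found")
    df = pd.read_csv(path, sep="\t", na_values=[NA], keep_default_na=True)
    if required:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValidationError(
                f"{path}: missing required column(s) {missing} "
                f"(found {list(df.columns)})")
    return df


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, na_rep=NA)
    return path


def read_panel(path) -> pd.DataFrame:
    """Expression panel: gene rows x sample columns, first column gene id."""
    df = read_tsv(path)
    gene_col = df.columns[0]
    panel = df.set_index(gene_col)
    panel.index.name = "gene"
    if panel.index.duplicated().any():
        dup = panel.index[panel.index.duplicated()].tolist()[:5]
        raise ValidationError(f"{path}: duplicate gene ids, e.g. {dup}")
    if panel.isna().any().any():
        bad = panel.columns[panel.isna().any()].tolist()[:5]
        raise ValidationError(
            f"{path}: missing expression values in columns {bad}; "
            "impute or filter before loading")
    return panel


def read_gmt(path) -> list[GeneSet]:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"{path}: file not found")
    sets = []
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValidationError(
                f"{path}:{lineno}: GMT line needs name, description and "
                f">= 1 gene")
        name, _desc, *genes = parts
        genes = [g for g in genes if g]
        sets.append(GeneSet(name=name, genes=tuple(dict.fromkeys(genes))))
    return sets


def write_gmt(sets: Sequence[GeneSet], path, description: str = "") -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, description, *gs.genes]) + "\n")
    return path


def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
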