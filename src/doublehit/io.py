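"""Plain-text readers/writers for the pipeline's tabular formats.

All matrices travel as TSV: first column holds row identifiers, the header
row holds sample identifiers. Gene sets use the GMT convention
(set name <tab> description <tab> gene ...). Coordinates are 1-based
inclusive throughout.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

__all__ = [
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_table_tsv",
    "write_table_tsv",
    "read_gmt",
    "write_gmt",
    "write_json",
    "read_json",
]


def read_matrix_tsv(path: str | Path, index_name: str | None = None) -> pd.DataFrame:
    """Read a rows-by-samples numeric matrix (first column = row ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if index_name is not None:
        df.index.name = index_name
    return df


def write_matrix_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t")


def read_table_tsv(path: str | Path, index_col: int | None = None) -> pd.DataFrame:
    """Read a plain table; lines starting with '#' are comments."""
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


def write_table_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT file into {set_name: genes}. Gene symbols are uppercased."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line (need name, description, >=1 gene): {line[:80]!r}")
            name = fields[0]
            genes = {g.strip().upper() for g in fields[2:] if g.strip()}
            if name in sets:
                raise ValueError(f"duplicate gene-set name in GMT: {name}")
            sets[name] = genes
    return sets


def write_gmt(sets: dict[str, set[str]], path: str | Path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *sorted(genes)]) + "\n")


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
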