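"""Readers and writers for the plain-text formats the pipeline exchanges.

Matrices travel as TSV with probes in rows and samples in columns; sample
sheets as CSV; gene sets as GMT; probe/gene signatures as one-ID-per-line
text files.  Writers use fixed float formatting (6 significant digits,
p/q-like columns in 3-digit scientific notation) so repeated runs produce
byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Iterable, List, Set, Union

import numpy as np
import pandas as pd

__all__ = [
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_annotation",
    "write_annotation",
    "write_table",
    "read_id_list",
    "write_id_list",
    "read_gmt",
    "write_gmt",
    "write_json",
]

PathLike = Union[str, Path]

_P_COLUMN_HINTS = ("p_value", "q_value", "p_bartlett", "q_bartlett", "p_ttest",
                   "p_enriched", "p_depleted")


def read_matrix_tsv(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix_tsv(matrix: pd.DataFrame, path: PathLike) -> None:
    matrix.to_csv(path, sep="\t", float_format="%.6g")


def read_sample_sheet(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)


def write_sample_sheet(sheet: pd.DataFrame, path: PathLike) -> None:
    sheet.to_csv(path, float_format="%.6g")


def read_annotation(path: PathLike) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", index_col=0, keep_default_na=False)
    for col in ("SNP_within_2bp", "Cross_reactive"):
        if col in ann.columns:
            ann[col] = ann[col].astype(str).str.lower().isin(("true", "1"))
    return ann


def write_annotation(annotation: pd.DataFrame, path: PathLike) -> None:
    annotation.to_csv(path, sep="\t")


def write_table(table: pd.DataFrame, path: PathLike) -> None:
    """Write a result table with per-column formatting.

    p/q-style columns are written in scientific notation with 3 digits;
    other floats at 6 significant digits.
    """
    out = table.copy()
    for col in out.columns:
        if out[col].dtype.kind != "f":
            continue
        if any(h in col for h in _P_COLUMN_HINTS):
            out[col] = out[col].map(lambda v: "" if pd.isna(v) else f"{v:.3e}")
        else:
            out[col] = out[col].map(lambda v: "" if pd.isna(v) else f"{v:.6g}")
    out.to_csv(path, sep="\t")


def read_id_list(path: PathLike) -> List[str]:
    with open(path) as handle:
        return [line.strip() for line in handle if line.strip()]


def write_id_list(ids: Iterable[str], path: PathLike) -> None:
    with open(path, "w") as handle:
        for item in ids:
            handle.write(f"{item}\n")


def read_gmt(path: PathLike) -> Dict[str, Set[str]]:
    """GMT gene-set file: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets: Dict[str, Set[str]] = {}
    with open(path) as handle:
        for line in handle:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def write_gmt(gene_sets: Dict[str, Iterable[str]], path: PathLike) -> None:
    with open(path, "w") as handle:
        for name, genes in gene_sets.items():
            members = "\t".join(sorted(set(genes)))
            handle.write(f"{name}\tsynthetic\t{members}\n")


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.bool_,)):
            return bool(obj)
        return super().default(obj)


def write_json(payload, path: PathLike) -> None:
    with open(path, "w") as handle:
        json.dump(payload, handle, indent=2, sort_keys=True, cls=_NumpyEncoder)
        handle.write("\n")
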