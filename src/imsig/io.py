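"""Readers and writers for expression matrices and clinical tables.

Expression files are TSV/CSV with genes as rows by default: first column
"gene", header row of sample ids. An optional leading metadata line
``#scale=<tag>`` records the normalization state; files without it are taken
to be linear FPKM. Clinical files carry columns sample_id, response and
optionally os_time, os_event, cohort.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import ClinicalTable, ExpressionMatrix

logger = logging.getLogger("imsig")

_SEPS = {"tsv": "\t", "csv": ","}


def _sep_for(path: str, fmt: str | None) -> str:
    if fmt is None:
        fmt = "csv" if str(path).endswith(".csv") else "tsv"
    if fmt not in _SEPS:
        raise ValueError(f"unknown format {fmt!r}; expected tsv or csv")
    return _SEPS[fmt]


def _read_metadata(path: str) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            for token in line[1:].strip().split():
                if "=" in token:
                    k, v = token.split("=", 1)
                    meta[k] = v
    return meta


def read_expression_matrix(path: str, fmt: str | None = None,
                           orientation: str = "genes_rows") -> ExpressionMatrix:
    """Read a TSV/CSV expression matrix.

    Duplicate gene symbols (after uppercasing) are collapsed by arithmetic
    mean with a logged warning. Missing or non-numeric cells are a parse
    error naming the offending row and column.
    """
    sep = _sep_for(path, fmt)
    meta = _read_metadata(path)
    with open(path) as fh:
        header = next((ln for ln in fh if not ln.startswith("#")), "")
    ids = header.rstrip("\n").split(sep)[1:]
    if orientation == "genes_rows" and len(ids) != len(set(ids)):
        dups = sorted({s for s in ids if ids.count(s) > 1})
        raise ValueError(f"{path}: duplicate sample id(s) in header: {dups}")
    df = pd.read_csv(path, sep=sep, index_col=0, comment="#",
                     keep_default_na=False, na_values=[])
    if orientation == "samples_rows":
        df = df.T
    elif orientation != "genes_rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    if df.size == 0:
        raise ValueError(f"{path}: empty expression matrix")
    # coerce the body, reporting the first bad cell precisely
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(numeric.isna().to_numpy())
    if bad.size:
        r, c = bad[0]
        raise ValueError(
            f"{path}: non-numeric cell {df.iat[r, c]!r} at gene "
            f"{df.index[r]!r}, sample {df.columns[c]!r}"
        )
    numeric.index = [str(g).upper() for g in numeric.index]
    if pd.Index(numeric.index).has_duplicates:
        dup = pd.Index(numeric.index)
        names = dup[dup.duplicated()].unique().tolist()
        logger.warning("%s: duplicate gene symbol(s) collapsed by mean: %s",
                       path, ", ".join(names))
        numeric = numeric.groupby(level=0, sort=False).mean()
    scale_tag = meta.get("scale", "linear_fpkm")
    return ExpressionMatrix(numeric, scale_tag=scale_tag)


def write_expression_matrix(m: ExpressionMatrix, path: str, fmt: str | None = None) -> str:
    """Write a matrix with its scale tag; round-trips to 6 significant digits."""
    sep = _sep_for(path, fmt)
    with open(path, "w") as fh:
        fh.write(f"#scale={m.scale_tag}\n")
        fh.write("gene" + sep + sep.join(m.sample_ids) + "\n")
        for gene, row in m.values.iterrows():
            fh.write(gene + sep + sep.join(f"{v:.6g}" for v in row) + "\n")
    return path


def read_clinical_table(path: str, fmt: str | None = None) -> ClinicalTable:
    """Read a clinical table; response tokens are normalized case-insensitively."""
    sep = _sep_for(path, fmt)
    df = pd.read_csv(path, sep=sep, comment="#",
                     keep_default_na=False, na_values=[""])
    if "sample_id" not in df.columns or "response" not in df.columns:
        raise ValueError(f"{path}: clinical table requires sample_id and response columns")
    return ClinicalTable(df)


def write_clinical_table(c: ClinicalTable, path: str, fmt: str | None = None) -> str:
    sep = _sep_for(path, fmt)
    out = c.table.reset_index(names="sample_id")
    out.to_csv(path, sep=sep, index=False)
    return path
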