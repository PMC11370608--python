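"""Readers, writers, normalization and filtering.

Expression is accepted either as a dense genes-by-spots TSV/CSV (header
row of spot ids, first column gene ids) or as a Matrix-Market sparse
triplet with companion ``genes.tsv``/``barcodes.tsv`` files (10x-style
layout, genes in rows).  Coordinates come from a TSV with columns
``spot_id``, ``x``, ``y``.  All outputs are TSV with a ``#``-prefixed
header block recording configuration and seed, so every table is
self-describing and byte-reproducible.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .containers import ExpressionMatrix
from .geometry import SpotSet

__all__ = [
    "read_expression",
    "read_coords",
    "write_expression",
    "write_coords",
    "write_table",
    "read_table",
    "normalize_and_filter",
    "align_to_spots",
]


def read_expression(
    path, genes: Optional[str] = None, barcodes: Optional[str] = None
) -> ExpressionMatrix:
    """Load a genes-by-spots expression matrix.

    A ``.mtx`` path requires the companion ``genes``/``barcodes``
    files (one id per line; a second tab-separated column is allowed
    and ignored).  Any other extension is parsed as a dense delimited
    table.
    """
    path = Path(path)
    if path.suffix == ".mtx":
        if genes is None or barcodes is None:
            raise ValueError("MTX input needs companion genes and barcodes files")
        mat = spio.mmread(path)
        values = np.asarray(mat.todense() if sparse.issparse(mat) else mat, dtype=float)
        gene_ids = _read_id_column(genes)
        spot_ids = _read_id_column(barcodes)
        if len(gene_ids) != values.shape[0]:
            raise ValueError(
                f"genes file lists {len(gene_ids)} ids but matrix has {values.shape[0]} rows"
            )
        if len(spot_ids) != values.shape[1]:
            raise ValueError(
                f"barcodes file lists {len(spot_ids)} ids but matrix has {values.shape[1]} columns"
            )
        return ExpressionMatrix(tuple(gene_ids), tuple(spot_ids), values)
    sep = "," if path.suffix == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0, comment="#")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as err:
        raise ValueError(f"non-numeric expression value in {path}: {err}") from err
    if df.index.duplicated().any():
        raise ValueError("duplicate gene ids in expression input")
    return ExpressionMatrix(tuple(df.index), tuple(df.columns), values)


def _read_id_column(path) -> list:
    ids = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            ids.append(line.split("\t")[0])
    return ids


def read_coords(path) -> SpotSet:
    """Spot coordinates from TSV ``spot_id<TAB>x<TAB>y``.

    Row order defines spot order for every downstream artifact.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"spot_id", "x", "y"}
    if not required.issubset(df.columns):
        raise ValueError(f"coordinates file must have columns {sorted(required)}")
    coord_cols = [c for c in df.columns if c != "spot_id"]
    return SpotSet(tuple(df["spot_id"].astype(str)), df[coord_cols].to_numpy(dtype=float))


def _header_block(config: Optional[Mapping] = None) -> str:
    lines = []
    if config:
        for key in config:
            lines.append(f"# {key}={config[key]}")
    return "\n".join(lines)


def write_table(df: pd.DataFrame, path, config: Optional[Mapping] = None) -> None:
    """Write a TSV with a ``#``-prefixed header block."""
    buf = _io.StringIO()
    header = _header_block(config)
    if header:
        buf.write(header + "\n")
    df.to_csv(buf, sep="\t", index=False, lineterminator="\n")
    Path(path).write_text(buf.getvalue())


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_expression(expr: ExpressionMatrix, path, config: Optional[Mapping] = None) -> None:
    df = pd.DataFrame(expr.values, index=list(expr.gene_ids), columns=list(expr.spot_ids))
    df.index.name = "gene_id"
    buf = _io.StringIO()
    header = _header_block(config)
    if header:
        buf.write(header + "\n")
    df.to_csv(buf, sep="\t", lineterminator="\n")
    Path(path).write_text(buf.getvalue())


def write_coords(spots: SpotSet, path, config: Optional[Mapping] = None) -> None:
    cols = {"spot_id": list(spots.spot_ids)}
    for d in range(spots.coords.shape[1]):
        cols["xyzw"[d] if d < 4 else f"c{d}"] = spots.coords[:, d]
    write_table(pd.DataFrame(cols), path, config)


def align_to_spots(expr: ExpressionMatrix, spots: SpotSet) -> ExpressionMatrix:
    """Reorder expression columns to the coordinate file's spot order."""
    if expr.spot_ids == spots.spot_ids:
        return expr
    if set(expr.spot_ids) != set(spots.spot_ids):
        raise ValueError("expression and coordinates disagree on spot ids")
    order = [expr.spot_ids.index(s) for s in spots.spot_ids]
    return ExpressionMatrix(expr.gene_ids, spots.spot_ids, expr.values[:, order])


def normalize_and_filter(
    expr: ExpressionMatrix,
    min_nonzero_fraction: float = 0.01,
    do_lognorm: bool = False,
) -> ExpressionMatrix:
    """Drop sparse and constant genes; optionally library-normalize.

    Genes expressed (nonzero) in fewer than ``min_nonzero_fraction`` of
    spots are removed.  With ``do_lognorm`` each spot is scaled to the
    median library size and values are ``log1p``-transformed — the
    standard treatment for raw counts; leave it off for inputs that are
    already normalized.  Constant genes are always removed (they carry
    no testable signal).
    """
    if not (0.0 <= min_nonzero_fraction < 1.0):
        raise ValueError("min_nonzero_fraction must lie in [0, 1)")
    values = expr.values
    nonzero_frac = (values != 0).mean(axis=1)
    keep = nonzero_frac >= min_nonzero_fraction if min_nonzero_fraction > 0 else nonzero_frac > 0
    values = values[keep]
    gene_ids = tuple(g for g, k in zip(expr.gene_ids, keep) if k)
    if do_lognorm:
        libsize = values.sum(axis=0)
        if np.any(libsize <= 0):
            raise ValueError("cannot library-normalize spots with zero total signal")
        target = float(np.median(libsize))
        values = np.log1p(values / libsize[None, :] * target)
    sd = values.std(axis=1)
    keep2 = sd > 0
    values = values[keep2]
    gene_ids = tuple(g for g, k in zip(gene_ids, keep2) if k)
    if len(gene_ids) == 0:
        raise ValueError("all genes removed by filtering")
    return ExpressionMatrix(gene_ids, expr.spot_ids, values)
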