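"""Readers and writers for the standard text formats.

Counts come in as a MatrixMarket coordinate triplet (genes x cells, the
common deposition convention) plus two annotation TSVs, or as a dense
delimited table.  Gene sets use GMT; survival cohorts a flat CSV with
``time,event,subtype`` followed by one column per gene.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .datamodel import ExpressionDataset, GeneSignature, SurvivalCohort, make_unique
from .errors import ParseError, StructuralError, ValidationError

logger = logging.getLogger(__name__)


def read_counts(
    matrix_path,
    cells_path,
    genes_path,
    dialect: str = "mtx",
    scale: float = 1e4,
) -> ExpressionDataset:
    """Load a count matrix with its annotation tables.

    ``dialect='mtx'``: MatrixMarket coordinate file, genes in rows and
    cells in columns.  ``dialect='dense'``: delimited table with cells in
    rows (index column first) and genes in columns.

    Missing optional annotation columns are filled with the sentinel
    ``unknown``; a dimension mismatch raises :class:`StructuralError` and
    non-integer entries raise :class:`ValidationError`.
    """
    cells = pd.read_csv(cells_path, sep="\t", index_col=0)
    genes = pd.read_csv(genes_path, sep="\t", index_col=0)
    genes.index = make_unique(genes.index)

    if dialect == "mtx":
        mat = scipy.io.mmread(matrix_path)
        counts = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat).T
    elif dialect == "dense":
        df = pd.read_csv(matrix_path, sep=None, engine="python", index_col=0)
        counts = df.to_numpy()
    else:
        raise ParseError(f"unknown dialect {dialect!r}; expected 'mtx' or 'dense'")

    if counts.shape[0] != len(cells):
        raise StructuralError(
            f"matrix has {counts.shape[0]} cells but cells file has {len(cells)} rows"
        )
    if counts.shape[1] != len(genes):
        raise StructuralError(
            f"matrix has {counts.shape[1]} genes but genes file has {len(genes)} rows"
        )
    return ExpressionDataset(counts=counts, cell_meta=cells, gene_meta=genes, scale=scale)


def write_counts(dataset: ExpressionDataset, out_dir) -> dict[str, Path]:
    """Write MTX (genes x cells) + cells.tsv + genes.tsv into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out / "matrix.mtx",
        "cells": out / "cells.tsv",
        "genes": out / "genes.tsv",
    }
    sparse = scipy.sparse.coo_matrix(dataset.counts.T)
    scipy.io.mmwrite(str(paths["matrix"]), sparse, field="integer")
    dataset.cell_meta.to_csv(paths["cells"], sep="\t")
    dataset.gene_meta.to_csv(paths["genes"], sep="\t")
    return paths


def read_gmt(path) -> list[GeneSignature]:
    """Parse a GMT file: ``name<TAB>description<TAB>gene1<TAB>gene2...``.

    The description field is discarded; duplicate symbols within a line are
    deduplicated with a warning.  Lines with fewer than three fields raise
    :class:`ParseError` naming the line number.
    """
    signatures: list[GeneSignature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line has {len(fields)} fields, need >=3")
            name, _desc, *genes = fields
            genes = [g for g in genes if g]
            signatures.append(GeneSignature.from_genes(name, genes))
    return signatures


def write_gmt(signatures: Sequence[GeneSignature], path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for sig in signatures:
            fh.write("\t".join([sig.name, "na", *sig.genes]) + "\n")
    return path


def read_survival(path) -> SurvivalCohort:
    """Read a survival CSV with columns ``time,event,subtype`` then genes."""
    df = pd.read_csv(path)
    for col in ("time", "event", "subtype"):
        if col not in df.columns:
            raise ParseError(f"survival table missing required column {col!r}")
    expr = df.drop(columns=["time", "event", "subtype"])
    return SurvivalCohort(
        time=df["time"].to_numpy(),
        event=df["event"].to_numpy(),
        subtype=df["subtype"].to_numpy(),
        expression=expr,
    )


def write_survival(cohort: SurvivalCohort, path) -> Path:
    df = pd.DataFrame({"time": cohort.time, "event": cohort.event, "subtype": cohort.subtype})
    df = pd.concat([df, cohort.expression.reset_index(drop=True)], axis=1)
    df.to_csv(path, index=False, float_format="%.8g")
    return Path(path)


def pseudobulk(dataset: ExpressionDataset, group_keys: Sequence[str]):
    """Group x gene mean of the normalized layer, plus group sizes.

    Returns ``(means, sizes)`` where ``means`` is a DataFrame indexed by the
    observed group levels with one column per gene.
    """
    group_keys = list(group_keys)
    if not group_keys:
        raise ValidationError("pseudobulk requires at least one grouping key")
    for k in group_keys:
        if k not in dataset.cell_meta.columns:
            raise StructuralError(f"unknown cell_meta column {k!r}")
    norm = pd.DataFrame(dataset.normalized, index=dataset.cell_ids, columns=dataset.genes)
    grouper = [dataset.cell_meta[k].to_numpy() for k in group_keys]
    means = norm.groupby(grouper, sort=True).mean()
    sizes = norm.groupby(grouper, sort=True).size()
    means.index.set_names(group_keys, inplace=True)
    sizes.index.set_names(group_keys, inplace=True)
    return means, sizes
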