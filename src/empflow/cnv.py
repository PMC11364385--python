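"""Relative copy-number profiles inferred from expression.

Genes are ordered along the genome, each cell's normalized expression is
centered by a per-gene reference mean, clipped, smoothed with a moving
average that never crosses a chromosome boundary, and median-centered per
cell.  Pseudobulk profiles of matched compartments (primary tumor vs
metastasis of one model) are compared by Pearson correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import ExpressionDataset
from .errors import ConfigError, StructuralError, ValidationError


def chromosome_sort_key(chrom: str):
    """Numeric-aware chromosome order: 1..22, X, Y, then others."""
    c = str(chrom).removeprefix("chr")
    if c.isdigit():
        return (0, int(c), "")
    if c == "X":
        return (0, 23, "")
    if c == "Y":
        return (0, 24, "")
    return (1, 0, c)


def moving_average_chromwise(
    values: np.ndarray, chrom_sizes: list[int], window: int
) -> np.ndarray:
    """Centered moving average per chromosome block, symmetric truncation.

    ``values`` is (cells x genes) with genes already genome-ordered in
    contiguous chromosome blocks of the given sizes.  Near block ends the
    window shrinks symmetrically, so output length equals input length.
    """
    half = window // 2
    out = np.empty_like(values, dtype=float)
    start = 0
    for size in chrom_sizes:
        block = values[:, start : start + size]
        csum = np.cumsum(block, axis=1)
        for i in range(size):
            h = min(half, i, size - 1 - i)
            lo, hi = i - h, i + h
            total = csum[:, hi] - (csum[:, lo - 1] if lo > 0 else 0.0)
            out[:, start + i] = total / (hi - lo + 1)
        start += size
    return out


@dataclass
class CNVProfile:
    """Smoothed relative log2 profile per cell over genome-ordered genes."""

    gene_order: list[str]
    chromosomes: pd.Series  # per ordered gene
    matrix: np.ndarray  # cells x ordered genes
    cell_ids: pd.Index
    dropped_genes: list[str]
    window: int

    def pseudobulk(self, labels: np.ndarray) -> pd.DataFrame:
        """Mean profile per label (rows: labels, cols: ordered genes)."""
        labels = np.asarray(labels)
        rows = {lab: self.matrix[labels == lab].mean(axis=0) for lab in pd.unique(labels)}
        return pd.DataFrame.from_dict(rows, orient="index", columns=self.gene_order)


def infer_profiles(
    dataset: ExpressionDataset,
    window: int = 101,
    clip: float = 3.0,
    reference: str | pd.Series = "all-cells",
) -> CNVProfile:
    """Windowed expression smoothing as a copy-number proxy.

    Steps: per-gene centering by the reference mean (the all-cell mean by
    default, since a tumor-only panel has no normal reference), clipping to
    ``+-clip``, a ``window``-gene moving average within each chromosome,
    and per-cell median centering.  Genes without coordinates are dropped
    and reported.
    """
    if window < 3 or window % 2 == 0:
        raise ConfigError("window must be an odd integer >= 3")
    gm = dataset.gene_meta
    if "chromosome" not in gm.columns or "start" not in gm.columns:
        raise StructuralError("gene_meta needs 'chromosome' and 'start' columns")
    mappable = gm["chromosome"].notna() & gm["start"].notna()
    dropped = gm.index[~mappable].tolist()
    if not mappable.any():
        raise ValidationError("no gene has genomic coordinates")

    sub = gm[mappable].copy()
    sub["_key"] = sub["chromosome"].map(chromosome_sort_key)
    sub = sub.sort_values(["_key", "start"], kind="stable")
    order_idx = pd.Index(dataset.genes).get_indexer(sub.index)

    expr = dataset.normalized[:, order_idx]
    if isinstance(reference, str):
        if reference != "all-cells":
            raise ConfigError(f"unknown reference {reference!r}")
        ref_mean = expr.mean(axis=0)
    else:
        ref_mean = reference.reindex(sub.index).to_numpy(dtype=float)
        if np.isnan(ref_mean).any():
            raise ValidationError("reference is missing values for some mappable genes")

    centered = np.clip(expr - ref_mean[None, :], -clip, clip)
    chrom_sizes = sub.groupby("_key", sort=True).size().tolist()
    smoothed = moving_average_chromwise(centered, chrom_sizes, window)
    smoothed -= np.median(smoothed, axis=1, keepdims=True)

    return CNVProfile(
        gene_order=sub.index.tolist(),
        chromosomes=sub["chromosome"],
        matrix=smoothed,
        cell_ids=dataset.cell_ids,
        dropped_genes=dropped,
        window=window,
    )


def compare_compartments(
    profile: CNVProfile,
    cell_meta: pd.DataFrame,
    model_key: str = "tumor_model",
    tissue_key: str = "tissue",
) -> tuple[pd.DataFrame, list[str]]:
    """Per-model Pearson r and R^2 between compartment pseudobulk profiles.

    Models missing either compartment are skipped and reported.
    """
    meta = cell_meta.loc[profile.cell_ids]
    rows = []
    skipped: list[str] = []
    for model in sorted(meta[model_key].unique()):
        in_model = (meta[model_key] == model).to_numpy()
        tissues = meta.loc[in_model, tissue_key]
        masks = {}
        for tissue in ("primary", "metastasis"):
            m = in_model & (meta[tissue_key] == tissue).to_numpy()
            if m.sum() == 0:
                masks = None
                break
            masks[tissue] = m
        if masks is None:
            skipped.append(model)
            continue
        a = profile.matrix[masks["primary"]].mean(axis=0)
        b = profile.matrix[masks["metastasis"]].mean(axis=0)
        r = float(np.corrcoef(a, b)[0, 1])
        rows.append(
            {
                "tumor_model": model,
                "r": r,
                "r2": r * r,
                "n_primary": int(masks["primary"].sum()),
                "n_metastasis": int(masks["metastasis"].sum()),
            }
        )
    table = pd.DataFrame(rows).set_index("tumor_model") if rows else pd.DataFrame()
    return table, skipped
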