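"""Gene-set scoring and the epithelial-mesenchymal plasticity (EMP) state.

A signature score is the mean normalized expression of the signature genes
minus the mean over a control pool matched on expression abundance: genes
are binned by their dataset-wide mean expression and each signature gene
contributes ``n_ctrl`` control genes drawn from its own bin.  This centers
scores near zero, which the +-0.2 state thresholds presuppose.

The EMP signature of a cell is its mesenchymal score minus its epithelial
score; values above 0 indicate a more mesenchymal than epithelial cell.
Cells are classified as epithelial-like (EMP < -0.2), intermediate
(-0.2 <= EMP <= 0.2, closed band) or mesenchymal-like (EMP > 0.2).
"""

from __future__ import annotations

import zlib
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .datamodel import ExpressionDataset, GeneSignature
from .errors import ConfigError, StructuralError, ValidationError

STATES = ("epithelial-like", "intermediate", "mesenchymal-like")
DEFAULT_LOW = -0.2
DEFAULT_HIGH = 0.2


def _signature_seed(seed: int, name: str) -> int:
    # Stable per-signature stream: swapping two signatures in compute_emp
    # keeps each signature's control draw identical, so EMP negates exactly.
    return (int(seed) ^ zlib.crc32(name.encode())) % (2**31)


def score_gene_set(
    dataset: ExpressionDataset,
    signature: GeneSignature,
    n_bins: int = 25,
    n_ctrl: int = 50,
    seed: int = 0,
) -> tuple[pd.Series, list[str]]:
    """Bin-matched control-subtracted signature score per cell.

    Returns ``(scores, dropped)`` where ``dropped`` lists signature genes
    absent from the dataset.  Raises :class:`ValidationError` if no
    signature gene is present.
    """
    genes = pd.Index(dataset.genes)
    present = [g for g in signature.genes if g in genes]
    dropped = [g for g in signature.genes if g not in genes]
    if not present:
        raise ValidationError(f"no gene of signature {signature.name!r} is present in the dataset")

    norm = dataset.normalized
    gene_mean = norm.mean(axis=0)

    # Equal-occupancy abundance bins over the mean-expression ranking.
    order = np.argsort(gene_mean, kind="stable")
    n_bins_eff = min(n_bins, dataset.n_genes)
    bin_of = np.empty(dataset.n_genes, dtype=int)
    bin_of[order] = np.arange(dataset.n_genes) * n_bins_eff // dataset.n_genes
    bin_members = [np.flatnonzero(bin_of == b) for b in range(n_bins_eff)]

    rng = np.random.default_rng(_signature_seed(seed, signature.name))
    sig_idx = genes.get_indexer(present)
    ctrl_idx: list[np.ndarray] = []
    for j in sig_idx:
        members = bin_members[bin_of[j]]
        ctrl_idx.append(rng.choice(members, size=n_ctrl, replace=True))
    ctrl = np.concatenate(ctrl_idx)

    scores = norm[:, sig_idx].mean(axis=1) - norm[:, ctrl].mean(axis=1)
    return pd.Series(scores, index=dataset.cell_ids, name=signature.name), dropped


def classify_state(emp, low: float = DEFAULT_LOW, high: float = DEFAULT_HIGH):
    """Map EMP value(s) to the three-state classification.

    Epithelial-like below ``low``, mesenchymal-like above ``high``,
    intermediate on the closed band ``[low, high]``.
    """
    if low >= high:
        raise ConfigError(f"low threshold ({low}) must be < high threshold ({high})")
    arr = np.asarray(emp, dtype=float)
    if not np.isfinite(arr).all():
        raise ValidationError("EMP values must be finite")
    out = np.where(arr < low, STATES[0], np.where(arr > high, STATES[2], STATES[1]))
    if np.isscalar(emp) or arr.ndim == 0:
        return str(out)
    return out


def compute_emp(
    dataset: ExpressionDataset,
    epi_signature: GeneSignature,
    mes_signature: GeneSignature,
    n_bins: int = 25,
    n_ctrl: int = 50,
    seed: int = 0,
    low: float = DEFAULT_LOW,
    high: float = DEFAULT_HIGH,
) -> pd.DataFrame:
    """Per-cell epithelial/mesenchymal scores, EMP = mes - epi, and state.

    Returns a DataFrame indexed by cell id with columns ``epi_score``,
    ``mes_score``, ``emp`` and ``state``.
    """
    epi, _ = score_gene_set(dataset, epi_signature, n_bins=n_bins, n_ctrl=n_ctrl, seed=seed)
    mes, _ = score_gene_set(dataset, mes_signature, n_bins=n_bins, n_ctrl=n_ctrl, seed=seed)
    emp = mes - epi
    return pd.DataFrame(
        {
            "epi_score": epi,
            "mes_score": mes,
            "emp": emp,
            "state": classify_state(emp.to_numpy(), low=low, high=high),
        },
        index=dataset.cell_ids,
    )


def state_composition(
    score_table: pd.DataFrame, cell_meta: pd.DataFrame, group_key: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group EMP state proportions (rows sum to 1) and raw counts."""
    if group_key not in cell_meta.columns:
        raise StructuralError(f"unknown cell_meta column {group_key!r}")
    joined = score_table.join(cell_meta[[group_key]], how="inner")
    counts = (
        joined.groupby([group_key, "state"], observed=False).size().unstack("state", fill_value=0)
    )
    for s in STATES:
        if s not in counts.columns:
            counts[s] = 0
    counts = counts[list(STATES)]
    props = counts.div(counts.sum(axis=1), axis=0)
    return props, counts


def tf_summary(
    dataset: ExpressionDataset,
    tf_genes: Iterable[str],
    score_table: pd.DataFrame,
) -> tuple[pd.DataFrame, list[str]]:
    """Expressing-cell summaries of transcription factors per EMP state.

    For every (TF, state): fraction of cells with normalized expression > 0
    and the mean normalized expression among those expressing cells (NaN
    when no cell expresses the TF in that state).  TFs absent from the
    dataset are returned in the skipped list, not fatal.
    """
    genes = pd.Index(dataset.genes)
    tf_genes = list(tf_genes)
    present = [g for g in tf_genes if g in genes]
    skipped = [g for g in tf_genes if g not in genes]
    states = score_table.loc[dataset.cell_ids, "state"].to_numpy()
    rows = []
    for g in present:
        col = dataset.normalized[:, genes.get_loc(g)]
        for s in STATES:
            in_state = states == s
            n_state = int(in_state.sum())
            expressing = col[in_state] > 0
            n_expr = int(expressing.sum())
            rows.append(
                {
                    "gene": g,
                    "state": s,
                    "n_cells": n_state,
                    "fraction_expressing": (n_expr / n_state) if n_state else 0.0,
                    "mean_in_expressing": float(col[in_state][expressing].mean()) if n_expr else np.nan,
                }
            )
    return pd.DataFrame(rows), skipped
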