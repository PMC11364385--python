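"""Multi-level consensus signatures by sharing and intersection.

The sharing logic mirrors the panel analysis design: differential
expression is run per tumor model (excluding models with too few
metastatic cells), genes significant in the same direction in at least
``min_models`` models of the same metastatic-potential group form that
group's signature, and signatures derived independently on two sequencing
platforms are intersected.  The same machinery produces EMP-state marker
consensus lists, validated by peak-profile curves along the EMP axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel import ExpressionDataset
from .errors import ConfigError, StructuralError, ValidationError
from .hurdle import DEResult, run_de
from .scoring import DEFAULT_HIGH, DEFAULT_LOW, STATES


@dataclass
class ConsensusSignature:
    """Gene list with per-model and per-platform support."""

    label: str
    genes: set[str]
    support: dict[str, list[str]] = field(default_factory=dict)  # gene -> models
    platforms: dict[str, set[str]] = field(default_factory=dict)  # gene -> platforms

    def __len__(self) -> int:
        return len(self.genes)


def per_model_de(
    dataset: ExpressionDataset,
    min_met_cells: int = 10,
    min_cells: int = 3,
    **de_kwargs,
) -> tuple[dict[str, DEResult], list[str]]:
    """Primary-vs-metastasis DE for each tumor model separately.

    Models with fewer than ``min_met_cells`` metastatic cells are excluded
    and reported (second return value).  The within-model contrast uses no
    covariates.
    """
    meta = dataset.cell_meta
    results: dict[str, DEResult] = {}
    excluded: list[str] = []
    for model in sorted(meta["tumor_model"].unique()):
        sub = dataset.subset_cells((meta["tumor_model"] == model).to_numpy())
        n_met = int((sub.cell_meta["tissue"] == "metastasis").sum())
        if n_met < min_met_cells:
            excluded.append(model)
            continue
        results[model] = run_de(
            sub, "tissue", "metastasis", "primary", min_cells=min_cells, **de_kwargs
        )
    if not results:
        raise ValidationError("no tumor model passed the metastatic-cell filter")
    return results, excluded


def shared_upregulated(
    de_by_model: Mapping[str, DEResult],
    direction: str = "up",
    min_models: int = 2,
    within_groups: Mapping[str, str] | None = None,
    lfc_threshold: float = 0.5,
    p_threshold: float = 0.05,
    use_adjusted: bool = False,
    platform: str | None = None,
) -> tuple[dict[str, ConsensusSignature], dict[int, int]]:
    """Sharing consensus across models, optionally within potential groups.

    A gene enters a group's signature iff it passes the fold-change +
    p-value rule in the stated direction in at least ``min_models`` models
    of that group.  Also returns the sharing histogram over all models:
    ``{k: number of genes significant in exactly k models}``.
    """
    if within_groups is None:
        within_groups = {m: "all" for m in de_by_model}
    unknown = [m for m in de_by_model if m not in within_groups]
    if unknown:
        raise StructuralError(f"models without a group label: {unknown}")

    sig_genes: dict[str, set[str]] = {
        m: set(
            res.significant(
                direction=direction,
                lfc_threshold=lfc_threshold,
                p_threshold=p_threshold,
                use_adjusted=use_adjusted,
            ).index
        )
        for m, res in de_by_model.items()
    }

    # Sharing histogram across all models (exclusive-to-1, shared-by-k).
    gene_count: dict[str, int] = {}
    for genes in sig_genes.values():
        for g in genes:
            gene_count[g] = gene_count.get(g, 0) + 1
    histogram: dict[int, int] = {}
    for k in gene_count.values():
        histogram[k] = histogram.get(k, 0) + 1

    out: dict[str, ConsensusSignature] = {}
    for group in sorted(set(within_groups[m] for m in de_by_model)):
        members = [m for m in de_by_model if within_groups[m] == group]
        support: dict[str, list[str]] = {}
        for m in members:
            for g in sig_genes[m]:
                support.setdefault(g, []).append(m)
        admitted = {g for g, ms in support.items() if len(ms) >= min_models}
        out[group] = ConsensusSignature(
            label=group,
            genes=admitted,
            support={g: sorted(support[g]) for g in admitted},
            platforms={g: {platform} for g in admitted} if platform else {},
        )
    return out, histogram


def potential_group_de(
    dataset: ExpressionDataset,
    min_cells: int = 3,
    min_models: int = 2,
    lfc_threshold: float = 0.5,
    p_threshold: float = 0.05,
    platform: str | None = None,
    **de_kwargs,
) -> tuple[dict[str, DEResult], dict[str, ConsensusSignature]]:
    """Each primary tumor vs the pooled tumors of other potential groups.

    Uses primary-tumor cells only; signatures are formed per potential
    group by the >= ``min_models`` sharing rule on upregulated genes.
    """
    primary = dataset.subset_cells((dataset.cell_meta["tissue"] == "primary").to_numpy())
    meta = primary.cell_meta
    groups = meta.groupby("tumor_model")["metastatic_potential"].first()
    if groups.nunique() < 2:
        raise ValidationError("need tumors from at least 2 metastatic-potential groups")

    per_tumor: dict[str, DEResult] = {}
    for model in sorted(groups.index):
        pot = groups[model]
        own = (meta["tumor_model"] == model).to_numpy()
        other = (meta["metastatic_potential"] != pot).to_numpy()
        sub = primary.subset_cells(own | other)
        labels = np.where(
            (sub.cell_meta["tumor_model"] == model).to_numpy(), "self", "other"
        )
        sub.cell_meta = sub.cell_meta.assign(_contrast=labels)
        per_tumor[model] = run_de(
            sub, "_contrast", "self", "other", min_cells=min_cells, **de_kwargs
        )

    signatures, _ = shared_upregulated(
        per_tumor,
        direction="up",
        min_models=min_models,
        within_groups=groups.to_dict(),
        lfc_threshold=lfc_threshold,
        p_threshold=p_threshold,
        platform=platform,
    )
    return per_tumor, signatures


def cross_platform_intersect(
    signatures_a: Mapping[str, ConsensusSignature],
    signatures_b: Mapping[str, ConsensusSignature],
) -> dict[str, ConsensusSignature]:
    """Per-label set intersection of signatures from two platforms."""
    unmatched = sorted(set(signatures_a) ^ set(signatures_b))
    if unmatched:
        raise StructuralError(f"labels present on only one platform: {unmatched}")
    out: dict[str, ConsensusSignature] = {}
    for label in sorted(signatures_a):
        a, b = signatures_a[label], signatures_b[label]
        genes = a.genes & b.genes
        if not genes:
            warnings.warn(f"empty cross-platform intersection for label {label!r}", stacklevel=2)
        platforms = {
            g: set(a.platforms.get(g, set())) | set(b.platforms.get(g, set())) for g in genes
        }
        support = {
            g: sorted(set(a.support.get(g, [])) | set(b.support.get(g, []))) for g in genes
        }
        out[label] = ConsensusSignature(label=label, genes=genes, support=support, platforms=platforms)
    return out


def state_marker_de(
    dataset: ExpressionDataset,
    score_table: pd.DataFrame,
    min_cells: int = 3,
    **de_kwargs,
) -> tuple[dict[str, DEResult], list[str]]:
    """One-vs-rest DE for each populated EMP state.

    States with fewer than ``min_cells`` cells are skipped with a warning;
    fewer than two populated states is an error.
    """
    states = score_table.loc[dataset.cell_ids, "state"].to_numpy()
    populated = [s for s in STATES if (states == s).sum() >= min_cells]
    if len(populated) < 2:
        raise ValidationError(
            f"need >= 2 populated EMP states, found {populated} at min_cells={min_cells}"
        )
    skipped = [s for s in STATES if s not in populated]
    for s in skipped:
        warnings.warn(f"EMP state {s!r} has < {min_cells} cells; skipped", stacklevel=2)
    results: dict[str, DEResult] = {}
    ds = dataset
    for s in populated:
        labels = np.where(states == s, "state", "rest")
        ds.cell_meta = ds.cell_meta.assign(_state=labels)
        results[s] = run_de(ds, "_state", "state", "rest", min_cells=min_cells, **de_kwargs)
    ds.cell_meta = ds.cell_meta.drop(columns=["_state"])
    return results, skipped


@dataclass
class PeakProfile:
    """Expression of one gene along the EMP axis."""

    gene: str
    emp: np.ndarray  # emp of expressing cells, ascending
    expression: np.ndarray  # normalized expression of those cells
    smoothed: np.ndarray
    positive_fraction: dict[str, float]  # per-state fraction expressing
    peaks_in_intermediate: bool | None


def _moving_average(values: np.ndarray, span: int) -> np.ndarray:
    """Centered moving average with symmetric truncation at the ends."""
    n = values.size
    half = span // 2
    out = np.empty(n)
    for i in range(n):
        h = min(half, i, n - 1 - i)
        out[i] = values[i - h : i + h + 1].mean()
    return out


def peak_profile(
    dataset: ExpressionDataset,
    gene: str,
    score_table: pd.DataFrame,
    smoothing_span: float = 0.3,
    low: float = DEFAULT_LOW,
    high: float = DEFAULT_HIGH,
    plateau_tol: float = 0.05,
) -> PeakProfile:
    """Smoothed expression of one gene over cells ordered by EMP signature.

    ``smoothing_span`` is the local-mean window: a fraction of the
    expressing cells when < 1 (loess-like neighborhood, default 0.3),
    otherwise an absolute cell count.

    The ``peaks_in_intermediate`` flag asks whether the smoothed maximum
    falls inside the closed intermediate band ``[low, high]``.  Because a
    noisy bump has a near-flat top, the maximum is treated as the plateau
    of points within ``plateau_tol`` of the maximum (relative to the curve
    amplitude): the flag is true iff the curve is not flat overall and the
    plateau intersects the band at a strictly interior point.  A flat
    curve or a maximum only at the ends is "not peaked".
    """
    if smoothing_span <= 0:
        raise ConfigError("smoothing_span must be positive")
    genes = pd.Index(dataset.genes)
    if gene not in genes:
        raise ValidationError(f"gene {gene!r} not in dataset")
    col = dataset.normalized[:, genes.get_loc(gene)]
    emp = score_table.loc[dataset.cell_ids, "emp"].to_numpy()
    states = score_table.loc[dataset.cell_ids, "state"].to_numpy()

    positive_fraction = {
        s: float((col[states == s] > 0).mean()) if (states == s).any() else 0.0 for s in STATES
    }

    expressing = col > 0
    if not expressing.any():
        warnings.warn(f"gene {gene!r} expressed nowhere; peak flag undefined", stacklevel=2)
        return PeakProfile(gene, np.empty(0), np.empty(0), np.empty(0), positive_fraction, None)

    order = np.argsort(emp[expressing], kind="stable")
    e = emp[expressing][order]
    x = col[expressing][order]
    n = e.size
    span = int(round(smoothing_span * n)) if smoothing_span < 1 else int(smoothing_span)
    span = max(span, 1)
    smoothed = _moving_average(x, span)

    amplitude = float(smoothed.max() - smoothed.min())
    flat = np.isclose(amplitude, 0.0)
    if flat:
        flag = False
    else:
        plateau = np.flatnonzero(smoothed >= smoothed.max() - plateau_tol * amplitude)
        interior = plateau[(plateau > 0) & (plateau < n - 1)]
        flag = bool(np.any((e[interior] >= low) & (e[interior] <= high)))
    return PeakProfile(gene, e, x, smoothed, positive_fraction, flag)
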