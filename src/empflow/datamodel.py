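"""Core data containers.

An :class:`ExpressionDataset` carries a cell x gene integer count matrix, a
deterministically derived log-normalized layer, and cell/gene annotation
tables.  It is the universal carrier between all analysis stages.

Cell annotations follow the matched primary-tumor/metastasis panel design:
each cell belongs to a tumor model, a tissue compartment (``primary`` or
``metastasis``), a sequencing platform (deep ``plate`` or shallow
``droplet``), and its model's metastatic-potential class (``low``,
``moderate``, ``high``).  Gene annotations optionally carry genomic
coordinates (chromosome, 1-based start) for copy-number smoothing.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import StructuralError, ValidationError

logger = logging.getLogger(__name__)

#: Sentinel used when an optional annotation column is missing on input.
UNKNOWN = "unknown"

#: Canonical cell annotation columns.
CELL_COLUMNS = ("tumor_model", "tissue", "platform", "metastatic_potential")

TISSUES = ("primary", "metastasis")
PLATFORMS = ("plate", "droplet")
POTENTIALS = ("low", "moderate", "high")


def _as_2d_int_counts(counts: np.ndarray) -> np.ndarray:
    arr = np.asarray(counts)
    if arr.ndim != 2:
        raise StructuralError(f"counts must be 2-D, got shape {arr.shape}")
    if np.issubdtype(arr.dtype, np.floating):
        frac = arr - np.round(arr)
        bad = np.argwhere(np.abs(frac) > 1e-9)
        if bad.size:
            entries = ", ".join(f"({i},{j})={arr[i, j]!r}" for i, j in bad[:10])
            raise ValidationError(f"non-integer counts at entries: {entries}")
        arr = np.round(arr).astype(np.int64)
    if not np.issubdtype(arr.dtype, np.integer):
        raise ValidationError(f"counts must be integer-valued, got dtype {arr.dtype}")
    if (arr < 0).any():
        i, j = np.argwhere(arr < 0)[0]
        raise ValidationError(f"negative count at entry ({i},{j})={arr[i, j]}")
    return arr.astype(np.int64, copy=False)


def normalize_counts(counts: np.ndarray, scale: float = 1e4, strict: bool = True) -> np.ndarray:
    """Log2 counts-per-``scale`` normalization.

    ``normalized[c, g] = log2(1 + counts[c, g] * scale / library_size[c])``.
    Deterministic in the counts, hence bit-identically recomputable.
    Zero-library cells raise when ``strict``; otherwise their normalized
    row is all zero (used when merely loading data).
    """
    counts = np.asarray(counts, dtype=np.float64)
    lib = counts.sum(axis=1)
    zero = np.flatnonzero(lib == 0)
    if zero.size and strict:
        raise ValidationError(
            f"cells with zero library size cannot be normalized: rows {zero[:20].tolist()}"
        )
    safe_lib = np.where(lib > 0, lib, 1.0)
    return np.log2(1.0 + counts * (scale / safe_lib[:, None]))


def make_unique(symbols: Sequence[str]) -> list[str]:
    """Disambiguate duplicate gene symbols by suffixing ``-1``, ``-2``, ...

    The first occurrence keeps the bare symbol.  Duplicates are logged.
    """
    seen: dict[str, int] = {}
    out: list[str] = []
    dups: list[str] = []
    for s in symbols:
        s = str(s)
        if s in seen:
            seen[s] += 1
            dups.append(s)
            out.append(f"{s}-{seen[s]}")
        else:
            seen[s] = 0
            out.append(s)
    if dups:
        logger.warning("made %d duplicate gene symbols unique: %s", len(dups), sorted(set(dups))[:10])
    return out


@dataclass
class ExpressionDataset:
    """Cell x gene counts with annotations and a derived normalized layer."""

    counts: np.ndarray
    cell_meta: pd.DataFrame
    gene_meta: pd.DataFrame
    scale: float = 1e4
    normalized: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.counts = _as_2d_int_counts(self.counts)
        n_cells, n_genes = self.counts.shape
        if len(self.cell_meta) != n_cells:
            raise StructuralError(
                f"cell_meta has {len(self.cell_meta)} rows but counts has {n_cells} cells"
            )
        if len(self.gene_meta) != n_genes:
            raise StructuralError(
                f"gene_meta has {len(self.gene_meta)} rows but counts has {n_genes} genes"
            )
        if self.gene_meta.index.duplicated().any():
            dup = self.gene_meta.index[self.gene_meta.index.duplicated()].tolist()
            raise StructuralError(f"duplicate gene symbols in gene_meta: {dup[:10]}")
        for col in CELL_COLUMNS:
            if col not in self.cell_meta.columns:
                self.cell_meta[col] = UNKNOWN
        if self.normalized is None:
            self.normalized = normalize_counts(self.counts, self.scale, strict=False)
        else:
            self.normalized = np.asarray(self.normalized, dtype=np.float64)
            if self.normalized.shape != self.counts.shape:
                raise StructuralError("normalized layer shape differs from counts")

    # -- basic accessors -------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def cell_ids(self) -> pd.Index:
        return self.cell_meta.index

    @property
    def genes(self) -> pd.Index:
        return self.gene_meta.index

    def gene_index(self, symbols: Iterable[str]) -> np.ndarray:
        """Integer positions of ``symbols`` present in the dataset."""
        lookup = pd.Index(self.genes)
        present = [s for s in symbols if s in lookup]
        return lookup.get_indexer(present)

    # -- subsetting ------------------------------------------------------
    def subset_cells(self, mask) -> "ExpressionDataset":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return ExpressionDataset(
            counts=self.counts[idx],
            cell_meta=self.cell_meta.iloc[idx].copy(),
            gene_meta=self.gene_meta,
            scale=self.scale,
        )

    def subset_genes(self, symbols: Sequence[str]) -> "ExpressionDataset":
        idx = self.gene_index(symbols)
        return ExpressionDataset(
            counts=self.counts[:, idx],
            cell_meta=self.cell_meta,
            gene_meta=self.gene_meta.iloc[idx].copy(),
            scale=self.scale,
        )

    def recompute_normalized(self) -> np.ndarray:
        """Recompute the normalized layer from counts (bit-identical)."""
        return normalize_counts(self.counts, self.scale, strict=False)


def normalize(dataset: ExpressionDataset, scale: float = 1e4) -> ExpressionDataset:
    """Return the dataset with its normalized layer (re)computed at ``scale``."""
    dataset.scale = scale
    dataset.normalized = normalize_counts(dataset.counts, scale)
    return dataset


@dataclass(frozen=True)
class GeneSignature:
    """A named, ordered, duplicate-free gene list."""

    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError(f"signature {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError(f"signature {self.name!r} contains duplicate symbols")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, g: str) -> bool:
        return g in set(self.genes)

    @classmethod
    def from_genes(cls, name: str, genes: Iterable[str], warn_duplicates: bool = True) -> "GeneSignature":
        seen: list[str] = []
        dropped = 0
        for g in genes:
            if g not in seen:
                seen.append(g)
            else:
                dropped += 1
        if dropped and warn_duplicates:
            warnings.warn(f"signature {name!r}: dropped {dropped} duplicate symbols", stacklevel=2)
        return cls(name, tuple(seen))


@dataclass
class SurvivalCohort:
    """Per-patient follow-up: time (months), event flag, subtype, expression."""

    time: np.ndarray
    event: np.ndarray
    subtype: np.ndarray
    expression: pd.DataFrame  # patients x genes

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=np.float64)
        self.event = np.asarray(self.event)
        self.subtype = np.asarray(self.subtype, dtype=object)
        if (self.time < 0).any():
            raise ValidationError("survival times must be non-negative")
        if not np.isin(self.event, [0, 1]).all():
            raise ValidationError("event indicators must be 0 (censored) or 1 (event)")
        self.event = self.event.astype(np.int64)
        n = len(self.time)
        if not (len(self.event) == len(self.subtype) == len(self.expression) == n):
            raise StructuralError("survival cohort fields have inconsistent lengths")

    @property
    def n_patients(self) -> int:
        return len(self.time)
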