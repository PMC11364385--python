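"""Histology-derived metastasis quantification.

Metastatic foci are classed by tumor-cell count: micrometastases below 10
cells, intermediate foci at 10-100 cells (inclusive), macrometastases
above 100.  Summaries report foci per mm^2 of tissue and the metastatic
burden fraction, from which a configurable rule calls the model's
metastatic potential.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .errors import ValidationError

FOCUS_CLASSES = ("micro", "intermediate", "macro")


def classify_focus(cell_count: int) -> str:
    """micro if < 10 cells; intermediate if 10-100; macro if > 100."""
    if cell_count < 1:
        raise ValidationError(f"focus must contain at least 1 cell, got {cell_count}")
    if cell_count < 10:
        return "micro"
    if cell_count <= 100:
        return "intermediate"
    return "macro"


@dataclass
class FociSummary:
    n_foci: int
    class_counts: dict[str, int]
    tissue_area: float
    foci_per_mm2: float
    burden: float  # fraction of tissue area occupied by foci


def summarize_foci(foci: Sequence[tuple[int, float]], tissue_area: float) -> FociSummary:
    """Accumulate (cell_count, area_mm2) foci over a tissue section."""
    if tissue_area <= 0:
        raise ValidationError("tissue_area must be positive")
    total_area = sum(area for _, area in foci)
    if total_area > tissue_area:
        raise ValidationError(
            f"total focus area {total_area} exceeds tissue area {tissue_area}"
        )
    counts = {c: 0 for c in FOCUS_CLASSES}
    for cells, _area in foci:
        counts[classify_focus(cells)] += 1
    return FociSummary(
        n_foci=len(foci),
        class_counts=counts,
        tissue_area=tissue_area,
        foci_per_mm2=len(foci) / tissue_area,
        burden=total_area / tissue_area,
    )


def call_potential(
    summary: FociSummary,
    tau_low: float = 0.05,
    tau_high: float = 0.5,
    kappa_macro: int = 3,
) -> tuple[str, str]:
    """Low/moderate/high metastatic-potential call with the rule that fired.

    low: foci density below ``tau_low`` and no macrometastasis;
    high: at least ``kappa_macro`` macrometastases or density at or above
    ``tau_high``; moderate otherwise.  Thresholds are explicit config so
    the qualitative judgment is reproducible.
    """
    macro = summary.class_counts.get("macro", 0)
    if macro >= kappa_macro:
        return "high", f"macro count {macro} >= {kappa_macro}"
    if summary.foci_per_mm2 >= tau_high:
        return "high", f"density {summary.foci_per_mm2:.3g} >= {tau_high}"
    if summary.foci_per_mm2 < tau_low and macro == 0:
        return "low", f"density {summary.foci_per_mm2:.3g} < {tau_low} and no macro"
    return "moderate", "residual rule"
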