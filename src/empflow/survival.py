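"""Kaplan-Meier estimation, log-rank testing, and signature stratification.

The product-limit estimator and the k-group log-rank statistic (observed
minus expected with hypergeometric variance at each distinct event time)
are implemented directly.  Cohorts are stratified by the mean expression
of a gene signature at the cohort median (ties to the low group), overall
or within each disease subtype.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import GeneSignature, SurvivalCohort
from .errors import ConfigError, ValidationError


@dataclass
class KMCurve:
    """Right-continuous product-limit survival curve."""

    event_times: np.ndarray  # distinct times with >=1 event, ascending
    n_at_risk: np.ndarray
    n_events: np.ndarray
    survival: np.ndarray  # S(t) just after each event time

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(times, events) -> KMCurve:
    """Kaplan-Meier estimate: S(t) = prod_{t_i <= t} (1 - d_i / n_i)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValidationError("empty survival input")
    if (times < 0).any():
        raise ValidationError("times must be non-negative")
    if not np.isin(events, [0, 1]).all():
        raise ValidationError("events must be 0 or 1")

    distinct = np.unique(times[events == 1])
    n_at_risk = np.array([(times >= t).sum() for t in distinct], dtype=int)
    n_events = np.array([((times == t) & (events == 1)).sum() for t in distinct], dtype=int)
    surv = np.cumprod(1.0 - n_events / n_at_risk) if distinct.size else np.empty(0)
    return KMCurve(distinct, n_at_risk, n_events, surv)


@dataclass
class LogRankResult:
    chi2: float
    df: int
    p: float


def logrank(times, events, group_labels) -> LogRankResult:
    """k-group log-rank test with hypergeometric variance at tied times."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(group_labels)
    levels = pd.unique(groups)
    k = len(levels)
    if k < 2:
        raise ValidationError("log-rank test needs at least 2 groups")

    distinct = np.unique(times[events == 1])
    O = np.zeros(k)
    E = np.zeros(k)
    V = np.zeros((k, k))
    for t in distinct:
        at_risk = times >= t
        n = at_risk.sum()
        d = ((times == t) & (events == 1)).sum()
        n_g = np.array([(at_risk & (groups == lev)).sum() for lev in levels], dtype=float)
        d_g = np.array(
            [((times == t) & (events == 1) & (groups == lev)).sum() for lev in levels],
            dtype=float,
        )
        O += d_g
        E += d * n_g / n
        if n > 1:
            factor = d * (n - d) / (n - 1)
            for i in range(k):
                for j in range(k):
                    delta = 1.0 if i == j else 0.0
                    V[i, j] += factor * (n_g[i] / n) * (delta - n_g[j] / n)

    z = (O - E)[: k - 1]
    Vsub = V[: k - 1, : k - 1]
    try:
        chi2 = float(z @ np.linalg.solve(Vsub, z))
    except np.linalg.LinAlgError:
        chi2 = float(z @ np.linalg.pinv(Vsub) @ z)
    chi2 = max(chi2, 0.0)
    df = k - 1
    return LogRankResult(chi2=chi2, df=df, p=float(stats.chi2.sf(chi2, df)))


@dataclass
class StratificationResult:
    labels: np.ndarray  # 'low' / 'high' per patient
    logrank: LogRankResult
    km_low: KMCurve
    km_high: KMCurve
    n_low: int
    n_high: int
    dropped_genes: list[str]


def stratify_by_signature(
    cohort: SurvivalCohort,
    signature: GeneSignature | Sequence[str],
    split: str = "median",
) -> StratificationResult:
    """Median split on the mean signature expression, then KM + log-rank.

    Ties at the median go to the low group.  Missing signature genes are
    dropped and reported; fewer than 2 usable genes is an error, as is a
    degenerate split leaving one group empty.
    """
    if split != "median":
        raise ConfigError(f"unsupported split {split!r}; only 'median'")
    genes = list(signature.genes) if isinstance(signature, GeneSignature) else list(signature)
    present = [g for g in genes if g in cohort.expression.columns]
    dropped = [g for g in genes if g not in cohort.expression.columns]
    if len(present) < 2:
        raise ValidationError(
            f"need >= 2 usable signature genes, found {len(present)} (dropped {len(dropped)})"
        )
    score = cohort.expression[present].mean(axis=1).to_numpy()
    cut = float(np.median(score))
    labels = np.where(score > cut, "high", "low")
    n_low, n_high = int((labels == "low").sum()), int((labels == "high").sum())
    if n_low == 0 or n_high == 0:
        raise ValidationError("degenerate split: all patients fall in one group")
    lr = logrank(cohort.time, cohort.event, labels)
    km_low = km_estimate(cohort.time[labels == "low"], cohort.event[labels == "low"])
    km_high = km_estimate(cohort.time[labels == "high"], cohort.event[labels == "high"])
    return StratificationResult(labels, lr, km_low, km_high, n_low, n_high, dropped)


def subtype_stratified(
    cohort: SurvivalCohort,
    signature: GeneSignature | Sequence[str],
    min_group_size: int = 20,
) -> tuple[dict[str, StratificationResult], list[str]]:
    """Run the signature stratification independently within each subtype.

    Subtypes with fewer than ``min_group_size`` patients are skipped and
    reported; no passing subtype is an error.
    """
    results: dict[str, StratificationResult] = {}
    skipped: list[str] = []
    for subtype in sorted(pd.unique(cohort.subtype)):
        mask = cohort.subtype == subtype
        if mask.sum() < min_group_size:
            skipped.append(subtype)
            continue
        sub = SurvivalCohort(
            time=cohort.time[mask],
            event=cohort.event[mask],
            subtype=cohort.subtype[mask],
            expression=cohort.expression.loc[mask].reset_index(drop=True),
        )
        results[subtype] = stratify_by_signature(sub, signature)
    if not results:
        raise ValidationError("no subtype reached the minimum group size")
    return results, skipped
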