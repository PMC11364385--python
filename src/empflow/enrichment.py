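"""Preranked gene-set enrichment (weighted Kolmogorov-Smirnov statistic).

Given a gene ranking with a per-gene statistic, the enrichment score (ES)
of a set is the signed maximum deviation of a running sum that increments
proportionally to ``|stat|^weight`` at set members ("hits") and decrements
``1/(N - N_hits)`` at non-members.  Significance comes from a gene-label
permutation null: size-matched random sets drawn from the ranking.  The
normalized score (NES) divides ES by the mean magnitude of same-sign null
scores; FDR uses the sign-stratified pooled null-NES method.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel import GeneSignature
from .errors import ConfigError, ValidationError
from .hurdle import DEResult


def rank_from_de(de_result: DEResult, stat: str = "log2fc") -> pd.Series:
    """Descending gene ranking from a DE table.

    Default statistic is the log2 fold change; ``stat='signed_logp'``
    ranks by ``sign(log2fc) * -log10(p_hurdle)``.  Ties break by gene
    symbol (ascending) for determinism.
    """
    t = de_result.table
    if t.empty:
        raise ValidationError("empty DE table")
    if stat == "log2fc":
        values = t["log2fc"]
    elif stat == "signed_logp":
        values = np.sign(t["log2fc"]) * (-np.log10(np.clip(t["p_hurdle"], 1e-300, None)))
    else:
        raise ConfigError(f"unknown ranking stat {stat!r}")
    df = pd.DataFrame({"stat": values}).reset_index(names="gene")
    df = df.sort_values(["stat", "gene"], ascending=[False, True], kind="stable")
    return pd.Series(df["stat"].to_numpy(), index=df["gene"].to_numpy(), name="stat")


def enrichment_score(
    ranked_genes: Sequence[str],
    ranking_stat: Sequence[float],
    gene_set: Sequence[str] | GeneSignature,
    weight: float = 1.0,
) -> tuple[float, np.ndarray, list[str]]:
    """ES, full running sum, and leading-edge genes for one set."""
    genes = list(ranked_genes)
    stats_ = np.asarray(ranking_stat, dtype=float)
    if len(genes) != stats_.size:
        raise ValidationError("ranking genes and stats differ in length")
    if len(set(genes)) != len(genes):
        raise ValidationError("ranking contains duplicate genes")
    members = set(gene_set.genes) if isinstance(gene_set, GeneSignature) else set(gene_set)
    hit = np.array([g in members for g in genes])
    n_hits = int(hit.sum())
    if n_hits == 0:
        raise ValidationError("gene set does not intersect the ranking")
    if n_hits == len(genes):
        raise ValidationError("gene set covers the entire ranking (miss denominator is 0)")
    return _es_from_hits(genes, stats_, hit, weight)


def _es_from_hits(genes, stats_, hit, weight):
    w = np.abs(stats_) ** weight
    w_hit = np.where(hit, w, 0.0)
    total = w_hit.sum()
    if total == 0:  # all hit stats are zero: equal increments
        w_hit = hit.astype(float)
        total = w_hit.sum()
    n_miss = (~hit).sum()
    step = np.where(hit, w_hit / total, -1.0 / n_miss)
    running = np.cumsum(step)
    i_max = int(np.argmax(np.abs(running)))
    es = float(running[i_max])
    if es >= 0:
        leading = [g for k, g in enumerate(genes) if hit[k] and k <= i_max]
    else:
        leading = [g for k, g in enumerate(genes) if hit[k] and k >= i_max]
    return es, running, leading


@dataclass
class GSEAResult:
    table: pd.DataFrame  # per set: es, nes, p, fdr, size, leading_edge
    skipped: list[str]


def preranked_gsea(
    ranking: pd.Series,
    gene_sets: Sequence[GeneSignature] | Mapping[str, Sequence[str]],
    n_perm: int = 1000,
    weight: float = 1.0,
    seed: int = 0,
    min_size: int = 5,
) -> GSEAResult:
    """Permutation-normalized enrichment over a collection of sets.

    ``ranking`` is a gene-indexed Series of statistics (sorted descending
    internally, ties broken by symbol).  The null for each set is the ES of
    ``n_perm`` size-matched random sets; ``p = (1 + #null at least as
    extreme, same sign) / (1 + n_perm)``.
    """
    if n_perm < 100:
        raise ConfigError("n_perm must be >= 100")
    df = pd.DataFrame({"stat": ranking})
    df = df.reset_index(names="gene").sort_values(
        ["stat", "gene"], ascending=[False, True], kind="stable"
    )
    genes = df["gene"].tolist()
    stats_ = df["stat"].to_numpy()
    gene_pos = {g: i for i, g in enumerate(genes)}
    N = len(genes)

    if isinstance(gene_sets, Mapping):
        sets = [GeneSignature.from_genes(k, v, warn_duplicates=False) for k, v in gene_sets.items()]
    else:
        sets = list(gene_sets)

    rng = np.random.default_rng(seed)
    rows = []
    skipped: list[str] = []
    null_nes_pos: list[float] = []
    null_nes_neg: list[float] = []
    for sig in sets:
        idx = [gene_pos[g] for g in sig.genes if g in gene_pos]
        size = len(idx)
        if size < min_size or size >= N:
            skipped.append(sig.name)
            continue
        hit = np.zeros(N, dtype=bool)
        hit[idx] = True
        es, _, leading = _es_from_hits(genes, stats_, hit, weight)

        null = np.empty(n_perm)
        for b in range(n_perm):
            rand_idx = rng.choice(N, size=size, replace=False)
            h = np.zeros(N, dtype=bool)
            h[rand_idx] = True
            null[b], _, _ = _es_from_hits(genes, stats_, h, weight)

        same_sign = null >= 0 if es >= 0 else null < 0
        denom = np.abs(null[same_sign]).mean() if same_sign.any() else np.abs(null).mean()
        nes = es / denom if denom > 0 else 0.0
        extreme = int((same_sign & (np.abs(null) >= abs(es))).sum())
        p = (1 + extreme) / (1 + n_perm)
        # pool sign-normalized null NES for the FDR step
        pos_mean = np.abs(null[null >= 0]).mean() if (null >= 0).any() else np.nan
        neg_mean = np.abs(null[null < 0]).mean() if (null < 0).any() else np.nan
        if np.isfinite(pos_mean):
            null_nes_pos.extend((null[null >= 0] / pos_mean).tolist())
        if np.isfinite(neg_mean):
            null_nes_neg.extend((null[null < 0] / neg_mean).tolist())
        rows.append(
            {"set": sig.name, "size": size, "es": es, "nes": float(nes), "p": float(p),
             "leading_edge": ",".join(leading)}
        )

    table = pd.DataFrame(rows).set_index("set") if rows else pd.DataFrame(
        columns=["size", "es", "nes", "p", "leading_edge"]
    )
    if len(table):
        fdr = np.ones(len(table))
        nes_obs = table["nes"].to_numpy()
        pos_null = np.asarray(null_nes_pos)
        neg_null = np.asarray(null_nes_neg)
        for i, nes in enumerate(nes_obs):
            if nes >= 0:
                null_frac = (pos_null >= nes).mean() if pos_null.size else 1.0
                obs_frac = (nes_obs[nes_obs >= 0] >= nes).mean()
            else:
                null_frac = (neg_null <= nes).mean() if neg_null.size else 1.0
                obs_frac = (nes_obs[nes_obs < 0] <= nes).mean()
            fdr[i] = min(1.0, null_frac / obs_frac) if obs_frac > 0 else 1.0
        table["fdr"] = fdr
    return GSEAResult(table=table, skipped=skipped)
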