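"""Cross-cutting association statistics.

Principal components of the normalized expression (top variable genes,
deterministic sign convention), per-tumor correlation of the EMP signature
with the leading PCs, the EMP vs metastatic-potential correlation over
tumors, paired compartment/platform EMP correlations with a linear fit,
and group separation along a chosen PC axis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import ExpressionDataset
from .errors import ConfigError, StructuralError, ValidationError
from .hurdle import wilcoxon_test

DEFAULT_ENCODING = {"low": 1, "moderate": 2, "high": 3}


@dataclass
class PCAResult:
    coords: pd.DataFrame  # cells x PC1..PCk
    explained_variance_ratio: np.ndarray
    loadings: pd.DataFrame  # genes x PCs


def pca(
    dataset: ExpressionDataset,
    n_components: int = 5,
    scope: str = "global",
    n_top_genes: int = 2000,
) -> "PCAResult | dict[str, PCAResult]":
    """PCA of the centered normalized matrix on dispersion-ranked genes.

    Sign convention: within each component the gene with the largest
    absolute loading is made positive, so repeated runs are identical.
    ``scope='per-tumor'`` returns one PCAResult per tumor model.
    """
    if scope == "per-tumor":
        out = {}
        for model in sorted(dataset.cell_meta["tumor_model"].unique()):
            sub = dataset.subset_cells((dataset.cell_meta["tumor_model"] == model).to_numpy())
            k = min(n_components, sub.n_cells - 1)
            if k < 1:
                continue
            out[model] = pca(sub, n_components=k, scope="global", n_top_genes=n_top_genes)
        return out
    if scope != "global":
        raise ConfigError(f"unknown scope {scope!r}")
    if dataset.n_cells <= n_components:
        raise ValidationError(
            f"need more cells ({dataset.n_cells}) than components ({n_components})"
        )

    norm = dataset.normalized
    mean = norm.mean(axis=0)
    var = norm.var(axis=0)
    nonconstant = var > 0
    if int(nonconstant.sum()) < n_components:
        raise ValidationError("fewer non-constant genes than requested components")
    dispersion = np.where(mean > 0, var / np.maximum(mean, 1e-12), 0.0)
    dispersion[~nonconstant] = -np.inf
    n_top = min(n_top_genes, int(nonconstant.sum()))
    top = np.sort(np.argsort(-dispersion, kind="stable")[:n_top])

    X = norm[:, top] - norm[:, top].mean(axis=0)
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    k = n_components
    components = Vt[:k]
    # deterministic sign: largest-|loading| gene positive per component
    for i in range(k):
        j = int(np.argmax(np.abs(components[i])))
        if components[i, j] < 0:
            components[i] = -components[i]
            U[:, i] = -U[:, i]
    coords = U[:, :k] * S[:k]
    total_var = (S**2).sum()
    evr = (S[:k] ** 2) / total_var if total_var > 0 else np.zeros(k)
    pcs = [f"PC{i + 1}" for i in range(k)]
    return PCAResult(
        coords=pd.DataFrame(coords, index=dataset.cell_ids, columns=pcs),
        explained_variance_ratio=evr,
        loadings=pd.DataFrame(components.T, index=dataset.genes[top], columns=pcs),
    )


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def emp_pc_correlation(
    score_table: pd.DataFrame,
    dataset: ExpressionDataset,
    group_key: str = "tumor_model",
    n_components: int = 5,
    n_top_genes: int = 2000,
) -> pd.DataFrame:
    """Per-tumor Pearson r between the EMP signature and PCs 1..k.

    PCA runs per tumor (within-tumor variation); tumors with fewer than 3
    cells are skipped, and correlations undefined because of a constant
    EMP score are reported as NaN.
    """
    per_tumor = pca(dataset, n_components=n_components, scope="per-tumor", n_top_genes=n_top_genes)
    rows = {}
    for model, res in per_tumor.items():
        cells = res.coords.index
        if len(cells) < 3:
            continue
        emp = score_table.loc[cells, "emp"].to_numpy()
        rows[model] = {
            pc: pearson(emp, res.coords[pc].to_numpy()) for pc in res.coords.columns
        }
    return pd.DataFrame.from_dict(rows, orient="index").sort_index()


def potential_correlation(
    score_table: pd.DataFrame,
    cell_meta: pd.DataFrame,
    encoding: Mapping[str, float] = DEFAULT_ENCODING,
    group_key: str = "tumor_model",
    potential_key: str = "metastatic_potential",
) -> float:
    """Pearson r of per-tumor mean EMP vs ordinally encoded potential."""
    joined = score_table.join(cell_meta[[group_key, potential_key]], how="inner")
    per_tumor = joined.groupby(group_key).agg(
        emp=("emp", "mean"), potential=(potential_key, "first")
    )
    if per_tumor["potential"].nunique() < 2:
        raise ValidationError("need tumors spanning at least 2 potential levels")
    if len(per_tumor) < 3:
        raise ValidationError("need at least 3 tumors")
    encoded = per_tumor["potential"].map(dict(encoding))
    if encoded.isna().any():
        missing = per_tumor["potential"][encoded.isna()].unique().tolist()
        raise ConfigError(f"encoding missing levels: {missing}")
    return pearson(per_tumor["emp"].to_numpy(), encoded.to_numpy(dtype=float))


@dataclass
class PairedCorrelation:
    table: pd.DataFrame  # per model: mean emp in each compartment
    r: float
    r2: float
    slope: float
    intercept: float
    slope_ci: tuple[float, float]  # 95% CI


def paired_emp_correlation(
    score_table: pd.DataFrame,
    cell_meta: pd.DataFrame,
    pair_key: str = "tissue",
    group_key: str = "tumor_model",
) -> PairedCorrelation:
    """One point per model: mean EMP in each of the two pair levels.

    Works for primary-vs-metastasis (``pair_key='tissue'``) and for
    cross-platform reproducibility (``pair_key='platform'``).  Requires
    at least 3 complete pairs.
    """
    joined = score_table.join(cell_meta[[group_key, pair_key]], how="inner")
    levels = sorted(joined[pair_key].unique())
    if len(levels) != 2:
        raise ValidationError(f"pair_key {pair_key!r} must have exactly 2 levels, found {levels}")
    means = joined.groupby([group_key, pair_key])["emp"].mean().unstack(pair_key)
    complete = means.dropna()
    if len(complete) < 3:
        raise ValidationError(f"need >= 3 complete pairs, found {len(complete)}")
    x = complete[levels[0]].to_numpy()
    y = complete[levels[1]].to_numpy()
    r = pearson(x, y)
    fit = stats.linregress(x, y)
    tcrit = stats.t.ppf(0.975, len(x) - 2) if len(x) > 2 else np.nan
    ci = (fit.slope - tcrit * fit.stderr, fit.slope + tcrit * fit.stderr)
    return PairedCorrelation(
        table=complete, r=r, r2=r * r, slope=float(fit.slope),
        intercept=float(fit.intercept), slope_ci=(float(ci[0]), float(ci[1])),
    )


@dataclass
class PCSeparation:
    axis: str
    groups: list[str]
    coordinates: dict[str, np.ndarray]
    histograms: dict[str, tuple[np.ndarray, np.ndarray]]  # (density, bin_edges)
    p: float


def pc_separation(
    pc_coords: pd.DataFrame,
    cell_meta: pd.DataFrame,
    axis: int = 2,
    group_key: str = "tissue",
    bins: int = 30,
) -> PCSeparation:
    """Density summaries + Wilcoxon p for two groups along one PC axis."""
    col = f"PC{axis}"
    if col not in pc_coords.columns:
        raise ConfigError(f"axis PC{axis} beyond computed components {list(pc_coords.columns)}")
    if group_key not in cell_meta.columns:
        raise StructuralError(f"unknown cell_meta column {group_key!r}")
    joined = pc_coords[[col]].join(cell_meta[[group_key]], how="inner")
    levels = sorted(joined[group_key].unique())
    if len(levels) != 2:
        raise ValidationError(f"need exactly 2 groups along {col}, found {levels}")
    coords = {lev: joined.loc[joined[group_key] == lev, col].to_numpy() for lev in levels}
    for lev, v in coords.items():
        if v.size == 0:
            raise ValidationError(f"group {lev!r} is empty")
    edges = np.histogram_bin_edges(joined[col].to_numpy(), bins=bins)
    histograms = {
        lev: np.histogram(v, bins=edges, density=True) for lev, v in coords.items()
    }
    p = wilcoxon_test(coords[levels[0]], coords[levels[1]])
    return PCSeparation(axis=col, groups=levels, coordinates=coords, histograms=histograms, p=p)
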