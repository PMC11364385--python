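"""Two-part (hurdle) differential expression for single-cell data.

Expression of a gene is modeled in two parts: a logistic regression on the
detection indicator ``1{y > 0}`` and a Gaussian linear model on the
log-normalized expression of the expressing cells.  Both parts share the
same design matrix; a covariate of interest is tested by a likelihood-ratio
statistic summed over the two components and referred to a chi-square
distribution with degrees of freedom equal to the number of coefficients
dropped across the fitted components.

The logistic part carries a small ridge penalty (default 1e-3) on all
coefficients so the fit survives complete separation; full and reduced
models share the penalty, which keeps the LRT statistic non-negative.

Also provided: the simple two-group Wilcoxon rank and Fisher exact
alternatives, and Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datamodel import ExpressionDataset
from .errors import ConfigError, StructuralError, ValidationError

_LOG2PI = np.log(2.0 * np.pi)
_SIGMA2_FLOOR = 1e-12


def _check_full_rank(X: np.ndarray, names: Sequence[str] | None = None) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        names = list(names) if names is not None else [f"col{j}" for j in range(X.shape[1])]
        # identify columns whose removal restores full column rank
        collinear = []
        for j in range(X.shape[1]):
            keep = [k for k in range(X.shape[1]) if k != j]
            if np.linalg.matrix_rank(X[:, keep]) == rank:
                collinear.append(names[j])
        raise StructuralError(f"design matrix is rank-deficient; collinear columns: {collinear}")


def _logistic_ridge(z: np.ndarray, X: np.ndarray, ridge: float, max_iter: int = 50, tol: float = 1e-10):
    """Newton fit of ridge-penalized logistic regression.

    Returns ``(beta, penalized_loglik)`` where the penalized log-likelihood
    is ``sum[z log p + (1-z) log(1-p)] - 0.5 * ridge * ||beta||^2``.
    """
    from scipy.special import expit

    n, p = X.shape
    beta = np.zeros(p)
    I = ridge * np.eye(p)
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        grad = X.T @ (z - mu) - ridge * beta
        W = np.clip(mu * (1.0 - mu), 1e-12, None)
        H = (X * W[:, None]).T @ X + I
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    eta = X @ beta
    ll = float(np.sum(z * eta - np.logaddexp(0.0, eta))) - 0.5 * ridge * float(beta @ beta)
    return beta, ll


def _gaussian_loglik(y: np.ndarray, X: np.ndarray):
    """OLS fit with MLE variance; returns (coef, sigma2, loglik)."""
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    n = y.size
    sigma2 = max(float(resid @ resid) / n, _SIGMA2_FLOOR)
    ll = -0.5 * n * (_LOG2PI + np.log(sigma2) + 1.0)
    return coef, sigma2, ll


@dataclass
class HurdleFit:
    """Fitted two-part model for one gene and one design."""

    logistic_coef: np.ndarray
    logistic_loglik: float
    continuous_coef: np.ndarray | None
    sigma2: float | None
    continuous_loglik: float | None
    n_expressing: int

    @property
    def continuous_fitted(self) -> bool:
        return self.continuous_loglik is not None

    @property
    def total_loglik(self) -> float:
        return self.logistic_loglik + (self.continuous_loglik or 0.0)


def fit_hurdle(
    y: np.ndarray,
    X: np.ndarray,
    ridge: float = 1e-3,
    column_names: Sequence[str] | None = None,
    check_rank: bool = True,
) -> HurdleFit:
    """Fit the two-part model of ``y`` (normalized expression) on design ``X``.

    The logistic component models ``1{y > 0}``; the continuous component is
    ordinary least squares on the expressing cells and is marked absent when
    fewer than 2 cells express the gene.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if y.shape[0] != X.shape[0]:
        raise StructuralError("y and X have different numbers of rows")
    if check_rank:
        _check_full_rank(X, column_names)
    z = (y > 0).astype(float)
    beta, ll_log = _logistic_ridge(z, X, ridge)
    pos = y > 0
    n_expr = int(pos.sum())
    if n_expr >= 2:
        coef, sigma2, ll_cont = _gaussian_loglik(y[pos], X[pos])
        return HurdleFit(beta, ll_log, coef, sigma2, ll_cont, n_expr)
    return HurdleFit(beta, ll_log, None, None, None, n_expr)


def _columns_subset(X_full: np.ndarray, X_reduced: np.ndarray) -> None:
    """Require every reduced column to appear among the full columns."""
    for j in range(X_reduced.shape[1]):
        col = X_reduced[:, j]
        if not any(np.array_equal(col, X_full[:, k]) for k in range(X_full.shape[1])):
            raise StructuralError(f"reduced design column {j} is not a column of the full design")


@dataclass
class LRTResult:
    stat: float
    df: int
    p: float
    p_discrete: float
    p_continuous: float
    fit_full: HurdleFit
    fit_reduced: HurdleFit


def hurdle_lrt(
    y: np.ndarray,
    X_full: np.ndarray,
    X_reduced: np.ndarray,
    ridge: float = 1e-3,
    check_designs: bool = True,
) -> LRTResult:
    """Likelihood-ratio test of the columns present in the full design only.

    The statistic is twice the penalized log-likelihood difference summed
    over both components (absent components contribute 0); df counts the
    dropped columns once per fitted component.
    """
    X_full = np.asarray(X_full, dtype=float)
    X_reduced = np.asarray(X_reduced, dtype=float)
    k_dropped = X_full.shape[1] - X_reduced.shape[1]
    if k_dropped <= 0:
        raise ConfigError("full design must have more columns than the reduced design")
    if check_designs:
        _columns_subset(X_full, X_reduced)
    full = fit_hurdle(y, X_full, ridge=ridge, check_rank=check_designs)
    red = fit_hurdle(y, X_reduced, ridge=ridge, check_rank=check_designs)

    y_arr = np.asarray(y, dtype=float)
    n = y_arr.size
    # A constant detection indicator carries no information about any
    # covariate: the discrete component then contributes neither statistic
    # nor degrees of freedom (else the combined test is conservative for
    # fully detected genes).
    disc_informative = 0 < full.n_expressing < n
    df = 0
    stat = 0.0
    if disc_informative:
        stat_disc = max(2.0 * (full.logistic_loglik - red.logistic_loglik), 0.0)
        p_disc = float(stats.chi2.sf(stat_disc, k_dropped))
        df += k_dropped
        stat += stat_disc
    else:
        stat_disc, p_disc = 0.0, np.nan
    if full.continuous_fitted and red.continuous_fitted:
        stat_cont = max(2.0 * (full.continuous_loglik - red.continuous_loglik), 0.0)
        p_cont = float(stats.chi2.sf(stat_cont, k_dropped))
        df += k_dropped
        stat += stat_cont
    else:
        stat_cont, p_cont = 0.0, np.nan
    p = float(stats.chi2.sf(stat, df)) if df > 0 else 1.0
    return LRTResult(stat=float(stat), df=df, p=p, p_discrete=p_disc, p_continuous=p_cont,
                     fit_full=full, fit_reduced=red)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


def _dummies(values: np.ndarray) -> tuple[np.ndarray, list[str]]:
    levels = sorted(pd.unique(values).tolist())
    cols = []
    names = []
    for lev in levels[1:]:  # drop first level
        cols.append((values == lev).astype(float))
        names.append(str(lev))
    if cols:
        return np.column_stack(cols), names
    return np.empty((values.size, 0)), names


@dataclass
class DEResult:
    """Per-gene hurdle-test table for one two-group contrast."""

    table: pd.DataFrame
    group_A: str
    group_B: str
    n_A: int
    n_B: int
    skipped_genes: list[str] = field(default_factory=list)

    def significant(
        self,
        direction: str | None = None,
        lfc_threshold: float = 0.5,
        p_threshold: float = 0.05,
        use_adjusted: bool = False,
    ) -> pd.DataFrame:
        """Genes passing the fold-change + p-value rule.

        ``direction='up'`` keeps genes higher in group A, ``'down'`` lower;
        ``None`` keeps both.  Default thresholds |log2FC| > 0.5 and raw
        p < 0.05, with ``use_adjusted`` switching to BH-adjusted p.
        """
        t = self.table
        pcol = "adj_p" if use_adjusted else "p_hurdle"
        keep = (t[pcol] < p_threshold) & (t["log2fc"].abs() > lfc_threshold)
        if direction == "up":
            keep &= t["log2fc"] > 0
        elif direction == "down":
            keep &= t["log2fc"] < 0
        elif direction is not None:
            raise ConfigError(f"unknown direction {direction!r}")
        return t[keep]


def run_de(
    dataset: ExpressionDataset,
    contrast_key: str,
    group_A: str,
    group_B: str,
    covariate_keys: Sequence[str] = (),
    min_cells: int = 3,
    ridge: float = 1e-3,
    genes: Sequence[str] | None = None,
) -> DEResult:
    """Hurdle-test every gene for group A vs group B of ``contrast_key``.

    Covariates (e.g. the tumor model) enter both the full and reduced
    designs; the contrast indicator is dropped in the reduced design.
    ``log2fc`` is the difference of group means of the normalized layer
    (A minus B).  Genes expressed in fewer than ``min_cells`` cells are
    skipped and listed.  BH adjustment runs across the tested genes.
    """
    meta = dataset.cell_meta
    if contrast_key not in meta.columns:
        raise StructuralError(f"unknown cell_meta column {contrast_key!r}")
    in_A = (meta[contrast_key] == group_A).to_numpy()
    in_B = (meta[contrast_key] == group_B).to_numpy()
    if in_A.sum() < min_cells or in_B.sum() < min_cells:
        raise ValidationError(
            f"both groups need >= {min_cells} cells (A={int(in_A.sum())}, B={int(in_B.sum())})"
        )
    sel = in_A | in_B
    sub = dataset.subset_cells(sel)
    a_mask = (sub.cell_meta[contrast_key] == group_A).to_numpy()

    # Symmetric +-1/2 coding keeps the ridge-penalized LRT exactly
    # invariant under exchanging the two group labels.
    contrast_col = (a_mask.astype(float) - 0.5)[:, None]
    design_cols = [np.ones((sub.n_cells, 1)), contrast_col]
    names = ["intercept", f"{contrast_key}[{group_A}]"]
    for key in covariate_keys:
        if key not in sub.cell_meta.columns:
            raise StructuralError(f"unknown covariate column {key!r}")
        block, levels = _dummies(sub.cell_meta[key].to_numpy())
        design_cols.append(block)
        names += [f"{key}[{lev}]" for lev in levels]
    X_full = np.hstack(design_cols)
    X_reduced = np.hstack([design_cols[0]] + design_cols[2:])
    _check_full_rank(X_full, names)

    gene_index = pd.Index(dataset.genes)
    if genes is None:
        test_genes = list(gene_index)
    else:
        test_genes = [g for g in genes if g in gene_index]

    rows = []
    skipped: list[str] = []
    norm = sub.normalized
    for g in test_genes:
        j = gene_index.get_loc(g)
        y = norm[:, j]
        expressed = y > 0
        if int(expressed.sum()) < min_cells:
            skipped.append(g)
            continue
        lrt = hurdle_lrt(y, X_full, X_reduced, ridge=ridge, check_designs=False)
        mean_A = float(y[a_mask].mean())
        mean_B = float(y[~a_mask].mean())
        lfc = mean_A - mean_B
        rows.append(
            {
                "gene": g,
                "log2fc": lfc,
                "p_discrete": lrt.p_discrete,
                "p_continuous": lrt.p_continuous,
                "p_hurdle": lrt.p,
                "frac_expr_A": float(expressed[a_mask].mean()),
                "frac_expr_B": float(expressed[~a_mask].mean()),
                "direction": int(np.sign(lfc)),
            }
        )
    if not rows:
        raise ValidationError("no gene passed the expression filter")
    table = pd.DataFrame(rows).set_index("gene")
    table["adj_p"] = bh_adjust(table["p_hurdle"].to_numpy())
    table["n_A"] = int(a_mask.sum())
    table["n_B"] = int((~a_mask).sum())
    return DEResult(
        table=table,
        group_A=group_A,
        group_B=group_B,
        n_A=int(a_mask.sum()),
        n_B=int((~a_mask).sum()),
        skipped_genes=skipped,
    )


def wilcoxon_test(x, y) -> float:
    """Two-sided, unpaired Wilcoxon rank (Mann-Whitney) p-value.

    Exact enumeration when n+m <= 20 and the data are tie-free; otherwise
    the tie-corrected normal approximation.  Fully tied input returns 1
    with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.unique(pooled).size == 1:
        warnings.warn("all observations tied; Wilcoxon p set to 1", stacklevel=2)
        return 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (x.size + y.size <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.pvalue)


def fisher_exact(table) -> float:
    """Two-sided Fisher exact p for a 2x2 contingency table."""
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValidationError("Fisher test requires a 2x2 table")
    if (arr < 0).any() or not np.issubdtype(arr.dtype, np.integer):
        raise ValidationError("table entries must be non-negative integers")
    return float(stats.fisher_exact(arr, alternative="two-sided")[1])
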