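"""Copy-number-associated gene detection by permutation-tested correlation.

For every gene inside a significant copy-number region, paired copy-number
and expression values across samples are correlated (Pearson r).  The null
distribution is built by permuting sample labels of the expression matrix:
one shared permutation per iteration applied to all genes, which preserves
the inter-gene correlation structure of the null.  The empirical p-value is
the fraction of permutation correlations strictly exceeding the observed one
(one-sided: dosage effects produce positive r for both gains-with-higher and
losses-with-lower expression).  P-values are Benjamini–Hochberg adjusted and
genes with q < 0.1 are selected as copy-number associated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AssociationResult",
    "correlate_gene",
    "permutation_pvalues",
    "bh_fdr",
]


@dataclass(frozen=True)
class AssociationResult:
    """Per-gene association statistics."""

    gene: str
    r: float
    p_perm: float
    q: float
    selected: bool
    degenerate: bool = False


class DegenerateGeneError(ValueError):
    """Raised when a correlation is undefined (zero variance in either vector)."""


def correlate_gene(cn_row: np.ndarray, expr_row: np.ndarray) -> float:
    """Sample Pearson correlation between one gene's copy-number and expression.

    Raises
    ------
    DegenerateGeneError
        If either vector has zero variance (r undefined); callers exclude
        such genes from testing.
    """
    x = np.asarray(cn_row, dtype=float)
    y = np.asarray(expr_row, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("cn_row and expr_row must be 1-D vectors of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt((xc**2).sum())
    sy = np.sqrt((yc**2).sum())
    if sx == 0.0 or sy == 0.0:
        raise DegenerateGeneError("zero variance: correlation undefined")
    return float((xc * yc).sum() / (sx * sy))


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted values, in input order, capped at 1."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must be in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _row_correlations(cn: np.ndarray, expr: np.ndarray) -> np.ndarray:
    """Row-wise Pearson r between aligned (genes x samples) matrices."""
    xc = cn - cn.mean(axis=1, keepdims=True)
    yc = expr - expr.mean(axis=1, keepdims=True)
    num = (xc * yc).sum(axis=1)
    den = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / den


def permutation_pvalues(
    cn: pd.DataFrame,
    expr: pd.DataFrame,
    n_perm: int = 1000,
    seed: int | None = None,
    fdr_threshold: float = 0.1,
    smooth: bool = False,
) -> list[AssociationResult]:
    """Permutation-tested copy-number/expression association for each gene.

    Parameters
    ----------
    cn, expr
        Aligned (genes x samples) DataFrames; identical index and columns.
    n_perm
        Number of whole-column expression permutations (shared across genes
        per iteration).
    smooth
        If True, report (1 + count) / (1 + n_perm) instead of the raw
        count / n_perm, avoiding exact zeros.  Off by default: the raw
        empirical fraction is the primary definition.

    Returns
    -------
    One :class:`AssociationResult` per gene, in ``cn``'s gene order.  Genes
    with zero variance in either matrix are flagged degenerate, excluded
    from testing and multiplicity correction, and reported with NaN
    statistics.
    """
    if not cn.index.equals(expr.index):
        raise ValueError("cn and expr must have identical gene sets and order")
    if not cn.columns.equals(expr.columns):
        raise ValueError("cn and expr must have identical samples and order")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")

    X = cn.to_numpy(dtype=float)
    Y = expr.to_numpy(dtype=float)
    n_genes, n_samples = X.shape
    if n_samples < 3:
        raise ValueError("need at least 3 samples")

    ok = (X.std(axis=1) > 0) & (Y.std(axis=1) > 0)
    r_obs = np.full(n_genes, np.nan)
    r_obs[ok] = _row_correlations(X[ok], Y[ok])

    rng = np.random.default_rng(seed)
    exceed = np.zeros(ok.sum())
    Xok, Yok, robs_ok = X[ok], Y[ok], r_obs[ok]
    for _ in range(n_perm):
        perm = rng.permutation(n_samples)
        r_perm = _row_correlations(Xok, Yok[:, perm])
        exceed += r_perm > robs_ok  # strict: ties do not count

    if smooth:
        p_ok = (1.0 + exceed) / (1.0 + n_perm)
    else:
        p_ok = exceed / n_perm
    q_ok = bh_fdr(p_ok)

    results: list[AssociationResult] = []
    k = 0
    for i, gene in enumerate(cn.index):
        if ok[i]:
            results.append(
                AssociationResult(
                    gene=str(gene),
                    r=float(r_obs[i]),
                    p_perm=float(p_ok[k]),
                    q=float(q_ok[k]),
                    selected=bool(q_ok[k] < fdr_threshold),
                )
            )
            k += 1
        else:
            results.append(
                AssociationResult(
                    gene=str(gene), r=float("nan"), p_perm=float("nan"),
                    q=float("nan"), selected=False, degenerate=True,
                )
            )
    return results


def association_table(results: list[AssociationResult]) -> pd.DataFrame:
    """Tabular view (gene, r, p, q, selected, degenerate) of association results."""
    return pd.DataFrame(
        {
            "gene": [a.gene for a in results],
            "r": [a.r for a in results],
            "p": [a.p_perm for a in results],
            "q": [a.q for a in results],
            "selected": [a.selected for a in results],
            "degenerate": [a.degenerate for a in results],
        }
    )
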