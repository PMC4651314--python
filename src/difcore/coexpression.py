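"""Per-condition Pearson co-expression networks over a selected gene set.

Networks are built separately from each condition's samples, because the
differential core statistic needs one graph per condition. Edges carry the
signed correlation; thresholding is on |r| (``abs_r`` mode, the practical
default at 3 samples per condition) or on the BH-adjusted correlation
p-value (``fdr`` mode).
"""

from __future__ import annotations

import warnings

import numpy as np
import networkx as nx
import pandas as pd
from scipy import stats

from .de import CountMatrix, bh_fdr

__all__ = [
    "normalize_expression",
    "pairwise_correlation",
    "build_network",
    "condition_network",
]


def normalize_expression(
    counts: pd.DataFrame,
    factors: pd.Series,
    log2: bool = True,
) -> pd.DataFrame:
    """Size-factor normalized expression, optionally log2(x + 1) transformed."""
    factors = factors.reindex(counts.columns)
    if not (factors > 0).all():
        raise ValueError("size factors must be positive")
    expr = counts / factors
    if log2:
        expr = np.log2(expr + 1.0)
    return expr


def pairwise_correlation(expr: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All-pairs Pearson r over samples (columns) with two-sided p-values.

    p comes from the t transform with n - 2 degrees of freedom; pairs with
    |r| = 1 get p = 0. Genes with zero variance across samples are dropped
    with a warning. Requires at least 3 samples.
    """
    n = expr.shape[1]
    if n < 3:
        raise ValueError("at least 3 samples are required for correlation p-values")
    variances = expr.var(axis=1)
    constant = variances[variances == 0].index
    if len(constant):
        warnings.warn(
            f"dropping {len(constant)} constant gene(s) from correlation", stacklevel=2
        )
        expr = expr.drop(index=constant)
    genes = expr.index
    r = np.atleast_2d(np.corrcoef(expr.to_numpy()))
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.abs(r) >= 1.0] = 0.0
    np.fill_diagonal(p, 0.0)
    return (
        pd.DataFrame(r, index=genes, columns=genes),
        pd.DataFrame(p, index=genes, columns=genes),
    )


def build_network(
    corr: pd.DataFrame,
    pvals: pd.DataFrame,
    mode: str = "abs_r",
    cutoff: float = 0.95,
    condition: str | None = None,
) -> nx.Graph:
    """Threshold the correlation matrix into an undirected gene graph.

    mode="abs_r" keeps pairs with |r| >= cutoff; mode="fdr" BH-adjusts the
    upper-triangle p-values across all pairs and keeps q < cutoff. Every
    selected gene stays in the graph, isolated genes at degree 0. Edges store
    the signed r (and q in fdr mode).
    """
    if mode not in {"abs_r", "fdr"}:
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "abs_r" and not 0 < cutoff <= 1:
        raise ValueError("abs_r cutoff must lie in (0, 1]")
    if mode == "fdr" and not 0 < cutoff < 1:
        raise ValueError("fdr cutoff must lie in (0, 1)")
    if not corr.index.equals(pvals.index) or not corr.columns.equals(pvals.columns):
        raise ValueError("correlation and p-value matrices are inconsistent")

    genes = list(corr.index)
    g = nx.Graph(condition=condition, mode=mode, cutoff=cutoff)
    g.add_nodes_from(genes)
    iu, ju = np.triu_indices(len(genes), k=1)
    r_flat = corr.to_numpy()[iu, ju]
    if mode == "abs_r":
        keep = np.abs(r_flat) >= cutoff
        q_flat = np.full(r_flat.shape, np.nan)
    else:
        q_flat = bh_fdr(pvals.to_numpy()[iu, ju])
        keep = q_flat < cutoff
    for a, b, r, q in zip(iu[keep], ju[keep], r_flat[keep], q_flat[keep]):
        g.add_edge(genes[a], genes[b], r=float(r), q=float(q))
    return g


def condition_network(
    cm: CountMatrix,
    genes,
    condition: str,
    factors: pd.Series | None = None,
    mode: str = "abs_r",
    cutoff: float = 0.95,
    log2: bool = True,
) -> nx.Graph:
    """Convenience path: counts -> normalized expression -> one condition's graph."""
    from .de import size_factors

    if factors is None:
        factors = size_factors(cm.counts)
    samples = cm.samples_of(condition)
    genes = [g for g in genes if g in cm.counts.index]
    expr = normalize_expression(cm.counts.loc[genes, samples], factors[samples], log2=log2)
    corr, pvals = pairwise_correlation(expr)
    return build_network(corr, pvals, mode=mode, cutoff=cutoff, condition=condition)
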