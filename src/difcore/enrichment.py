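"""Gene-set over-representation by Fisher's exact test, split by direction.

One-sided hypergeometric upper-tail p-values (over-representation framing),
Benjamini-Hochberg FDR within each (category, direction) family, and
independent enrichment runs for the up- and down-regulated DE sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .de import bh_fdr

__all__ = ["GeneSet", "AnnotationMap", "fisher_enrichment", "split_by_direction"]

VALID_CATEGORIES = ("BP", "MF", "CC", "pathway")


@dataclass(frozen=True)
class GeneSet:
    term_id: str
    category: str
    genes: frozenset[str]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"term {self.term_id} has an empty gene set")
        if self.category not in VALID_CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


@dataclass
class AnnotationMap:
    """term id -> GeneSet mapping; the union of sets is the annotated universe."""

    terms: dict[str, GeneSet]

    def __len__(self) -> int:
        return len(self.terms)

    def __getitem__(self, term_id: str) -> GeneSet:
        return self.terms[term_id]

    def __iter__(self):
        return iter(self.terms.values())

    @property
    def annotated_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for gs in self.terms.values():
            out |= gs.genes
        return frozenset(out)


def fisher_enrichment(
    de_genes,
    universe,
    annotation: AnnotationMap,
    min_term_size: int = 2,
    direction: str = "all",
) -> pd.DataFrame:
    """One-sided over-representation test of ``de_genes`` per annotated term.

    p = P(X >= k) for X hypergeometric with universe size N, term size K and
    draw size n = |de_genes|; q-values are BH-adjusted within each category.
    Terms smaller than ``min_term_size`` (after intersecting with the
    universe) are skipped.
    """
    universe = set(universe)
    de_set = set(de_genes)
    stray = de_set - universe
    if stray:
        raise ValueError(f"DE genes not in universe: {sorted(stray)[:5]}")
    if not de_set:
        warnings.warn("empty DE set: returning no enrichment results", stacklevel=2)

    n_univ = len(universe)
    n_de = len(de_set)
    rows = []
    for gs in annotation:
        members = gs.genes & universe
        big_k = len(members)
        if big_k < min_term_size:
            continue
        k = len(members & de_set)
        p = float(stats.hypergeom.sf(k - 1, n_univ, big_k, n_de)) if n_de else 1.0
        rows.append(
            {
                "term": gs.term_id,
                "category": gs.category,
                "k": k,
                "K": big_k,
                "n": n_de,
                "N": n_univ,
                "expected": n_de * big_k / n_univ if n_univ else 0.0,
                "p_value": p,
                "direction": direction,
            }
        )
    result = pd.DataFrame(
        rows,
        columns=["term", "category", "k", "K", "n", "N", "expected", "p_value", "direction"],
    )
    if result.empty:
        result["q_value"] = pd.Series(dtype=float)
        return result
    result["q_value"] = np.nan
    for _, idx in result.groupby("category").groups.items():
        result.loc[idx, "q_value"] = bh_fdr(result.loc[idx, "p_value"].to_numpy())
    return result.sort_values(["p_value", "term"], kind="mergesort").reset_index(drop=True)


def split_by_direction(
    de_table: pd.DataFrame,
    annotation: AnnotationMap,
    universe,
    min_term_size: int = 2,
) -> dict[str, pd.DataFrame]:
    """Independent up- and down-set enrichment runs from a directioned DE table.

    ``de_table`` must be indexed by gene with a ``direction`` column; each
    direction's run uses its own DE-set size n. Results carry a
    ``neg_log10_p`` column for bar-chart style sorting.
    """
    out: dict[str, pd.DataFrame] = {}
    for direction in ("up", "down"):
        genes = de_table.index[de_table["direction"] == direction]
        genes = [g for g in genes if g in set(universe)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = fisher_enrichment(
                genes, universe, annotation, min_term_size=min_term_size, direction=direction
            )
        if not table.empty:
            table["neg_log10_p"] = -np.log10(np.maximum(table["p_value"], 1e-300))
        else:
            table["neg_log10_p"] = pd.Series(dtype=float)
        out[direction] = table
    return out
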