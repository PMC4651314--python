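"""Degree centrality, k-core decomposition and the dif-k-core hub ranking.

The dif-k-core statistic of a gene is its core number in the fertile-condition
network minus its core number in the sterile-condition network; large negative
values flag genes that sit in a dense co-expression core only in the sterile
gonad, large positive values the reverse. Genes absent from one condition's
graph are scored degree 0 / core 0 there rather than dropped.
"""

from __future__ import annotations

from importlib import resources

import networkx as nx
import pandas as pd

__all__ = [
    "degree",
    "core_number",
    "condition_stats",
    "dif_kcore",
    "load_hub_gene_table",
]


def degree(graph: nx.Graph) -> dict[str, int]:
    """Number of incident edges per node (isolated nodes score 0)."""
    return {node: int(d) for node, d in graph.degree()}


def core_number(graph: nx.Graph) -> dict[str, int]:
    """Core number per node by the linear-time bucket-peeling algorithm.

    The core number of a node is the largest k such that the node survives
    iterative deletion of all nodes of degree < k; equivalently the largest
    k for which it belongs to the k-core (maximal subgraph of minimum
    degree k).
    """
    if any(graph.has_edge(n, n) for n in graph):
        raise ValueError("self-loops are not allowed in a co-expression graph")
    degrees = {node: graph.degree(node) for node in graph}
    if not degrees:
        return {}
    max_deg = max(degrees.values())
    # bucket-sort nodes by degree into one flat array with per-degree offsets
    buckets: list[list] = [[] for _ in range(max_deg + 1)]
    for node, d in degrees.items():
        buckets[d].append(node)
    start = [0] * (max_deg + 1)
    for d in range(max_deg):
        start[d + 1] = start[d] + len(buckets[d])
    pos = {}
    flat = [None] * len(degrees)
    idx = 0
    for d in range(max_deg + 1):
        for node in buckets[d]:
            flat[idx] = node
            pos[node] = idx
            idx += 1

    core = dict(degrees)
    for i in range(len(flat)):
        v = flat[i]
        for u in graph.neighbors(v):
            if core[u] > core[v]:
                # move u one bucket down: swap with first node of its bucket
                du, pu = core[u], pos[u]
                pw = start[du]
                w = flat[pw]
                if u is not w:
                    flat[pu], flat[pw] = w, u
                    pos[u], pos[w] = pw, pu
                start[du] += 1
                core[u] -= 1
    return {node: int(k) for node, k in core.items()}


def condition_stats(graph: nx.Graph) -> pd.DataFrame:
    """Per-gene degree and core number for one condition's graph."""
    deg = degree(graph)
    core = core_number(graph)
    return pd.DataFrame(
        {"degree": pd.Series(deg), "kcore": pd.Series(core)}
    ).rename_axis("gene")


def dif_kcore(
    stats_f: pd.DataFrame,
    stats_s: pd.DataFrame,
    de_directions=None,
) -> pd.DataFrame:
    """Differential-core hub table across the fertile and sterile networks.

    Takes the per-condition (degree, kcore) frames; genes present in only one
    frame get (0, 0) in the other. dif_kcore = kcore_f - kcore_s. Rows are
    sorted by ascending dif_kcore, then descending sterile degree, then gene
    id, so the genes most specific to the sterile core rank first.
    """
    for name, frame in (("fertile", stats_f), ("sterile", stats_s)):
        if frame.index.has_duplicates:
            raise ValueError(f"duplicate gene rows in {name} table")
    genes = stats_f.index.union(stats_s.index)
    f = stats_f.reindex(genes).fillna(0).astype(int)
    s = stats_s.reindex(genes).fillna(0).astype(int)
    table = pd.DataFrame(
        {
            "degree_f": f["degree"],
            "kcore_f": f["kcore"],
            "degree_s": s["degree"],
            "kcore_s": s["kcore"],
        },
        index=genes,
    ).rename_axis("gene")
    table["dif_kcore"] = table["kcore_f"] - table["kcore_s"]
    if de_directions is not None:
        table["direction"] = pd.Series(dict(de_directions)).reindex(genes)
    table = table.sort_values(
        ["dif_kcore", "degree_s", "gene"],
        ascending=[True, False, True],
        kind="mergesort",
        key=lambda col: col if col.name != "gene" else col.astype(str),
    )
    return table


def load_hub_gene_table() -> pd.DataFrame:
    """The published 18-gene hub table from the flounder gonad study.

    Per-condition degree and core numbers for the 18 genes the original
    co-expression analysis highlighted, with the published dif-k-core column
    (`dif_kcore_published`) and the reported expression direction in sterile
    relative to fertile gonads. One published row (CXCR3) is internally
    inconsistent with its own core numbers; the recomputed statistic is the
    authoritative one.
    """
    ref = resources.files("difcore.datasets") / "dh_flounder_hub_genes.tsv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", index_col="gene")
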