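"""Readers and writers for the pipeline's plain-text formats.

All tables are single-header-row, tab-delimited UTF-8. Floats serialize at 6
significant digits (percent columns are pre-rounded to 2 decimals upstream).
FASTQ input and output is gzip-transparent by file suffix.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from .de import CountMatrix
from .enrichment import AnnotationMap, GeneSet, VALID_CATEGORIES

__all__ = [
    "read_fastq",
    "write_fastq",
    "read_counts",
    "write_counts",
    "read_conditions",
    "write_conditions",
    "read_count_matrix",
    "read_gmt",
    "write_gmt",
    "read_ct_table",
    "write_table",
    "read_gene_list",
    "graph_to_edge_table",
]

FLOAT_FORMAT = "%.6g"


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path) -> Iterator[tuple[str, str, str]]:
    """Yield (title, sequence, quality) from a 4-line FASTQ file.

    Raises a ValueError naming the (0-based) record index on malformed
    records: missing lines, bad separators, or seq/qual length mismatch.
    """
    with _open_text(path) as handle:
        record = 0
        while True:
            header = handle.readline()
            if not header:
                return
            header = header.rstrip("\n")
            if not header.startswith("@"):
                raise ValueError(f"record {record}: header does not start with '@'")
            seq = handle.readline().rstrip("\n")
            plus = handle.readline().rstrip("\n")
            qual = handle.readline().rstrip("\n")
            if not plus.startswith("+"):
                raise ValueError(f"record {record}: separator line does not start with '+'")
            if len(seq) != len(qual):
                raise ValueError(
                    f"record {record}: sequence length {len(seq)} != quality length {len(qual)}"
                )
            yield header[1:], seq, qual
            record += 1


def write_fastq(path, records: Iterable[tuple[str, str, str]]) -> None:
    with _open_text(path, "wt") as handle:
        for title, seq, qual in records:
            handle.write(f"@{title}\n{seq}\n+\n{qual}\n")


def read_counts(path) -> pd.DataFrame:
    """Gene x sample integer count TSV; validates shape, dtypes and signs."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate gene id {dup!r} in {path}")
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        bad = df.columns[[not np.issubdtype(t, np.number) for t in df.dtypes]][0]
        raise ValueError(f"non-numeric counts in column {bad!r} of {path}")
    if not np.allclose(arr, np.round(arr)):
        g, s = np.argwhere(arr != np.round(arr))[0]
        raise ValueError(f"non-integer count at line {g + 2} ({df.index[g]!r}) in {path}")
    if (arr < 0).any():
        g = int(np.argwhere((arr < 0).any(axis=1))[0][0])
        raise ValueError(f"negative count at line {g + 2} ({df.index[g]!r}) in {path}")
    return df.astype(np.int64)


def write_counts(path, counts: pd.DataFrame) -> None:
    counts.rename_axis("gene").to_csv(path, sep="\t")


def read_conditions(path) -> pd.Series:
    """Two-column TSV (sample, condition) -> Series mapping sample to label."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError(f"condition table {path} needs columns (sample, condition)")
    sample_col, cond_col = df.columns[:2]
    if df[sample_col].duplicated().any():
        raise ValueError(f"duplicate sample id in {path}")
    return pd.Series(df[cond_col].to_numpy(), index=df[sample_col], name="condition")


def write_conditions(path, conditions: pd.Series) -> None:
    conditions.rename_axis("sample").rename("condition").to_csv(path, sep="\t")


def read_count_matrix(counts_path, conditions_path) -> CountMatrix:
    return CountMatrix(read_counts(counts_path), read_conditions(conditions_path))


def read_gmt(path, category_map=None, default_category: str = "pathway") -> AnnotationMap:
    """GMT reader: term, description, then tab-separated gene ids per line.

    Categories are looked up per term in ``category_map`` when given; a
    description field equal to a known category name (the writer's
    convention) is also honoured.
    """
    terms: dict[str, GeneSet] = {}
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs term, description, >=1 gene")
            term_id, description = fields[0], fields[1]
            if term_id in terms:
                raise ValueError(f"{path}:{lineno}: duplicate term {term_id!r}")
            if category_map and term_id in category_map:
                category = category_map[term_id]
            elif description.split("|")[0] in VALID_CATEGORIES:
                category = description.split("|")[0]
            else:
                category = default_category
            terms[term_id] = GeneSet(
                term_id=term_id,
                category=category,
                genes=frozenset(fields[2:]),
                description=description,
            )
    return AnnotationMap(terms)


def write_gmt(path, annotation: AnnotationMap) -> None:
    """Writes category|description in the description slot so categories round-trip."""
    with _open_text(path, "wt") as handle:
        for gs in annotation:
            desc = f"{gs.category}|{gs.description}"
            genes = "\t".join(sorted(gs.genes))
            handle.write(f"{gs.term_id}\t{desc}\t{genes}\n")


def read_ct_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    needed = {"gene", "condition", "replicate", "target_ct", "reference_ct"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"Ct table {path} lacks columns: {sorted(missing)}")
    return df


def write_table(path, table: pd.DataFrame, index: bool = True) -> None:
    """Standard TSV writer: header row, floats at 6 significant digits."""
    table.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)


def read_gene_list(path) -> list[str]:
    """One gene id per line; blank lines and '#' comments ignored."""
    genes: list[str] = []
    with _open_text(path) as handle:
        for line in handle:
            line = line.strip()
            if line and not line.startswith("#"):
                genes.append(line)
    return genes


def graph_to_edge_table(graph) -> pd.DataFrame:
    """Edge-list frame (gene_a, gene_b, r, q) with lexically ordered endpoints."""
    rows = []
    for a, b, data in graph.edges(data=True):
        a, b = sorted((str(a), str(b)))
        rows.append({"gene_a": a, "gene_b": b, "r": data.get("r"), "q": data.get("q")})
    table = pd.DataFrame(rows, columns=["gene_a", "gene_b", "r", "q"])
    return table.sort_values(["gene_a", "gene_b"]).reset_index(drop=True)
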