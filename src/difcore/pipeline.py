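"""End-to-end orchestration: counts -> DE -> enrichment -> networks -> hubs -> qPCR.

Every stage persists its table under the output directory and the run ends
with a manifest recording versions, seed, thresholds, per-stage row counts
and SHA-256 checksums, so a rerun with the same configuration is verifiably
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from . import coexpression, enrichment, io, network, qpcr
from .de import CountMatrix, run_de, filter_de, size_factors

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Paths and thresholds for one pipeline run."""

    counts: str
    conditions: str
    annotation: str | None = None
    gene_list: str | None = None
    ct_table: str | None = None
    outdir: str = "difcore_out"
    fc_hi: float = 2.0
    fc_lo: float = 0.5
    max_fdr: float = 0.05
    go_p_cutoff: float = 0.01
    pathway_fdr_cutoff: float = 0.05
    network_mode: str = "abs_r"
    network_cutoff: float = 0.95
    max_network_genes: int = 72
    seed: int = 1

    def validate(self) -> None:
        if not 0 < self.max_fdr < 1:
            raise ValueError("max_fdr must lie in (0, 1)")
        if self.fc_hi <= 1 or not 0 < self.fc_lo < 1:
            raise ValueError("fold-change cutoffs must bracket 1")
        if self.network_mode not in {"abs_r", "fdr"}:
            raise ValueError("network_mode must be 'abs_r' or 'fdr'")


class PipelineError(RuntimeError):
    """Raised when a stage fails; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all configured stages in order and return the manifest dict.

    Stages whose inputs are not configured (annotation, qPCR) are skipped and
    marked so in the manifest. On failure a ``FAILED`` marker naming the
    stage is written next to whatever partial outputs exist.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "difcore",
        "version": __version__,
        "seed": config.seed,
        "thresholds": {
            k: v
            for k, v in asdict(config).items()
            if k not in {"counts", "conditions", "annotation", "gene_list", "ct_table", "outdir"}
        },
        "stages": {},
        "outputs": {},
    }
    stage = "load"
    try:
        cm = io.read_count_matrix(config.counts, config.conditions)
        manifest["stages"]["load"] = {"genes": int(cm.counts.shape[0]), "samples": int(cm.counts.shape[1])}

        stage = "de"
        results = run_de(cm, fc_hi=config.fc_hi, fc_lo=config.fc_lo, max_fdr=config.max_fdr)
        de_table, summary = filter_de(results, config.fc_hi, config.fc_lo, config.max_fdr)
        io.write_table(outdir / "de_results.tsv", results.rename_axis("gene"))
        io.write_table(outdir / "de_genes.tsv", de_table.rename_axis("gene"))
        manifest["stages"]["de"] = {
            "up": summary.up,
            "down": summary.down,
            "total": summary.total,
        }

        stage = "enrichment"
        if config.annotation:
            annot = io.read_gmt(config.annotation)
            universe = sorted(annot.annotated_genes & set(cm.counts.index))
            tables = enrichment.split_by_direction(de_table, annot, universe)
            for direction, table in tables.items():
                io.write_table(outdir / f"enrichment_{direction}.tsv", table, index=False)
            manifest["stages"]["enrichment"] = {
                d: int(len(t)) for d, t in tables.items()
            }
        else:
            manifest["stages"]["enrichment"] = "skipped (no annotation)"

        stage = "network"
        if config.gene_list:
            selected = io.read_gene_list(config.gene_list)
        else:
            # study-scale default: most extreme DE genes by |log2fc|
            ranked = de_table["log2fc"].abs().sort_values(ascending=False)
            selected = list(ranked.index[: config.max_network_genes])
        factors = size_factors(cm.counts)
        graphs = {}
        for cond in ("F", "S"):
            graphs[cond] = coexpression.condition_network(
                cm,
                selected,
                cond,
                factors=factors,
                mode=config.network_mode,
                cutoff=config.network_cutoff,
            )
            io.write_table(
                outdir / f"edges_{cond}.tsv", io.graph_to_edge_table(graphs[cond]), index=False
            )
        manifest["stages"]["network"] = {
            cond: {"nodes": g.number_of_nodes(), "edges": g.number_of_edges()}
            for cond, g in graphs.items()
        }

        stage = "kcore"
        hub_table = network.dif_kcore(
            network.condition_stats(graphs["F"]),
            network.condition_stats(graphs["S"]),
            de_directions=results["direction"],
        )
        io.write_table(outdir / "kcore_table.tsv", hub_table)
        manifest["stages"]["kcore"] = {"genes": int(len(hub_table))}

        stage = "qpcr"
        if config.ct_table:
            ct = io.read_ct_table(config.ct_table)
            records = qpcr.delta_delta_ct(ct, calibrator_condition="F")
            table, summary_q = qpcr.concordance(records, results)
            io.write_table(outdir / "qpcr_table.tsv", records.join(table[["rnaseq_log2fc", "sign_agree"]]))
            manifest["stages"]["qpcr"] = summary_q
        else:
            manifest["stages"]["qpcr"] = "skipped (no Ct table)"
    except Exception as exc:  # noqa: BLE001 - stage name must reach the user
        (outdir / "FAILED").write_text(f"stage {stage!r} failed: {exc}\n")
        raise PipelineError(stage, exc) from exc

    for path in sorted(outdir.glob("*.tsv")):
        manifest["outputs"][path.name] = {
            "sha256": _sha256(path),
            "rows": sum(1 for _ in open(path)) - 1,
        }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
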