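"""Synthetic inputs with the statistical structure the pipeline assumes.

Generates every input the analysis consumes so all stages can be exercised
offline: NB-distributed counts for a 2 x 3 design with planted DE genes and
condition-specific correlated gene blocks, GMT-style annotations with planted
enriched terms, FASTQ reads with planted quality defects, and qPCR Ct tables
consistent with chosen fold changes.

Correlation between genes is injected through a latent Gaussian copula: a
multivariate normal with an equicorrelated block structure is drawn per
condition and quantile-mapped onto the NB margins, so the marginal count law
of each gene is unaffected by its block membership.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .de import CountMatrix
from .enrichment import AnnotationMap, GeneSet

__all__ = [
    "BlockSpec",
    "SimulationConfig",
    "SyntheticTruth",
    "generate_counts",
    "generate_annotations",
    "generate_fastq",
    "generate_qpcr",
]

CATEGORIES = ("BP", "MF", "CC", "pathway")


@dataclass(frozen=True)
class BlockSpec:
    """A planted co-expression block.

    size genes share a latent equicorrelation ``rho`` in ``condition``
    ("F", "S", or "both"); outside that condition they are independent,
    which is what creates differential k-cores downstream.
    """

    size: int
    rho: float
    condition: str = "S"

    def __post_init__(self) -> None:
        if self.size < 2:
            raise ValueError("block size must be >= 2")
        if not -1 < self.rho < 1:
            raise ValueError("rho must lie in (-1, 1)")
        if self.condition not in {"F", "S", "both"}:
            raise ValueError("block condition must be 'F', 'S' or 'both'")


@dataclass
class SimulationConfig:
    """Study-scale defaults: 2 conditions x 3 replicates, NB dispersion 0.1.

    ``lfc_values`` are assigned cyclically to the planted DE genes;
    ``base_mean_range`` is sampled log-uniformly; ``size_factor_range``
    controls library-size variation between samples (default none).
    """

    n_genes: int = 2000
    n_per_group: int = 3
    de_fraction: float = 0.1
    lfc_values: tuple[float, ...] = (2.0, -2.0)
    dispersion: float = 0.1
    base_mean_range: tuple[float, float] = (20.0, 500.0)
    block_spec: tuple[BlockSpec, ...] = ()
    n_terms: int = 50
    enriched_term_fraction: float = 0.1
    size_factor_range: tuple[float, float] = (1.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_per_group <= 0:
            raise ValueError("n_genes and n_per_group must be positive")
        if not 0 <= self.de_fraction <= 1:
            raise ValueError("de_fraction must lie in [0, 1]")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.base_mean_range[0] <= 0 or self.base_mean_range[1] < self.base_mean_range[0]:
            raise ValueError("invalid base_mean_range")
        if self.n_terms <= 0:
            raise ValueError("n_terms must be positive")
        if not 0 <= self.enriched_term_fraction <= 1:
            raise ValueError("enriched_term_fraction must lie in [0, 1]")
        self.block_spec = tuple(self.block_spec)
        if sum(b.size for b in self.block_spec) > self.n_genes:
            raise ValueError("block sizes exceed n_genes")

    @property
    def n_de(self) -> int:
        return int(round(self.de_fraction * self.n_genes))


@dataclass
class SyntheticTruth:
    """Ground truth of a simulation run."""

    de_genes: dict[str, float] = field(default_factory=dict)
    module_assignment: dict[str, int] = field(default_factory=dict)
    enriched_terms: set[str] = field(default_factory=set)


def _nb_ppf(u: np.ndarray, mean: np.ndarray, alpha: float) -> np.ndarray:
    """Quantile map uniforms onto NB(mean, var = mean + alpha mean^2)."""
    if alpha == 0:
        return stats.poisson.ppf(u, mean).astype(np.int64)
    r = 1.0 / alpha
    p = r / (r + mean)
    return stats.nbinom.ppf(u, r, p).astype(np.int64)


def _block_latent(rng: np.random.Generator, size: int, rho: float, n_cols: int) -> np.ndarray:
    """Draw an equicorrelated latent block; rejects non-PD correlations."""
    corr = np.full((size, size), rho)
    np.fill_diagonal(corr, 1.0)
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"block correlation rho={rho} not positive definite for size {size}") from exc
    return chol @ rng.standard_normal((size, n_cols))


def generate_counts(config: SimulationConfig) -> tuple[CountMatrix, SyntheticTruth]:
    """Draw the planted count matrix and its ground truth.

    Group-S means of DE genes are the fertile baseline scaled by 2**lfc, so
    the downstream fold change (sterile/fertile) recovers the planted value.
    Identical config and seed reproduce the matrix exactly.
    """
    rng = np.random.default_rng(config.seed)
    n, k = config.n_genes, config.n_per_group
    genes = [f"g{i:05d}" for i in range(n)]
    samples = [f"F{j + 1}" for j in range(k)] + [f"S{j + 1}" for j in range(k)]
    conditions = pd.Series(["F"] * k + ["S"] * k, index=samples)

    lo, hi = config.base_mean_range
    base_mean = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))

    lo_sf, hi_sf = config.size_factor_range
    sf = np.exp(rng.uniform(np.log(lo_sf), np.log(hi_sf), size=2 * k)) if hi_sf > lo_sf else np.full(2 * k, lo_sf)

    truth = SyntheticTruth()
    lfc = np.zeros(n)
    if config.n_de:
        de_idx = np.sort(rng.choice(n, size=config.n_de, replace=False))
        for rank, gi in enumerate(de_idx):
            lfc[gi] = config.lfc_values[rank % len(config.lfc_values)]
            truth.de_genes[genes[gi]] = lfc[gi]

    # non-overlapping block members drawn from a random permutation
    perm = rng.permutation(n)
    cursor = 0
    block_members: list[np.ndarray] = []
    for bid, block in enumerate(config.block_spec):
        members = np.sort(perm[cursor : cursor + block.size])
        cursor += block.size
        block_members.append(members)
        for gi in members:
            truth.module_assignment[genes[gi]] = bid

    counts = np.empty((n, 2 * k), dtype=np.int64)
    for cond, cols in (("F", slice(0, k)), ("S", slice(k, 2 * k))):
        z = rng.standard_normal((n, k))
        for block, members in zip(config.block_spec, block_members):
            if block.condition in (cond, "both"):
                z[members, :] = _block_latent(rng, block.size, block.rho, k)
        u = np.clip(stats.norm.cdf(z), 1e-12, 1 - 1e-12)
        mean = base_mean * (2.0**lfc if cond == "S" else 1.0)
        mean_js = mean[:, None] * sf[None, cols]
        counts[:, cols] = _nb_ppf(u, mean_js, config.dispersion)

    cm = CountMatrix(pd.DataFrame(counts, index=genes, columns=samples), conditions)
    return cm, truth


def generate_annotations(
    genes,
    truth: SyntheticTruth,
    config: SimulationConfig,
    de_weight: float = 20.0,
) -> AnnotationMap:
    """Term -> gene-set annotations with a planted enriched fraction.

    Enriched terms sample their members with weight ``de_weight`` on the true
    DE genes (uniform weight 1 elsewhere); the remaining terms sample
    uniformly. Updates ``truth.enriched_terms`` in place.
    """
    genes = list(genes)
    if not genes:
        raise ValueError("gene list must be non-empty")
    rng = np.random.default_rng([config.seed, 1])
    n_terms = config.n_terms
    n_enriched = int(round(config.enriched_term_fraction * n_terms))
    enriched_ids = set(rng.choice(n_terms, size=n_enriched, replace=False).tolist())

    weights = np.ones(len(genes))
    de_set = set(truth.de_genes)
    for i, g in enumerate(genes):
        if g in de_set:
            weights[i] = de_weight
    weights = weights / weights.sum()

    terms: dict[str, GeneSet] = {}
    max_size = max(2, min(40, len(genes)))
    for t in range(n_terms):
        size = int(rng.integers(min(10, max_size), max_size + 1))
        if t in enriched_ids and de_set:
            members = rng.choice(genes, size=size, replace=False, p=weights)
        else:
            members = rng.choice(genes, size=size, replace=False)
        term_id = f"T{t:04d}"
        terms[term_id] = GeneSet(
            term_id=term_id,
            category=CATEGORIES[t % len(CATEGORIES)],
            genes=frozenset(members.tolist()),
            description=f"synthetic term {t}",
        )
        if t in enriched_ids:
            truth.enriched_terms.add(term_id)
    return AnnotationMap(terms)


def generate_fastq(
    n_reads: int,
    read_length: int,
    frac_high_n: float,
    frac_low_quality: float,
    seed: int = 0,
) -> tuple[list[tuple[str, str, str]], list[str]]:
    """Reads with planted filter violations, Phred+33, qualities in [2, 41].

    Returns ``(records, labels)`` where each record is (title, sequence,
    quality string) and each label is one of ``ok``, ``high_n`` (>5% N
    bases) or ``low_quality`` (>30% bases below Q20). ``ok`` reads violate
    neither rule, including at the exact boundaries.
    """
    if read_length <= 0:
        raise ValueError("read_length must be positive")
    if n_reads < 0:
        raise ValueError("n_reads must be >= 0")
    for frac in (frac_high_n, frac_low_quality):
        if not 0 <= frac <= 1:
            raise ValueError("fractions must lie in [0, 1]")
    if frac_high_n + frac_low_quality > 1:
        raise ValueError("defect fractions must sum to <= 1")

    rng = np.random.default_rng(seed)
    n_high = int(round(frac_high_n * n_reads))
    n_low = int(round(frac_low_quality * n_reads))
    labels = ["high_n"] * n_high + ["low_quality"] * n_low + ["ok"] * (n_reads - n_high - n_low)
    labels = [labels[i] for i in rng.permutation(n_reads)]

    max_n_ok = int(np.floor(0.05 * read_length))       # N count still retained
    max_lowq_ok = int(np.floor(0.30 * read_length))    # low-Q count still retained
    bases = np.array(list("ACGT"))
    records = []
    for i, label in enumerate(labels):
        seq = rng.choice(bases, size=read_length)
        qual = rng.integers(25, 42, size=read_length)
        if label == "high_n":
            n_n = int(rng.integers(max_n_ok + 1, min(read_length, 2 * max_n_ok + 5) + 1))
            pos = rng.choice(read_length, size=n_n, replace=False)
            seq[pos] = "N"
        elif label == "low_quality":
            n_lq = int(rng.integers(max_lowq_ok + 1, read_length + 1))
            pos = rng.choice(read_length, size=n_lq, replace=False)
            qual[pos] = rng.integers(2, 20, size=n_lq)
        else:
            # occasionally sit exactly on the retention boundary
            n_lq = int(rng.integers(0, max_lowq_ok + 1))
            if n_lq:
                pos = rng.choice(read_length, size=n_lq, replace=False)
                qual[pos] = rng.integers(2, 20, size=n_lq)
        records.append(
            (f"read_{i:06d}", "".join(seq), "".join(chr(q + 33) for q in qual))
        )
    return records, labels


def generate_qpcr(
    genes,
    true_log2fc,
    ct_ref_level: float = 16.0,
    noise_sd: float = 0.2,
    n_replicates: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Ct table whose expected 2^-ddCt equals 2^true_log2fc per gene.

    The target-gene Ct in the sterile condition is the fertile baseline minus
    the planted log2 fold change (one PCR cycle per doubling); the reference
    gene sits at ``ct_ref_level`` in both conditions. Gaussian noise of sd
    ``noise_sd`` is added independently to every measured Ct.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    genes = list(genes)
    lfc = dict(zip(genes, np.broadcast_to(np.asarray(true_log2fc, dtype=float), (len(genes),))))
    rng = np.random.default_rng(seed)
    rows = []
    for gene in genes:
        base_ct = rng.uniform(22.0, 30.0)
        for cond in ("F", "S"):
            target_mean = base_ct - (lfc[gene] if cond == "S" else 0.0)
            for rep in range(1, n_replicates + 1):
                rows.append(
                    {
                        "gene": gene,
                        "sample": f"{cond}{rep}",
                        "condition": cond,
                        "replicate": rep,
                        "target_ct": target_mean + rng.normal(0.0, noise_sd),
                        "reference_ct": ct_ref_level + rng.normal(0.0, noise_sd),
                    }
                )
    return pd.DataFrame(rows)
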