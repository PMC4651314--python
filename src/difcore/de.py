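"""Negative-binomial differential expression for a two-condition design.

The workflow mirrors the classic count-based DE recipe for small designs:
median-of-ratios size factors, method-of-moments pooled dispersion, and a
conditioned NB exact test per gene, followed by Benjamini-Hochberg FDR and a
fold-change / FDR filter.  Fold changes are oriented sterile over fertile
("S" over "F"), so ``direction == "up"`` means higher expression in the
sterile condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CountMatrix",
    "DESummary",
    "size_factors",
    "estimate_dispersion",
    "nb_test",
    "bh_fdr",
    "classify_directions",
    "filter_de",
    "run_de",
]

#: fold-change pseudocount added to both normalized group means
PSEUDOCOUNT = 0.5

#: per-gene total above which the exact test switches to a normal approximation
BIG_TOTAL = 10_000


@dataclass
class CountMatrix:
    """Integer gene x sample count matrix with a sample -> condition map.

    Parameters
    ----------
    counts
        DataFrame of non-negative integers, genes as rows, samples as columns.
    conditions
        Series mapping each sample id to a condition label ("F" fertile,
        "S" sterile in the study design); every condition must have at least
        two samples.
    """

    counts: pd.DataFrame
    conditions: pd.Series

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate gene ids in count matrix")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate sample ids in count matrix")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
            arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")
        self.conditions = self.conditions.reindex(self.counts.columns)
        if self.conditions.isna().any():
            missing = list(self.counts.columns[self.conditions.isna()])
            raise ValueError(f"samples without condition label: {missing}")
        sizes = self.conditions.value_counts()
        if (sizes < 2).any():
            raise ValueError("each condition needs at least 2 samples")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def samples_of(self, condition: str) -> list[str]:
        return list(self.conditions.index[self.conditions == condition])


@dataclass(frozen=True)
class DESummary:
    """Up/down/total accounting of a DE gene list."""

    up: int
    down: int

    @property
    def total(self) -> int:
        return self.up + self.down


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalization factors, one per sample.

    For every gene with a strictly positive geometric mean across samples,
    form the ratio count / geometric mean; the size factor of a sample is the
    median of these ratios.
    """
    arr = counts.to_numpy(dtype=float)
    if arr.sum() == 0:
        raise ValueError("all-zero count matrix")
    with np.errstate(divide="ignore"):
        log_arr = np.log(arr)
    log_geomean = log_arr.mean(axis=1)
    usable = np.isfinite(log_geomean)
    if not usable.any():
        raise ValueError("no gene has a non-zero geometric mean; cannot normalize")
    log_ratios = log_arr[usable] - log_geomean[usable, None]
    factors = np.exp(np.median(log_ratios, axis=0))
    if not (factors > 0).all():
        raise ValueError("non-positive size factor")
    return pd.Series(factors, index=counts.columns, name="size_factor")


def estimate_dispersion(
    counts: pd.DataFrame,
    factors: pd.Series,
    conditions: pd.Series,
) -> pd.Series:
    """Method-of-moments NB dispersion per gene, pooled within conditions.

    alpha_g = max(0, (pooled within-group variance - mean) / mean**2) on
    normalized counts; genes with zero mean get alpha = 0.
    """
    factors = factors.reindex(counts.columns)
    q = counts.to_numpy(dtype=float) / factors.to_numpy()[None, :]
    mu = q.mean(axis=1)
    labels = conditions.reindex(counts.columns).to_numpy()
    groups = [labels == g for g in np.unique(labels)]
    n_total = q.shape[1]
    ss = np.zeros(q.shape[0])
    for mask in groups:
        sub = q[:, mask]
        ss += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    pooled_var = ss / (n_total - len(groups))
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (pooled_var - mu) / mu**2
    alpha = np.where(mu > 0, np.maximum(alpha, 0.0), 0.0)
    return pd.Series(alpha, index=counts.index, name="dispersion")


def _nb_pmf(x: np.ndarray, mean: float, var: float) -> np.ndarray:
    """NB pmf parameterized by mean/variance; Poisson when var <= mean."""
    if var <= mean * (1 + 1e-12):
        return stats.poisson.pmf(x, mean)
    r = mean * mean / (var - mean)
    p = r / (r + mean)
    return stats.nbinom.pmf(x, r, p)


def _exact_p(k_a: int, total: int, m_a: float, v_a: float, m_b: float, v_b: float) -> float:
    """Conditioned two-sided exact p: enumerate splits of ``total`` between the
    pooled group counts and sum the probabilities of splits no more probable
    than the observed one."""
    x = np.arange(total + 1)
    joint = _nb_pmf(x, m_a, v_a) * _nb_pmf(total - x, m_b, v_b)
    denom = joint.sum()
    if denom <= 0 or not np.isfinite(denom):
        return 1.0
    p_obs = joint[k_a]
    p = joint[joint <= p_obs * (1 + 1e-10)].sum() / denom
    return float(min(p, 1.0))


def _approx_p(k_a: float, total: float, m_a: float, v_a: float, m_b: float, v_b: float) -> float:
    """Normal approximation to the conditioned split for very large totals."""
    cond_mean = m_a + v_a / (v_a + v_b) * (total - m_a - m_b)
    cond_var = v_a * v_b / (v_a + v_b)
    if cond_var <= 0:
        return 1.0
    z = abs(k_a - cond_mean) / np.sqrt(cond_var)
    return float(min(1.0, 2.0 * stats.norm.sf(z)))


def nb_test(
    counts: pd.DataFrame,
    factors: pd.Series,
    dispersions: pd.Series,
    conditions: pd.Series,
    big_total: int = BIG_TOTAL,
) -> pd.DataFrame:
    """Per-gene two-sided NB exact test of S vs F plus normalized fold change.

    Conditions on each gene's observed total count and enumerates its splits
    between the pooled F and S counts under NB laws whose means scale with the
    group size-factor sums; genes whose total exceeds ``big_total`` use a
    normal approximation instead of enumeration.

    Returns a frame indexed by gene with columns ``mean_f``, ``mean_s``,
    ``fold_change`` (sterile/fertile, pseudocount 0.5), ``log2fc`` and
    ``p_value``.
    """
    factors = factors.reindex(counts.columns)
    conditions = conditions.reindex(counts.columns)
    f_mask = (conditions == "F").to_numpy()
    s_mask = (conditions == "S").to_numpy()
    arr = counts.to_numpy(dtype=np.int64)
    fac = factors.to_numpy(dtype=float)
    alpha = dispersions.reindex(counts.index).to_numpy(dtype=float)

    q = arr / fac[None, :]
    mean_f = q[:, f_mask].mean(axis=1)
    mean_s = q[:, s_mask].mean(axis=1)
    mu = q.mean(axis=1)

    s_f, s_s = fac[f_mask].sum(), fac[s_mask].sum()
    sq_f, sq_s = (fac[f_mask] ** 2).sum(), (fac[s_mask] ** 2).sum()
    k_f = arr[:, f_mask].sum(axis=1)
    k_s = arr[:, s_mask].sum(axis=1)
    totals = k_f + k_s

    pvals = np.ones(arr.shape[0])
    for i in range(arr.shape[0]):
        if totals[i] == 0:
            continue
        m_a = mu[i] * s_f
        m_b = mu[i] * s_s
        v_a = mu[i] * s_f + alpha[i] * mu[i] ** 2 * sq_f
        v_b = mu[i] * s_s + alpha[i] * mu[i] ** 2 * sq_s
        if totals[i] <= big_total:
            pvals[i] = _exact_p(int(k_f[i]), int(totals[i]), m_a, v_a, m_b, v_b)
        else:
            pvals[i] = _approx_p(k_f[i], totals[i], m_a, v_a, m_b, v_b)

    fc = (mean_s + PSEUDOCOUNT) / (mean_f + PSEUDOCOUNT)
    return pd.DataFrame(
        {
            "mean_f": mean_f,
            "mean_s": mean_s,
            "fold_change": fc,
            "log2fc": np.log2(fc),
            "p_value": pvals,
        },
        index=counts.index,
    )


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def classify_directions(
    results: pd.DataFrame,
    fc_hi: float = 2.0,
    fc_lo: float = 0.5,
    max_fdr: float = 0.05,
) -> pd.Series:
    """Label genes up / down / ns with strict fold-change inequalities."""
    fc = results["fold_change"]
    sig = results["q_value"] < max_fdr
    direction = pd.Series("ns", index=results.index, name="direction")
    direction[sig & (fc > fc_hi)] = "up"
    direction[sig & (fc < fc_lo)] = "down"
    return direction


def filter_de(
    results: pd.DataFrame,
    fc_hi: float = 2.0,
    fc_lo: float = 0.5,
    max_fdr: float = 0.05,
) -> tuple[pd.DataFrame, DESummary]:
    """Apply the DE filter (fold change > fc_hi or < fc_lo, q < max_fdr).

    Returns the selected rows with a ``direction`` column plus an up/down
    accounting whose total is the partition of the selected set.
    """
    direction = classify_directions(results, fc_hi, fc_lo, max_fdr)
    table = results.copy()
    table["direction"] = direction
    selected = table[direction != "ns"].copy()
    summary = DESummary(
        up=int((selected["direction"] == "up").sum()),
        down=int((selected["direction"] == "down").sum()),
    )
    return selected, summary


def run_de(
    cm: CountMatrix,
    fc_hi: float = 2.0,
    fc_lo: float = 0.5,
    max_fdr: float = 0.05,
    big_total: int = BIG_TOTAL,
) -> pd.DataFrame:
    """Full DE pass: normalization, dispersion, exact test, FDR, direction."""
    factors = size_factors(cm.counts)
    alpha = estimate_dispersion(cm.counts, factors, cm.conditions)
    results = nb_test(cm.counts, factors, alpha, cm.conditions, big_total=big_total)
    results["q_value"] = bh_fdr(results["p_value"].to_numpy())
    results["direction"] = classify_directions(results, fc_hi, fc_lo, max_fdr)
    return results
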