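"""Differential expression: normalization, dispersion, exact test, BH, filter."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from difcore import CountMatrix, bh_fdr, filter_de, run_de
from difcore.de import (
    classify_directions,
    estimate_dispersion,
    nb_test,
    size_factors,
)
from difcore.simulate import SimulationConfig, generate_counts


def _matrix(columns: dict, conditions: list[str]) -> CountMatrix:
    counts = pd.DataFrame(columns)
    counts.index = [f"g{i}" for i in range(len(counts))]
    return CountMatrix(counts, pd.Series(conditions, index=counts.columns))


class TestSizeFactors:
    def test_identical_samples_equal_factors(self):
        counts = pd.DataFrame({"a": [5, 9, 14], "b": [5, 9, 14], "c": [5, 9, 14]})
        f = size_factors(counts)
        assert np.allclose(f, f.iloc[0])

    def test_doubled_sample_gets_double_factor(self):
        counts = pd.DataFrame({"a": [5, 9, 14], "b": [10, 18, 28]})
        f = size_factors(counts)
        assert f["b"] == pytest.approx(2 * f["a"])

    def test_hand_computed_median_of_ratios(self):
        """counts[g, j] = (g+1)*j gives factors j / geomean(1..4)."""
        counts = pd.DataFrame(
            [[(g + 1) * j for j in range(1, 5)] for g in range(5)],
            columns=list("wxyz"),
        )
        f = size_factors(counts)
        geomean = math.exp(np.mean(np.log([1, 2, 3, 4])))
        assert np.allclose(f, np.array([1, 2, 3, 4]) / geomean)

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            size_factors(pd.DataFrame({"a": [0, 0], "b": [0, 0]}))


class TestEstimateDispersion:
    def test_constant_gene_zero_dispersion(self):
        counts = pd.DataFrame({c: [7, 7] for c in ["F1", "F2", "S1", "S2"]})
        cond = pd.Series(["F", "F", "S", "S"], index=counts.columns)
        alpha = estimate_dispersion(counts, pd.Series(1.0, index=counts.columns), cond)
        assert (alpha == 0).all()

    def test_poisson_counts_yield_near_zero_alpha(self):
        config = SimulationConfig(
            n_genes=10000, de_fraction=0.0, dispersion=0.0,
            base_mean_range=(100.0, 100.0), seed=1,
        )
        cm, _ = generate_counts(config)
        alpha = estimate_dispersion(cm.counts, size_factors(cm.counts), cm.conditions)
        assert np.median(alpha) <= 0.01

    def test_nb_counts_recover_alpha(self):
        """Median moment estimate lands in [0.1, 0.3] for true alpha 0.2."""
        config = SimulationConfig(
            n_genes=10000, de_fraction=0.0, dispersion=0.2,
            base_mean_range=(200.0, 200.0), seed=3,
        )
        cm, _ = generate_counts(config)
        alpha = estimate_dispersion(cm.counts, size_factors(cm.counts), cm.conditions)
        assert 0.1 <= np.median(alpha) <= 0.3


def _single_gene_p(k_f, k_s, alpha=0.0, factors=(1.0,) * 6):
    counts = pd.DataFrame(
        [list(k_f) + list(k_s)],
        columns=["F1", "F2", "F3", "S1", "S2", "S3"],
        index=["g0"],
    )
    cond = pd.Series(["F"] * 3 + ["S"] * 3, index=counts.columns)
    fac = pd.Series(factors, index=counts.columns, dtype=float)
    disp = pd.Series([alpha], index=["g0"])
    return nb_test(counts, fac, disp, cond)


class TestNbTest:
    def test_poisson_split_matches_binomial_enumeration(self):
        """With alpha=0 and unit factors, the conditioned exact test reduces to
        a Binomial(total, 1/2) split; enumerate that tail independently."""
        res = _single_gene_p([1, 1, 0], [10, 10, 10])  # group sums 2 vs 30
        total = 32
        pmf = stats.binom.pmf(np.arange(total + 1), total, 0.5)
        expected = math.fsum(p for p in pmf if p <= pmf[2] * (1 + 1e-10))
        assert res.loc["g0", "p_value"] == pytest.approx(expected, abs=1e-9)

    def test_matches_bruteforce_enumeration_small_totals(self):
        """Exact agreement with an independent per-split enumeration oracle
        (NB pmf per pooled group, normalized over all splits), totals <= 50."""
        rng = np.random.default_rng(17)
        for _ in range(25):
            k_f = rng.integers(0, 9, size=3)
            k_s = rng.integers(0, 9, size=3)
            total = int(k_f.sum() + k_s.sum())
            if total == 0:
                continue
            alpha = float(rng.uniform(0, 0.5))
            res = _single_gene_p(k_f, k_s, alpha=alpha)
            mu = total / 6
            m, v = mu * 3, mu * 3 + alpha * mu**2 * 3
            if v <= m:
                pmf = lambda x: stats.poisson.pmf(x, m)  # noqa: E731
            else:
                r = m * m / (v - m)
                pmf = lambda x: stats.nbinom.pmf(x, r, r / (r + m))  # noqa: E731
            joint = [pmf(a) * pmf(total - a) for a in range(total + 1)]
            p_obs = joint[int(k_f.sum())]
            expected = math.fsum(p for p in joint if p <= p_obs * (1 + 1e-10)) / math.fsum(joint)
            assert res.loc["g0", "p_value"] == pytest.approx(min(expected, 1.0), abs=1e-9)

    def test_identical_profiles_not_significant(self):
        res = _single_gene_p([500, 480, 520], [500, 480, 520], alpha=0.1)
        assert res.loc["g0", "p_value"] >= 0.5

    def test_label_swap_inverts_fold_change_preserves_p(self, null_sim):
        _, cm, _ = null_sim
        sub = CountMatrix(cm.counts.iloc[:50], cm.conditions)
        f = size_factors(sub.counts)
        alpha = estimate_dispersion(sub.counts, f, sub.conditions)
        res = nb_test(sub.counts, f, alpha, sub.conditions)
        swapped = sub.conditions.map({"F": "S", "S": "F"})
        res_sw = nb_test(sub.counts, f, alpha, swapped)
        assert np.allclose(res_sw["fold_change"], 1 / res["fold_change"])
        assert np.allclose(res_sw["p_value"], res["p_value"])

    def test_type_i_error_calibrated_on_null(self, null_sim):
        """Nominal 5% level holds within the 99% binomial CI on a 2,000-gene
        null given the generating dispersion."""
        config, cm, _ = null_sim
        f = size_factors(cm.counts)
        disp = pd.Series(config.dispersion, index=cm.counts.index)
        res = nb_test(cm.counts, f, disp, cm.conditions)
        rate = (res["p_value"] < 0.05).mean()
        half_width = 2.576 * math.sqrt(0.05 * 0.95 / 2000)
        assert abs(rate - 0.05) < half_width

    def test_scaling_a_sample_with_its_factor_is_stable(self):
        """Scaling one sample's counts and factor together leaves normalized
        means unchanged and p-values nearly unchanged (the conditioned split
        is discrete, so equality is approximate)."""
        k_f, k_s = [30, 28, 33], [60, 58, 62]
        base = _single_gene_p(k_f, k_s, alpha=0.05)
        scaled = _single_gene_p([60, 28, 33], k_s, alpha=0.05,
                                factors=(2.0, 1, 1, 1, 1, 1))
        assert scaled.loc["g0", "mean_f"] == pytest.approx(base.loc["g0", "mean_f"])
        assert scaled.loc["g0", "fold_change"] == pytest.approx(base.loc["g0", "fold_change"])
        assert scaled.loc["g0", "p_value"] == pytest.approx(base.loc["g0", "p_value"], rel=0.15)


class TestBhFdr:
    def test_direct_formula(self):
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_fdr([0.2]) == pytest.approx([0.2])

    def test_monotone_and_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(0)
        p = rng.uniform(size=200)
        q = bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        assert np.allclose(q, multipletests(p, method="fdr_bh")[1])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.1, 1.5])


class TestFilterDe:
    def test_boundary_fold_change_excluded(self):
        results = pd.DataFrame(
            {"fold_change": [2.0, 2.01, 0.5, 0.49], "q_value": [0.01] * 4},
            index=list("abcd"),
        )
        direction = classify_directions(results)
        assert direction.tolist() == ["ns", "up", "ns", "down"]

    def test_fdr_boundary_excluded(self):
        results = pd.DataFrame(
            {"fold_change": [4.0, 4.0], "q_value": [0.05, 0.049]}, index=list("ab")
        )
        _, summary = filter_de(results)
        assert summary.total == 1

    def test_partition_up_down_total(self, planted_sim):
        _, cm, _ = planted_sim
        results = run_de(cm)
        selected, summary = filter_de(results)
        assert summary.up + summary.down == summary.total == len(selected)

    def test_planted_de_recovery(self, planted_sim):
        """>=80% of planted |lfc|=2 genes recovered; false-discovery <=10%."""
        _, cm, truth = planted_sim
        results = run_de(cm)
        selected, _ = filter_de(results)
        found = set(selected.index)
        truth_set = set(truth.de_genes)
        assert len(found & truth_set) / len(truth_set) >= 0.80
        assert len(found - truth_set) / max(len(found), 1) <= 0.10

    def test_recovered_directions_match_planted_sign(self, planted_sim):
        _, cm, truth = planted_sim
        selected, _ = filter_de(run_de(cm))
        hits = [g for g in selected.index if g in truth.de_genes]
        signs = {g: ("up" if truth.de_genes[g] > 0 else "down") for g in hits}
        agree = np.mean([selected.loc[g, "direction"] == signs[g] for g in hits])
        assert agree == 1.0


class TestCountMatrix:
    def test_rejects_negative_counts(self):
        counts = pd.DataFrame({"F1": [1], "F2": [1], "S1": [-1], "S2": [1]})
        with pytest.raises(ValueError, match="non-negative"):
            CountMatrix(counts, pd.Series(["F", "F", "S", "S"], index=counts.columns))

    def test_rejects_single_replicate(self):
        counts = pd.DataFrame({"F1": [1], "S1": [2], "S2": [3]})
        with pytest.raises(ValueError, match="at least 2"):
            CountMatrix(counts, pd.Series(["F", "S", "S"], index=counts.columns))
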