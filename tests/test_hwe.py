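"""The core statistic: random-mating update, zero-observation probability,
cross-population combination, Bonferroni threshold."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from lethalscan.hapmap import SNPMeta
from lethalscan.harmonize import GenotypeCounts, MultiPopulationCounts
from lethalscan.hwe import (bonferroni_threshold, combine_populations,
                            log_prob_zero_observed, next_gen_distribution,
                            evaluate_genotype_class)


def simplexes(draw_zero_ok=True):
    return st.lists(st.floats(0, 1), min_size=3, max_size=3).filter(
        lambda v: sum(v) > 1e-6
    ).map(lambda v: [x / sum(v) for x in v])


class TestNextGenDistribution:
    @pytest.mark.parametrize("p,expected", [
        ([0.5, 0.0, 0.5], [0.25, 0.5, 0.25]),   # split-homozygote population
        ([1.0, 0.0, 0.0], [1.0, 0.0, 0.0]),      # fixed major allele
        ([0.25, 0.5, 0.25], [0.25, 0.5, 0.25]),  # HWE fixed point at q=0.5
    ])
    def test_worked_values(self, p, expected):
        assert next_gen_distribution(p) == pytest.approx(expected, abs=1e-15)

    def test_allele_relabel_symmetry(self):
        p = [0.1, 0.3, 0.6]
        fwd = next_gen_distribution(p)
        rev = next_gen_distribution(p[::-1])
        assert fwd[0] == pytest.approx(rev[2]) and fwd[2] == pytest.approx(rev[0])

    @pytest.mark.parametrize("bad", [[0.5, 0.5, 0.5], [-0.1, 0.6, 0.5],
                                     [1.0, 0.0]])
    def test_invalid_simplex_rejected(self, bad):
        with pytest.raises(ValueError):
            next_gen_distribution(bad)

    @settings(max_examples=300, derandomize=True, deadline=None)
    @given(simplexes())
    def test_properties_normalization_idempotence_conservation(self, p):
        out = next_gen_distribution(p)
        assert abs(out.sum() - 1.0) < 1e-12
        again = next_gen_distribution(out)
        assert np.allclose(again, out, atol=1e-12)
        # random mating does not change allele frequencies
        assert out[0] + out[1] / 2 == pytest.approx(p[0] + p[1] / 2, abs=1e-12)


class TestLogProbZeroObserved:
    @pytest.mark.parametrize("p_star,n,expected", [
        (0.0, 174, 0.0),
        (0.3, 0, 0.0),
        (0.5, 2, math.log(0.25)),
        # frozen high-precision value of 174*log1p(-11.6/174)
        (11.6 / 174, 174, -12.004759638729553),
    ])
    def test_closed_forms(self, p_star, n, expected):
        assert log_prob_zero_observed(p_star, n) == pytest.approx(
            expected, abs=1e-12)

    def test_certain_genotype_never_absent(self):
        assert log_prob_zero_observed(1.0, 5) == -math.inf

    @pytest.mark.parametrize("bad", [-0.1, 1.5])
    def test_domain_errors(self, bad):
        with pytest.raises(ValueError):
            log_prob_zero_observed(bad, 10)
        with pytest.raises(ValueError):
            log_prob_zero_observed(0.5, -1)

    def test_matches_binomial_pmf_oracle(self):
        # scipy's binomial pmf at zero successes is the independent route
        for p, n in [(0.01, 50), (0.05, 200), (0.1, 1000), (0.3, 17)]:
            assert math.exp(log_prob_zero_observed(p, n)) == pytest.approx(
                stats.binom.pmf(0, n, p), rel=1e-10)

    def test_monte_carlo_oracle(self):
        rng = np.random.default_rng(2024)
        n_draws = 200_000
        p, n = 0.05, 50
        frac = np.mean(rng.binomial(n, p, size=n_draws) == 0)
        p0 = math.exp(log_prob_zero_observed(p, n))
        se = math.sqrt(p0 * (1 - p0) / n_draws)
        assert abs(frac - p0) <= 3 * se

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(st.floats(0, 0.999), st.floats(0, 0.999), st.integers(0, 5000),
           st.integers(0, 5000))
    def test_monotone_in_frequency_and_sample_size(self, p1, p2, n1, n2):
        lo_p, hi_p = sorted([p1, p2])
        lo_n, hi_n = sorted([n1, n2])
        assert (log_prob_zero_observed(hi_p, lo_n)
                <= log_prob_zero_observed(lo_p, lo_n))
        assert (log_prob_zero_observed(lo_p, hi_n)
                <= log_prob_zero_observed(lo_p, lo_n))


class TestCombinePopulations:
    def test_all_certain_gives_one(self):
        assert combine_populations([0.0, 0.0, 0.0]) == (0.0, 1.0)

    def test_product_rule(self):
        log_p, p = combine_populations([math.log(1e-3), math.log(1e-3)])
        assert p == pytest.approx(1e-6, rel=1e-9)

    def test_underflow_keeps_log(self):
        log_p, p = combine_populations([-500.0, -500.0])
        assert log_p == -1000.0 and p == 0.0

    def test_positive_entry_rejected(self):
        with pytest.raises(ValueError):
            combine_populations([0.1])

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.lists(st.floats(-50, 0), min_size=1, max_size=11))
    def test_combined_never_exceeds_any_single_probability(self, logs):
        _, p = combine_populations(logs)
        assert p <= math.exp(min(logs)) * (1 + 1e-12)


class TestBonferroniThreshold:
    @pytest.mark.parametrize("k,alpha,expected", [
        (1, 0.05, 0.05 / 3),
        (117068, 0.05, 0.05 / (3 * 117068)),   # ~1.4237e-7
        (10, 0.3, 0.01),
    ])
    def test_values(self, k, alpha, expected):
        assert bonferroni_threshold(k, alpha) == pytest.approx(expected)

    def test_chr1_scale_magnitude(self):
        assert bonferroni_threshold(117068, 0.05) == pytest.approx(
            1.4237e-7, rel=1e-4)

    @pytest.mark.parametrize("k,alpha", [(0, 0.05), (5, 0.0), (5, 1.0)])
    def test_domain_errors(self, k, alpha):
        with pytest.raises(ValueError):
            bonferroni_threshold(k, alpha)


def _mpc(per_pop, alleles=("A", "C")):
    return MultiPopulationCounts(
        snp=SNPMeta("rs1", "1", 100, alleles),
        per_pop=[GenotypeCounts(f"P{j}", *c) for j, c in enumerate(per_pop)],
    )


class TestEvaluateGenotypeClass:
    def test_split_homozygote_population_missing_heterozygotes(self):
        """1000 individuals split 500 'AA' / 500 'aa': the absent
        heterozygote class has expected frequency 0.5, giving a combined
        log-probability of 1000*ln(0.5)."""
        r = evaluate_genotype_class(_mpc([(500, 0, 500, 0)]), 1)
        assert r is not None and r.genotype == "AC"
        assert r.per_pop_pstar == [pytest.approx(0.5)]
        assert r.log_p_value == pytest.approx(1000 * math.log(0.5), rel=1e-12)
        assert r.p_value == pytest.approx(9.33e-302, rel=1e-2)

    def test_observed_class_returns_none(self):
        assert evaluate_genotype_class(_mpc([(10, 1, 0, 0), (5, 0, 0, 0)]), 1) is None

    def test_monomorphic_gives_pvalue_one(self):
        r = evaluate_genotype_class(_mpc([(10, 0, 0, 0), (7, 0, 0, 0)]), 2)
        assert r is not None
        assert r.p_value == 1.0 and r.log_p_value == 0.0

    def test_n_source_panel_uses_missing_calls(self):
        mpc = _mpc([(50, 0, 50, 100)])
        called = evaluate_genotype_class(mpc, 1, n_source="called")
        panel = evaluate_genotype_class(mpc, 1, n_source="panel")
        assert called.log_p_value == pytest.approx(100 * math.log(0.5))
        assert panel.log_p_value == pytest.approx(200 * math.log(0.5))
        assert panel.per_pop_expectation[0] == pytest.approx(100.0)

    def test_combined_across_populations_is_product(self):
        mpc = _mpc([(8, 4, 0, 0), (6, 2, 0, 0)])
        r = evaluate_genotype_class(mpc, 2)
        expected = sum(
            n * math.log1p(-((n1 / (2 * n)) ** 2))
            for n, n1 in [(12, 4), (8, 2)]
        )
        assert r.log_p_value == pytest.approx(expected, rel=1e-12)

    def test_invalid_class_index(self):
        with pytest.raises(ValueError):
            evaluate_genotype_class(_mpc([(1, 0, 0, 0)]), 3)
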