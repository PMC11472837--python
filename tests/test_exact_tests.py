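import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pgxfreq import (
    ContingencyTable,
    chisq_contingency,
    fisher_freeman_halton,
    scan_loci,
    simulate_cohort,
)
from pgxfreq.exact_tests import count_margin_tables
from pgxfreq.simulate import CohortConfig, StratumSpec, calibrate_alphas


class TestContingencyTable:
    def test_rejects_one_dimensional_or_tiny(self):
        with pytest.raises(ValueError):
            ContingencyTable(np.array([[1, 2]]))

    def test_rejects_negative_and_empty(self):
        with pytest.raises(ValueError):
            ContingencyTable(np.array([[1, -1], [0, 2]]))
        with pytest.raises(ValueError):
            ContingencyTable(np.zeros((2, 2), dtype=int))


class TestTableCounting:
    def _brute(self, rm, cm):
        count = 0
        R, C = len(rm), len(cm)
        for cells in itertools.product(*[range(min(max(rm), max(cm)) + 1)] * (R * C)):
            t = np.array(cells).reshape(R, C)
            if (t.sum(1) == rm).all() and (t.sum(0) == cm).all():
                count += 1
        return count

    @pytest.mark.parametrize(
        "rm,cm",
        [((4, 4), (4, 4)), ((3, 4, 5), (6, 3, 3)), ((2, 2, 2), (3, 2, 1))],
    )
    def test_matches_brute_force(self, rm, cm):
        assert count_margin_tables(rm, cm) == self._brute(np.array(rm), np.array(cm))

    def test_cap_truncation(self):
        assert count_margin_tables((150, 140, 67), (190, 101, 66), cap=1000) > 1000


class TestFisherFreemanHalton:
    def test_two_by_two_enumeration_oracle(self):
        # margins (4,4)/(4,4): 5 tables with probs (1,16,36,16,1)/70;
        # observed [[3,1],[1,3]] has prob 16/70, tail = (1+16+16+1)/70
        res = fisher_freeman_halton([[3, 1], [1, 3]])
        assert res.method == "full_enumeration" and res.n_tables == 5
        assert res.p_value == pytest.approx(34 / 70, rel=1e-12)

    def test_modal_balanced_table_has_p_one(self):
        res = fisher_freeman_halton([[2, 2], [2, 2]])
        assert res.p_value == pytest.approx(1.0, rel=1e-9)

    def test_monte_carlo_agrees_with_enumeration_within_3_se(self):
        tab = np.array([[3, 1, 2], [1, 3, 1], [2, 1, 3]])  # margins <= 6
        full = fisher_freeman_halton(tab, mode="enumerate")
        mc = fisher_freeman_halton(tab, mode="mc", n_permutations=100_000, seed=13)
        se = np.sqrt(full.p_value * (1 - full.p_value) / 100_000)
        assert abs(mc.p_value - full.p_value) <= 3 * se

    def test_monte_carlo_converges_with_more_permutations(self):
        tab = np.array([[8, 2, 4], [3, 9, 2], [4, 3, 8]])
        exact = fisher_freeman_halton(tab, mode="enumerate").p_value
        for n_perm in (1_000, 100_000):
            mc = fisher_freeman_halton(tab, mode="mc", n_permutations=n_perm, seed=21)
            se = np.sqrt(exact * (1 - exact) / n_perm)
            assert abs(mc.p_value - exact) <= 4 * se

    def test_monte_carlo_reproducible_given_seed(self):
        tab = np.array([[8, 2], [3, 9]])
        a = fisher_freeman_halton(tab, mode="mc", n_permutations=5_000, seed=3)
        b = fisher_freeman_halton(tab, mode="mc", n_permutations=5_000, seed=3)
        assert a.p_value == b.p_value

    def test_monte_carlo_without_seed_is_an_error(self):
        with pytest.raises(ValueError, match="seed"):
            fisher_freeman_halton([[8, 2], [3, 9]], mode="mc")

    def test_degenerate_margin_is_an_error(self):
        with pytest.raises(ValueError, match="margin"):
            fisher_freeman_halton([[0, 0], [3, 9]])

    def test_auto_switches_to_monte_carlo_for_large_margin_space(self):
        tab = np.array([[90, 50, 30], [80, 40, 25], [20, 11, 11]])
        assert count_margin_tables(tab.sum(1), tab.sum(0)) > 1_000_000
        res = fisher_freeman_halton(tab, seed=1, n_permutations=2_000)
        assert res.method == "monte_carlo"

    @settings(max_examples=40)
    @given(
        cells=st.lists(st.integers(0, 5), min_size=4, max_size=4).filter(
            lambda c: sum(c) > 0 and sum(c[:2]) > 0 and sum(c[2:]) > 0
            and c[0] + c[2] > 0 and c[1] + c[3] > 0
        )
    )
    def test_enumeration_invariant_under_row_and_column_permutation(self, cells):
        tab = np.array(cells).reshape(2, 2)
        p = fisher_freeman_halton(tab, mode="enumerate").p_value
        for perm in (tab[::-1], tab[:, ::-1], tab.T):
            assert fisher_freeman_halton(perm, mode="enumerate").p_value == pytest.approx(p, rel=1e-9)
        assert 0.0 < p <= 1.0 + 1e-12

    def test_three_by_three_permutation_invariance(self):
        tab = np.array([[5, 1, 2], [2, 6, 1], [1, 2, 7]])
        p = fisher_freeman_halton(tab, mode="enumerate").p_value
        rperm = tab[[2, 0, 1]]
        cperm = tab[:, [1, 2, 0]]
        for t in (rperm, cperm):
            assert fisher_freeman_halton(t, mode="enumerate").p_value == pytest.approx(p, rel=1e-9)


class TestChisq:
    def test_homogeneous_table(self):
        res = chisq_contingency([[10, 10], [10, 10]])
        assert res.chi2 == 0.0 and res.p_value == pytest.approx(1.0)

    def test_hand_computed_statistic(self):
        res = chisq_contingency([[20, 5], [5, 20]])
        assert res.chi2 == pytest.approx(18.0) and res.df == 1

    def test_zero_expected_cell_suggests_exact_test(self):
        with pytest.raises(ValueError, match="exact"):
            chisq_contingency([[0, 0], [3, 9]])

    def test_agrees_with_exact_on_balanced_tables(self):
        """Asymptotic and exact p-values agree closely on well-filled 2x3
        tables at survey scale (n = 357)."""
        rng = np.random.default_rng(8)
        for _ in range(5):
            probs = rng.dirichlet(np.ones(6)).reshape(2, 3)
            tab = rng.multinomial(357, probs.ravel()).reshape(2, 3)
            if (tab.sum(0) == 0).any() or (tab.sum(1) == 0).any():
                continue
            p_chi = chisq_contingency(tab).p_value
            p_exact = fisher_freeman_halton(tab, seed=4, n_permutations=100_000).p_value
            assert abs(p_chi - p_exact) <= 0.02


def _null_config(seed, L=39):
    """Exchangeable strata: every stratum draws ancestry from the same Dirichlet."""
    alpha = tuple(calibrate_alphas((0.678, 0.272, 0.053), 10.0))
    strata = tuple(
        StratumSpec(lab, n, alpha)
        for lab, n in (("white", 190), ("admixed", 101), ("black", 66))
    )
    return CohortConfig(strata=strata, L=L, seed=seed)


class TestScanLoci:
    def test_significant_counting(self, toy_vcf, toy_strata):
        import pandas as pd
        from pgxfreq.pipeline import summarize_hwe_deviations

        # trivially: p-vector (0.01, 0.2, 0.03) at alpha 0.05 -> 2 significant
        tab = pd.DataFrame({"rsid": ["a", "b", "c"], "p_value": [0.01, 0.2, 0.03]})
        assert summarize_hwe_deviations(tab, 0.05) == ["a", "c"]

    def test_null_cohort_rejects_at_nominal_rate(self):
        """With identical ancestry distributions in every stratum the exact
        scan's significant-locus count stays within binomial 95% bounds of
        39 x 0.05."""
        sim = simulate_cohort(_null_config(seed=424))
        scan = scan_loci(sim.cohort, "stratum", n_permutations=2_000, seed=7)
        n = len(scan.table)
        bound_hi = n * 0.05 + 1.96 * np.sqrt(n * 0.05 * 0.95)
        assert scan.n_significant <= np.ceil(bound_hi)

    def test_differentiated_strata_have_excess_significant_loci(self):
        """Strata that differ in ancestry produce genotype-frequency
        differences at far more loci than the 5% null expectation."""
        from pgxfreq import cuban_study_config

        sim = simulate_cohort(cuban_study_config(seed=11, L=39))
        scan = scan_loci(sim.cohort, "skin_color", n_permutations=2_000, seed=8)
        assert scan.n_significant > 39 * 0.05 + 3 * np.sqrt(39 * 0.05 * 0.95)

    def test_missing_stratum_variable_is_an_error(self):
        sim = simulate_cohort(_null_config(seed=1, L=4))
        with pytest.raises(ValueError, match="region"):
            scan_loci(sim.cohort, "region")

    def test_bonferroni_switch_reduces_significant_count(self):
        from pgxfreq import cuban_study_config

        sim = simulate_cohort(cuban_study_config(seed=11, L=20))
        raw = scan_loci(sim.cohort, "skin_color", n_permutations=1_000, seed=9)
        corrected = scan_loci(
            sim.cohort, "skin_color", n_permutations=1_000, seed=9,
            correction="bonferroni",
        )
        assert corrected.n_significant <= raw.n_significant
        assert "p_adjusted" in corrected.table.columns
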