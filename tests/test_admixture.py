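import numpy as np
import pytest

from pgxfreq import (
    ReferencePanel,
    cohort_ancestry,
    cuban_study_config,
    group_summary,
    kruskal_dunn,
    simulate_cohort,
    supervised_admixture_em,
)


def _sym_panel(L=50, eps=1e-6):
    """Two ancestral populations fixed for opposite alleles at every locus."""
    return ReferencePanel(("a", "b"), np.array([[1 - eps] * L, [eps] * L]))


class TestSupervisedEm:
    def test_single_population_is_trivial(self):
        panel = ReferencePanel(("only",), np.full((1, 10), 0.3))
        est = supervised_admixture_em(np.ones(10), panel)
        assert est.q.tolist() == [1.0] and est.converged

    def test_all_heterozygous_between_opposite_panels_gives_half_half(self):
        est = supervised_admixture_em(np.ones(50), _sym_panel())
        assert est.q == pytest.approx([0.5, 0.5], abs=1e-6)

    def test_all_alt_hom_drives_boundary_estimate(self):
        est = supervised_admixture_em(np.full(50, 2.0), _sym_panel())
        assert est.q[0] == pytest.approx(1.0, abs=1e-3)

    def test_all_missing_is_an_error(self):
        with pytest.raises(ValueError):
            supervised_admixture_em(np.full(50, np.nan), _sym_panel())

    def test_missing_loci_dropped_from_likelihood(self):
        doses = np.ones(50)
        doses[25:] = np.nan
        est = supervised_admixture_em(doses, _sym_panel())
        assert est.q == pytest.approx([0.5, 0.5], abs=1e-6)

    def test_loglik_nondecreasing_on_random_instances(self):
        rng = np.random.default_rng(41)
        for _ in range(20):
            K, L = rng.integers(2, 5), rng.integers(5, 60)
            panel = ReferencePanel(
                tuple(f"p{k}" for k in range(K)), rng.random((K, L))
            )
            doses = rng.integers(0, 3, size=L).astype(float)
            est = supervised_admixture_em(doses, panel)
            diffs = np.diff(est.loglik_path)
            assert (diffs >= -1e-8 * np.abs(est.loglik_path[:-1])).all()
            assert est.q.sum() == pytest.approx(1.0, abs=1e-8)
            assert (est.q >= 0).all()

    def test_estimate_invariant_under_locus_permutation(self):
        rng = np.random.default_rng(5)
        panel_freqs = rng.random((3, 40))
        doses = rng.integers(0, 3, size=40).astype(float)
        perm = rng.permutation(40)
        e1 = supervised_admixture_em(
            doses, ReferencePanel(("x", "y", "z"), panel_freqs)
        )
        e2 = supervised_admixture_em(
            doses[perm], ReferencePanel(("x", "y", "z"), panel_freqs[:, perm])
        )
        assert e1.q == pytest.approx(e2.q, abs=1e-9)

    def test_identical_genotypes_give_identical_estimates(self):
        sim = simulate_cohort(cuban_study_config(seed=2, L=20))
        cohort = sim.cohort
        cohort.genotypes[1] = cohort.genotypes[0]
        ests = cohort_ancestry(cohort, sim.panel)
        assert ests[0].q == pytest.approx(ests[1].q, abs=1e-12)


class TestRecovery:
    def test_parameter_recovery_improves_with_more_loci(self):
        maes = []
        for L in (34, 136):
            sim = simulate_cohort(cuban_study_config(seed=19, L=L))
            est = cohort_ancestry(sim.cohort, sim.panel)
            Q = np.vstack([e.q for e in est])
            maes.append(float(np.abs(Q - sim.true_q).mean()))
        assert maes[1] < maes[0]


class TestGroupSummary:
    def _est(self, q):
        from pgxfreq.admixture import AncestryEstimate

        return AncestryEstimate(np.asarray(q, float), 0.0, 1, True)

    def test_single_group_mean(self):
        ests = [self._est([0.8, 0.2, 0.0]), self._est([0.6, 0.4, 0.0])]
        out = group_summary(ests, ["g", "g"])
        means = out.set_index("component")["mean"]
        assert means["q0"] == pytest.approx(0.7)
        assert means["q1"] == pytest.approx(0.3)

    def test_group_of_size_one(self):
        ests = [self._est([0.9, 0.1]), self._est([0.2, 0.8])]
        out = group_summary(ests, ["a", "b"])
        row = out[(out["group"] == "b") & (out["component"] == "q0")].iloc[0]
        assert row["mean"] == row["min"] == row["max"] == pytest.approx(0.2)

    def test_recovered_group_means_match_generating_means(self):
        """EM group means track the per-stratum Dirichlet means used to
        generate the cohort, within EM bias plus sampling noise."""
        from pgxfreq.simulate import SKIN_COLOR_ANCESTRY_MEANS

        sim = simulate_cohort(cuban_study_config(seed=23, L=136))
        ests = cohort_ancestry(sim.cohort, sim.panel)
        labels = sim.cohort.strata["skin_color"]
        out = group_summary(ests, labels, components=sim.panel.labels)
        for grp, means in SKIN_COLOR_ANCESTRY_MEANS.items():
            sub = out[out["group"] == grp].set_index("component")
            for comp, target in zip(("EUR", "AFR", "AMR"), means):
                n = sub.loc[comp, "n"]
                se = np.sqrt(target * (1 - target) / (10 + 1) / n)  # Dirichlet SE
                assert abs(sub.loc[comp, "mean"] - target) <= 3 * se + 0.03


class TestKruskalDunn:
    def test_hand_computed_h_statistic(self):
        # ranks 1..9 in three blocks: H = 12/(9*10) * 54 = 7.2
        comp = kruskal_dunn(
            [1, 2, 3, 4, 5, 6, 7, 8, 9],
            ["a"] * 3 + ["b"] * 3 + ["c"] * 3,
        )
        assert comp.kw_h == pytest.approx(7.2)
        assert comp.kw_p == pytest.approx(0.0273, abs=0.001)
        assert len(comp.pairwise) == 3  # all group pairs covered

    def test_all_equal_observations(self):
        comp = kruskal_dunn([5.0] * 9, ["a"] * 3 + ["b"] * 3 + ["c"] * 3)
        assert comp.kw_h == 0.0 and comp.kw_p == 1.0
        assert all(p == pytest.approx(1.0) for *_, p, _sig in comp.pairwise)

    def test_single_group_is_an_error(self):
        with pytest.raises(ValueError):
            kruskal_dunn([1, 2, 3], ["a", "a", "a"])

    def test_empty_group_levels_rejected(self):
        with pytest.raises(ValueError):
            kruskal_dunn([1, 2], ["a", "b"], alpha_pairwise=0.017) and kruskal_dunn(
                [], []
            )

    def test_separated_groups_significant_at_stated_pairwise_alpha(self):
        rng = np.random.default_rng(3)
        values = np.concatenate([rng.normal(0, 1, 40), rng.normal(3, 1, 40)])
        comp = kruskal_dunn(values, ["lo"] * 40 + ["hi"] * 40)
        assert comp.kw_p < 0.001
        assert comp.pairwise[0][4] is True or comp.pairwise[0][3] < 0.017

    def test_type_one_error_calibrated(self):
        """Three groups drawn from one distribution: KW rejects at 5% at the
        nominal rate (vectorized rank computation, no ties)."""
        from scipy.stats import rankdata, chi2

        rng = np.random.default_rng(909)
        reps, per = 2000, 100
        x = rng.normal(size=(reps, 3 * per))
        ranks = rankdata(x, axis=1)
        N = 3 * per
        h = np.zeros(reps)
        for g in range(3):
            rbar = ranks[:, g * per:(g + 1) * per].mean(axis=1)
            h += per * (rbar - (N + 1) / 2) ** 2
        h *= 12 / (N * (N + 1))
        rate = float((chi2.sf(h, 2) < 0.05).mean())
        assert rate == pytest.approx(0.05, abs=0.015)


class TestReferencePanel:
    def test_tsv_round_trip(self, tmp_path):
        panel = ReferencePanel(("EUR", "AFR"), np.array([[0.1, 0.9], [0.8, 0.2]]), ("r1", "r2"))
        panel.to_tsv(tmp_path / "p.tsv")
        back = ReferencePanel.from_tsv(tmp_path / "p.tsv")
        assert back.labels == ("EUR", "AFR")
        assert back.freqs == pytest.approx(panel.freqs, abs=1e-6)

    def test_clamping_keeps_frequencies_interior(self):
        panel = ReferencePanel(("a",), np.array([[0.0, 1.0]]))
        assert (panel.freqs > 0).all() and (panel.freqs < 1).all()

    def test_mismatched_labels_rejected(self):
        with pytest.raises(ValueError):
            ReferencePanel(("a",), np.zeros((2, 3)))
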