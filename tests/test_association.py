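import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from etioscope.association import (CollinearScoresError, bh_fdr, compute_grs,
                                   compute_grs_table, extreme_group_tests,
                                   medication_odds, omics_screen,
                                   score_phenotype_association)
from etioscope.synthetic import generate_genotypes, generate_omics


def dirichlet_scores(n, seed, alpha=0.5):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(rng.dirichlet([alpha] * 4, size=n),
                        columns=list("ABCD"),
                        index=[f"S{i}" for i in range(n)])


class TestScorePhenotype:
    def test_outcome_equal_to_score_recovered_exactly(self):
        scores = dirichlet_scores(200, 0)
        out = score_phenotype_association(scores, scores["A"].rename("bmi"))
        a = out[out.archetype == "A"].iloc[0]
        assert a.estimate == pytest.approx(1.0, abs=1e-10)
        assert a.p_value < 1e-100

    def test_five_point_case_matches_normal_equations(self):
        scores = pd.DataFrame({"A": [0.9, 0.6, 0.4, 0.2, 0.1]},
                              index=[f"S{i}" for i in range(5)])
        scores["B"] = 1.0 - scores["A"]
        y = pd.Series([3.0, 2.0, 2.5, 1.0, 0.5], index=scores.index,
                      name="pheno")
        out = score_phenotype_association(scores[["A"]].join(scores[["B"]]), y)
        x = np.column_stack([np.ones(5), scores["A"]])
        beta = np.linalg.solve(x.T @ x, x.T @ y.to_numpy())
        a = out[out.archetype == "A"].iloc[0]
        assert a.estimate == pytest.approx(beta[1], rel=1e-10)

    def test_null_type_one_error_calibrated(self):
        rng = np.random.default_rng(1)
        n, reps = 400, 400
        hits = 0
        scores = dirichlet_scores(n, 2)
        for _ in range(reps):
            y = pd.Series(rng.standard_normal(n), index=scores.index)
            out = score_phenotype_association(scores[["A"]], y)
            hits += out.iloc[0].p_value < 0.05
        assert 0.03 <= hits / reps <= 0.07

    def test_joint_model_refused(self):
        scores = dirichlet_scores(50, 3)
        y = pd.Series(np.arange(50.0), index=scores.index)
        with pytest.raises(CollinearScoresError):
            score_phenotype_association(scores, y, joint=True)

    def test_zero_variance_outcome_rejected(self):
        scores = dirichlet_scores(20, 4)
        with pytest.raises(ValueError):
            score_phenotype_association(
                scores, pd.Series(np.ones(20), index=scores.index))


class TestExtremeGroupTests:
    def test_shifted_group_detected_with_direction(self):
        rng = np.random.default_rng(5)
        labels = np.repeat(["A", "B", "C", "D", "MIX"], 50)
        outcome = rng.standard_normal(250)
        outcome[labels == "A"] += 2.0
        kw_p, table = extreme_group_tests(labels, outcome)
        assert kw_p < 1e-6
        a = table[table.group == "A"].iloc[0]
        assert a.mannwhitney_p < 1e-6 and a.rank_biserial > 0.5

    def test_null_kruskal_p_roughly_uniform(self):
        rng = np.random.default_rng(6)
        labels = np.repeat(["A", "B", "C"], 40)
        pvals = [extreme_group_tests(labels, rng.standard_normal(120))[0]
                 for _ in range(200)]
        # under the null, p-values are approximately uniform
        assert 0.35 <= np.mean(np.asarray(pvals) < 0.5) <= 0.65
        assert np.mean(np.asarray(pvals) < 0.1) <= 0.2

    def test_small_group_skipped(self):
        labels = np.array(["A"] * 30 + ["B"])
        with pytest.warns(RuntimeWarning):
            with pytest.raises(ValueError):
                extreme_group_tests(labels, np.random.default_rng(7)
                                    .standard_normal(31))


class TestMedicationOdds:
    def test_two_by_two_matches_cross_product_ratio(self):
        status = pd.Series([1] * 30 + [0] * 10 + [1] * 5 + [0] * 25)
        exposed = pd.DataFrame({"A": [1.0] * 40 + [0.0] * 30})
        exposed.index = status.index
        out = medication_odds(exposed, status)
        expected = (30 * 25) / (10 * 5)
        assert out.iloc[0].odds_ratio == pytest.approx(expected, rel=1e-6)

    def test_planted_effect_significant(self):
        rng = np.random.default_rng(8)
        scores = dirichlet_scores(700, 9)
        prob = 1 / (1 + np.exp(-(-1.0 + 3.0 * scores["D"])))
        status = pd.Series(rng.random(700) < prob, index=scores.index,
                           dtype=float)
        out = medication_odds(scores, status)
        d = out[out.archetype == "D"].iloc[0]
        assert d.odds_ratio > 1 and d.p_value < 1e-4 and not d.penalized

    def test_null_confidence_intervals_cover_one(self):
        rng = np.random.default_rng(10)
        covered = 0
        reps = 200
        scores = dirichlet_scores(300, 11)
        for _ in range(reps):
            status = pd.Series(rng.random(300) < 0.4, index=scores.index,
                               dtype=float)
            out = medication_odds(scores[["A"]], status)
            row = out.iloc[0]
            covered += row.ci_low <= 1.0 <= row.ci_high
        assert covered / reps >= 0.93

    def test_separation_falls_back_to_penalized(self):
        scores = pd.DataFrame({"A": np.linspace(0, 1, 40)})
        status = pd.Series((scores["A"] > 0.5).astype(float))
        out = medication_odds(scores, status)
        assert bool(out.iloc[0].penalized)


class TestBhFdr:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.037])[0] == pytest.approx(0.037)

    def test_equal_ps_all_equal(self):
        np.testing.assert_allclose(bh_fdr([0.2, 0.2, 0.2]), 0.2)

    def test_worked_step_up_example(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.04, 0.05]),
                                   [0.04, 0.04, 0.05, 0.05], atol=1e-12)

    def test_matches_brute_force_definition(self):
        def brute(p):
            p = np.asarray(p)
            n = len(p)
            order = np.argsort(p)
            q = np.empty(n)
            # q_(i) = min over j >= i of p_(j) * n / j
            sorted_p = p[order]
            for i in range(n):
                q[order[i]] = min(sorted_p[j] * n / (j + 1)
                                  for j in range(i, n))
            return np.minimum(q, 1.0)

        rng = np.random.default_rng(12)
        for size in (1, 2, 5, 8):
            p = rng.random(size)
            np.testing.assert_allclose(bh_fdr(p), brute(p), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


class TestOmicsScreen:
    def test_matches_statsmodels_cellwise(self, truth_scores, small_cohort):
        _, _, truth = small_cohort
        feats = generate_omics(truth, 30, 20, 0.5, seed=5)
        out = omics_screen(truth_scores, feats)
        row = out.iloc[17]
        y = feats[row.target_name].to_numpy()
        x = sm.add_constant(truth_scores[row.archetype].to_numpy())
        fit = sm.OLS(y, x).fit()
        assert row.estimate == pytest.approx(fit.params[1], rel=1e-10)
        assert row.p_value == pytest.approx(fit.pvalues[1], rel=1e-10)

    def test_planted_features_recovered_at_fdr_threshold(self):
        from etioscope.synthetic import CohortConfig, generate_cohort
        config = CohortConfig(n_subjects=700, seed=31)
        matrix, truth = generate_cohort(config)
        scores = pd.DataFrame(truth.weights, index=matrix.subject_ids,
                              columns=list("ABCD"))
        feats = generate_omics(truth, 200, 150, effect_sd=0.5, seed=6)
        out = omics_screen(scores, feats)
        hits = out.groupby("target_name").q_value.min()
        planted = [f"feature_{j + 1:05d}" for j in range(50)]
        assert (hits[planted] < 0.05).mean() >= 0.8

    def test_metformin_covariate_mode_matches_unadjusted_when_irrelevant(
            self, truth_scores, small_cohort):
        _, _, truth = small_cohort
        rng = np.random.default_rng(13)
        feats = generate_omics(truth, 40, 20, 0.5, seed=7)
        met = pd.Series(rng.random(len(truth_scores)) < 0.4,
                        index=truth_scores.index, dtype=float)
        plain = omics_screen(truth_scores, feats)
        adj = omics_screen(truth_scores, feats, metformin=met,
                           stratify_metformin="covariate")
        merged = plain.merge(adj, on=["target_name", "archetype"],
                             suffixes=("_plain", "_adj"))
        diffs = (merged.estimate_plain - merged.estimate_adj).abs()
        assert np.all(diffs < merged.std_error_plain)

    def test_constant_feature_skipped(self, truth_scores):
        feats = pd.DataFrame({
            "flat": np.ones(len(truth_scores)),
            "ok": np.arange(len(truth_scores), dtype=float)},
            index=truth_scores.index)
        out = omics_screen(truth_scores, feats)
        assert set(out.target_name) == {"ok"}

    def test_realized_fdr_controlled_on_null_features(self):
        rng = np.random.default_rng(14)
        n, reps, alpha = 300, 100, 0.05
        scores = dirichlet_scores(n, 15)
        fdps = []
        for _ in range(reps):
            feats = pd.DataFrame(rng.standard_normal((n, 100)),
                                 index=scores.index,
                                 columns=[f"f{j}" for j in range(100)])
            out = omics_screen(scores, feats)
            rejected = (out.q_value < alpha).sum()
            fdps.append(1.0 if rejected else 0.0)  # all features null
        se = np.sqrt(alpha * (1 - alpha) / reps)
        assert np.mean(fdps) <= alpha + 2 * se


class TestGrs:
    def test_zero_dosages_give_zero_score(self):
        dosages, weights = generate_genotypes(20, 10, seed=0)
        zero = dosages * 0.0
        assert np.all(compute_grs(zero, weights) == 0)

    def test_unit_weights_count_alleles(self):
        dosages, weights = generate_genotypes(25, 8, seed=1)
        w = weights.assign(weight=1.0)
        np.testing.assert_allclose(compute_grs(dosages, w),
                                   dosages.sum(axis=1))

    def test_three_snp_hand_computed_case(self):
        dosages = pd.DataFrame([[0, 1, 2], [2, 2, 0]],
                               columns=["rs1", "rs2", "rs3"],
                               index=["s1", "s2"])
        weights = pd.DataFrame({"snp": ["rs1", "rs2", "rs3"],
                                "weight": [0.1, 0.2, 0.3],
                                "partition": ["IS1", "IS1", "BMI"]})
        grs = compute_grs(dosages, weights)
        np.testing.assert_allclose(grs, [0.1 * 0 + 0.2 * 1 + 0.3 * 2,
                                         0.1 * 2 + 0.2 * 2 + 0.3 * 0])
        np.testing.assert_allclose(compute_grs(dosages, weights, "IS1"),
                                   [0.2, 0.6])

    def test_missing_snp_rejected_with_names(self):
        dosages = pd.DataFrame([[0, 1]], columns=["rs1", "rs2"], index=["s1"])
        weights = pd.DataFrame({"snp": ["rs1", "rs9"], "weight": [0.1, 0.2],
                                "partition": ["IS1", "IS2"]})
        with pytest.raises(ValueError, match="rs9"):
            compute_grs(dosages, weights)

    def test_table_has_overall_plus_six_partitions(self):
        dosages, weights = generate_genotypes(30, 24, seed=2)
        table = compute_grs_table(dosages, weights)
        assert table.shape[1] == 7
        assert "grs_overall" in table.columns
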