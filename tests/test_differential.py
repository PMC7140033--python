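import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from conftest import make_design, make_matrix
from integromics.differential import (
    StageDifferentialAnalysis,
    anova_per_feature,
    attribute_transitions,
    bh_fdr,
    log_fold_change,
    studentized_range_sf,
    tukey_hsd,
    venn_partition,
)


class TestStudentizedRange:
    def test_boundaries_and_validation(self):
        assert studentized_range_sf(0.0, 4, 8) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            studentized_range_sf(1.0, 1, 8)
        with pytest.raises(ValueError):
            studentized_range_sf(1.0, 4, 0.5)
        with pytest.raises(ValueError):
            studentized_range_sf(-1.0, 4, 8)

    def test_k2_reduces_to_t_distribution(self):
        # for two groups, P(Q >= q) = P(|T_df| >= q / sqrt(2))
        for df in (3, 8, 25):
            for q in (0.5, 1.5, 3.0, 5.0):
                expected = 2 * stats.t.sf(q / np.sqrt(2), df)
                assert studentized_range_sf(q, 2, df) == pytest.approx(
                    expected, abs=1e-7
                )

    def test_matches_reference_quadrature(self):
        grid = [(2, 5, 2.0), (3, 10, 3.3), (4, 8, 6.928), (8, 12, 5.0), (4, 1, 3.0)]
        for k, df, q in grid:
            assert studentized_range_sf(q, k, df) == pytest.approx(
                stats.studentized_range.sf(q, k, df), abs=1e-6
            )

    def test_monotone_decreasing_and_vectorized_consistent(self):
        q = np.linspace(0, 10, 700)  # large enough to engage the grid path
        sf = studentized_range_sf(q, 4, 8)
        assert np.all(np.diff(sf) <= 1e-12)
        subset = [5, 100, 350, 699]
        for i in subset:
            assert sf[i] == pytest.approx(studentized_range_sf(float(q[i]), 4, 8),
                                          abs=1e-6)


class TestBHFDR:
    def test_hand_step_up(self):
        np.testing.assert_allclose(
            bh_fdr([0.01, 0.04, 0.03, 0.05]), [0.04, 0.05, 0.05, 0.05]
        )

    def test_single_and_equal_pvalues(self):
        assert bh_fdr([0.03]) == pytest.approx([0.03])
        np.testing.assert_allclose(bh_fdr([0.2] * 5), [0.2] * 5)
        np.testing.assert_allclose(bh_fdr([1.0, 1.0]), [1.0, 1.0])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])
        with pytest.raises(ValueError):
            bh_fdr([-0.1])

    def test_matches_brute_force_definition(self, rng):
        def brute(p):
            n = len(p)
            order = np.argsort(p, kind="stable")
            q = np.empty(n)
            for rank_pos, idx in enumerate(order):
                candidates = [
                    p[order[j]] * n / (j + 1) for j in range(rank_pos, n)
                ]
                q[idx] = min(min(candidates), 1.0)
            return q

        for _ in range(1000):
            p = rng.uniform(size=rng.integers(1, 12))
            np.testing.assert_allclose(bh_fdr(p), brute(p), atol=1e-12)


class TestANOVA:
    def test_hand_sums_of_squares(self, design, printed_style_matrix):
        res = anova_per_feature(printed_style_matrix, design)
        row = res.loc["feat"]
        assert row["F"] == pytest.approx(12.0)
        assert (row["df_between"], row["df_within"]) == (3, 8)
        assert row["p"] == pytest.approx(stats.f.sf(12.0, 3, 8))

    def test_degenerate_contracts(self, design):
        flat = make_matrix({"flat": [5.0] * 12}, design)
        res = anova_per_feature(flat, design)
        assert res.loc["flat", "F"] == 0.0 and res.loc["flat", "p"] == 1.0

        step = make_matrix({"step": [0.0] * 3 + [1.0] * 9}, design)
        with pytest.warns(RuntimeWarning, match="zero within-group"):
            res2 = anova_per_feature(step, design)
        assert res2.loc["step", "p"] == 0.0

    def test_partition_identity_on_random_data(self, design, rng):
        values = rng.normal(size=(50, 12))
        m = make_matrix({f"f{i}": values[i] for i in range(50)}, design)
        res = anova_per_feature(m, design)
        labels = design.stage_labels(m.sample_ids)
        for i in range(50):
            grand = values[i].mean()
            sst = ((values[i] - grand) ** 2).sum()
            ssb = ssw = 0.0
            for s in design.stages:
                g = values[i][labels == s]
                ssb += len(g) * (g.mean() - grand) ** 2
                ssw += ((g - g.mean()) ** 2).sum()
            assert ssb + ssw == pytest.approx(sst, abs=1e-9)
            assert res.iloc[i]["F"] == pytest.approx(
                (ssb / 3) / (ssw / 8), rel=1e-9
            )


class TestTukey:
    def test_hand_q_statistic(self, design, printed_style_matrix):
        pw = tukey_hsd(printed_style_matrix, design)
        row = pw[(pw["stage_a"] == "P") & (pw["stage_b"] == "AT1")].iloc[0]
        assert row["q_stat"] == pytest.approx(4 / np.sqrt(1 / 3), abs=1e-9)
        assert row["q_stat"] == pytest.approx(6.928, abs=1e-3)
        assert row["mean_diff"] == pytest.approx(4.0)
        assert len(pw) == 6  # all stage pairs for one feature

    def test_identical_groups_give_p_one(self, design):
        m = make_matrix({"f": [0, 1, 2] * 4}, design)
        pw = tukey_hsd(m, design)
        assert np.allclose(pw["q_stat"], 0.0)
        assert np.allclose(pw["p_adj"], 1.0)

    def test_zero_mse_boundary(self, design):
        m = make_matrix({"f": [0.0] * 3 + [2.0] * 3 + [0.0] * 6}, design)
        with pytest.warns(RuntimeWarning):
            pw = tukey_hsd(m, design)
        hit = pw[(pw["stage_a"] == "P") & (pw["stage_b"] == "AT1")].iloc[0]
        same = pw[(pw["stage_a"] == "P") & (pw["stage_b"] == "DCIS")].iloc[0]
        assert hit["p_adj"] == 0.0 and same["p_adj"] == 1.0

    def test_p_matches_distribution_oracle_on_random_input(self, design, rng):
        values = rng.normal(size=(20, 12))
        m = make_matrix({f"f{i}": values[i] for i in range(20)}, design)
        pw = tukey_hsd(m, design)
        for _, row in pw.sample(20, random_state=1).iterrows():
            expected = stats.studentized_range.sf(row["q_stat"], 4, 8)
            assert row["p_adj"] == pytest.approx(expected, abs=1e-4)


class TestFoldChangeAndCalls:
    def test_log_fold_change_values(self, design):
        m = make_matrix({"f": [2, 2, 2, 5, 5, 5, 2, 2, 2, 2, 2, 2]}, design)
        assert log_fold_change(m, design, "P", "AT1")["f"] == pytest.approx(3.0)
        assert log_fold_change(m, design, "P", "DCIS")["f"] == pytest.approx(0.0)
        with pytest.raises(ValueError):
            log_fold_change(m, design, "P", "NOPE")

    def test_antisymmetry(self, design, rng):
        m = make_matrix({f"f{i}": rng.normal(size=12) for i in range(5)}, design)
        ab = log_fold_change(m, design, "AT1", "DCIS")
        ba = log_fold_change(m, design, "DCIS", "AT1")
        np.testing.assert_allclose(ab, -ba)

    def test_flat_feature_has_no_calls(self, design):
        m = make_matrix({"flat": [3.0] * 12}, design)
        anova = anova_per_feature(m, design)
        pw = tukey_hsd(m, design)
        assert attribute_transitions(pw, anova, design) == {}

    def test_planted_monotone_feature_called_everywhere(self, design):
        vals = [0.0] * 3 + [3.0] * 3 + [6.0] * 3 + [9.0] * 3
        noise = np.tile([-0.05, 0.0, 0.05], 4)
        m = make_matrix({"g1": np.array(vals) + noise}, design)
        anova = anova_per_feature(m, design)
        pw = tukey_hsd(m, design)
        calls = attribute_transitions(pw, anova, design)
        assert calls["g1"] == {
            ("P->AT1", "up"), ("AT1->DCIS", "up"), ("DCIS->CA1D", "up"),
        }

    def test_anova_gate_excludes_features(self, design):
        vals = [0.0] * 3 + [3.0] * 3 + [6.0] * 3 + [9.0] * 3
        noise = np.tile([-0.05, 0.0, 0.05], 4)
        m = make_matrix({"g1": np.array(vals) + noise}, design)
        anova = anova_per_feature(m, design).assign(q=1.0)  # force gate shut
        pw = tukey_hsd(m, design)
        assert attribute_transitions(pw, anova, design) == {}


class TestVennPartition:
    def test_simple_regions(self, design):
        calls = {
            "a": {("P->AT1", "up"), ("AT1->DCIS", "up"), ("DCIS->CA1D", "up")},
            "b": {("P->AT1", "down")},
            "c": {("AT1->DCIS", "up")},
        }
        regions = venn_partition(calls, design)
        assert regions[("P->AT1", "AT1->DCIS", "DCIS->CA1D")] == 1
        assert regions[("P->AT1",)] == 1
        assert regions[("AT1->DCIS",)] == 1
        assert sum(regions.values()) == 3

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_matches_set_algebra(self, seed):
        rng = np.random.default_rng(seed)
        design = make_design()
        names = ["P->AT1", "AT1->DCIS", "DCIS->CA1D"]
        calls = {}
        for i in range(rng.integers(0, 30)):
            chosen = [n for n in names if rng.random() < 0.5]
            if chosen:
                calls[f"f{i}"] = {(n, "up") for n in chosen}
        regions = venn_partition(calls, design)
        assert sum(regions.values()) == len(calls)
        for region, count in regions.items():
            expected = sum(
                1
                for cs in calls.values()
                if {t for t, _ in cs} == set(region)
            )
            assert count == expected


class TestEstimatorFacade:
    def test_fit_produces_consistent_tables(self, rng):
        X = rng.normal(size=(12, 6))
        X[3:6, 0] += 8.0  # strong AT1 shift in feature 0
        y = ["P"] * 3 + ["AT1"] * 3 + ["DCIS"] * 3 + ["CA1D"] * 3
        est = StageDifferentialAnalysis(stages=("P", "AT1", "DCIS", "CA1D")).fit(X, y)
        assert est.anova_.shape[0] == 6
        assert set(est.pairwise_["stage_a"]).issubset({"P", "AT1", "DCIS"})
        assert "f0" in est.significant_features()

    def test_power_at_six_sigma_effect(self, rng):
        # a 6*noise_sd step passes both the |lfc|>=2 and Tukey p<0.01 gates
        # in >=90% of replicates under the triplicate design
        effect, noise = 3.0, 0.5
        hits = 0
        reps = 300
        y = np.repeat(["P", "AT1", "DCIS", "CA1D"], 3)
        for _ in range(reps):
            x = rng.normal(0, noise, 12)
            x[3:] += effect  # early step, sustained
            est = StageDifferentialAnalysis().fit(x[:, None], y)
            hits += ("P->AT1", "up") in est.transitions_.get("f0", set())
        assert hits / reps >= 0.9

    def test_calls_monotone_in_effect_size(self, rng):
        y = np.repeat(["P", "AT1", "DCIS", "CA1D"], 3)
        base = rng.normal(0, 0.5, (12, 40))
        counts = []
        for effect in (2.5, 3.5, 5.0):
            x = base.copy()
            x[3:, :] += effect
            est = StageDifferentialAnalysis().fit(x, y)
            counts.append(len(est.transitions_))
        assert counts == sorted(counts)
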