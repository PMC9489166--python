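"""Unit and property tests for weights, screening, correlators and clustering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ddpp_lung import (
    NoSignificantGenesError,
    aggregate,
    bh_fdr,
    classify_ddpp,
    fit_correlator,
    gene_weight,
    group_label,
    kmeans2_1d,
    partition_groups,
    pearson_with_p,
    screen_genes,
    score_patients,
    select_predictor,
)
from ddpp_lung.ddpp_core import brute_force_two_partition
from ddpp_lung.pipeline_cli import fit_group_correlators


class TestGeneWeight:
    @pytest.mark.parametrize(
        "t, n, i, expected",
        [
            (4.0, 4.0, 100.0, 0.0),  # unit fold-change
            (8.0, 2.0, 1.1, 2.0),  # log2(4) * log1.1(1.1)
            (2.0, 8.0, 1.1**3, -6.0),  # (-2) * 3
        ],
    )
    def test_exact_values(self, t, n, i, expected):
        assert gene_weight(t, n, i) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("bad", [(0, 1, 1), (1, -2, 1), (1, 1, 0)])
    def test_nonpositive_rejected(self, bad):
        with pytest.raises(ValueError):
            gene_weight(*bad)

    @settings(derandomize=True, max_examples=50)
    @given(
        t=st.floats(0.1, 1e4), n=st.floats(0.1, 1e4), i=st.floats(0.1, 1e4)
    )
    def test_antisymmetric_in_tissues(self, t, n, i):
        assert gene_weight(t, n, i) == pytest.approx(-gene_weight(n, t, i), abs=1e-9)


class TestPearson:
    def test_exact_linearity(self):
        x = np.array([1.0, 2, 3, 4])
        r, p = pearson_with_p(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        rneg, _ = pearson_with_p(x, -x)
        assert rneg == pytest.approx(-1.0)

    def test_matches_closed_form(self):
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([2.0, 1, 4, 3, 5])
        r, p = pearson_with_p(x, y)
        # closed-form Pearson and two-sided t-test with n-2 df
        rx, ry = x - x.mean(), y - y.mean()
        r_hand = (rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum())
        t_hand = r_hand * np.sqrt(3 / (1 - r_hand**2))
        from scipy.stats import t as tdist

        assert r == pytest.approx(r_hand, abs=1e-12)
        assert p == pytest.approx(2 * tdist.sf(abs(t_hand), df=3), rel=1e-9)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            pearson_with_p([1, 1, 1], [1, 2, 3])


class TestBHFDR:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([0.03], [0.03]),
            ([0.05, 0.05, 0.05, 0.05], [0.05] * 4),
            ([0.01, 0.02, 0.03, 0.04], [0.04] * 4),  # min_{j>=i} p(j)*m/j
        ],
    )
    def test_step_up_examples(self, p, expected):
        np.testing.assert_allclose(bh_fdr(p), expected, atol=1e-12)

    @settings(derandomize=True, max_examples=30)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=1000))
    def test_matches_literal_step_up(self, p):
        """q_i = min over j with p(j) >= p(i) of p(j) * m / rank(j)."""
        p = np.asarray(p)
        m = p.size
        order = np.argsort(p, kind="stable")
        q_lit = np.empty(m)
        running = np.inf
        for rank_from_top in range(m, 0, -1):
            i = order[rank_from_top - 1]
            running = min(running, p[i] * m / rank_from_top)
            q_lit[i] = min(running, 1.0)
        np.testing.assert_allclose(bh_fdr(p), q_lit, atol=1e-12)

    def test_q_at_least_p(self):
        rng = np.random.default_rng(0)
        p = rng.random(500)
        q = bh_fdr(p)
        assert (q >= p - 1e-15).all() and (q <= 1).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


class TestScreenGenes:
    def test_noiseless_planted_group(self, noiseless_cohort, noiseless_weights):
        _, _, clinical, truth = noiseless_cohort
        members = partition_groups(clinical)[("AC", False)]
        screen = screen_genes(noiseless_weights["tumor"], clinical["dfs_months"], members)
        planted = truth.planted_genes["AC:NC"]
        assert (screen.loc[planted, "p"] <= 1e-100).all()
        assert (screen.loc[planted, "q"] < 0.05).all()
        others = screen.drop(index=planted)
        # non-planted p-values look uniform
        assert 0.4 < others["p"].mean() < 0.6

    def test_null_group_yields_no_discoveries(self, null_cohort, null_weights):
        _, _, clinical = null_cohort
        members = partition_groups(clinical)[("SCC", False)]
        screen = screen_genes(null_weights["tumor"], clinical["dfs_months"], members)
        assert int((screen["q"] < 0.05).sum()) == 0

    def test_small_group_rejected(self, noiseless_weights, noiseless_cohort):
        _, _, clinical, _ = noiseless_cohort
        with pytest.raises(ValueError, match="4"):
            screen_genes(noiseless_weights["tumor"], clinical["dfs_months"],
                         list(clinical.index[:3]))


class TestAggregateAndFit:
    @pytest.mark.parametrize("mode, expected", [("median", 2.0), ("mean", 4.0), ("sum", 12.0)])
    def test_modes(self, mode, expected):
        w = pd.DataFrame([[1.0], [2.0], [9.0]], index=["a", "b", "c"], columns=["P1"])
        assert aggregate(w, ["a", "b", "c"], mode)["P1"] == expected

    def test_unknown_gene_rejected(self):
        w = pd.DataFrame([[1.0]], index=["a"], columns=["P1"])
        with pytest.raises(KeyError):
            aggregate(w, ["zz"], "mean")

    def test_exact_line(self):
        slope, intercept, r, _ = fit_correlator([1, 2, 3], [5, 7, 9])
        assert (slope, intercept, r) == pytest.approx((2.0, 3.0, 1.0))

    def test_two_point_interpolation(self):
        slope, intercept, _, _ = fit_correlator([0, 2], [1, 5])
        assert (slope, intercept) == pytest.approx((2.0, 1.0))

    def test_constant_aggregate_rejected(self):
        with pytest.raises(ValueError):
            fit_correlator([1, 1, 1], [1, 2, 3])

    def test_noiseless_link_recovery(self, noiseless_cohort, noiseless_weights):
        """Sum-aggregated planted weights recover the generator's line exactly."""
        _, _, clinical, truth = noiseless_cohort
        groups = partition_groups(clinical)
        for key, members in groups.items():
            label = group_label(key)
            agg = aggregate(noiseless_weights["tumor"][members],
                            truth.planted_genes[label], "sum")
            slope, intercept, r, _ = fit_correlator(agg, clinical.loc[members, "dfs_months"])
            assert slope == pytest.approx(truth.link_slope[label], rel=1e-8)
            assert intercept == pytest.approx(truth.link_intercept[label], rel=1e-8)
            assert abs(r) == pytest.approx(1.0, abs=1e-10)


class TestSelectPredictor:
    def test_noiseless_recovery_is_exact(self, noiseless_cohort, noiseless_weights):
        _, _, clinical, truth = noiseless_cohort
        groups = partition_groups(clinical)
        for key, members in groups.items():
            label = group_label(key)
            corr = select_predictor(noiseless_weights, clinical["dfs_months"],
                                    members, label)
            assert set(corr.gene_ids) == set(truth.planted_genes[label])
            assert abs(corr.fit_r) == pytest.approx(1.0, abs=1e-9)

    def test_null_group_raises(self, null_cohort, null_weights):
        _, _, clinical = null_cohort
        members = partition_groups(clinical)[("AC", False)]
        with pytest.raises(NoSignificantGenesError):
            select_predictor(null_weights, clinical["dfs_months"], members, "AC:NC")

    def test_tie_break_prefers_full_planted_set(self, noiseless_cohort, noiseless_weights):
        """Every planted subset ties at |r| = 1; the full set must win."""
        _, _, clinical, truth = noiseless_cohort
        members = partition_groups(clinical)[("SCC", False)]
        corr = select_predictor(noiseless_weights, clinical["dfs_months"], members, "SCC:NC")
        assert len(corr.gene_ids) == len(truth.planted_genes["SCC:NC"]) == 15


class TestScorePatients:
    def test_noiseless_scores_equal_dfs(self, noiseless_cohort, noiseless_weights):
        _, expr, clinical, _ = noiseless_cohort
        weights, groups, correlators, _ = fit_group_correlators(expr, clinical)
        scores, excluded = score_patients(correlators, weights, clinical, groups)
        assert not excluded
        np.testing.assert_allclose(
            scores["score"], clinical.loc[scores.index, "dfs_months"], atol=1e-6
        )

    def test_missing_correlator_goes_to_exclusions(self, noiseless_cohort, noiseless_weights):
        _, expr, clinical, _ = noiseless_cohort
        weights, groups, correlators, _ = fit_group_correlators(expr, clinical)
        del correlators[("LCC", False)]
        scores, excluded = score_patients(correlators, weights, clinical, groups)
        assert len(excluded) == 6
        assert all("LCC:NC" in e["reason"] for e in excluded)
        assert len(scores) + len(excluded) == len(clinical)

    def test_dfs_shift_shifts_group_scores(self, noiseless_cohort, noiseless_weights):
        """OLS: adding c months to one group's DFS adds c to its scores."""
        _, _, clinical, _ = noiseless_cohort
        members = partition_groups(clinical)[("AC", True)]
        dfs = clinical["dfs_months"].copy()
        corr = select_predictor(noiseless_weights, dfs, members, "AC:CT")
        shifted = dfs.copy()
        shifted.loc[members] += 7.0
        corr2 = select_predictor(noiseless_weights, shifted, members, "AC:CT")
        w = noiseless_weights[corr.intensity_source]
        p1 = corr.predict(w, members)
        w2 = noiseless_weights[corr2.intensity_source]
        p2 = corr2.predict(w2, members)
        np.testing.assert_allclose(p2, p1 + 7.0, atol=1e-6)


class TestKMeans1D:
    def test_symmetric_example(self):
        labels, centers, threshold = kmeans2_1d([0.0, 0.0, 10.0, 10.0])
        assert threshold == 5.0
        assert centers == (0.0, 10.0)
        np.testing.assert_array_equal(labels, [0, 0, 1, 1])

    def test_outlier_split(self):
        labels, centers, _ = kmeans2_1d([1.0, 2.0, 3.0, 100.0])
        np.testing.assert_array_equal(labels, [0, 0, 0, 1])

    @settings(derandomize=True, max_examples=60)
    @given(st.lists(st.floats(-100, 100), min_size=2, max_size=12).filter(
        lambda v: len(set(v)) > 1))
    def test_matches_brute_force_optimum(self, values):
        labels, centers, threshold = kmeans2_1d(values)
        v = np.asarray(values)
        a, b = v[labels == 0], v[labels == 1]
        wss = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
        assert wss == pytest.approx(brute_force_two_partition(values), abs=1e-8)

    def test_threshold_between_centers(self):
        rng = np.random.default_rng(4)
        v = rng.normal(size=40)
        _, centers, threshold = kmeans2_1d(v)
        assert centers[0] < threshold < centers[1]

    def test_identical_values_rejected(self):
        with pytest.raises(ValueError):
            kmeans2_1d([3.0, 3.0, 3.0])


class TestClassifyDDPP:
    def test_example_partition(self):
        scores = pd.Series([-40.0, -30.0, 10.0, 50.0, 60.0],
                           index=list("abcde"))
        result = classify_ddpp(scores)
        assert set(result.classes[result.classes == "low"].index) == {"a", "b"}
        assert set(result.classes[result.classes == "high"].index) == {"c", "d", "e"}

    def test_two_patients(self):
        result = classify_ddpp(pd.Series([1.0, 5.0], index=["a", "b"]))
        assert result.classes.to_dict() == {"a": "low", "b": "high"}

    def test_order_invariance(self):
        scores = pd.Series([3.0, -8.0, 12.0, -9.0], index=list("abcd"))
        r1 = classify_ddpp(scores)
        r2 = classify_ddpp(scores.iloc[::-1])
        assert r1.classes.sort_index().equals(r2.classes.sort_index())
        assert r1.threshold == r2.threshold
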