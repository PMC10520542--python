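"""K-L divergences, cut-point scanning, information graphs and the Bregman
representation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from postgdm.info_diagnostics import (
    DEFAULT_GRID,
    bregman_total_kl,
    info_distinguishability,
    information_graph,
    kl_in,
    kl_out,
    pin_pout,
    scan_cutpoints,
    threshold_metrics,
    youden,
)

unit_interior = st.floats(0.02, 0.98)


class TestDivergences:
    def test_uninformative_test_has_zero_divergence(self):
        # g1 = 1 - g2 means the two Bernoulli responses are identical
        assert kl_in(0.7, 0.3) == pytest.approx(0.0, abs=1e-12)
        assert kl_out(0.7, 0.3) == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_good_test_value(self):
        # 0.9 ln(0.9/0.1) + 0.1 ln(0.1/0.9) = 0.8 ln 9
        assert kl_in(0.9, 0.9) == pytest.approx(1.7578, abs=5e-5)

    @given(g1=unit_interior, g2=unit_interior)
    @settings(max_examples=200, derandomize=True)
    def test_swap_symmetry_and_nonnegativity(self, g1, g2):
        assert kl_in(g1, g2) == pytest.approx(kl_out(g2, g1), abs=1e-12)
        assert kl_in(g1, g2) >= -1e-12
        assert kl_out(g1, g2) >= -1e-12

    @given(g1=unit_interior, g2=unit_interior)
    @settings(max_examples=200, derandomize=True)
    def test_divergences_vanish_iff_uninformative(self, g1, g2):
        both_zero = (kl_in(g1, g2) < 1e-10) and (kl_out(g1, g2) < 1e-10)
        assert both_zero == (abs(g1 + g2 - 1.0) < 1e-4)

    def test_out_of_range_inputs_rejected(self):
        with pytest.raises(ValueError):
            kl_in(1.2, 0.5)
        with pytest.raises(ValueError):
            pin_pout(-0.1)
        with pytest.raises(ValueError):
            info_distinguishability(-1.0)

    def test_odds_multiplier_and_distinguishability(self):
        assert pin_pout(0.0) == pytest.approx(1.0)
        assert info_distinguishability(0.0) == pytest.approx(0.0)
        # the reported rule-in test: D = 0.30 nats -> 1.35-fold odds update
        assert round(pin_pout(0.30), 2) == 1.35
        # and its distinguishability at the unrounded divergence
        assert info_distinguishability(0.2965) == pytest.approx(0.2566,
                                                                abs=5e-5)


class TestThresholdMetrics:
    def test_combined_cutpoint_row_reproduces_summary_stats(self, make_preds):
        # counts chosen to mirror the combined rule-in/rule-out operating
        # point: 92 diseased (53 above c), 302 controls (71 above c)
        probs = np.r_[np.full(53, 0.9), np.full(39, 0.1),
                      np.full(71, 0.9), np.full(231, 0.1)]
        labels = np.r_[np.ones(92), np.zeros(302)].astype(int)
        row = threshold_metrics(make_preds(probs, labels), 0.5)
        assert round(row.j, 2) == 0.34
        assert round(row.f1, 2) == 0.49
        assert row.ppv == pytest.approx(53 / 124)
        assert youden(0.58, 0.76) == pytest.approx(0.34)

    def test_perfect_separation_interior_cutpoint(self, make_preds):
        preds = make_preds([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        row = threshold_metrics(preds, 0.5)
        for v in (row.g1, row.g2, row.ppv, row.npv, row.accuracy):
            assert v == pytest.approx(1.0)
        assert row.j == pytest.approx(1.0)
        assert row.degenerate  # divergences are clamped, not infinite
        assert np.isfinite(row.tkl)

    def test_empty_predicted_positive_set_reports_missing_ppv(self, make_preds):
        row = threshold_metrics(make_preds([0.1, 0.2], [1, 0]), 0.9)
        assert np.isnan(row.ppv)
        assert np.isnan(row.f1)

    def test_ta_is_percent_strictly_below(self, make_preds):
        probs = np.r_[np.full(28, 0.05), np.full(72, 0.5)]
        labels = np.r_[np.zeros(50), np.ones(50)].astype(int)
        assert threshold_metrics(make_preds(probs, labels), 0.14).ta == 28

    @given(c=st.floats(0.05, 0.95))
    @settings(max_examples=100, derandomize=True)
    def test_row_internal_identities(self, c):
        rng = np.random.default_rng(12)
        probs = rng.random(120)
        labels = (rng.random(120) < 0.3).astype(int)
        from postgdm.nested_cv import AggregatedPredictions
        preds = AggregatedPredictions.from_arrays(probs, labels)
        row = threshold_metrics(preds, c)
        assert row.tkl == pytest.approx(row.kl_in + row.kl_out, abs=1e-12)
        assert row.p_in == pytest.approx(np.exp(row.kl_in), abs=1e-12)
        assert row.id_in == pytest.approx(1 - np.exp(-row.kl_in), abs=1e-12)
        assert row.p_out == pytest.approx(np.exp(row.kl_out), abs=1e-12)
        assert row.id_out == pytest.approx(1 - np.exp(-row.kl_out), abs=1e-12)
        assert row.j == pytest.approx(row.g1 + row.g2 - 1.0, abs=1e-12)
        # Bayes' identity at the empirical prevalence
        pi = labels.mean()
        denom = pi * row.g1 + (1 - pi) * (1 - row.g2)
        if denom > 0 and np.isfinite(row.ppv):
            assert row.ppv == pytest.approx(pi * row.g1 / denom, abs=1e-12)


class TestScan:
    def test_grid_shape_and_monotone_sensitivity(self, make_preds):
        rng = np.random.default_rng(3)
        preds = make_preds(rng.random(200), (rng.random(200) < 0.25))
        rows, sel = scan_cutpoints(preds)
        assert len(rows) == 1000
        assert rows["c"].iloc[0] == 0.0
        assert rows["c"].iloc[-1] == pytest.approx(0.999)
        g1 = rows["g1"].to_numpy()
        g2 = rows["g2"].to_numpy()
        assert (np.diff(g1) <= 1e-12).all()   # sensitivity non-increasing
        assert (np.diff(g2) >= -1e-12).all()  # specificity non-decreasing
        # each selected divergence dominates every scanned cut-point
        assert sel.d_in >= rows["kl_in"].max() - 1e-12
        assert sel.d_out >= rows["kl_out"].max() - 1e-12
        assert sel.tkl_max >= rows["tkl"].max() - 1e-12

    def test_separated_uniform_scores_select_midpoint(self, make_preds):
        rng = np.random.default_rng(5)
        pos = rng.uniform(0.5, 1.0, 1000)
        neg = rng.uniform(0.0, 0.5, 1000)
        preds = make_preds(np.r_[pos, neg],
                           np.r_[np.ones(1000), np.zeros(1000)])
        _, sel = scan_cutpoints(preds)
        assert sel.c_in_out == pytest.approx(0.5, abs=0.02)

    def test_grid_argmax_matches_brute_force_oracle(self, make_preds):
        """On small instances the grid scan must find the same maximal
        divergences as scanning every distinct score value."""
        rng = np.random.default_rng(11)
        for _ in range(20):
            n = int(rng.integers(12, 50))
            probs = np.round(rng.random(n), 2)
            labels = (rng.random(n) < 0.4).astype(int)
            if labels.min() == labels.max():
                continue
            preds = make_preds(probs, labels)
            _, sel = scan_cutpoints(preds)
            best_in = best_out = best_both = -np.inf
            for c in np.unique(probs):  # oracle: every achievable cut
                row = threshold_metrics(preds, float(c))
                best_in = max(best_in, row.kl_in)
                best_out = max(best_out, row.kl_out)
                best_both = max(best_both, row.tkl)
            assert sel.d_in == pytest.approx(best_in, abs=1e-10)
            assert sel.d_out == pytest.approx(best_out, abs=1e-10)
            assert sel.tkl_max == pytest.approx(best_both, abs=1e-10)

    def test_anti_informative_scores_flagged_by_youden(self, make_preds):
        rng = np.random.default_rng(6)
        pos = rng.uniform(0.0, 0.5, 300)   # positives score LOW
        neg = rng.uniform(0.5, 1.0, 300)
        preds = make_preds(np.r_[pos, neg],
                           np.r_[np.ones(300), np.zeros(300)])
        rows, sel = scan_cutpoints(preds)
        j_at_sel = rows.loc[rows["c"] == sel.c_in_out, "j"].iloc[0]
        assert j_at_sel <= 0.0

    def test_ties_break_toward_smaller_cutpoint(self, make_preds):
        preds = make_preds([0.9, 0.9, 0.1, 0.1], [1, 1, 0, 0])
        _, sel = scan_cutpoints(preds)
        # the whole interval (0.1, 0.9] is maximal; the first grid point
        # above 0.1 must be chosen
        assert sel.c_in_out == pytest.approx(0.101)


class TestInformationGraph:
    def test_uninformative_test_is_flat_zero(self):
        g = information_graph(0.7, 0.3, np.linspace(0.05, 0.95, 19))
        assert np.allclose(g[["i_plus", "i_minus", "i_expected"]], 0.0,
                           atol=1e-10)

    def test_decomposition_identity_everywhere(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            g1, g2, x = rng.uniform(0.05, 0.95, 3)
            g = information_graph(g1, g2, [x])
            lhs = g["i_expected"].iloc[0]
            rhs = (g["pr_t1"] * g["i_plus"]
                   + (1 - g["pr_t1"]) * g["i_minus"]).iloc[0]
            assert lhs == pytest.approx(rhs, abs=1e-10)

    def test_expected_information_is_mutual_information(self):
        """Cross-check against a direct joint-entropy oracle."""
        rng = np.random.default_rng(14)

        def entropy(p):
            p = np.asarray(p, float)
            p = p[p > 0]
            return -(p * np.log(p)).sum()

        for _ in range(50):
            g1, g2, x = rng.uniform(0.05, 0.95, 3)
            joint = np.array([[x * g1, x * (1 - g1)],
                              [(1 - x) * (1 - g2), (1 - x) * g2]])
            mi = (entropy(joint.sum(1)) + entropy(joint.sum(0))
                  - entropy(joint.ravel()))
            g = information_graph(g1, g2, [x])
            assert g["i_expected"].iloc[0] == pytest.approx(mi, abs=1e-10)

    def test_low_pretest_probability_favors_positive_result(self):
        # a rule-in style test (high specificity): as x -> 0 the negative
        # result carries ~no information while the positive one dominates
        g = information_graph(0.36, 0.92, [0.01, 0.02, 0.05])
        assert (g["i_minus"] < 0.01).all()
        assert (g["i_plus"] > g["i_minus"]).all()
        low = information_graph(0.36, 0.92, [0.001])["i_minus"].iloc[0]
        assert low == pytest.approx(0.0, abs=1e-3)


class TestBregman:
    def test_equals_total_kl_on_interior_lattice(self):
        grid = np.linspace(0.04, 0.96, 20)
        for g1 in grid:
            for g2 in grid:
                expected = kl_in(g1, g2) + kl_out(g1, g2)
                assert bregman_total_kl(g1, g2) == pytest.approx(
                    expected, abs=1e-10)

    def test_tangent_point_coincidence_gives_zero(self):
        assert bregman_total_kl(0.6, 0.4) == pytest.approx(0.0, abs=1e-12)

    @given(g1=unit_interior, g2=unit_interior)
    @settings(max_examples=100, derandomize=True)
    def test_nonnegative_by_convexity(self, g1, g2):
        assert bregman_total_kl(g1, g2) >= -1e-12
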