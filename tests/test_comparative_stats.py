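"""Binary and survival comparisons, exact tests, and classification."""

import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st_hyp
from scipy.optimize import minimize_scalar

from vtdmaic.comparative_stats import (
    ConvergenceError,
    MarginSet,
    binary_compare,
    classify,
    fisher_exact_two_sided,
    weighted_cox_hr,
    weighted_logrank,
)
from vtdmaic.trial_data import ValidationError


class TestFisherExact:
    @pytest.mark.parametrize(
        "table",
        [((1, 9), (9, 1)), ((2, 8), (8, 2)), ((5, 0), (3, 4)), ((10, 3), (2, 11))],
    )
    def test_agrees_with_scipy_enumeration(self, table):
        ours = fisher_exact_two_sided(table)
        ref = scipy.stats.fisher_exact(np.array(table)).pvalue
        assert ours == pytest.approx(ref, abs=1e-12)

    def test_enumeration_oracle_small_table(self):
        # direct minlike enumeration over all tables with the fixed margins
        a, b, c, d = 2, 8, 8, 2
        n, row1, col1 = a + b + c + d, a + b, a + c
        support = range(max(0, row1 + col1 - n), min(row1, col1) + 1)
        pmf = {k: scipy.stats.hypergeom.pmf(k, n, row1, col1) for k in support}
        expected = sum(p for p in pmf.values() if p <= pmf[a] * (1 + 1e-7))
        assert fisher_exact_two_sided(((a, b), (c, d))) == pytest.approx(
            expected, abs=1e-12
        )

    def test_identical_rows_give_p_one(self):
        assert fisher_exact_two_sided(((5, 5), (5, 5))) == pytest.approx(1.0)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st_hyp.tuples(*[st_hyp.integers(0, 12)] * 4))
    def test_row_swap_symmetry(self, cells):
        a, b, c, d = cells
        p1 = fisher_exact_two_sided(((a, b), (c, d)))
        p2 = fisher_exact_two_sided(((c, d), (a, b)))
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_zero_margin_convention(self):
        assert fisher_exact_two_sided(((0, 0), (3, 4))) == 1.0

    def test_non_integer_rejected(self):
        with pytest.raises(ValidationError):
            fisher_exact_two_sided(((1.5, 2), (3, 4)))


class TestBinaryCompare:
    def test_printed_postinduction_cr_row(self):
        c = binary_compare(50, 591, 46, 130)
        assert round(c.rd, 2) == -26.92
        assert round(c.rd_ci[0], 2) == -35.44
        assert round(c.rd_ci[1], 2) == -18.40
        assert round(c.or_, 3) == 0.169
        assert round(c.or_ci[0], 3) == 0.106
        assert round(c.or_ci[1], 3) == 0.268
        assert c.p < 1e-4

    def test_cross_check_against_statsmodels(self):
        sm = pytest.importorskip("statsmodels.api")
        t22 = sm.stats.Table2x2(np.array([[50, 541], [46, 84]]))
        c = binary_compare(50, 591, 46, 130)
        assert c.or_ == pytest.approx(t22.oddsratio)
        np.testing.assert_allclose(c.or_ci, t22.oddsratio_confint(), rtol=1e-6)

    def test_null_case(self):
        c = binary_compare(10, 50, 10, 50)
        assert c.rd == pytest.approx(0.0)
        assert c.or_ == pytest.approx(1.0)
        assert c.p == pytest.approx(1.0)

    def test_unit_weights_reduce_to_unweighted(self):
        rng = np.random.default_rng(17)
        flags = rng.integers(0, 2, 80).astype(float)
        unw = binary_compare(30, 100, float(flags.sum()), 80.0)
        wtd = binary_compare(
            30, 100, label_responders=flags, label_weights=np.ones(80)
        )
        assert wtd.rd == pytest.approx(unw.rd)
        assert wtd.or_ == pytest.approx(unw.or_)
        assert wtd.rd_ci == pytest.approx(unw.rd_ci)
        assert wtd.p == pytest.approx(unw.p)

    def test_zero_cell_reports_undefined_or_with_sensitivity(self):
        c = binary_compare(0, 20, 5, 20)
        assert math.isnan(c.or_)
        assert c.or_continuity is not None and c.or_continuity > 0

    def test_weighted_mode_uses_ess_denominator(self):
        flags = np.array([1.0, 1.0, 0.0, 0.0])
        weights = np.array([1.0, 3.0, 1.0, 3.0])
        c = binary_compare(5, 10, label_responders=flags, label_weights=weights)
        assert c.ess == pytest.approx(3.2)  # (8)^2 / 20
        assert c.n_lab == pytest.approx(3.2)
        assert c.k_lab == pytest.approx(0.5 * 3.2)


class TestWeightedCox:
    def test_four_subject_grid_oracle(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.ones(4, dtype=int)
        x = np.array([1.0, 0.0, 1.0, 0.0])

        def neg_partial_loglik(beta):
            ll = 0.0
            for i in range(4):
                risk = t >= t[i]
                ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
            return -ll

        opt = minimize_scalar(
            neg_partial_loglik, bounds=(-5, 5), method="bounded",
            options={"xatol": 1e-12},
        )
        res = weighted_cox_hr(t, e, x)
        assert math.log(res.hr) == pytest.approx(opt.x, abs=1e-6)

    def test_constant_weight_scale_invariance(self):
        rng = np.random.default_rng(23)
        t = rng.exponential(10, 100)
        e = rng.integers(0, 2, 100)
        e[:10] = 1  # ensure events
        x = rng.integers(0, 2, 100).astype(float)
        r1 = weighted_cox_hr(t, e, x)
        r2 = weighted_cox_hr(t, e, x, 3.5 * np.ones(100))
        assert r1.hr == pytest.approx(r2.hr, rel=1e-10)

    def test_integer_weights_equal_duplication(self):
        rng = np.random.default_rng(29)
        n = 150
        t = rng.exponential(8, n)
        e = rng.integers(0, 2, n)
        x = rng.integers(0, 2, n).astype(float)
        w = rng.integers(1, 4, n)
        r_w = weighted_cox_hr(t, e, x, w.astype(float))
        r_dup = weighted_cox_hr(np.repeat(t, w), np.repeat(e, w), np.repeat(x, w))
        assert r_w.hr == pytest.approx(r_dup.hr, rel=1e-10)

    def test_agrees_with_lifelines_unit_weights(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(3)
        n = 400
        x = rng.integers(0, 2, n).astype(float)
        te = rng.exponential(10 * np.exp(-0.4 * x))
        tc = rng.uniform(0, 25, n)
        t = np.minimum(te, tc)
        e = (te <= tc).astype(int)
        res = weighted_cox_hr(t, e, x)
        cph = lifelines.CoxPHFitter().fit(
            pd.DataFrame({"t": t, "e": e, "x": x}), "t", "e", robust=True
        )
        assert math.log(res.hr) == pytest.approx(cph.params_["x"], abs=1e-6)
        assert res.log_hr_se == pytest.approx(
            cph.standard_errors_["x"], rel=1e-4
        )

    def test_no_events_in_arm_errors(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.array([1, 1, 0, 0])
        x = np.array([0.0, 0.0, 1.0, 1.0])
        with pytest.raises(ConvergenceError, match="arm 1"):
            weighted_cox_hr(t, e, x)


class TestWeightedLogrank:
    def test_identical_arms_give_p_one(self):
        t = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        e = np.array([1, 1, 0, 1, 1, 0])
        x = np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0])
        assert weighted_logrank(t, e, x) == pytest.approx(1.0)

    def test_agrees_with_lifelines_on_simulated_data(self):
        lifelines_stats = pytest.importorskip("lifelines.statistics")
        rng = np.random.default_rng(41)
        n = 200
        x = rng.integers(0, 2, n).astype(float)
        te = rng.exponential(12 * np.exp(-0.5 * x))
        tc = rng.uniform(0, 30, n)
        t = np.minimum(te, tc)
        e = (te <= tc).astype(int)
        p = weighted_logrank(t, e, x)
        ref = lifelines_stats.logrank_test(t[x == 1], t[x == 0], e[x == 1], e[x == 0])
        assert p == pytest.approx(ref.p_value, abs=1e-8)

    def test_integer_weights_equal_duplication(self):
        rng = np.random.default_rng(43)
        n = 120
        t = rng.exponential(9, n)
        e = rng.integers(0, 2, n)
        x = rng.integers(0, 2, n).astype(float)
        w = rng.integers(1, 4, n)
        p_w = weighted_logrank(t, e, x, w.astype(float))
        p_dup = weighted_logrank(np.repeat(t, w), np.repeat(e, w), np.repeat(x, w))
        assert p_w == pytest.approx(p_dup, abs=1e-12)


class TestClassify:
    margins = MarginSet()

    @pytest.mark.parametrize(
        "kind, est, ci, p, endpoint, expected",
        [
            ("rate_difference_benefit", 6.15, (-0.82, 13.11), 0.065, None, "noninferior"),
            ("hazard_ratio", 0.640, (0.363, 1.129), 0.121, "os", "noninferior"),
            ("rate_difference_benefit", -27.51, (-36.5, -18.52), 1e-5, None, "inferior"),
            ("rate_difference_benefit", 0.0, (-20.0, 20.0), 1.0, None, "inconclusive"),
            ("rate_difference_harm", 1.28, (-0.61, 3.16), 0.481, None, "noninferior"),
            ("rate_difference_harm", -8.0, (-14.0, -2.0), 0.01, None, "superior"),
            ("hazard_ratio", 0.663, (0.467, 0.941), 0.021, "pfs", "superior"),
            ("hazard_ratio", 1.50, (1.05, 2.14), 0.02, "os", "inferior"),
        ],
    )
    def test_classification_rules(self, kind, est, ci, p, endpoint, expected):
        assert classify(kind, est, ci, p, self.margins, endpoint) == expected

    def test_boundary_p_takes_margin_path(self):
        # p exactly at alpha is non-significant: CI vs margin decides
        label = classify(
            "rate_difference_benefit", 5.0, (-1.0, 11.0), 0.05, self.margins
        )
        assert label == "noninferior"

    def test_hazard_ratio_requires_endpoint(self):
        with pytest.raises(ValidationError, match="os.*pfs"):
            classify("hazard_ratio", 0.7, (0.5, 0.9), 0.01, self.margins)

    def test_ci_must_bracket_estimate(self):
        with pytest.raises(ValidationError):
            classify("rate_difference_benefit", 5.0, (6.0, 10.0), 0.5, self.margins)

    def test_margin_validation(self):
        with pytest.raises(ValidationError):
            MarginSet(response_margin=-1.0)
        with pytest.raises(ValidationError):
            MarginSet(alpha=1.5)
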