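"""Normalization, replicate statistics, dose-response and barrier fits."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from epbarriers.core import DomainError
from epbarriers.quant import (FitError, bonferroni, delta_f_on,
                              fit_barrier_model, fit_dose_response,
                              fold_change, fraction_readthrough, normalize,
                              welch_test)


def make_table(rows):
    return pd.DataFrame(rows, columns=[
        "construct_id", "ligand_conc", "experimental_rep", "biological_rep",
        "fluorescence_raw", "od600_raw", "is_blank"])


class TestNormalize:
    def test_blank_correction_arithmetic(self):
        table = make_table([
            ("wt", 0.0, 1, 1, 1100.0, 0.45, False),
            ("", 0.0, 1, 1, 90.0, 0.04, True),
            ("", 0.0, 1, 2, 110.0, 0.06, True),
        ])
        out = normalize(table)
        # blank means (100, 0.05): (1100-100)/(0.45-0.05) = 2500
        assert out["value"].tolist() == [pytest.approx(2500.0)]

    def test_table_of_only_blanks_gives_empty_output(self):
        table = make_table([("", 0.0, 1, 1, 100.0, 0.05, True)])
        assert normalize(table).empty

    def test_no_blanks_is_configuration_error(self):
        table = make_table([("wt", 0.0, 1, 1, 1100.0, 0.45, False)])
        with pytest.raises(DomainError, match="blank"):
            normalize(table)

    def test_nonpositive_corrected_od_excluded_with_warning(self):
        table = make_table([
            ("wt", 0.0, 1, 1, 1100.0, 0.45, False),
            ("dead", 0.0, 1, 2, 150.0, 0.04, False),
            ("", 0.0, 1, 1, 100.0, 0.05, True),
        ])
        with pytest.warns(UserWarning, match="OD"):
            out = normalize(table)
        assert out["construct_id"].tolist() == ["wt"]


class TestFoldChangeAndDelta:
    def test_identical_groups_give_unity(self):
        assert fold_change([5.0, 5.0], [5.0, 5.0]) == 1.0

    def test_headline_arithmetic(self):
        assert fold_change([3400.0] * 3, [100.0] * 3) == pytest.approx(34.0)

    def test_empty_group_rejected(self):
        with pytest.raises(DomainError):
            fold_change([], [1.0])

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(DomainError):
            fold_change([1.0], [-2.0, 1.0])

    def test_delta_f_on(self):
        assert delta_f_on([1500.0] * 9, [1000.0] * 9) == 500.0
        assert delta_f_on([1.0], [1.0]) == 0.0
        assert delta_f_on([800.0], [1000.0]) == -200.0


class TestWelch:
    def test_identical_groups(self):
        res = welch_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0 and res.p == 1.0 and res.tier == "ns"

    def test_matches_hand_computed_formula(self):
        a, b = [1, 2, 3, 4, 5], [2, 3, 4, 5, 6]
        res = welch_test(a, b)
        va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
        t_hand = (np.mean(a) - np.mean(b)) / math.sqrt(va / 5 + vb / 5)
        df_hand = (va / 5 + vb / 5) ** 2 / (
            (va / 5) ** 2 / 4 + (vb / 5) ** 2 / 4)
        p_hand = 2 * stats.t.sf(abs(t_hand), df_hand)
        assert res.t == pytest.approx(t_hand)
        assert res.df == pytest.approx(df_hand)
        assert res.p == pytest.approx(p_hand)

    def test_agrees_with_scipy_reference(self, rng):
        for _ in range(20):
            a = rng.normal(0, 1, size=int(rng.integers(3, 12)))
            b = rng.normal(0.5, 2, size=int(rng.integers(3, 12)))
            res = welch_test(a, b)
            ref = stats.ttest_ind(a, b, equal_var=False)
            assert res.t == pytest.approx(ref.statistic)
            assert res.p == pytest.approx(ref.pvalue)

    def test_symmetry_up_to_sign(self, rng):
        a, b = rng.normal(0, 1, 9), rng.normal(1, 1, 9)
        fwd, rev = welch_test(a, b), welch_test(b, a)
        assert fwd.t == pytest.approx(-rev.t)
        assert fwd.p == pytest.approx(rev.p)

    def test_group_too_small_rejected(self):
        with pytest.raises(DomainError):
            welch_test([1.0], [1.0, 2.0])

    def test_bonferroni_caps_at_one(self):
        base = welch_test([1, 2, 3], [10, 11, 12])
        res, = bonferroni([base.with_adjusted(0.0)], m=10)
        assert res.p_adj == pytest.approx(min(1.0, base.p * 10))
        hi = base.with_adjusted(base.p)
        assert bonferroni([hi], m=10 ** 9)[0].p_adj == 1.0

    def test_tiers_follow_pre_correction_alphas(self):
        from epbarriers.quant import _tier
        assert _tier(0.2) == "ns"
        assert _tier(0.02) == "*"
        assert _tier(0.002) == "**"
        assert _tier(0.0002) == "***"
        assert _tier(0.00002) == "****"


class TestDoseResponse:
    CONCS = np.array([0.0, 0.001, 0.005, 0.02, 0.05, 0.1, 0.5, 1.0])

    @staticmethod
    def model(z, a, b, ec50):
        return a + b * z / (ec50 + z)

    def test_exact_recovery_on_noiseless_points(self):
        y = self.model(self.CONCS, 100.0, 900.0, 0.01)
        fit = fit_dose_response(np.column_stack([self.CONCS, y]))
        assert fit.a == pytest.approx(100.0, rel=1e-6)
        assert fit.b == pytest.approx(900.0, rel=1e-6)
        assert fit.ec50 == pytest.approx(0.01, rel=1e-6)

    def test_half_maximal_at_ec50(self):
        y = self.model(self.CONCS, 50.0, 400.0, 0.05)
        fit = fit_dose_response(np.column_stack([self.CONCS, y]))
        assert fit.predict(fit.ec50) - fit.a == pytest.approx(fit.b / 2)

    def test_curve_at_zero_equals_baseline(self):
        y = self.model(self.CONCS, 120.0, 700.0, 0.1)
        fit = fit_dose_response(np.column_stack([self.CONCS, y]))
        assert fit.predict(0.0) == pytest.approx(fit.a)

    def test_scale_equivariance(self):
        y = self.model(self.CONCS, 100.0, 900.0, 0.02)
        f1 = fit_dose_response(np.column_stack([self.CONCS, y]))
        f2 = fit_dose_response(np.column_stack([self.CONCS, 7.5 * y]))
        assert f2.a == pytest.approx(7.5 * f1.a, rel=1e-6)
        assert f2.b == pytest.approx(7.5 * f1.b, rel=1e-6)
        assert f2.ec50 == pytest.approx(f1.ec50, rel=1e-6)

    def test_noisy_recovery_within_fifteen_percent(self, rng):
        truth = (1000.0, 9000.0, 0.1)
        pts = []
        for z in self.CONCS:
            mu = self.model(z, *truth)
            pts += [(z, v) for v in mu * (1 + rng.normal(0, 0.05, 9))]
        fit = fit_dose_response(np.array(pts))
        assert abs(fit.ec50 - truth[2]) / truth[2] < 0.15

    def test_too_few_concentrations_rejected(self):
        with pytest.raises(DomainError):
            fit_dose_response([(0.0, 1.0), (1.0, 2.0)])

    def test_missing_zero_condition_rejected(self):
        with pytest.raises(DomainError):
            fit_dose_response([(0.1, 1.0), (0.5, 2.0), (1.0, 3.0)])


class TestBarrierModel:
    def test_exact_on_noiseless_power_law(self):
        pts = [(r, 400.0 / r ** 2) for r in range(1, 7)]
        fit = fit_barrier_model(pts)
        assert fit.B == pytest.approx(400.0)
        assert fit.rss == pytest.approx(0.0, abs=1e-18)

    def test_single_point(self):
        fit = fit_barrier_model([(1, 250.0)])
        assert fit.B == 250.0 and math.isnan(fit.se_B)

    def test_negative_b_is_flagged(self):
        fit = fit_barrier_model([(r, -300.0 / r ** 2) for r in (1, 2, 3)])
        assert fit.B < 0 and fit.negative_B

    def test_closed_form_matches_numerical_optimizer(self, rng):
        for _ in range(10):
            r = rng.integers(1, 8, size=8).astype(float)
            df = rng.normal(0, 200, size=8)
            closed = fit_barrier_model(list(zip(r, df))).B
            res = optimize.least_squares(
                lambda B: df - B[0] * r ** -2.0, x0=[0.0],
                jac=lambda B: -(r ** -2.0).reshape(-1, 1),
                xtol=None, ftol=None, gtol=1e-14)
            assert closed == pytest.approx(res.x[0], abs=1e-9)
            svd = np.linalg.lstsq(
                (r ** -2.0).reshape(-1, 1), df, rcond=None)[0][0]
            assert closed == pytest.approx(svd, abs=1e-9)

    def test_r_below_one_rejected(self):
        with pytest.raises(DomainError):
            fit_barrier_model([(0, 100.0)])

    def test_empty_rejected(self):
        with pytest.raises(DomainError):
            fit_barrier_model([])


class TestFractionReadthrough:
    @pytest.mark.parametrize("at,t,expected", [
        (50.0, 50.0, 0.5), (0.0, 80.0, 0.0), (30.0, 70.0, 0.3),
    ])
    def test_arithmetic(self, at, t, expected):
        table = pd.DataFrame({"lane": ["L1"], "terminated": [t],
                              "antiterminated": [at]})
        out = fraction_readthrough(table)
        assert out["fraction_readthrough"].iloc[0] == pytest.approx(expected)

    def test_always_in_unit_interval(self, rng):
        table = pd.DataFrame({
            "lane": [f"L{i}" for i in range(30)],
            "terminated": rng.uniform(0.01, 100, 30),
            "antiterminated": rng.uniform(0.01, 100, 30)})
        frac = fraction_readthrough(table)["fraction_readthrough"]
        assert ((frac >= 0) & (frac <= 1)).all()

    def test_double_zero_lane_rejected(self):
        table = pd.DataFrame({"lane": ["L1"], "terminated": [0.0],
                              "antiterminated": [0.0]})
        with pytest.raises(DomainError):
            fraction_readthrough(table)
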