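"""Residuals, linear adjustment, CMAE and leave-one-out cross-validation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from shiftdiscrim import (
    Nucleus,
    ShiftObservation,
    ShiftTable,
    ValidationError,
    cmae,
    corrected_shifts,
    evaluate_candidate,
    linear_fit,
    loo_cross_validation,
    mae,
    residuals,
)

from conftest import PW91, B3LYP, loo_press_explicit


def table_from(exp, calc, nucleus=Nucleus.C13, candidate="X", method="m"):
    obs = tuple(
        ShiftObservation(f"p{i}", float(e), float(c))
        for i, (e, c) in enumerate(zip(exp, calc))
    )
    return ShiftTable(nucleus, candidate, method, obs)


@st.composite
def random_tables(draw):
    """Affine-plus-noise shift tables built from a seeded numpy stream."""
    n = draw(st.integers(5, 24))
    seed = draw(st.integers(0, 2**20))
    slope = draw(st.floats(0.7, 1.3))
    intercept = draw(st.floats(-10, 15))
    sd = draw(st.floats(0.0, 5.0))
    rng = np.random.default_rng(seed)
    exp = rng.uniform(10, 180, size=n)
    calc = slope * exp + intercept + rng.normal(0, sd, size=n)
    return table_from(exp, calc)


class TestResidualsAndMae:
    def test_known_residues(self, builtin):
        rs = residuals(builtin.table("S", "C13", PW91))
        pos9 = builtin.table("S", "C13", PW91).positions.index("9")
        assert rs[pos9] == pytest.approx(30.6, abs=1e-12)
        rs_n = residuals(builtin.table("N", "C13", PW91))
        pos2 = builtin.table("N", "C13", PW91).positions.index("2")
        assert rs_n[pos2] == pytest.approx(9.3, abs=1e-12)

    def test_identity_residues_zero(self):
        t = table_from([1, 2, 3, 4], [1, 2, 3, 4])
        assert residuals(t).tolist() == [0, 0, 0, 0]
        assert mae(t) == 0.0

    @pytest.mark.parametrize(
        "candidate, nucleus, expected",
        [("N", "C13", 4.5778), ("N", "H1", 0.4069), ("O", "C13", 5.5056)],
    )
    def test_mean_absolute_error_fixture_values(self, builtin, candidate, nucleus, expected):
        assert mae(builtin.table(candidate, nucleus, PW91)) == pytest.approx(
            expected, abs=5e-4
        )


class TestLinearFit:
    def test_adjustment_fit_on_reference_data(self, builtin):
        fit = linear_fit(builtin.table("N", "C13", PW91))
        assert fit.a == pytest.approx(0.9777, abs=5e-4)
        assert fit.b == pytest.approx(6.9104, abs=5e-4)
        assert fit.r2 == pytest.approx(0.9905, abs=5e-4)

    def test_predictive_fit_dispersion(self, builtin):
        fit = linear_fit(builtin.table("N", "C13", PW91), response="exp")
        assert fit.s == pytest.approx(3.2706, abs=5e-4)
        assert fit.f_stat == pytest.approx(1672.78, rel=1e-4)

    def test_identity_data(self):
        fit = linear_fit(table_from([1, 2, 3, 4], [1, 2, 3, 4]))
        assert (fit.a, fit.b, fit.r2, fit.s) == (1.0, 0.0, 1.0, 0.0)

    def test_exact_affine_recovered(self):
        exp = [10, 20, 30, 40, 50, 60]
        t = table_from(exp, [2 * e + 5 for e in exp])
        fit = linear_fit(t)
        assert fit.a == pytest.approx(2.0, abs=1e-12)
        assert fit.b == pytest.approx(5.0, abs=1e-10)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)

    def test_degenerate_predictor_rejected(self):
        with pytest.raises(ValidationError, match="degenerate"):
            linear_fit(table_from([5, 5, 5, 5], [1, 2, 3, 4]))

    def test_r2_consistency_with_sums_of_squares(self, builtin):
        for response in ("calc", "exp"):
            fit = linear_fit(builtin.table("O", "H1", B3LYP), response=response)
            assert fit.r2 == pytest.approx(1 - fit.sse / fit.tss, abs=1e-12)


class TestCorrectedShifts:
    def test_inverts_exact_affine_map(self):
        exp = np.array([10.0, 20, 30, 40, 50, 60])
        t = table_from(exp, 2 * exp + 5)
        assert corrected_shifts(t) == pytest.approx(exp, abs=1e-9)
        assert cmae(t) == pytest.approx(0.0, abs=1e-10)

    def test_identity_fit_leaves_calc_unchanged(self):
        t = table_from([1, 2, 3, 4.0], [1.5, 2.5, 3.5, 4.5])
        # slope 1, intercept 0.5: corrected = calc - 0.5 = exp
        assert cmae(t) == pytest.approx(0.0, abs=1e-10)

    def test_fixture_cmae(self, builtin):
        assert cmae(builtin.table("N", "C13", PW91)) == pytest.approx(2.2235, abs=5e-4)

    def test_wrong_direction_fit_rejected(self, builtin):
        t = builtin.table("N", "C13", PW91)
        with pytest.raises(ValueError, match="calculated-on-experimental"):
            corrected_shifts(t, linear_fit(t, response="exp"))


class TestLooCrossValidation:
    def test_fixture_diagnostics(self, builtin):
        cv = loo_cross_validation(builtin.table("N", "C13", PW91))
        assert cv.press == pytest.approx(205.745, abs=5e-3)
        assert cv.s_press == pytest.approx(0.8965, abs=5e-4)
        assert cv.q2 == pytest.approx(0.98861, abs=5e-5)

    def test_proton_press_reproduced_exactly(self, builtin):
        cv = loo_cross_validation(builtin.table("N", "H1", PW91))
        assert cv.press == pytest.approx(2.6661, abs=5e-4)

    def test_perfect_affine_gives_zero_press(self):
        exp = [10, 20, 30, 40, 50]
        cv = loo_cross_validation(table_from(exp, [2 * e + 5 for e in exp]))
        assert cv.press == pytest.approx(0.0, abs=1e-18)
        assert cv.q2 == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("response", ["exp", "calc"])
    def test_matches_explicit_refit_oracle(self, builtin, response):
        t = builtin.table("S", "C13", B3LYP)
        x, y = ((t.delta_calc, t.delta_exp) if response == "exp"
                else (t.delta_exp, t.delta_calc))
        press, preds = loo_press_explicit(x, y)
        cv = loo_cross_validation(t, response=response)
        assert cv.press == pytest.approx(press, rel=1e-12)
        assert np.asarray(cv.loo_predictions) == pytest.approx(preds, rel=1e-12)

    def test_s_press_variants(self, builtin):
        t = builtin.table("N", "C13", PW91)
        default = loo_cross_validation(t)
        alt = loo_cross_validation(t, s_press_variant="sqrt_of_ratio")
        assert default.s_press == pytest.approx(np.sqrt(default.press) / 16, rel=1e-12)
        assert alt.s_press == pytest.approx(np.sqrt(default.press / 16), rel=1e-12)

    def test_k_controls_denominator(self, builtin):
        t = builtin.table("N", "C13", PW91)
        assert loo_cross_validation(t, k=2).s_press == pytest.approx(
            np.sqrt(loo_cross_validation(t).press) / 15, rel=1e-12
        )
        with pytest.raises(ValidationError):
            loo_cross_validation(t, k=0)

    def test_near_degenerate_omission_rejected(self):
        # removing the one informative point leaves zero predictor variance
        t = table_from([1, 1, 1, 2], [1, 1, 1, 2])
        with pytest.raises(ValidationError):
            loo_cross_validation(t, response="calc")


class TestEvaluateCandidate:
    def test_bundles_all_statistics(self, builtin):
        sc = evaluate_candidate(builtin.table("FA", "C13", B3LYP))
        assert sc.mae == pytest.approx(4.92, abs=5e-3)
        assert 100 * sc.q2 == pytest.approx(97.81, abs=5e-2)
        assert sc.fit.response == "calc" and sc.cv.response == "exp"
        assert min(sc.rs) >= 0.0

    def test_identity_table_is_perfect(self):
        sc = evaluate_candidate(table_from([1, 2, 3, 4], [1, 2, 3, 4]))
        assert sc.mae == sc.cmae == 0.0
        assert sc.fit.r2 == sc.cv.q2 == 1.0

    def test_deterministic(self, builtin):
        t = builtin.table("O", "H1", PW91)
        assert evaluate_candidate(t) == evaluate_candidate(t)


class TestStatisticalProperties:
    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(random_tables())
    def test_press_dominates_sse_and_q2_below_r2(self, table):
        for response in ("exp", "calc"):
            cv = loo_cross_validation(table, response=response)
            fit = linear_fit(table, response=response)
            assert cv.press >= cv.sse - 1e-9
            assert cv.q2 <= fit.r2 + 1e-12

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(random_tables(), st.floats(-40, 40))
    def test_translation_changes_only_intercept(self, table, c):
        shifted = table_from(table.delta_exp, np.asarray(table.delta_calc) + c)
        f0, f1 = linear_fit(table), linear_fit(shifted)
        assert f1.a == pytest.approx(f0.a, abs=1e-9)
        assert f1.b == pytest.approx(f0.b + c, abs=1e-7)
        assert f1.r2 == pytest.approx(f0.r2, abs=1e-9)
        assert cmae(shifted) == pytest.approx(cmae(table), abs=1e-7)
        for response in ("exp", "calc"):
            cv0 = loo_cross_validation(table, response=response)
            cv1 = loo_cross_validation(shifted, response=response)
            assert cv1.press == pytest.approx(cv0.press, rel=1e-9, abs=1e-9)
            assert cv1.q2 == pytest.approx(cv0.q2, abs=1e-9)
            assert cv1.s_press == pytest.approx(cv0.s_press, rel=1e-9, abs=1e-9)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(random_tables(), st.floats(0.3, 3.0))
    def test_scaling_calculated_shifts(self, table, lam):
        scaled = table_from(table.delta_exp, lam * np.asarray(table.delta_calc))
        # response = calc: PRESS scales as lambda^2, Q2 and R2 unchanged
        cv0 = loo_cross_validation(table, response="calc")
        cv1 = loo_cross_validation(scaled, response="calc")
        assert cv1.press == pytest.approx(lam**2 * cv0.press, rel=1e-9, abs=1e-9)
        assert cv1.q2 == pytest.approx(cv0.q2, abs=1e-9)
        # response = exp: rescaling the predictor leaves predictions alone
        cve0 = loo_cross_validation(table, response="exp")
        cve1 = loo_cross_validation(scaled, response="exp")
        assert cve1.press == pytest.approx(cve0.press, rel=1e-9, abs=1e-9)
        assert linear_fit(scaled).r2 == pytest.approx(linear_fit(table).r2, abs=1e-9)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(random_tables(), st.randoms(use_true_random=False))
    def test_permutation_invariance(self, table, rnd):
        order = list(range(len(table)))
        rnd.shuffle(order)
        exp = [table.delta_exp[i] for i in order]
        calc = [table.delta_calc[i] for i in order]
        shuffled = table_from(exp, calc)
        assert mae(shuffled) == pytest.approx(mae(table), rel=1e-12)
        assert cmae(shuffled) == pytest.approx(cmae(table), rel=1e-9, abs=1e-12)
        cv0, cv1 = loo_cross_validation(table), loo_cross_validation(shuffled)
        assert cv1.press == pytest.approx(cv0.press, rel=1e-9, abs=1e-12)
        assert cv1.q2 == pytest.approx(cv0.q2, abs=1e-9)
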