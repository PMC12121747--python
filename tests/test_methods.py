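import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from rdrtb.frames import ARM_PLACEBO, ARM_TREATMENT
from rdrtb.methods import (
    ArmCorrection,
    CorrectionLedger,
    DegenerateScaleError,
    InsufficientDonorsError,
    assign_gamma_delta,
    build_correction_ledger,
    compute_alpha,
    compute_alpha0,
    compute_beta,
    compute_efficacy_rates,
    compute_phi,
    compute_sign_rho,
    exponential_weight,
    final_adjust,
    rd_impute,
    rd_rtb_impute,
    rtb_adjust,
    rtb_impute,
)
from rdrtb.mi import ImputationDraw, ImputationModelSpec, impute_monotone

from conftest import make_frame


def _draw_from(frame, imputed_rows, visits=(4,)):
    mask = np.zeros((len(frame), 5), dtype=bool)
    for r in imputed_rows:
        for j in visits:
            mask[r, j] = True
    return ImputationDraw(frame.copy(), mask, 0)


class TestRtbAdjust:
    def test_recenters_to_baseline_mean(self):
        frame = make_frame([
            (1, "treatment", [25, 20, 18, 14, 10], 2, False),
            (2, "treatment", [27, 22, 20, 16, 14], 2, False),
            (3, "treatment", [25, 22, 20, 18, 16], None, False),
            (4, "placebo", [25, 24, 24, 23, 23], None, False),
        ])
        out = rtb_adjust(_draw_from(frame, [0, 1]))
        # imputed values [10, 14], baselines [25, 27] -> means 12, 26 -> [24, 28]
        assert out.frame.loc[0, "y4"] == pytest.approx(24.0)
        assert out.frame.loc[1, "y4"] == pytest.approx(28.0)
        # observed subjects untouched
        assert out.frame.loc[2, "y4"] == 16

    def test_noop_when_means_already_equal(self):
        frame = make_frame([
            (1, "treatment", [24, 23, 22, 21, 20], 4, False),
            (2, "treatment", [26, 25, 24, 23, 30], 4, False),
            (3, "placebo", [25, 24, 24, 23, 23], None, False),
        ])
        out = rtb_adjust(_draw_from(frame, [0, 1]))
        assert out.frame.loc[0, "y4"] == pytest.approx(20.0)
        assert out.frame.loc[1, "y4"] == pytest.approx(30.0)

    def test_recentering_invariant_any_input(self, sim_pair):
        _, observed = sim_pair
        spec = ImputationModelSpec(donor_rule="all_observed", n_imputations=3)
        for d in rtb_impute(observed, spec, 0):
            for arm in (ARM_TREATMENT, ARM_PLACEBO):
                rows = d.imputed_mask[:, -1] & (d.frame["arm"] == arm).to_numpy()
                if not rows.any():
                    continue
                sub = d.frame.loc[rows]
                assert sub["y4"].mean() == pytest.approx(sub["y0"].mean(), abs=1e-9)


class TestLedgerPieces:
    def test_beta_direct_arithmetic(self):
        frame = make_frame([
            (1, "treatment", [24, 20, 15, 12, 10], 2, False),
            (2, "treatment", [26, 22, 18, 16, 14], 2, False),
        ])
        assert compute_beta(_draw_from(frame, [0, 1]), arm="treatment") == pytest.approx(13.0)

    def test_beta_zero_and_sign(self):
        frame = make_frame([(1, "treatment", [25, 25, 25, 25, 25], 2, False)])
        assert compute_beta(_draw_from(frame, [0]), arm="treatment") == 0.0
        improving = make_frame([(1, "treatment", [25, 20, 18, 16, 15], 2, False)])
        assert compute_beta(_draw_from(improving, [0]), arm="treatment") > 0

    def test_alpha0_frozen_value(self):
        # w = exp(-5 * 4/8) = e^-2.5 = 0.0820849986..., alpha0 = 3 * w
        alpha0 = compute_alpha0(3.0, 30.0, 25.0, 4.0, 8.0)
        assert alpha0 == pytest.approx(0.2462549959, abs=1e-9)

    def test_alpha0_limits(self):
        assert compute_alpha0(3.0, 25.0, 25.0, 4.0, 8.0) == pytest.approx(3.0)
        assert compute_alpha0(0.0, 30.0, 25.0, 4.0, 8.0) == 0.0
        with pytest.raises(ValueError):
            compute_alpha0(3.0, 30.0, 25.0, 9.0, 8.0)  # t > T

    @given(
        beta=st.floats(-20, 20),
        y0=st.floats(15, 35),
        min_y0=st.floats(10, 15),
        t=st.floats(0.5, 8.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_alpha0_identity_alpha0_equals_w_beta(self, beta, y0, min_y0, t):
        w = exponential_weight(y0, min_y0, t, 8.0)
        alpha0 = compute_alpha0(beta, y0, min_y0, t, 8.0)
        assert alpha0 == w * beta  # exact, not approx
        assert 0 < w <= 1
        assert abs(alpha0) <= abs(beta)

    def test_inverse_time_exponent_form(self):
        w = exponential_weight(30.0, 25.0, 4.0, 8.0, exponent_form="inverse_time")
        assert w == pytest.approx(np.exp(-5.0 / 32.0))

    def test_efficacy_rates_direct(self):
        # RD deltas -4 (4 weeks) and -6 (8 weeks): V_rd = -10/12 points/week
        frame = make_frame([
            (1, "treatment", [25, 24, 21, 21, 21, 21], 3, True),
            (2, "treatment", [26, 25, 23, 21, 20, 20], 5, True),
            (3, "treatment", [25, 24, 23, 22, 21, 21], 3, False),
        ], n_visits=5)
        v_rd, v_mis = compute_efficacy_rates(frame, "treatment")
        assert v_rd == pytest.approx(-10.0 / 12.0)
        assert v_mis == pytest.approx(-2.0 / 4.0)  # single subject, -2 over 4 weeks

    def test_rescue_substitution_uses_best_improvement(self):
        frame = make_frame([
            (1, "placebo", [25, 24, 23, 23, 23], 3, True),   # delta -2, 4 wk
            (2, "placebo", [26, 20, 18, 18, 18], 2, False),  # delta -6, 2 wk (best)
        ])
        v_rd, v_mis = compute_efficacy_rates(frame, "placebo", rescue_substitution=True)
        assert v_rd == pytest.approx(-6.0 / 4.0)
        assert v_mis == pytest.approx(-6.0 / 2.0)

    def test_sign_rho_convention(self):
        assert compute_sign_rho(-0.5, -0.8) == 1   # rho = 0.3
        assert compute_sign_rho(-0.8, -0.5) == -1  # antisymmetric
        assert compute_sign_rho(-0.5, -0.5) == 1   # tie rule

    def test_phi_scale_symmetry(self):
        assert abs(1 - 4 / 8) == pytest.approx(0.5)
        assert abs(1 - 12 / 8) == pytest.approx(0.5)
        frame = make_frame([
            (1, "treatment", [25, 24, 23, 22, 21], 2, False),   # withdrawer
            (2, "treatment", [25, 23, 21, 19, 17], None, False),  # completer, |chg| 8
            (3, "treatment", [25, 24, 23, 22, 17], None, False),  # completer, |chg| 8
        ])
        stack = frame[[f"y{j}" for j in range(5)]].to_numpy()[None, :, :].copy()
        stack[0, 0, 4] = 21.0  # withdrawer imputed endpoint: |change| 4
        phi0, phi1 = compute_phi(stack, frame, "treatment")
        assert (phi0, phi1) == (pytest.approx(4.0), pytest.approx(8.0))

    def test_phi_degenerate_when_completers_unchanged(self):
        frame = make_frame([
            (1, "treatment", [25, 24, 23, 22, 21], 2, False),
            (2, "treatment", [25, 25, 25, 25, 25], None, False),
        ])
        stack = frame[[f"y{j}" for j in range(5)]].to_numpy()[None, :, :]
        with pytest.raises(DegenerateScaleError):
            compute_phi(stack, frame, "treatment")

    def test_compute_alpha_elementwise(self):
        np.testing.assert_allclose(
            compute_alpha(1, 0.5, np.array([0.2462549959])), [0.1231274979]
        )
        assert compute_alpha(1, 0.0, 5.0) == 0.0
        np.testing.assert_allclose(
            compute_alpha(-1, 0.5, np.array([0.2, -0.4])), [-0.1, 0.2]
        )

    def test_gamma_delta_assignment(self):
        g, d, arm = assign_gamma_delta(
            {"treatment": np.array([0.4, 0.4]), "placebo": np.array([-0.1, -0.1])}
        )
        assert (g, d, arm) == (pytest.approx(0.4), pytest.approx(-0.1), "treatment")
        g, d, arm = assign_gamma_delta(
            {"treatment": np.array([0.2]), "placebo": np.array([-0.2])}
        )
        assert arm == "treatment"  # tie broken toward treatment
        g, d, arm = assign_gamma_delta(
            {"treatment": np.array([]), "placebo": np.array([])}
        )
        assert g == 0.0 and d == 0.0


class TestFinalAdjust:
    def _ledger(self, frame, alpha_trt, alpha_pbo, w_trt=None, gamma=None):
        ids_t = frame.loc[(frame["arm"] == "treatment") & ~frame["rd_flag"]
                          & frame["withdrawal_visit"].notna(), "id"].to_numpy()
        ids_p = frame.loc[(frame["arm"] == "placebo") & ~frame["rd_flag"]
                          & frame["withdrawal_visit"].notna(), "id"].to_numpy()
        a_t = np.full(ids_t.size, alpha_trt)
        a_p = np.full(ids_p.size, alpha_pbo)
        w_t = np.full(ids_t.size, 0.5 if w_trt is None else w_trt)
        g, d, garm = assign_gamma_delta({"treatment": a_t, "placebo": a_p})
        if gamma is not None:
            g = gamma
        arms = {
            "treatment": ArmCorrection("treatment", ids_t, 1.0, 15.0, w_t, a_t,
                                       -1.0, -1.0, 0.0, 1, 1.0, 2.0, 0.5, a_t),
            "placebo": ArmCorrection("placebo", ids_p, 1.0, 15.0,
                                     np.full(ids_p.size, 0.5), a_p,
                                     -1.0, -1.0, 0.0, 1, 1.0, 2.0, 0.5, a_p),
        }
        return CorrectionLedger(arms, g, d, garm, 8.0)

    def test_zero_alpha_zero_gamma_is_identity(self, toy_frame):
        draws = rd_impute(toy_frame, ImputationModelSpec("rd_only", 3), 0)
        ledger = self._ledger(toy_frame, 0.0, 0.0)
        for d in draws:
            out = final_adjust(d, ledger)
            pd.testing.assert_frame_equal(out.frame, d.frame)

    def test_delta_arm_gets_exactly_alpha(self, toy_frame):
        draws = rd_impute(toy_frame, ImputationModelSpec("rd_only", 3), 0)
        ledger = self._ledger(toy_frame, 0.5, 0.123)  # treatment is gamma arm
        out = final_adjust(draws[0], ledger)
        pbo_imp = (draws[0].frame["arm"] == "placebo").to_numpy() & draws[0].imputed_mask[:, -1]
        np.testing.assert_allclose(
            out.frame.loc[pbo_imp, "y4"].to_numpy(),
            draws[0].frame.loc[pbo_imp, "y4"].to_numpy() + 0.123,
        )

    def test_gamma_arm_with_unit_weight_gets_exactly_alpha(self, toy_frame):
        draws = rd_impute(toy_frame, ImputationModelSpec("rd_only", 3), 0)
        ledger = self._ledger(toy_frame, 0.5, 0.1, w_trt=1.0, gamma=2.0)
        out = final_adjust(draws[0], ledger)
        trt_imp = (draws[0].frame["arm"] == "treatment").to_numpy() & draws[0].imputed_mask[:, -1]
        np.testing.assert_allclose(
            out.frame.loc[trt_imp, "y4"].to_numpy(),
            draws[0].frame.loc[trt_imp, "y4"].to_numpy() + 0.5,
        )


class TestRdAndRdRtb:
    def test_rd_no_missing_returns_input(self, sim_pair):
        truth, _ = sim_pair
        draws = rd_impute(truth, ImputationModelSpec("rd_only", 3), 0)
        for d in draws:
            pd.testing.assert_frame_equal(d.frame, truth)

    def test_insufficient_rd_donors_message(self):
        frame = make_frame([
            (1, "treatment", [25, 24, 23, 22, 21], 2, True),
            (2, "treatment", [26, 25, None, None, None], 2, False),
            (3, "placebo", [25, 24, 23, 22, 21], 2, True),
            (4, "placebo", [26, 25, None, None, None], 2, False),
        ])
        with pytest.raises(InsufficientDonorsError, match="RD donors"):
            rd_impute(frame, ImputationModelSpec("rd_only", 3), 0)

    def test_ledger_identity_alpha0_w_beta(self, sim_pair):
        _, observed = sim_pair
        draws = rd_impute(observed, ImputationModelSpec("rd_only", 4), 1)
        ledger = build_correction_ledger(observed, draws)
        for rec in ledger.arms.values():
            np.testing.assert_array_equal(rec.alpha0, rec.w * rec.beta)
            assert np.all(np.abs(rec.alpha0) <= abs(rec.beta) + 1e-12)
            assert rec.sign_rho in (1, -1)
        assert abs(ledger.gamma) >= abs(ledger.delta)

    def test_sign_coherence_follows_rate_ordering(self, sim_pair):
        _, observed = sim_pair
        draws = rd_impute(observed, ImputationModelSpec("rd_only", 4), 1)
        ledger = build_correction_ledger(observed, draws, rescue_substitution=False)
        for arm, rec in ledger.arms.items():
            v_rd, v_mis = compute_efficacy_rates(observed, arm, rescue_substitution=False)
            assert rec.sign_rho == compute_sign_rho(v_rd, v_mis)
            if rec.beta > 0:
                assert np.all(np.sign(rec.alpha) == rec.sign_rho) or rec.scale == 0

    def test_phi_equal_reduces_to_rd(self, toy_frame):
        # scale = |1 - phi0/phi1| = 0 forces alpha = 0 and gamma = 0, so the
        # corrected draws coincide with the RD draws
        spec = ImputationModelSpec("rd_only", 3)
        draws = rd_impute(toy_frame, spec, 7)
        ledger = build_correction_ledger(toy_frame, draws)
        for arm in ledger.arms:
            ledger.arms[arm].phi0 = ledger.arms[arm].phi1
            ledger.arms[arm].scale = 0.0
            ledger.arms[arm].alpha = 0.0 * ledger.arms[arm].alpha
        ledger.gamma = 0.0
        ledger.delta = 0.0
        for d in draws:
            out = final_adjust(d, ledger)
            pd.testing.assert_frame_equal(out.frame, d.frame)

    def test_rd_rtb_deterministic_under_seed(self, sim_pair):
        _, observed = sim_pair
        spec = ImputationModelSpec("rd_only", 3)
        a = rd_rtb_impute(observed, spec, np.random.default_rng(5))
        b = rd_rtb_impute(observed, spec, np.random.default_rng(5))
        for da, db in zip(a, b):
            pd.testing.assert_frame_equal(da.frame, db.frame)

    def test_rd_rtb_matches_rd_plus_ledger_adjustment(self, sim_pair):
        _, observed = sim_pair
        spec = ImputationModelSpec("rd_only", 3)
        rd_draws = rd_impute(observed, spec, np.random.default_rng(5))
        corrected, ledger = rd_rtb_impute(
            observed, spec, np.random.default_rng(5), return_ledger=True
        )
        recomputed = [final_adjust(d, ledger) for d in rd_draws]
        for da, db in zip(corrected, recomputed):
            pd.testing.assert_frame_equal(da.frame, db.frame)
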