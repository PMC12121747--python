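"""The RTB, RD and RD-RTB imputation strategies.

Three ways to complete a monotone-missing trial frame:

* **RTB (return to baseline)** — impute under the MAR model, then re-center
  each arm's imputed final-visit values so their mean equals the mean
  baseline of the imputed subjects (Qu-and-Dai-style mean re-centering
  rather than carrying each subject's own baseline forward).
* **RD (retrieved dropout)** — impute from RD-only donor models, so non-RD
  withdrawers inherit the outcome/history relationship of subjects who
  withdrew but kept contributing data.
* **RD-RTB** — RD imputation followed by a signed, exponentially weighted,
  φ-scaled correction toward (or away from) baseline.  Per arm:

  - ``beta = mean(Y0) - mean(imputed YJ)`` over imputed subjects — the full
    return-to-baseline correction;
  - ``w_i = exp(-(Y_i0 - min Y0) * t_i / T)`` shrinks it per subject by
    baseline severity and exposure time, giving ``alpha0_i = w_i * beta``;
  - the sign of ``rho``, the gap between RD and non-RD pre-withdrawal
    efficacy rates, decides whether the correction pulls the RD-imputed
    values toward baseline (``rho > 0``) or pushes them further from it
    (``rho < 0``), compensating the direction in which the RD donors
    misrepresent the non-RD withdrawers;
  - ``|1 - phi0/phi1|`` scales it by how much withdrawers' imputed change
    differs from completers' observed change;
  - the arm with the larger mean |alpha| (the γ arm) additionally pulls each
    subject's correction toward that mean with weight ``1 - w_i``.

Efficacy-rate convention: all change quantities are signed raw-score
changes (HAMD-17 decreases under effective treatment, so improvement is
negative).  The pre-withdrawal efficacy *rate* of a group is the summed
change from baseline divided by the summed exposure weeks, in points/week;
``rho = V_rd - V_mis`` is therefore positive exactly when the non-RD
withdrawers were improving *faster* (more negative rate) than the RD
withdrawers, in which case the correction is applied toward baseline for
the subjects whose RD-based imputation borrowed the slower RD trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .frames import (
    ARM_PLACEBO,
    ARM_TREATMENT,
    ARMS,
    WEEKS_PER_VISIT,
    StateError,
    clamp_scores,
    score_matrix,
    validate_trial_frame,
    visit_columns,
    withdrawal_vector,
)
from .mi import (
    ImputationDraw,
    ImputationModelSpec,
    SingularFitError,
    _impute_stack,
    impute_monotone,
)


class InsufficientDonorsError(SingularFitError):
    """Too few RD donors to fit the imputation models."""


class DegenerateScaleError(ZeroDivisionError):
    """phi1 = 0: completers show no change, the phi ratio is undefined."""


# ---------------------------------------------------------------------------
# correction ledger
# ---------------------------------------------------------------------------


@dataclass
class ArmCorrection:
    """Per-arm record of every quantity entering the RD-RTB correction."""

    arm: str
    subject_ids: np.ndarray  # non-RD withdrawers, the subjects being corrected
    beta: float
    min_baseline: float
    w: np.ndarray  # exponential weight per subject, in (0, 1]
    alpha0: np.ndarray  # w * beta
    v_rd: float  # signed change rate of RD withdrawers, points/week
    v_mis: float  # signed change rate of non-RD withdrawers, points/week
    rho: float
    sign_rho: int
    phi0: float
    phi1: float
    scale: float  # |1 - phi0/phi1|
    alpha: np.ndarray  # sign_rho * scale * alpha0


@dataclass
class CorrectionLedger:
    """Both arms' corrections plus the γ/δ group assignment."""

    arms: dict[str, ArmCorrection]
    gamma: float
    delta: float
    gamma_arm: str
    total_weeks: float

    def to_dict(self) -> dict:
        out = {
            "gamma": self.gamma,
            "delta": self.delta,
            "gamma_arm": self.gamma_arm,
            "total_weeks": self.total_weeks,
            "arms": {},
        }
        for arm, rec in self.arms.items():
            out["arms"][arm] = {
                "beta": rec.beta,
                "min_baseline": rec.min_baseline,
                "v_rd": rec.v_rd,
                "v_mis": rec.v_mis,
                "rho": rec.rho,
                "sign_rho": rec.sign_rho,
                "phi0": rec.phi0,
                "phi1": rec.phi1,
                "scale": rec.scale,
                "subject_ids": [int(s) for s in rec.subject_ids],
                "w": rec.w.tolist(),
                "alpha0": rec.alpha0.tolist(),
                "alpha": rec.alpha.tolist(),
            }
        return out


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------


def exponential_weight(
    y_i0: np.ndarray | float,
    min_y0: float,
    t_i: np.ndarray | float,
    total_weeks: float,
    exponent_form: str = "exposure_ratio",
) -> np.ndarray | float:
    """Baseline/exposure shrinkage weight ``w_i`` in (0, 1].

    Default reading: ``exp(-(Y_i0 - min Y0) * t_i / T)`` — the excess
    baseline severity scaled by the fraction of the planned exposure time
    actually spent on treatment.  The alternative typographic reading
    ``exp(-(Y_i0 - min Y0) / (T * t_i))`` is available as
    ``exponent_form="inverse_time"`` but is not the default.
    """
    if total_weeks <= 0:
        raise ValueError("total_weeks must be positive")
    t = np.asarray(t_i, dtype=float)
    if np.any(t <= 0) or np.any(t > total_weeks):
        raise ValueError("exposure time t_i must lie in (0, T]")
    excess = np.asarray(y_i0, dtype=float) - min_y0
    if np.any(excess < 0):
        raise ValueError("baseline below the arm minimum")
    if exponent_form == "exposure_ratio":
        w = np.exp(-excess * t / total_weeks)
    elif exponent_form == "inverse_time":
        w = np.exp(-excess / (total_weeks * t))
    else:
        raise ValueError(f"unknown exponent_form {exponent_form!r}")
    return w if w.ndim else float(w)


def compute_alpha0(
    beta: float,
    y_i0: np.ndarray | float,
    min_y0: float,
    t_i: np.ndarray | float,
    total_weeks: float,
    exponent_form: str = "exposure_ratio",
) -> np.ndarray | float:
    """Per-subject damped correction ``alpha0_i = w_i * beta``."""
    w = exponential_weight(y_i0, min_y0, t_i, total_weeks, exponent_form)
    return w * beta


def compute_beta(draw: ImputationDraw, missing_ids=None, arm: str | None = None) -> float:
    """Full RTB correction for one draw: mean baseline − mean imputed final value.

    Means are taken over the arm's imputed subjects only.  Returns 0.0 for an
    arm with nothing imputed.
    """
    y = score_matrix(draw.frame)
    rows = _imputed_final_rows(draw, missing_ids, arm)
    if rows.size == 0:
        return 0.0
    return float(y[rows, 0].mean() - y[rows, -1].mean())


def _imputed_final_rows(draw: ImputationDraw, missing_ids, arm: str | None) -> np.ndarray:
    frame = draw.frame
    final = draw.imputed_mask[:, -1]
    if missing_ids is not None:
        final = final & frame["id"].isin(list(missing_ids)).to_numpy()
    if arm is not None:
        final = final & (frame["arm"] == arm).to_numpy()
    return np.flatnonzero(final)


def compute_efficacy_rates(
    frame: pd.DataFrame,
    arm: str,
    rescue_substitution: bool = True,
    rescue_arm: str = ARM_PLACEBO,
) -> tuple[float, float]:
    """Pre-withdrawal efficacy rates ``(V_rd, V_mis)`` for one arm.

    Each withdrawer contributes the signed change from baseline to the last
    pre-withdrawal visit, ``Y_{w-1} - Y_0`` (negative = improvement on
    HAMD-17), and the weeks elapsed to that visit; the rate is the ratio of
    sums, in points/week.  ``V_rd`` covers RD withdrawers, ``V_mis`` non-RD
    withdrawers.

    If ``rescue_substitution`` is on, subjects in the rescue-medication arm
    have their change replaced by the maximum change in the improving
    direction among all of that arm's withdrawers, as remedial-medication
    subjects are judged by the best pre-withdrawal response rather than
    their own.
    """
    y = score_matrix(frame)
    wvis = withdrawal_vector(frame)
    rd = frame["rd_flag"].to_numpy(dtype=bool)
    in_arm = (frame["arm"] == arm).to_numpy()
    withdrawn = in_arm & (wvis >= 0)
    if not withdrawn.any():
        raise ValueError(f"arm {arm!r} has no withdrawers")
    rows = np.flatnonzero(withdrawn)
    last_pre = wvis[rows] - 1
    if np.any(last_pre < 1):
        raise ValueError("every withdrawer needs >= 1 pre-withdrawal post-baseline visit")
    delta = y[rows, last_pre] - y[rows, 0]
    weeks = last_pre * WEEKS_PER_VISIT
    if rescue_substitution and arm == rescue_arm:
        delta = np.full_like(delta, delta.min())  # max change in improving direction
    is_rd = rd[rows]
    out = []
    for mask in (is_rd, ~is_rd):
        if not mask.any():
            out.append(np.nan)
            continue
        total_weeks = weeks[mask].sum()
        if total_weeks <= 0:
            raise ZeroDivisionError("zero total pre-withdrawal duration")
        out.append(float(delta[mask].sum() / total_weeks))
    return out[0], out[1]


def compute_sign_rho(v_rd: float, v_mis: float) -> int:
    """Sign of ``rho = V_rd - V_mis`` (signed rates); ties resolve to +1.

    With signed rates (improvement negative), ``rho`` is positive when the
    non-RD withdrawers were improving faster than the RD withdrawers before
    withdrawal, and the correction is applied toward baseline.
    """
    if not (np.isfinite(v_rd) and np.isfinite(v_mis)):
        raise ValueError("efficacy rates must be finite")
    rho = v_rd - v_mis
    return 1 if rho >= 0 else -1


def compute_phi(
    rd_draws: list[ImputationDraw] | np.ndarray,
    frame: pd.DataFrame,
    arm: str,
) -> tuple[float, float]:
    """``(phi0, phi1)`` for one arm.

    ``phi0`` — mean |change from baseline to final visit| over all
    withdrawers (RD and non-RD) and over the RD-imputed draws; ``phi1`` —
    the same mean over completers (observed, draw-independent).
    """
    y = score_matrix(frame)
    wvis = withdrawal_vector(frame)
    in_arm = (frame["arm"] == arm).to_numpy()
    withdrawn = np.flatnonzero(in_arm & (wvis >= 0))
    completer = np.flatnonzero(in_arm & (wvis < 0))
    if completer.size == 0:
        raise DegenerateScaleError(f"arm {arm!r} has no completers")
    phi1 = float(np.abs(y[completer, -1] - y[completer, 0]).mean())
    if phi1 == 0.0:
        raise DegenerateScaleError("completers show zero mean change; phi ratio undefined")
    if isinstance(rd_draws, np.ndarray):
        stack = rd_draws
    else:
        stack = np.stack([score_matrix(d.frame) for d in rd_draws])
    phi0 = float(np.abs(stack[:, withdrawn, -1] - stack[:, withdrawn, 0]).mean())
    return phi0, phi1


def compute_alpha(
    sign_rho: int, scale: float, alpha0: np.ndarray | float
) -> np.ndarray | float:
    """Final per-subject correction ``alpha_i = sign(rho) * |1 - phi0/phi1| * alpha0_i``."""
    return sign_rho * scale * np.asarray(alpha0, dtype=float)


def assign_gamma_delta(
    alpha_by_arm: dict[str, np.ndarray]
) -> tuple[float, float, str]:
    """Pick the γ arm (larger |mean alpha|); ties go to the treatment arm."""
    means = {
        arm: float(np.mean(a)) if np.size(a) else 0.0 for arm, a in alpha_by_arm.items()
    }
    trt = means.get(ARM_TREATMENT, 0.0)
    pbo = means.get(ARM_PLACEBO, 0.0)
    if abs(trt) >= abs(pbo):
        return trt, pbo, ARM_TREATMENT
    return pbo, trt, ARM_PLACEBO


# ---------------------------------------------------------------------------
# strategy pipelines (array core + public wrappers)
# ---------------------------------------------------------------------------


def _rtb_adjust_stack(stack: np.ndarray, miss: np.ndarray, arm_codes: np.ndarray) -> np.ndarray:
    """Re-center every draw's imputed final-visit values to the baseline mean.

    Per arm and per draw, each imputed final value is shifted by
    (mean baseline − mean imputed final value) of that arm's imputed
    subjects; the same per-arm constant shifts intermediate imputed visits
    so trajectories stay coherent.  Works in place and returns the stack.
    """
    final_imp = miss[:, -1]
    for arm in ARMS:
        rows = np.flatnonzero(final_imp & (arm_codes == arm))
        if rows.size == 0:
            continue
        shift = stack[:, rows, 0].mean(axis=1) - stack[:, rows, -1].mean(axis=1)
        sub_miss = miss[rows]  # (n_rows, J+1)
        adj = shift[:, None, None] * sub_miss[None, :, :]
        stack[:, rows, :] = clamp_scores(stack[:, rows, :] + adj)
    return stack


def rtb_adjust(draw: ImputationDraw, missing_ids=None) -> ImputationDraw:
    """Return-to-baseline re-centering of one completed dataset (one draw)."""
    frame = draw.frame.copy()
    y = score_matrix(frame)
    mask = draw.imputed_mask.copy()
    if missing_ids is not None:
        keep = frame["id"].isin(list(missing_ids)).to_numpy()
        mask = mask & keep[:, None]
    arm_codes = frame["arm"].to_numpy()
    stack = y[None, :, :].copy()
    _rtb_adjust_stack(stack, mask, arm_codes)
    frame[visit_columns(y.shape[1] - 1)] = stack[0]
    return ImputationDraw(frame, draw.imputed_mask.copy(), draw.m)


def rtb_impute(
    frame: pd.DataFrame,
    spec: ImputationModelSpec | None = None,
    rng: np.random.Generator | int | None = None,
) -> list[ImputationDraw]:
    """RTB method: MAR base imputation followed by per-draw re-centering."""
    spec = spec or ImputationModelSpec(donor_rule="all_observed")
    if spec.donor_rule != "all_observed":
        raise ValueError("RTB base imputation uses the all_observed donor rule")
    draws = impute_monotone(frame, spec, rng)
    return [rtb_adjust(d) for d in draws]


def _check_rd_donors(
    frame: pd.DataFrame, n_visits: int, spec: ImputationModelSpec | None = None
) -> None:
    rd = frame["rd_flag"].to_numpy(dtype=bool)
    n_cov = spec.n_covariates(n_visits) if spec is not None else 1
    needed = n_cov + 2  # covariates at the final visit + 2
    for arm in ARMS:
        n_rd = int((rd & (frame["arm"] == arm).to_numpy()).sum())
        if n_rd < needed:
            raise InsufficientDonorsError(
                f"arm {arm!r} has {n_rd} RD donors but the final-visit model needs "
                f">= {needed}; pool visits or reduce the covariate set"
            )


def rd_impute(
    frame: pd.DataFrame,
    spec: ImputationModelSpec | None = None,
    rng: np.random.Generator | int | None = None,
) -> list[ImputationDraw]:
    """RD method: sequential-regression imputation from RD-only donors."""
    spec = spec or ImputationModelSpec(donor_rule="rd_only")
    if spec.donor_rule != "rd_only":
        spec = ImputationModelSpec(
            donor_rule="rd_only",
            n_imputations=spec.n_imputations,
            fit_per_arm=spec.fit_per_arm,
            prior=spec.prior,
        )
    n_visits = validate_trial_frame(frame)
    if frame[visit_columns(n_visits)].isna().any().any():
        _check_rd_donors(frame, n_visits, spec)
    return impute_monotone(frame, spec, rng)


def _build_ledger_arrays(
    y_obs: np.ndarray,
    arm_codes: np.ndarray,
    wvis: np.ndarray,
    rd: np.ndarray,
    ids: np.ndarray,
    rd_stack: np.ndarray,
    miss: np.ndarray,
    total_weeks: float,
    rescue_substitution: bool = True,
    exponent_form: str = "exposure_ratio",
) -> tuple[CorrectionLedger, dict[str, np.ndarray]]:
    """Compute the full correction ledger from observed data and RD-imputed stack.

    Returns the ledger plus a per-arm map of the corrected subjects' row
    indices (for applying the final adjustment).
    """
    arm_records: dict[str, ArmCorrection] = {}
    rows_by_arm: dict[str, np.ndarray] = {}
    n_visits = y_obs.shape[1] - 1
    for arm in ARMS:
        in_arm = arm_codes == arm
        nonrd_rows = np.flatnonzero(in_arm & (wvis >= 0) & ~rd)
        rows_by_arm[arm] = nonrd_rows
        if nonrd_rows.size == 0:
            arm_records[arm] = ArmCorrection(
                arm, ids[nonrd_rows], 0.0, np.nan, np.empty(0), np.empty(0),
                np.nan, np.nan, 0.0, 1, np.nan, np.nan, 0.0, np.empty(0),
            )
            continue
        # beta: arm-level constant, averaged over draws (Eq. 6 on imputed values)
        beta = float(
            y_obs[nonrd_rows, 0].mean() - rd_stack[:, nonrd_rows, -1].mean()
        )
        min_y0 = float(y_obs[nonrd_rows, 0].min())
        t_i = (wvis[nonrd_rows] - 1) * WEEKS_PER_VISIT
        w = np.asarray(
            exponential_weight(y_obs[nonrd_rows, 0], min_y0, t_i, total_weeks, exponent_form)
        )
        alpha0 = w * beta

        # rates and sign from observed pre-withdrawal data
        rd_rows = np.flatnonzero(in_arm & (wvis >= 0) & rd)
        all_wd = np.concatenate([rd_rows, nonrd_rows])
        last_pre = wvis[all_wd] - 1
        delta = y_obs[all_wd, last_pre] - y_obs[all_wd, 0]
        weeks = last_pre * WEEKS_PER_VISIT
        if rescue_substitution and arm == ARM_PLACEBO:
            delta = np.full_like(delta, delta.min())
        is_rd_part = np.zeros(all_wd.size, dtype=bool)
        is_rd_part[: rd_rows.size] = True
        v_rd = float(delta[is_rd_part].sum() / weeks[is_rd_part].sum()) if rd_rows.size else np.nan
        v_mis = float(delta[~is_rd_part].sum() / weeks[~is_rd_part].sum())
        rho = v_rd - v_mis if np.isfinite(v_rd) else 0.0
        sign_rho = 1 if rho >= 0 else -1

        # phi scale from the RD-imputed draws
        wd_rows = all_wd
        completers = np.flatnonzero(in_arm & (wvis < 0))
        phi1 = float(np.abs(y_obs[completers, -1] - y_obs[completers, 0]).mean())
        if phi1 == 0.0:
            raise DegenerateScaleError("completers show zero mean change; phi ratio undefined")
        phi0 = float(np.abs(rd_stack[:, wd_rows, -1] - rd_stack[:, wd_rows, 0]).mean())
        scale = abs(1.0 - phi0 / phi1)
        alpha = sign_rho * scale * alpha0
        arm_records[arm] = ArmCorrection(
            arm, ids[nonrd_rows], beta, min_y0, w, alpha0,
            v_rd, v_mis, float(rho), sign_rho, phi0, phi1, scale, alpha,
        )
    gamma, delta, gamma_arm = assign_gamma_delta(
        {arm: rec.alpha for arm, rec in arm_records.items()}
    )
    ledger = CorrectionLedger(arm_records, gamma, delta, gamma_arm, total_weeks)
    return ledger, rows_by_arm


def _final_adjust_stack(
    stack: np.ndarray,
    miss: np.ndarray,
    ledger: CorrectionLedger,
    rows_by_arm: dict[str, np.ndarray],
) -> np.ndarray:
    """Apply the γ/δ-group corrections to every draw in place."""
    for arm, rec in ledger.arms.items():
        rows = rows_by_arm[arm]
        if rows.size == 0:
            continue
        if arm == ledger.gamma_arm:
            adj = rec.alpha + (1.0 - rec.w) * (ledger.gamma - rec.alpha)
        else:
            adj = rec.alpha
        sub_miss = miss[rows]
        stack[:, rows, :] = clamp_scores(
            stack[:, rows, :] + adj[None, :, None] * sub_miss[None, :, :]
        )
    return stack


def final_adjust(draw: ImputationDraw, ledger: CorrectionLedger) -> ImputationDraw:
    """Apply the ledger's corrections to one completed dataset.

    δ-arm imputed final values get ``+alpha_i``; γ-arm values get
    ``+alpha_i + (1 - w_i)(γ - alpha_i)``.  Intermediate imputed visits of a
    subject receive the same per-subject shift; observed cells are untouched.
    """
    if set(ledger.arms) != set(ARMS):
        raise StateError("ledger must cover both arms")
    frame = draw.frame.copy()
    y = score_matrix(frame)
    ids = frame["id"].to_numpy()
    rows_by_arm = {}
    for arm, rec in ledger.arms.items():
        pos = {s: i for i, s in enumerate(ids)}
        rows_by_arm[arm] = np.array([pos[s] for s in rec.subject_ids], dtype=int)
    stack = y[None, :, :].copy()
    _final_adjust_stack(stack, draw.imputed_mask, ledger, rows_by_arm)
    frame[visit_columns(y.shape[1] - 1)] = stack[0]
    return ImputationDraw(frame, draw.imputed_mask.copy(), draw.m)


def build_correction_ledger(
    frame: pd.DataFrame,
    rd_draws: list[ImputationDraw],
    rescue_substitution: bool = True,
    exponent_form: str = "exposure_ratio",
) -> CorrectionLedger:
    """Assemble the RD-RTB correction ledger from a frame and its RD draws."""
    n_visits = validate_trial_frame(frame)
    y_obs = score_matrix(frame, n_visits)
    stack = np.stack([score_matrix(d.frame, n_visits) for d in rd_draws])
    ledger, _ = _build_ledger_arrays(
        y_obs,
        frame["arm"].to_numpy(),
        withdrawal_vector(frame),
        frame["rd_flag"].to_numpy(dtype=bool),
        frame["id"].to_numpy(),
        stack,
        rd_draws[0].imputed_mask,
        total_weeks=n_visits * WEEKS_PER_VISIT,
        rescue_substitution=rescue_substitution,
        exponent_form=exponent_form,
    )
    return ledger


def rd_rtb_impute(
    frame: pd.DataFrame,
    spec: ImputationModelSpec | None = None,
    rng: np.random.Generator | int | None = None,
    rescue_substitution: bool = True,
    exponent_form: str = "exposure_ratio",
    return_ledger: bool = False,
):
    """RD-RTB method: RD imputation plus the signed weighted RTB correction.

    Runs the RD pass, builds the correction ledger (β, w_i, rates, sign, φ
    scale, γ/δ) and applies the final adjustment to every draw.  With
    ``return_ledger=True`` returns ``(draws, ledger)``.
    """
    draws = rd_impute(frame, spec, rng)
    ledger = build_correction_ledger(
        frame, draws, rescue_substitution=rescue_substitution, exponent_form=exponent_form
    )
    corrected = [final_adjust(d, ledger) for d in draws]
    if return_ledger:
        return corrected, ledger
    return corrected
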