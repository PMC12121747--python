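"""Trial-data containers, schema and validation.

A trial frame is a wide-format :class:`pandas.DataFrame`, one row per
subject, with columns::

    id, arm, y0, y1, ..., yJ, withdrawal_visit, rd_flag

``y0`` is the baseline score and ``yJ`` the final-visit score.  A *truth*
frame is fully observed; an *observed* frame has ``NaN`` at every visit from
the withdrawal visit onward for non-retrieved-dropout (non-RD) withdrawers.
Missingness is always monotone: once missing, missing at all later visits.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

ARM_TREATMENT = "treatment"
ARM_PLACEBO = "placebo"
ARMS = (ARM_TREATMENT, ARM_PLACEBO)

#: HAMD-17 total score range; all simulated and imputed scores are clamped here.
SCORE_MIN = 0.0
SCORE_MAX = 52.0

#: Visits are biweekly: visit j happens at 2*j weeks.
WEEKS_PER_VISIT = 2.0


class TrialDataError(ValueError):
    """Raised when a trial frame violates the schema or its invariants."""


class ConfigError(ValueError):
    """Raised for invalid simulation or imputation configuration."""


class StateError(RuntimeError):
    """Raised when pipeline steps are called out of order."""


def visit_columns(n_visits: int) -> list[str]:
    """Column names ``y0..yJ`` for a trial with ``n_visits`` post-baseline visits."""
    return [f"y{j}" for j in range(n_visits + 1)]


def infer_n_visits(frame: pd.DataFrame) -> int:
    """Number of post-baseline visits implied by the ``y*`` columns."""
    j = 0
    while f"y{j + 1}" in frame.columns:
        j += 1
    if j == 0:
        raise TrialDataError("frame has no post-baseline visit columns (y1, y2, ...)")
    return j


def score_matrix(frame: pd.DataFrame, n_visits: int | None = None) -> np.ndarray:
    """Scores as an ``(n_subjects, J+1)`` float array (NaN = missing)."""
    if n_visits is None:
        n_visits = infer_n_visits(frame)
    return frame[visit_columns(n_visits)].to_numpy(dtype=float)


def withdrawal_vector(frame: pd.DataFrame) -> np.ndarray:
    """Withdrawal visit per subject as int, ``-1`` for completers."""
    w = frame["withdrawal_visit"].to_numpy(dtype=float)
    out = np.where(np.isnan(w), -1, w).astype(int)
    return out


def validate_trial_frame(
    frame: pd.DataFrame,
    n_visits: int | None = None,
    allow_missing: bool = True,
    require_missing_after_withdrawal: bool = False,
) -> int:
    """Validate schema and invariants; return the number of post-baseline visits.

    Checks: required columns, arms, baseline completeness, monotone
    missingness, consistency of ``withdrawal_visit`` and ``rd_flag`` with the
    missingness pattern.  ``allow_missing=False`` additionally requires a
    fully observed (truth) frame; ``require_missing_after_withdrawal=True``
    requires an observed frame in which every non-RD withdrawer is missing
    from the withdrawal visit onward.
    """
    if n_visits is None:
        n_visits = infer_n_visits(frame)
    required = ["id", "arm", *visit_columns(n_visits), "withdrawal_visit", "rd_flag"]
    missing_cols = [c for c in required if c not in frame.columns]
    if missing_cols:
        raise TrialDataError(f"missing required columns: {missing_cols}")
    if frame["id"].duplicated().any():
        dup = frame.loc[frame["id"].duplicated(), "id"].iloc[0]
        raise TrialDataError(f"duplicate subject id {dup!r}")
    bad_arm = set(frame["arm"].unique()) - set(ARMS)
    if bad_arm:
        raise TrialDataError(f"unknown arm labels {sorted(bad_arm)}; expected {ARMS}")

    y = score_matrix(frame, n_visits)
    wvis = withdrawal_vector(frame)
    rd = frame["rd_flag"].to_numpy(dtype=bool)
    ids = frame["id"].to_numpy()

    if np.isnan(y[:, 0]).any():
        sub = ids[np.isnan(y[:, 0])][0]
        raise TrialDataError(f"subject {sub!r}: baseline y0 is missing")
    obs = ~np.isnan(y)
    # monotone: an observed cell must not follow a missing one
    nonmono = obs[:, 1:] & ~obs[:, :-1]
    if nonmono.any():
        sub = ids[nonmono.any(axis=1)][0]
        raise TrialDataError(f"subject {sub!r}: non-monotone missingness pattern")
    if (rd & (wvis < 0)).any():
        sub = ids[rd & (wvis < 0)][0]
        raise TrialDataError(f"subject {sub!r}: rd_flag set without a withdrawal_visit")
    bad_w = (wvis >= 0) & ((wvis < 1) | (wvis > n_visits))
    if bad_w.any():
        sub = ids[bad_w][0]
        raise TrialDataError(
            f"subject {sub!r}: withdrawal_visit outside 1..{n_visits}"
        )
    if (rd & ~obs.all(axis=1)).any():
        sub = ids[rd & ~obs.all(axis=1)][0]
        raise TrialDataError(f"subject {sub!r}: RD subject has missing values")
    if not allow_missing and not obs.all():
        sub = ids[~obs.all(axis=1)][0]
        raise TrialDataError(f"subject {sub!r}: truth frame has missing values")
    if require_missing_after_withdrawal:
        # observed frame: non-RD withdrawers are missing from withdrawal onward
        nonrd_wd = (~rd) & (wvis >= 0)
        for i in np.nonzero(nonrd_wd)[0]:
            if obs[i, wvis[i]:].any():
                raise TrialDataError(
                    f"subject {ids[i]!r}: non-RD subject has an observed value "
                    "at or after the withdrawal visit"
                )
    return n_visits


def clamp_scores(values: np.ndarray) -> np.ndarray:
    """Clamp scores to the instrument range [0, 52] (in place safe copy)."""
    return np.clip(values, SCORE_MIN, SCORE_MAX)
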