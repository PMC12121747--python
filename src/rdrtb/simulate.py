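"""Simulator for a two-arm longitudinal trial with treatment withdrawal.

Emulates an 8-week antidepressant trial with biweekly HAMD-17 assessments:
baseline ~ Normal(25, 5) truncated to [15, 35], a constant per-visit decline
per arm (2.5 treatment / 0.5 placebo) plus Normal(0, 0.5) visit noise, 400
subjects per arm.  30 % of each arm withdraws from treatment, spread 1:1:1
over visits 2-4; 20 % of withdrawers are retrieved dropouts (RD) who keep
contributing data.  Withdrawers retain a configurable fraction of their
pre-withdrawal efficacy (treatment arm) or receive rescue medication worth
150 % of it (placebo arm).  Four scenarios control whether withdrawers do
better or worse than completers and whether non-RD withdrawers do better or
worse than RD withdrawers before withdrawal.

The pipeline produces a *truth* frame (fully observed, the counterfactual
post-withdrawal values included) and an *observed* frame in which non-RD
withdrawers are missing from the withdrawal visit onward.
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
    ConfigError,
    StateError,
    clamp_scores,
    score_matrix,
    visit_columns,
    withdrawal_vector,
)

#: Scenarios in which non-RD withdrawers respond *better* than RD withdrawers
#: before withdrawal; in the complementary scenarios (2, 4) they respond worse.
SCENARIOS_NONRD_BETTER = (1, 3)

#: Scenarios in which withdrawers retain more than their full pre-withdrawal
#: efficacy (the retained weight runs 1.1-1.5 instead of 0.1-0.9).
SCENARIOS_WITHDRAWERS_BETTER = (3, 4)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated trial.

    Parameters
    ----------
    n_per_arm : subjects randomized per arm.
    n_visits : post-baseline visits (biweekly; the trial lasts 2*n_visits weeks).
    baseline_mean, baseline_sd : Normal parameters of the baseline score.
    baseline_range : inclusion range enforced by rejection sampling.
    decline_per_visit_trt, decline_per_visit_pbo : mean per-visit score drop.
    visit_noise_sd : SD of the Normal noise added at every post-baseline visit.
    withdrawal_frac : fraction of each arm withdrawing from treatment.
    withdrawal_visit_weights : ratio of withdrawals over visits 2..n_visits.
    rd_frac : fraction of withdrawers retained as RD subjects.
    retained_weight_trt : fraction of pre-withdrawal change from baseline that
        treatment-arm withdrawers keep at every post-withdrawal visit.
    rescue_weight_pbo : same for placebo-arm withdrawers (rescue medication).
    scenario : 1-4, sets the sign of the non-RD efficacy shift.
    nonrd_rate_shift : signed improvement-rate shift (points/week) applied to
        non-RD withdrawers' pre-withdrawal slopes; ``None`` derives the
        magnitude from the 70 %-overlap rate-difference rule and the sign
        from ``scenario``.
    seed : default RNG seed used when no generator is passed explicitly.
    """

    n_per_arm: int = 400
    n_visits: int = 4
    baseline_mean: float = 25.0
    baseline_sd: float = 5.0
    baseline_range: tuple[float, float] = (15.0, 35.0)
    decline_per_visit_trt: float = 2.5
    decline_per_visit_pbo: float = 0.5
    visit_noise_sd: float = 0.5
    withdrawal_frac: float = 0.30
    withdrawal_visit_weights: tuple[float, ...] = (1.0, 1.0, 1.0)
    rd_frac: float = 0.20
    retained_weight_trt: float = 0.10
    rescue_weight_pbo: float = 1.50
    scenario: int = 1
    nonrd_rate_shift: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_per_arm < 1:
            raise ConfigError("n_per_arm must be positive")
        if self.n_visits < 2:
            raise ConfigError("need at least 2 post-baseline visits")
        if self.baseline_sd <= 0 or self.visit_noise_sd < 0:
            raise ConfigError("baseline_sd must be > 0 and visit_noise_sd >= 0")
        lo, hi = self.baseline_range
        if not lo < hi:
            raise ConfigError("baseline_range low must be < high")
        if not 0 <= self.withdrawal_frac < 1:
            raise ConfigError("withdrawal_frac must be in [0, 1)")
        if not 0 <= self.rd_frac <= 1:
            raise ConfigError("rd_frac must be in [0, 1]")
        if len(self.withdrawal_visit_weights) != self.n_visits - 1:
            raise ConfigError(
                "withdrawal_visit_weights must have one entry per visit 2..J"
            )
        if min(self.withdrawal_visit_weights) < 0 or sum(self.withdrawal_visit_weights) <= 0:
            raise ConfigError("withdrawal_visit_weights must sum to a positive value")
        if self.scenario not in (1, 2, 3, 4):
            raise ConfigError("scenario must be 1, 2, 3 or 4")

    @property
    def total_weeks(self) -> float:
        return self.n_visits * WEEKS_PER_VISIT

    def arm_decline(self, arm: str) -> float:
        return self.decline_per_visit_trt if arm == ARM_TREATMENT else self.decline_per_visit_pbo

    def arm_retained_weight(self, arm: str) -> float:
        return self.retained_weight_trt if arm == ARM_TREATMENT else self.rescue_weight_pbo


def _as_rng(rng: np.random.Generator | int | None, config: SimConfig) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    if rng is None:
        rng = config.seed
    return np.random.default_rng(rng)


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, size: int
) -> np.ndarray:
    """Rejection-sample Normal(mean, sd) restricted to [lo, hi]."""
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(mean, sd, size=max(size - filled, 16))
        keep = draw[(draw >= lo) & (draw <= hi)]
        take = min(keep.size, size - filled)
        out[filled : filled + take] = keep[:take]
        filled += take
    return out


def simulate_on_treatment(
    config: SimConfig, rng: np.random.Generator | int | None = None
) -> pd.DataFrame:
    """Generate fully observed on-treatment trajectories (no withdrawal yet).

    Visit j score = visit j-1 score − arm decline + Normal(0, visit_noise_sd),
    clamped to the instrument range.
    """
    rng = _as_rng(rng, config)
    n = config.n_per_arm
    lo, hi = config.baseline_range
    rows = {}
    arms = np.repeat([ARM_TREATMENT, ARM_PLACEBO], n)
    y = np.empty((2 * n, config.n_visits + 1))
    y[:, 0] = _truncated_normal(rng, config.baseline_mean, config.baseline_sd, lo, hi, 2 * n)
    decline = np.where(arms == ARM_TREATMENT, config.decline_per_visit_trt,
                       config.decline_per_visit_pbo)
    for j in range(1, config.n_visits + 1):
        noise = rng.normal(0.0, config.visit_noise_sd, size=2 * n) if config.visit_noise_sd else 0.0
        y[:, j] = clamp_scores(y[:, j - 1] - decline + noise)
    rows["id"] = np.arange(1, 2 * n + 1)
    rows["arm"] = arms
    for j, col in enumerate(visit_columns(config.n_visits)):
        rows[col] = y[:, j]
    rows["withdrawal_visit"] = np.full(2 * n, np.nan)
    rows["rd_flag"] = np.zeros(2 * n, dtype=bool)
    return pd.DataFrame(rows)


def _largest_remainder_split(total: int, weights: tuple[float, ...]) -> np.ndarray:
    """Split ``total`` into integer parts proportional to ``weights``."""
    w = np.asarray(weights, dtype=float)
    exact = total * w / w.sum()
    base = np.floor(exact).astype(int)
    rem = total - base.sum()
    order = np.argsort(-(exact - base))
    base[order[:rem]] += 1
    return base


def assign_withdrawal(
    truth: pd.DataFrame, config: SimConfig, rng: np.random.Generator | int | None = None
) -> pd.DataFrame:
    """Select withdrawers per arm, give them withdrawal visits and RD flags.

    Per arm, ``round(withdrawal_frac * n)`` subjects withdraw, spread over
    visits ``2..n_visits`` in the configured ratio; ``round(rd_frac *
    n_withdrawn)`` of them are flagged as retrieved dropouts.  Selection is
    uniformly random within arm.
    """
    if truth["withdrawal_visit"].notna().any():
        raise StateError("withdrawal already assigned")
    rng = _as_rng(rng, config)
    truth = truth.copy()
    wvis = np.full(len(truth), np.nan)
    rd = np.zeros(len(truth), dtype=bool)
    for arm in ARMS:
        idx = np.flatnonzero((truth["arm"] == arm).to_numpy())
        n_wd = int(round(config.withdrawal_frac * idx.size))
        if n_wd > idx.size:
            raise ConfigError("withdrawal count exceeds arm size")
        chosen = rng.choice(idx, size=n_wd, replace=False)
        counts = _largest_remainder_split(n_wd, config.withdrawal_visit_weights)
        visits = np.repeat(np.arange(2, config.n_visits + 1), counts)
        wvis[chosen] = visits  # chosen order is already random
        n_rd = int(round(config.rd_frac * n_wd))
        rd_ids = rng.choice(chosen, size=n_rd, replace=False)
        rd[rd_ids] = True
    truth["withdrawal_visit"] = wvis
    truth["rd_flag"] = rd
    return truth


def apply_retained_efficacy(
    truth: pd.DataFrame, config: SimConfig, rng: np.random.Generator | int | None = None
) -> pd.DataFrame:
    """Rewrite post-withdrawal visits as retained fractions of pre-withdrawal change.

    For each withdrawer (RD and non-RD alike) with withdrawal visit w, the
    change from baseline at every visit j >= w becomes
    ``weight * (y_{w-1} - y0)`` plus visit noise, where the weight is
    ``retained_weight_trt`` (treatment) or ``rescue_weight_pbo`` (placebo).
    Non-RD values written here become the hidden truth.
    """
    if truth["withdrawal_visit"].isna().all() and config.withdrawal_frac > 0:
        raise StateError("apply_retained_efficacy called before assign_withdrawal")
    rng = _as_rng(rng, config)
    truth = truth.copy()
    y = score_matrix(truth, config.n_visits)
    wvis = withdrawal_vector(truth)
    arms = truth["arm"].to_numpy()
    for i in np.flatnonzero(wvis >= 0):
        w = wvis[i]
        weight = config.arm_retained_weight(arms[i])
        delta_pre = y[i, w - 1] - y[i, 0]
        for j in range(w, config.n_visits + 1):
            noise = rng.normal(0.0, config.visit_noise_sd) if config.visit_noise_sd else 0.0
            y[i, j] = clamp_scores(y[i, 0] + weight * delta_pre + noise)
    truth[visit_columns(config.n_visits)] = y
    return truth


def _improvement_rates(y: np.ndarray, wvis: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Pre-withdrawal improvement rate (points/week, positive = improvement)."""
    last_pre = wvis[idx] - 1
    delta = y[idx, 0] - y[idx, last_pre]
    weeks = last_pre * WEEKS_PER_VISIT
    return delta / weeks


def seventy_percent_rate_gap(rates: np.ndarray) -> float:
    """Rate gap between the best-70 % and worst-70 % subsets of withdrawers.

    Sorts the pre-withdrawal improvement rates, then returns the difference
    between the mean of the top 70 % and the mean of the bottom 70 %
    (overlapping subsets).  Used as the magnitude of the non-RD efficacy
    shift when ``nonrd_rate_shift`` is not given.
    """
    if rates.size < 2:
        raise ConfigError("need at least 2 withdrawers to compute the rate gap")
    k = max(int(np.ceil(0.7 * rates.size)), 1)
    srt = np.sort(rates)
    return float(srt[-k:].mean() - srt[:k].mean())


def shift_nonrd_efficacy(
    truth: pd.DataFrame, config: SimConfig, rng: np.random.Generator | int | None = None
) -> pd.DataFrame:
    """Differentiate non-RD from RD withdrawers by shifting pre-withdrawal slopes.

    Per arm, the shift magnitude is the 70 %-overlap rate gap among that
    arm's withdrawers (or the explicit ``nonrd_rate_shift``); its sign makes
    non-RD subjects improve faster than RD subjects in scenarios 1 and 3 and
    slower in scenarios 2 and 4.  Non-RD withdrawers' pre-withdrawal
    trajectories are regenerated with the shifted slope and their
    post-withdrawal retained-efficacy values recomputed from the new
    pre-withdrawal change.
    """
    rng = _as_rng(rng, config)
    truth = truth.copy()
    y = score_matrix(truth, config.n_visits)
    wvis = withdrawal_vector(truth)
    rd = truth["rd_flag"].to_numpy(dtype=bool)
    arms = truth["arm"].to_numpy()
    sign = 1.0 if config.scenario in SCENARIOS_NONRD_BETTER else -1.0
    for arm in ARMS:
        in_arm = arms == arm
        withdrawers = np.flatnonzero(in_arm & (wvis >= 0))
        nonrd = np.flatnonzero(in_arm & (wvis >= 0) & ~rd)
        if nonrd.size == 0:
            continue
        if config.nonrd_rate_shift is not None:
            shift = float(config.nonrd_rate_shift)
        else:
            rates = _improvement_rates(y, wvis, withdrawers)
            shift = sign * seventy_percent_rate_gap(rates)
        # improvement rate shift (points/week) -> extra per-visit decline
        extra_decline = shift * WEEKS_PER_VISIT
        decline = config.arm_decline(arm) + extra_decline
        weight = config.arm_retained_weight(arm)
        for i in nonrd:
            w = wvis[i]
            for j in range(1, w):
                noise = rng.normal(0.0, config.visit_noise_sd) if config.visit_noise_sd else 0.0
                y[i, j] = clamp_scores(y[i, j - 1] - decline + noise)
            delta_pre = y[i, w - 1] - y[i, 0]
            for j in range(w, config.n_visits + 1):
                noise = rng.normal(0.0, config.visit_noise_sd) if config.visit_noise_sd else 0.0
                y[i, j] = clamp_scores(y[i, 0] + weight * delta_pre + noise)
    truth[visit_columns(config.n_visits)] = y
    return truth


def induce_missingness(truth: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Blank non-RD withdrawers' visits from the withdrawal visit onward.

    Returns ``(truth, observed)``; the truth frame is passed through
    unchanged for true-effect computation.
    """
    observed = truth.copy()
    y = score_matrix(observed)
    wvis = withdrawal_vector(observed)
    rd = observed["rd_flag"].to_numpy(dtype=bool)
    for i in np.flatnonzero((wvis >= 0) & ~rd):
        y[i, wvis[i]:] = np.nan
    observed[visit_columns(y.shape[1] - 1)] = y
    return truth, observed


def simulate_trial(
    config: SimConfig, rng: np.random.Generator | int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full generator pipeline; return ``(truth, observed)``."""
    rng = _as_rng(rng, config)
    truth = simulate_on_treatment(config, rng)
    if config.withdrawal_frac > 0:
        truth = assign_withdrawal(truth, config, rng)
        truth = apply_retained_efficacy(truth, config, rng)
        truth = shift_nonrd_efficacy(truth, config, rng)
    return induce_missingness(truth)


def scenario_retained_weights(scenario: int) -> tuple[float, ...]:
    """Default treatment-arm retained-efficacy weight grid for a scenario.

    Scenarios 1-2 study withdrawers retaining 10-90 % of their pre-withdrawal
    efficacy; scenarios 3-4 study the 110-150 % branch, in which withdrawers
    outperform completers.
    """
    if scenario in SCENARIOS_WITHDRAWERS_BETTER:
        return (1.1, 1.2, 1.3, 1.4, 1.5)
    return (0.1, 0.3, 0.5, 0.7, 0.9)
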