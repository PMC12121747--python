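"""Per-draw ANCOVA with LS means and Rubin's-rules pooling.

The endpoint is change from baseline at the final visit.  Each completed
dataset is analysed with the two-arm one-covariate ANCOVA

    change_i = b0 + b1 * 1[arm_i = treatment] + b2 * baseline_i + e_i

whose least-squares means, evaluated at the grand-mean baseline, differ by
exactly the arm coefficient b1 — the treatment-minus-placebo difference in
adjusted change from baseline (negative favours treatment on HAMD-17).
The M per-draw estimates are pooled with Rubin's rules: pooled estimate Q̄,
within-imputation variance W = mean(se²), between-imputation variance B =
sample variance of the estimates, total variance W + (1 + 1/M) B, with
Barnard-Rubin small-sample degrees of freedom when the complete-data df is
known.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .frames import ARM_PLACEBO, ARM_TREATMENT, score_matrix

from .mi import ImputationDraw


class FitError(RuntimeError):
    """ANCOVA design matrix is singular."""


@dataclass(frozen=True)
class AncovaFit:
    """One completed dataset's ANCOVA summary."""

    lsmean_treatment: float
    lsmean_placebo: float
    diff: float  # treatment - placebo adjusted change from baseline
    lsm_se: float  # standard error of diff
    df: int  # residual degrees of freedom, n - 3

    @property
    def lsmeans(self) -> dict[str, float]:
        return {ARM_TREATMENT: self.lsmean_treatment, ARM_PLACEBO: self.lsmean_placebo}


@dataclass(frozen=True)
class PooledResult:
    """Rubin-combined treatment effect across M imputations."""

    estimate: float  # Q-bar
    within_variance: float  # W
    between_variance: float  # B
    se: float  # sqrt(W + (1 + 1/M) B)
    m: int
    df: float  # Barnard-Rubin (or large-sample) degrees of freedom

    @property
    def total_variance(self) -> float:
        return self.within_variance + (1.0 + 1.0 / self.m) * self.between_variance


def _ancova_arrays(y0: np.ndarray, yj: np.ndarray, is_trt: np.ndarray) -> AncovaFit:
    """Closed-form normal-equations ANCOVA on arrays (hot path)."""
    n = y0.size
    if n < 4:
        raise FitError("ANCOVA needs at least 4 subjects")
    change = yj - y0
    x = np.column_stack([np.ones(n), is_trt.astype(float), y0])
    xtx = x.T @ x
    if np.linalg.matrix_rank(xtx) < 3:
        raise FitError("singular ANCOVA design (constant baseline or single arm)")
    xtx_inv = np.linalg.inv(xtx)
    beta = xtx_inv @ (x.T @ change)
    resid = change - x @ beta
    df = n - 3
    sigma2 = float(resid @ resid) / df
    se = float(np.sqrt(sigma2 * xtx_inv[1, 1]))
    grand_y0 = float(y0.mean())
    lsm_pbo = float(beta[0] + beta[2] * grand_y0)
    lsm_trt = float(lsm_pbo + beta[1])
    return AncovaFit(lsm_trt, lsm_pbo, float(beta[1]), se, df)


def ancova_fit(draw: ImputationDraw | pd.DataFrame) -> AncovaFit:
    """ANCOVA of final-visit change from baseline on arm and baseline."""
    frame = draw.frame if isinstance(draw, ImputationDraw) else draw
    y = score_matrix(frame)
    if np.isnan(y).any():
        raise ValueError("ANCOVA requires a completed (fully observed) dataset")
    is_trt = (frame["arm"] == ARM_TREATMENT).to_numpy()
    if is_trt.all() or not is_trt.any():
        raise FitError("both arms must be present")
    return _ancova_arrays(y[:, 0], y[:, -1], is_trt)


def rubin_pool(
    estimates: np.ndarray,
    ses: np.ndarray,
    df_com: float | None = None,
) -> PooledResult:
    """Combine M per-imputation estimates and standard errors.

    ``df_com`` is the complete-data residual df; when given, the
    Barnard-Rubin adjusted degrees of freedom are reported, otherwise the
    classic large-sample value.
    """
    estimates = np.asarray(estimates, dtype=float)
    ses = np.asarray(ses, dtype=float)
    if estimates.shape != ses.shape or estimates.ndim != 1:
        raise ValueError("estimates and ses must be equal-length vectors")
    m = estimates.size
    if m < 2:
        raise ValueError("Rubin pooling needs at least 2 imputations")
    qbar = float(estimates.mean())
    w = float((ses**2).mean())
    b = float(estimates.var(ddof=1))
    total = w + (1.0 + 1.0 / m) * b
    lam = (1.0 + 1.0 / m) * b / total if total > 0 else 0.0
    if lam**2 == 0.0:  # no (or numerically negligible) between-imputation spread
        df = float("inf")
    else:
        df_old = (m - 1) / lam**2
        if df_com is None:
            df = df_old
        else:
            df_obs = (df_com + 1.0) / (df_com + 3.0) * df_com * (1.0 - lam)
            df = 1.0 / (1.0 / df_old + 1.0 / df_obs)
    return PooledResult(qbar, w, b, float(np.sqrt(total)), m, df)


def pool_draws(
    draws: list[ImputationDraw] | np.ndarray, frame: pd.DataFrame | None = None
) -> tuple[PooledResult, np.ndarray, np.ndarray]:
    """Fit the ANCOVA on every draw and pool; returns (pooled, estimates, ses)."""
    if isinstance(draws, np.ndarray):
        if frame is None:
            raise ValueError("frame required when pooling a raw stack")
        is_trt = (frame["arm"] == ARM_TREATMENT).to_numpy()
        fits = [_ancova_arrays(d[:, 0], d[:, -1], is_trt) for d in draws]
    else:
        fits = [ancova_fit(d) for d in draws]
    estimates = np.array([f.diff for f in fits])
    ses = np.array([f.lsm_se for f in fits])
    pooled = rubin_pool(estimates, ses, df_com=fits[0].df)
    return pooled, estimates, ses
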