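"""Posterior-draw sequential-regression multiple imputation for monotone missingness.

Missing visits are imputed in increasing visit order, separately per arm.
For visit j the imputation model is an ordinary least-squares regression of
Y_j on the baseline and all earlier visits, fitted over a donor set:

* ``all_observed`` — every subject in the arm with Y_j observed (the MAR
  model used by the return-to-baseline method's base imputation);
* ``rd_only`` — the arm's retrieved-dropout subjects only (the retrieved-
  dropout method, which transfers the RD subjects' post-withdrawal
  outcome/history relationship to the non-RD withdrawers).

The covariate set is configurable: ``baseline_only`` (default) conditions
each visit model on the baseline score alone, the literal conditioning set
of the return-to-baseline predictive distribution; ``history`` additionally
conditions on all earlier visits (a richer MAR-style model — note that it
lets the donors' pre-withdrawal trajectory carry information that the
baseline-only model deliberately ignores).

Each of the M imputations perturbs the fit by a proper posterior draw under
the standard noninformative prior: residual variance from a scaled
inverse-chi-square, coefficients from a multivariate normal around the OLS
solution.  Missing cells are filled with the drawn linear predictor plus
Normal(0, drawn residual SD) noise, clamped to the instrument range, and
earlier imputed values feed the covariates of later visits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .frames import (
    ARMS,
    clamp_scores,
    score_matrix,
    validate_trial_frame,
    visit_columns,
)

_ZERO_SSE_TOL = 1e-10


class SingularFitError(RuntimeError):
    """Imputation model cannot be fitted (too few donors or collinear design)."""


@dataclass(frozen=True)
class ImputationModelSpec:
    """Settings of the sequential-regression imputation engine.

    ``donor_rule`` selects the donor set per visit ("all_observed" or
    "rd_only") and ``covariates`` the conditioning set ("baseline_only" or
    "history"); models are always fitted separately per arm.
    ``n_imputations`` is Rubin's M.
    """

    donor_rule: str = "all_observed"
    n_imputations: int = 100
    covariates: str = "baseline_only"
    fit_per_arm: bool = True
    prior: str = "noninformative"

    def __post_init__(self) -> None:
        if self.donor_rule not in ("all_observed", "rd_only"):
            raise ValueError(f"unknown donor_rule {self.donor_rule!r}")
        if self.covariates not in ("baseline_only", "history"):
            raise ValueError(f"unknown covariates {self.covariates!r}")
        if self.n_imputations < 2:
            raise ValueError("n_imputations must be >= 2")

    def n_covariates(self, visit_j: int) -> int:
        """Number of regressors (excluding intercept) in the visit-j model."""
        return 1 if self.covariates == "baseline_only" else visit_j


@dataclass(frozen=True)
class PosteriorDraw:
    """One posterior draw of the visit-j imputation model for one arm."""

    visit: int
    arm: str
    coefficients: np.ndarray  # intercept, baseline[, visits 1..j-1]
    residual_sd: float

    def predict(self, covariates: np.ndarray) -> np.ndarray:
        """Linear predictor for rows of ``[y0, y1, ..., y_{j-1}]``."""
        x = np.column_stack([np.ones(len(covariates)), covariates])
        return x @ self.coefficients


@dataclass
class ImputationDraw:
    """A completed dataset: the input frame with missing cells filled in."""

    frame: pd.DataFrame
    imputed_mask: np.ndarray  # bool (n_subjects, n_visits+1)
    m: int


@dataclass
class _VisitFit:
    """Precomputed OLS fit for one (arm, visit); posterior draws reuse it."""

    visit: int
    arm: str
    beta_hat: np.ndarray
    sse: float
    df: int
    chol_cov: np.ndarray | None  # L with coef cov = sigma2 * L @ L.T; None = degenerate


def _covariate_cols(visit_j: int, covariates: str) -> list[int]:
    return [0] if covariates == "baseline_only" else list(range(visit_j))


def _fit_visit(
    y: np.ndarray, donors: np.ndarray, visit_j: int, arm: str, covariates: str
) -> _VisitFit:
    resp = y[donors, visit_j]
    cols = _covariate_cols(visit_j, covariates)
    x = np.column_stack([np.ones(donors.sum()), y[np.ix_(np.flatnonzero(donors), cols)]])
    n_d, p = x.shape
    if resp.size and np.ptp(resp) < _ZERO_SSE_TOL:
        # constant response: the regression degenerates to that constant
        beta = np.zeros(p)
        beta[0] = resp[0] if resp.size else 0.0
        return _VisitFit(visit_j, arm, beta, 0.0, max(n_d - p, 0), None)
    if n_d <= p:
        raise SingularFitError(
            f"visit {visit_j}, arm {arm!r}: {n_d} donors for {p - 1} covariates "
            "(need more donors than covariates + 1)"
        )
    beta, res, rank, _ = np.linalg.lstsq(x, resp, rcond=None)
    fitted = x @ beta
    sse = float(((resp - fitted) ** 2).sum())
    if rank < p:
        if sse < _ZERO_SSE_TOL:
            # exact fit on a degenerate design: keep the minimum-norm solution
            return _VisitFit(visit_j, arm, beta, 0.0, n_d - rank, None)
        raise SingularFitError(
            f"visit {visit_j}, arm {arm!r}: collinear covariates (rank {rank} < {p})"
        )
    df = n_d - p
    if sse < _ZERO_SSE_TOL:
        return _VisitFit(visit_j, arm, beta, 0.0, df, None)
    xtx_inv = np.linalg.inv(x.T @ x)
    chol = np.linalg.cholesky((xtx_inv + xtx_inv.T) / 2.0)
    return _VisitFit(visit_j, arm, beta, sse, df, chol)


def _draw_from_fit(fit: _VisitFit, rng: np.random.Generator) -> tuple[np.ndarray, float]:
    """Draw (coefficients, residual SD) from the posterior around an OLS fit."""
    if fit.chol_cov is None or fit.sse < _ZERO_SSE_TOL:
        return fit.beta_hat, 0.0
    sigma2 = fit.sse / rng.chisquare(fit.df)
    beta = fit.beta_hat + np.sqrt(sigma2) * fit.chol_cov @ rng.standard_normal(fit.beta_hat.size)
    return beta, float(np.sqrt(sigma2))


def _donor_mask(
    y: np.ndarray, arm_mask: np.ndarray, rd: np.ndarray, visit_j: int, donor_rule: str
) -> np.ndarray:
    if donor_rule == "rd_only":
        return arm_mask & rd
    return arm_mask & ~np.isnan(y[:, visit_j])


def fit_posterior_draw(
    frame: pd.DataFrame,
    spec: ImputationModelSpec,
    visit_j: int,
    arm: str,
    rng: np.random.Generator | int | None = None,
) -> PosteriorDraw:
    """Fit the visit-j model on the arm's donors and return one posterior draw."""
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    validate_trial_frame(frame)
    y = score_matrix(frame)
    arm_mask = (frame["arm"] == arm).to_numpy()
    rd = frame["rd_flag"].to_numpy(dtype=bool)
    donors = _donor_mask(y, arm_mask, rd, visit_j, spec.donor_rule)
    if donors.sum() == 0:
        raise SingularFitError(f"visit {visit_j}, arm {arm!r}: empty donor set")
    fit = _fit_visit(y, donors, visit_j, arm, spec.covariates)
    beta, sd = _draw_from_fit(fit, rng)
    return PosteriorDraw(visit_j, arm, beta, sd)


def _impute_stack(
    y: np.ndarray,
    arm_codes: np.ndarray,
    rd: np.ndarray,
    spec: ImputationModelSpec,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Fast core: return ``(stack, imputed_mask)`` with stack shape (M, n, J+1).

    OLS fits are computed once per (arm, visit); each imputation m only
    redraws the posterior and the residual noise.
    """
    miss = np.isnan(y)
    n_visits = y.shape[1] - 1
    visits = [j for j in range(1, n_visits + 1) if miss[:, j].any()]
    arm_masks = {arm: arm_codes == arm for arm in ARMS}
    fits: dict[tuple[str, int], _VisitFit] = {}
    targets: dict[tuple[str, int], np.ndarray] = {}
    for j in visits:
        for arm in ARMS:
            t = miss[:, j] & arm_masks[arm]
            if not t.any():
                continue
            donors = _donor_mask(y, arm_masks[arm], rd, j, spec.donor_rule)
            if donors.sum() == 0:
                raise SingularFitError(f"visit {j}, arm {arm!r}: empty donor set")
            fits[(arm, j)] = _fit_visit(y, donors, j, arm, spec.covariates)
            targets[(arm, j)] = np.flatnonzero(t)

    m_total = spec.n_imputations
    stack = np.empty((m_total,) + y.shape)
    for m in range(m_total):
        ym = y.copy()
        for j in visits:
            for arm in ARMS:
                key = (arm, j)
                if key not in fits:
                    continue
                beta, sd = _draw_from_fit(fits[key], rng)
                rows = targets[key]
                cols = _covariate_cols(j, spec.covariates)
                x = np.column_stack([np.ones(rows.size), ym[np.ix_(rows, cols)]])
                pred = x @ beta
                if sd > 0:
                    pred = pred + rng.normal(0.0, sd, size=rows.size)
                ym[rows, j] = clamp_scores(pred)
        stack[m] = ym
    return stack, miss


def impute_monotone(
    frame: pd.DataFrame,
    spec: ImputationModelSpec,
    rng: np.random.Generator | int | None = None,
) -> list[ImputationDraw]:
    """Produce M completed datasets from a monotone-missing trial frame.

    Observed cells are carried through untouched; each missing cell is filled
    from an independent posterior draw of the per-arm visit models.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    n_visits = validate_trial_frame(frame)
    y = score_matrix(frame, n_visits)
    arm_codes = frame["arm"].to_numpy()
    rd = frame["rd_flag"].to_numpy(dtype=bool)
    stack, miss = _impute_stack(y, arm_codes, rd, spec, rng)
    cols = visit_columns(n_visits)
    draws = []
    for m in range(spec.n_imputations):
        completed = frame.copy()
        completed[cols] = stack[m]
        draws.append(ImputationDraw(completed, miss.copy(), m))
    return draws
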