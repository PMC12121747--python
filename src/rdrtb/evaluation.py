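"""Monte-Carlo evaluation of the imputation methods against the simulated truth.

For each scenario × retained-efficacy weight, ``run_scenario`` simulates D
paired (truth, observed) datasets, imputes each observed dataset with the
RD, RD-RTB and RTB methods (M draws each), analyses every draw with the
ANCOVA and pools with Rubin's rules.  Three metrics are recorded per
dataset and method:

* **bias** — pooled estimate minus the complete-data (truth) ANCOVA effect;
* **LSM SE** — mean over draws of the per-draw ANCOVA standard error of the
  arm contrast;
* **Rubin SE** — the Rubin's-rules total standard error.

The RD and RD-RTB methods share the same RD imputation stack within a
dataset, so their comparison is paired: the difference between them is
exactly the RD-RTB correction, not Monte-Carlo noise.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .frames import WEEKS_PER_VISIT, score_matrix, withdrawal_vector
from .inference import _ancova_arrays, rubin_pool
from .methods import (
    InsufficientDonorsError,
    _build_ledger_arrays,
    _check_rd_donors,
    _final_adjust_stack,
    _rtb_adjust_stack,
)
from .mi import ImputationModelSpec, _impute_stack
from .simulate import SimConfig, scenario_retained_weights, simulate_trial

METHODS = ("RD", "RD-RTB", "RTB")


@dataclass
class ScenarioResult:
    """Per-dataset metrics for one scenario × retained weight × method."""

    scenario: int
    retained_weight: float
    method: str
    records: pd.DataFrame  # columns: dataset, true_effect, estimate, bias, lsm_se, rubin_se
    n_resimulated: int = 0

    @property
    def mean_bias(self) -> float:
        return float(self.records["bias"].mean())

    @property
    def mean_lsm_se(self) -> float:
        return float(self.records["lsm_se"].mean())

    @property
    def mean_rubin_se(self) -> float:
        return float(self.records["rubin_se"].mean())


def true_effect(truth: pd.DataFrame) -> float:
    """Complete-data ANCOVA treatment effect (the simulation ground truth)."""
    y = score_matrix(truth)
    is_trt = (truth["arm"] == "treatment").to_numpy()
    return _ancova_arrays(y[:, 0], y[:, -1], is_trt).diff


def _analyse_stack(stack: np.ndarray, is_trt: np.ndarray, df_com: int) -> tuple[float, float, float]:
    """Pooled estimate, mean per-draw SE, Rubin SE for one draw stack."""
    fits = [_ancova_arrays(d[:, 0], d[:, -1], is_trt) for d in stack]
    estimates = np.array([f.diff for f in fits])
    ses = np.array([f.lsm_se for f in fits])
    pooled = rubin_pool(estimates, ses, df_com=df_com)
    return pooled.estimate, float(ses.mean()), pooled.se


def _run_dataset(
    config: SimConfig,
    n_imputations: int,
    seed_entropy: list[int],
    methods: tuple[str, ...],
    max_retries: int = 5,
) -> tuple[dict[str, tuple[float, float, float]], float, int]:
    """Simulate one dataset and run the requested methods on it.

    Datasets whose RD donor pool is too small for the imputation models are
    resimulated with a bumped sub-seed (counted in the third return value).
    """
    for attempt in range(max_retries + 1):
        ss = np.random.SeedSequence(seed_entropy + [attempt])
        rng_sim, rng_rd, rng_mar = (np.random.default_rng(c) for c in ss.spawn(3))
        truth, observed = simulate_trial(config, rng_sim)
        y = score_matrix(observed, config.n_visits)
        if np.isnan(y).any():
            try:
                _check_rd_donors(
                    observed,
                    config.n_visits,
                    ImputationModelSpec(donor_rule="rd_only", n_imputations=n_imputations),
                )
            except InsufficientDonorsError:
                continue
        arm_codes = observed["arm"].to_numpy()
        wvis = withdrawal_vector(observed)
        rd = observed["rd_flag"].to_numpy(dtype=bool)
        ids = observed["id"].to_numpy()
        is_trt = arm_codes == "treatment"
        df_com = len(observed) - 3
        truth_diff = true_effect(truth)

        out: dict[str, tuple[float, float, float]] = {}
        if "RD" in methods or "RD-RTB" in methods:
            spec = ImputationModelSpec(donor_rule="rd_only", n_imputations=n_imputations)
            rd_stack, miss = _impute_stack(y, arm_codes, rd, spec, rng_rd)
            if "RD" in methods:
                out["RD"] = _analyse_stack(rd_stack, is_trt, df_com)
            if "RD-RTB" in methods:
                ledger, rows_by_arm = _build_ledger_arrays(
                    y, arm_codes, wvis, rd, ids, rd_stack, miss,
                    total_weeks=config.n_visits * WEEKS_PER_VISIT,
                )
                corrected = rd_stack.copy()
                _final_adjust_stack(corrected, miss, ledger, rows_by_arm)
                out["RD-RTB"] = _analyse_stack(corrected, is_trt, df_com)
        if "RTB" in methods:
            spec = ImputationModelSpec(donor_rule="all_observed", n_imputations=n_imputations)
            mar_stack, miss = _impute_stack(y, arm_codes, rd, spec, rng_mar)
            _rtb_adjust_stack(mar_stack, miss, arm_codes)
            out["RTB"] = _analyse_stack(mar_stack, is_trt, df_com)
        return out, truth_diff, attempt
    raise InsufficientDonorsError(
        f"could not simulate a dataset with enough RD donors in {max_retries + 1} attempts"
    )


def run_scenario(
    scenario: int,
    weights: tuple[float, ...] | None = None,
    n_datasets: int = 100,
    n_imputations: int = 100,
    seed: int = 0,
    config: SimConfig | None = None,
    methods: tuple[str, ...] = METHODS,
) -> list[ScenarioResult]:
    """Replicate experiment for one scenario over a grid of retained weights.

    Per-dataset seeds are derived from the master seed by counter hashing
    (``SeedSequence([seed, scenario, weight_index, dataset])``), so datasets
    are independent yet the whole run is reproducible bit-for-bit.
    """
    if n_datasets < 1:
        raise ValueError("n_datasets must be >= 1")
    base = config or SimConfig()
    base = replace(base, scenario=scenario)
    if weights is None:
        weights = scenario_retained_weights(scenario)
    results: list[ScenarioResult] = []
    for wi, weight in enumerate(weights):
        cfg = replace(base, retained_weight_trt=weight)
        rows: dict[str, list[dict]] = {m: [] for m in methods}
        n_resim = 0
        for d in range(n_datasets):
            out, truth_diff, attempt = _run_dataset(
                cfg, n_imputations, [int(seed), int(scenario), wi, d], methods
            )
            n_resim += attempt
            for m in methods:
                est, lsm_se, rubin_se = out[m]
                rows[m].append(
                    {
                        "dataset": d,
                        "true_effect": truth_diff,
                        "estimate": est,
                        "bias": est - truth_diff,
                        "lsm_se": lsm_se,
                        "rubin_se": rubin_se,
                    }
                )
        for m in methods:
            results.append(
                ScenarioResult(scenario, weight, m, pd.DataFrame(rows[m]), n_resim)
            )
    return results


def tabulate(results: list[ScenarioResult]) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Aggregate results into the three metric tables plus a tidy long frame.

    Returns ``(tables, tidy)`` where ``tables`` maps metric name ("bias",
    "lsm_se", "rubin_se") to a (scenario, method) × retained-weight table of
    means, and ``tidy`` holds one row per dataset × method × weight.
    """
    if not results:
        raise ValueError("no results to tabulate")
    tidy_parts = []
    for r in results:
        part = r.records.copy()
        part.insert(0, "scenario", r.scenario)
        part.insert(1, "retained_weight", r.retained_weight)
        part.insert(2, "method", r.method)
        tidy_parts.append(part)
    tidy = pd.concat(tidy_parts, ignore_index=True)
    agg = (
        tidy.groupby(["scenario", "method", "retained_weight"])[["bias", "lsm_se", "rubin_se"]]
        .mean()
        .reset_index()
    )
    tables = {}
    for metric in ("bias", "lsm_se", "rubin_se"):
        tables[metric] = agg.pivot_table(
            index=["scenario", "method"], columns="retained_weight", values=metric
        )
    return tables, tidy


def tables_to_markdown(tables: dict[str, pd.DataFrame]) -> str:
    """Render the three metric tables as a markdown report."""
    titles = {
        "bias": "Bias (estimate − true effect)",
        "lsm_se": "LS-means standard error (mean over draws)",
        "rubin_se": "Rubin's-rules combined standard error",
    }
    chunks = []
    for metric, table in tables.items():
        chunks.append(f"## {titles.get(metric, metric)}\n")
        chunks.append(table.round(4).to_markdown())
        chunks.append("")
    return "\n".join(chunks)


def plot_boxplots(results: list[ScenarioResult], out_dir) -> list[str]:
    """Per-scenario boxplots of the three metrics across datasets (optional).

    Uses the non-interactive matplotlib backend; returns the written paths.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    _, tidy = tabulate(results)
    paths = []
    for metric in ("bias", "lsm_se", "rubin_se"):
        for scenario, sub in tidy.groupby("scenario"):
            weights = sorted(sub["retained_weight"].unique())
            methods = sorted(sub["method"].unique())
            fig, axes = plt.subplots(
                1, len(weights), figsize=(3 * len(weights), 4), sharey=True, squeeze=False
            )
            for ax, weight in zip(axes[0], weights):
                cell = sub[sub["retained_weight"] == weight]
                data = [cell[cell["method"] == m][metric].to_numpy() for m in methods]
                ax.boxplot(data, tick_labels=methods)
                ax.set_title(f"weight {weight:g}")
                ax.tick_params(axis="x", rotation=45)
            axes[0][0].set_ylabel(metric)
            fig.suptitle(f"Scenario {scenario}: {metric}")
            fig.tight_layout()
            path = out_dir / f"scenario{scenario}_{metric}.png"
            fig.savefig(path, dpi=100)
            plt.close(fig)
            paths.append(str(path))
    return paths
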