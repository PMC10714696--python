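"""End-to-end pipeline: simulate, estimate, fit, select, report.

One seeded call reproduces the full analysis on a synthetic cohort:

1. draw baseline decision profiles and the longitudinal outcome panel
   (with the published retention pattern),
2. optionally run the four adaptive task sessions per participant and
   replace the true choice dimensions with their MAP estimates,
3. mean-center the covariates,
4. per outcome fit linear and quadratic base growth models, apply the
   chi-square-difference selection rule at 0.05,
5. refit the selected model with the five covariates, evaluate fit and
   standardized effects,
6. export model-comparison, fit-statistic and estimate tables plus
   implied trajectories and cumulative-intake summaries.

Every output embeds the package version, seed and config hash, and the
whole bundle is byte-reproducible from the seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .adaptive import default_task_config, run_session
from .cohort import (
    COVARIATE_NAMES,
    CohortPanel,
    CohortSpec,
    apply_attrition,
    default_cohort_spec,
    sample_decision_profiles,
    sample_growth_panel,
)
from .fitstats import chi_diff_test, evaluate_fit
from .growth import GrowthModelSpec, fit
from .io import RunConfig, write_panel
from .tasks import TASKS, DecisionProfile, consistency_score
from .trajectories import LEVELS, cumulative_intake_kg, implied_trajectory

log = logging.getLogger("choicetraj")

#: cohort-level mean log beta assumed per task when constructing true
#: profiles from the 5-vector of choice dimensions (consistency is defined
#: as deviation from these means)
DEFAULT_LOG_BETA_MEANS = {task: 1.0 for task in TASKS}

def profile_from_covariates(row: np.ndarray) -> DecisionProfile:
    """True decision profile implied by one covariate 5-vector.

    Per-task log beta = consistency + assumed cohort mean log beta, i.e. a
    participant's trial-to-trial consistency is shared across tasks.
    """
    log_betas = {t: float(row[4]) + DEFAULT_LOG_BETA_MEANS[t] for t in TASKS}
    return DecisionProfile(log_k_delay=float(row[0]), log_k_pgain=float(row[1]),
                           log_k_ploss=float(row[2]), log_lambda=float(row[3]),
                           log_beta=log_betas)


def estimate_profiles(true_covariates: np.ndarray, seed: int,
                      n_trials: int | None = None) -> np.ndarray:
    """Run the four adaptive sessions per participant; return the estimated
    covariate matrix (log k x3, log lambda, consistency).

    Consistency is computed from the estimated per-task log betas,
    mean-centered at the estimated cohort means.
    """
    n = true_covariates.shape[0]
    seeds = np.random.SeedSequence(seed).generate_state(n * 4) % (2 ** 31)
    prefs = np.zeros((n, 4))
    log_betas = np.zeros((n, 4))
    for i in range(n):
        profile = profile_from_covariates(true_covariates[i])
        for j, task in enumerate(TASKS):
            config = default_task_config(task, n_trials)
            _, (pref, log_beta) = run_session(profile, config,
                                              int(seeds[i * 4 + j]))
            prefs[i, j] = pref
            log_betas[i, j] = log_beta
    cohort_means = {t: float(log_betas[:, j].mean())
                    for j, t in enumerate(TASKS)}
    consistency = np.array([
        consistency_score({t: log_betas[i, j] for j, t in enumerate(TASKS)},
                          cohort_means) for i in range(n)])
    return np.column_stack([prefs, consistency])


def scaled_retention(counts: tuple[int, ...], n: int) -> tuple[int, ...]:
    """Retention counts rescaled to a cohort of size n (non-increasing)."""
    scaled = [int(round(c * n / counts[0])) for c in counts]
    scaled[0] = n
    for j in range(1, len(scaled)):
        scaled[j] = min(scaled[j], scaled[j - 1])
    return tuple(scaled)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full simulate -> estimate -> fit -> report pipeline."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    meta = {"version": __version__, "seed": config.seed, "config": chash}

    spec = default_cohort_spec(seed=config.seed,
                               attrition_mechanism=config.attrition_mechanism)
    if config.n_participants != spec.n_participants:
        spec = replace(spec, n_participants=config.n_participants,
                       retention_counts=scaled_retention(
                           spec.retention_counts, config.n_participants))

    rng = np.random.default_rng(config.seed)
    stage = "simulate-cohort"
    try:
        x_true = sample_decision_profiles(spec, rng)
        panel = sample_growth_panel(spec, x_true, rng)
        panel = apply_attrition(panel, spec, rng)
        log.info("%s: n=%d, outcomes=%s", stage, panel.n, list(panel.outcomes))

        stage = "simulate-sessions"
        if config.simulate_sessions:
            x_est = estimate_profiles(x_true, seed=config.seed + 1,
                                      n_trials=config.session_trials)
        else:
            x_est = x_true
        x_centered = x_est - x_est.mean(axis=0)
        panel = CohortPanel(covariates=x_centered,
                            covariate_names=COVARIATE_NAMES,
                            outcomes=panel.outcomes, times=panel.times,
                            centered=True)
        write_panel(panel, outdir / "panel.csv", seed=config.seed,
                    config_hash=chash)

        stage = "fit-growth"
        report = _fit_all(panel, config, meta, outdir)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with (outdir / "report.json").open("w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report


def _fit_all(panel: CohortPanel, config: RunConfig, meta: dict,
             outdir: Path) -> dict:
    report: dict = {"meta": meta, "outcomes": {}}
    comparison_rows, fitstat_rows, estimate_rows, std_rows = [], [], [], []
    traj_rows, auc_rows = [], []
    x = panel.covariates
    for name, y in panel.outcomes.items():
        times = tuple(panel.times[name])
        base_specs = {order: GrowthModelSpec(times, order)
                      for order in ("linear", "quadratic")}
        base_fits = {order: evaluate_fit(fit(spec_, y, compute_se=False), y)
                     for order, spec_ in base_specs.items()}
        delta_t, delta_df, p_diff = chi_diff_test(base_fits["linear"],
                                                  base_fits["quadratic"])
        selected = "linear" if p_diff >= 0.05 else "quadratic"
        comparison_rows.append({
            "outcome": name,
            "chi2_linear": base_fits["linear"].chi_square,
            "df_linear": base_fits["linear"].df,
            "chi2_quadratic": base_fits["quadratic"].chi_square,
            "df_quadratic": base_fits["quadratic"].df,
            "delta_chi2": delta_t, "delta_df": delta_df, "p": p_diff,
            "selected": selected})

        final_spec = GrowthModelSpec(times, selected, n_covariates=x.shape[1])
        final = evaluate_fit(fit(final_spec, y, x), y, x)
        lo, hi = final.rmsea_ci90
        fitstat_rows.append({
            "outcome": name, "chi2": final.chi_square, "df": final.df,
            "p": final.p_value, "cfi": final.cfi, "tli": final.tli,
            "rmsea": final.rmsea, "rmsea_lo90": lo, "rmsea_hi90": hi,
            "converged": final.converged, "n": final.n_used})
        factors = ("intercept", "linear", "quadratic")[:final.spec.n_factors]
        for fi, fname in enumerate(factors):
            estimate_rows.append({
                "outcome": name, "component": fname,
                "estimate": float(final.params.nu[fi]),
                "se": float(final.se.nu[fi]) if final.se else np.nan})
            for ci, cname in enumerate(panel.covariate_names):
                std_rows.append({
                    "outcome": name, "component": fname, "covariate": cname,
                    "beta_std": float(final.standardized[fi, ci]),
                    "b": float(final.params.b[fi, ci])})

        grid = np.round(np.arange(0.0, times[-1] + 1e-9,
                                  config.trajectory_step), 10)
        for ci, cname in enumerate(panel.covariate_names):
            for level in LEVELS:
                curve = implied_trajectory(final, grid, covariate=ci,
                                           level=level)
                traj_rows.extend(
                    {"outcome": name, "covariate": cname, "level": level,
                     "time": float(t), "value": float(v)}
                    for t, v in zip(grid, curve))
                if name == "average_use":
                    from .trajectories import curve_coefficients
                    coefs = curve_coefficients(final, ci, level)
                    auc_rows.append({
                        "covariate": cname, "level": level,
                        "cumulative_kg": cumulative_intake_kg(coefs, 6.0)})

        report["outcomes"][name] = {
            "selected_order": selected,
            "chi2": final.chi_square, "df": final.df, "p": final.p_value,
            "cfi": final.cfi, "tli": final.tli, "rmsea": final.rmsea,
            "rmsea_ci90": list(final.rmsea_ci90),
            "growth_means": [float(v) for v in final.params.nu],
            "growth_se": ([float(v) for v in final.se.nu]
                          if final.se else None),
            "converged": final.converged}
        log.info("fit-growth %s: order=%s chi2=%.3f df=%d rmsea=%.3f",
                 name, selected, final.chi_square, final.df, final.rmsea)

    header = "# choicetraj {version} seed={seed} config={config}\n".format(**meta)
    for fname, rows in (("model_comparison.csv", comparison_rows),
                        ("fit_statistics.csv", fitstat_rows),
                        ("growth_estimates.csv", estimate_rows),
                        ("standardized_effects.csv", std_rows),
                        ("trajectories.csv", traj_rows),
                        ("cumulative_intake.csv", auc_rows)):
        path = outdir / fname
        with path.open("w", newline="") as fh:
            fh.write(header)
            pd.DataFrame(rows).to_csv(fh, index=False,
                                      lineterminator="\n")
    return report
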