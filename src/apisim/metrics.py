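"""Replicate batteries and summary statistics.

For each scenario the study runs many independent replicates of
simulate -> encode -> relationship matrix -> AI-REML and summarizes the
errors of the genetic-parameter estimates:

* relative bias (%): mean over converged replicates of
  ``(estimate - truth) / truth * 100`` for each variance;
* relative SE (%): the standard deviation across replicates of the same
  relative differences;
* strong deviations (%): share of replicates whose estimate differs from
  the truth by more than 20%;
* the error of the worker-queen genetic correlation in absolute units
  (its true value may be zero);
* true and estimated genetic trends: the ordinary least-squares slope of
  cohort-mean (E)BVs of breeding-queen candidates on birth year over the
  closed-nucleus years 5-10, and their relative difference.

Non-converged replicates are excluded from the error aggregation but
reported as a convergence rate.  Replicate ``r`` of a battery uses seed
``base_seed + r``; batteries are embarrassingly parallel and merge
deterministically in replicate order.
"""

from __future__ import annotations

from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pedigree import Pedigree
from .relationship import GROUP_LEVEL, build_factor
from .reml import REMLOptions, REMLResult, ai_reml, build_model
from .scenarios import SCENARIOS, ScenarioSpec, build_estimation
from .simulate import ROLE_BQ, ROLE_FOUNDER, SimResult, run_replicate

TREND_YEARS = (5, 10)


def genetic_trend(cohort_means: pd.DataFrame,
                  years: tuple[int, int] = TREND_YEARS) -> np.ndarray:
    """OLS slope of cohort-mean values on birth year, cohorts 5-10.

    ``cohort_means`` is indexed by birth year with one column per trait.
    Returns one slope per column; requires at least two cohorts in range.
    """
    lo, hi = years
    sub = cohort_means.loc[(cohort_means.index >= lo) & (cohort_means.index <= hi)]
    if len(sub) < 2:
        raise ValueError("need at least two cohorts for a trend")
    x = sub.index.to_numpy(float)
    out = []
    for c in sub.columns:
        out.append(np.polyfit(x, sub[c].to_numpy(float), 1)[0])
    return np.asarray(out)


@dataclass
class ReplicateSummary:
    """Estimates, errors and trends of one replicate x scenario."""

    scenario: str
    seed: int
    converged: bool
    n_iter: int = 0
    estimates: dict = field(default_factory=dict)
    predicted_se: dict = field(default_factory=dict)
    truth: dict = field(default_factory=dict)
    rel_err: dict = field(default_factory=dict)      # var_w, var_q, var_e
    r_err: float = np.nan                            # absolute error of r_wq
    true_trend: tuple[float, float] = (np.nan, np.nan)
    est_trend: tuple[float, float] = (np.nan, np.nan)
    trend_err: tuple[float, float] = (np.nan, np.nan)
    error: str = ""


def estimated_cohort_means(result: REMLResult, est, sim: SimResult
                           ) -> pd.DataFrame:
    """Cohort-mean EBVs of all BQ candidates per birth year."""
    ebv = result.ebv()
    true_ids = ebv.id.map(est.true_id)
    roles = sim.queens.set_index("id").role
    mask = true_ids.map(roles).isin([ROLE_BQ, ROLE_FOUNDER]).to_numpy()
    sub = ebv[mask]
    return sub.groupby("byear")[["ebv_w", "ebv_q"]].mean()


def summarize_replicate(scenario: ScenarioSpec, seed: int, sim: SimResult,
                        est, result: REMLResult) -> ReplicateSummary:
    p = sim.params
    truth = {"var_w": p.var_w, "cov_wq": p.cov_wq, "var_q": p.var_q,
             "var_e": p.var_e, "r_wq": p.r_wq}
    rel = {k: (result.estimates[k] - truth[k]) / truth[k]
           for k in ("var_w", "var_q", "var_e") if truth[k] != 0}
    true_tr = genetic_trend(sim.cohort_bv_means())
    est_tr = genetic_trend(estimated_cohort_means(result, est, sim))
    trend_err = tuple(
        (e - t) / t if t != 0 else np.nan for e, t in zip(est_tr, true_tr))
    return ReplicateSummary(
        scenario=scenario.name, seed=seed, converged=result.converged,
        n_iter=result.n_iter, estimates=dict(result.estimates),
        predicted_se=dict(result.predicted_se), truth=truth, rel_err=rel,
        r_err=result.r_wq - p.r_wq, true_trend=tuple(true_tr),
        est_trend=tuple(est_tr), trend_err=trend_err)


def run_one(scenario: ScenarioSpec | str, seed: int,
            scheme_overrides: dict | None = None,
            options: REMLOptions | None = None,
            sim: SimResult | None = None) -> ReplicateSummary:
    """Run one full replicate of a scenario (simulate if not supplied)."""
    if isinstance(scenario, str):
        scenario = SCENARIOS[scenario]
    ss = np.random.SeedSequence(seed)
    rng_sim, rng_enc = (np.random.default_rng(s) for s in ss.spawn(2))
    if sim is None:
        sim = run_replicate(scenario.params(),
                            scenario.scheme(**(scheme_overrides or {})),
                            rng_sim)
    est = build_estimation(sim, scenario, rng_enc)
    factor = build_factor(est.pedigree, GROUP_LEVEL)
    result = ai_reml(build_model(est, factor), options)
    return summarize_replicate(scenario, seed, sim, est, result)


def _battery_worker(args) -> ReplicateSummary:
    name, seed, overrides, options = args
    scenario = SCENARIOS[name]
    try:
        return run_one(scenario, seed, overrides, options)
    except Exception as exc:  # pragma: no cover - defensive
        return ReplicateSummary(scenario=scenario.name, seed=seed,
                                converged=False, error=str(exc))


def run_battery(scenario: ScenarioSpec | str, n_rep: int, base_seed: int,
                n_jobs: int = 1, scheme_overrides: dict | None = None,
                options: REMLOptions | None = None
                ) -> tuple[pd.DataFrame, list[ReplicateSummary]]:
    """Run ``n_rep`` replicates; replicate r uses seed ``base_seed + r``."""
    if isinstance(scenario, str):
        scenario = SCENARIOS[scenario]
    jobs = [(scenario.name, base_seed + r, scheme_overrides, options)
            for r in range(n_rep)]
    if n_jobs > 1:
        with ProcessPoolExecutor(max_workers=n_jobs) as ex:
            summaries = list(ex.map(_battery_worker, jobs))
    else:
        summaries = [_battery_worker(j) for j in jobs]
    return aggregate(summaries), summaries


def aggregate(summaries: list[ReplicateSummary]) -> pd.DataFrame:
    """Scenario table mirroring the study's summary statistics."""
    rows = []
    for name in dict.fromkeys(s.scenario for s in summaries):
        subs = [s for s in summaries if s.scenario == name]
        conv = [s for s in subs if s.converged]
        row = {"scenario": name, "n_rep": len(subs), "n_converged": len(conv),
               "convergence_rate": len(conv) / len(subs)}
        if len(conv) >= 1:
            # SE is the plain SD across replicates of the relative errors
            for key in ("var_w", "var_q", "var_e"):
                errs = np.array([s.rel_err[key] for s in conv
                                 if key in s.rel_err])
                if len(errs) == 0:
                    continue
                row[f"bias_{key}"] = 100.0 * errs.mean()
                row[f"se_{key}"] = 100.0 * errs.std()
                row[f"strong_{key}"] = 100.0 * np.mean(np.abs(errs) > 0.2)
            r_errs = np.array([s.r_err for s in conv])
            row["bias_r_wq"] = r_errs.mean()
            row["se_r_wq"] = r_errs.std()
            for k, trait in enumerate(("w", "q")):
                te = np.array([s.trend_err[k] for s in conv])
                tt = np.array([s.true_trend[k] for s in conv])
                et = np.array([s.est_trend[k] for s in conv])
                row[f"true_trend_{trait}"] = tt.mean()
                row[f"est_trend_{trait}"] = et.mean()
                if np.isfinite(te).any():
                    row[f"trend_err_{trait}"] = 100.0 * np.nanmean(te)
        rows.append(row)
    return pd.DataFrame(rows)


def summaries_frame(summaries: list[ReplicateSummary]) -> pd.DataFrame:
    """Raw per-replicate table (one row per replicate)."""
    recs = []
    for s in summaries:
        rec = {"scenario": s.scenario, "seed": s.seed,
               "converged": s.converged, "n_iter": s.n_iter, "error": s.error}
        for k, v in s.estimates.items():
            rec[f"est_{k}"] = v
        for k, v in s.rel_err.items():
            rec[f"rel_err_{k}"] = v
        rec["r_err"] = s.r_err
        rec["true_trend_w"], rec["true_trend_q"] = s.true_trend
        rec["est_trend_w"], rec["est_trend_q"] = s.est_trend
        rec["trend_err_w"], rec["trend_err_q"] = s.trend_err
        recs.append(rec)
    return pd.DataFrame(recs)
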