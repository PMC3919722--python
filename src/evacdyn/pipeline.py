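"""Run-log file formats and the end-to-end analysis pipeline.

Run logs are stored as one tidy CSV (one row per run, second and
participant) plus a JSON manifest carrying run-level metadata and a
schema version; readers validate states, the at-home bookkeeping
identity, and the shelter-capacity bound, and reject unknown schema
versions.

The pipeline driver chains generation, rate estimation, model fitting,
bootstrap, LOOCV and forward prediction from a single master seed; every
random stage draws its seed from the master via named substreams, so the
whole report is reproducible from (config, seed).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from .experiment import (
    AT_HOME,
    IN_SHELTER,
    IN_TRANSIT,
    STATES,
    LossMatrix,
    RunLog,
    default_trajectory_pool,
    generate_experiment,
    make_design,
    score_run,
)
from .fitting import (
    DEFAULT_POPULATION_MODEL,
    SixParamModel,
    bootstrap_params,
    fit_capacity_model,
    fit_hill,
    fit_six_param,
    loocv,
    _params_as_dict,
)
from .prediction import compare_runs, expected_at_home
from .rates import aggregate_counts, build_indicators
from .threat import Outcome, Regime

__all__ = [
    "SCHEMA_VERSION",
    "PipelineConfig",
    "write_run_logs",
    "read_run_logs",
    "recovery_study",
    "run_pipeline",
]

SCHEMA_VERSION = "1"

_LOG_COLUMNS = [
    "run_id",
    "t",
    "participant_id",
    "state",
    "evac_event",
    "q_display",
    "regime_window",
    "beds_filled",
    "bed",
]


def write_run_logs(logs: list[RunLog], path: str | Path) -> None:
    """Write run logs to ``path`` as ``logs.csv`` + ``manifest.json``."""
    from .experiment import time_window

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    frames = []
    meta = {"schema_version": SCHEMA_VERSION, "runs": []}
    for log in logs:
        log.validate()
        n = log.n_participants
        rows = []
        for t in range(log.end_time):
            occupied = int(np.sum((log.bed_index >= 0) & (log.evac_time <= t)))
            for i in range(n):
                at_home = log.evac_time[i] < 0 or log.evac_time[i] >= t
                if at_home:
                    state = AT_HOME
                elif log.bed_index[i] >= 0:
                    state = IN_SHELTER
                else:
                    state = IN_TRANSIT
                rows.append(
                    (
                        log.run_id,
                        t,
                        i,
                        state,
                        int(log.evac_time[i] == t),
                        log.q_display[t],
                        time_window(t, log.regime),
                        occupied,
                        int(log.bed_index[i]),
                    )
                )
        frames.append(pd.DataFrame(rows, columns=_LOG_COLUMNS))
        meta["runs"].append(
            {
                "run_id": log.run_id,
                "regime": log.regime.value,
                "end_time": int(log.end_time),
                "outcome": log.outcome.value,
                "shelter_capacity": int(log.shelter_capacity),
                "loss_matrix": log.loss_matrix.as_dict(),
            }
        )
    table = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=_LOG_COLUMNS)
    )
    table.to_csv(path / "logs.csv", index=False)
    (path / "manifest.json").write_text(json.dumps(meta, indent=1))


def read_run_logs(path: str | Path) -> list[RunLog]:
    """Read and validate run logs written by :func:`write_run_logs`.

    Raises on unknown schema versions, unknown states, violations of the
    at-home bookkeeping identity, or shelter occupancy above capacity.
    An empty or missing directory yields an empty list.
    """
    import warnings

    path = Path(path)
    if not (path / "manifest.json").exists():
        warnings.warn(f"no run logs found under {path}", stacklevel=2)
        return []
    meta = json.loads((path / "manifest.json").read_text())
    if meta.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(
            f"unsupported run-log schema version {meta.get('schema_version')!r}"
        )
    table = pd.read_csv(path / "logs.csv")
    bad_states = set(table["state"].unique()) - set(STATES)
    if bad_states:
        raise ValueError(f"unknown states in log: {sorted(bad_states)}")
    logs = []
    for entry in meta["runs"]:
        run_id = entry["run_id"]
        sub = table.loc[table["run_id"] == run_id]
        end_time = entry["end_time"]
        n = sub["participant_id"].nunique()
        evac_time = np.full(n, -1, dtype=int)
        bed_index = np.full(n, -1, dtype=int)
        H = np.ones((end_time + 1, n), dtype=int)
        E = np.zeros((end_time, n), dtype=int)
        q_display = np.zeros(end_time)
        for row in sub.itertuples(index=False):
            t, i = int(row.t), int(row.participant_id)
            q_display[t] = row.q_display
            H[t, i] = 1 if row.state == AT_HOME else 0
            E[t, i] = int(row.evac_event)
            if row.evac_event:
                evac_time[i] = t
            if int(row.bed) >= 0:
                bed_index[i] = int(row.bed)
        H[end_time] = H[end_time - 1] - E[end_time - 1]
        mismatch = np.argwhere(H[1:end_time] != H[:end_time - 1] - E[:end_time - 1])
        if mismatch.size:
            t_bad, i_bad = mismatch[0]
            raise ValueError(
                f"{run_id}: at-home identity violated at "
                f"(participant={i_bad}, t={t_bad})"
            )
        log = RunLog(
            run_id=run_id,
            regime=Regime(entry["regime"]),
            end_time=end_time,
            outcome=Outcome(entry["outcome"]),
            q_display=q_display,
            shelter_capacity=entry["shelter_capacity"],
            loss_matrix=LossMatrix(**entry["loss_matrix"]),
            evac_time=evac_time,
            bed_index=bed_index,
        )
        log.validate()
        logs.append(log)
    return logs


# ---------------------------------------------------------------------------
# recovery study


def recovery_study(
    true_model: SixParamModel = DEFAULT_POPULATION_MODEL,
    n_runs: int = 188,
    n_reps: int = 20,
    seed: int | None = 0,
) -> tuple[dict, pd.DataFrame]:
    """Generate-and-refit study of the six-parameter model.

    Each repetition simulates a fresh experiment (``n_runs`` runs of 50
    agents, shelter capacities and both timing regimes crossed, new
    threat trajectories) from ``true_model``, aggregates counts by
    (q, B, T) and refits by count MLE.  Returns mean recovered parameters
    over repetitions plus the per-repetition estimates.
    """
    ss = np.random.SeedSequence(seed, spawn_key=(404,))
    rep_seeds = ss.spawn(n_reps)
    rows = []
    for rep, rep_ss in enumerate(rep_seeds):
        gen_seed = int(rep_ss.generate_state(1)[0] % (2**31))
        pool = default_trajectory_pool(seed=gen_seed)
        design = make_design(n_runs=n_runs, trajectory_pool=pool, seed=gen_seed)
        logs, _ = generate_experiment(design, true_model, rng_seed=gen_seed)
        cells = aggregate_counts(build_indicators(logs), "by_q_B_T")
        fit = fit_six_param(cells)
        row = _params_as_dict(fit.params)
        row["replicate"] = rep
        row["log_likelihood"] = fit.log_likelihood
        rows.append(row)
    reps = pd.DataFrame(rows).set_index("replicate")
    names = ("h", "r_t1", "r_t2", "r_t3", "theta0", "c")
    summary = {
        "true": {k: getattr(true_model, k) for k in names},
        "mean": {k: float(reps[k].mean()) for k in names},
        "sd": {k: float(reps[k].std(ddof=1)) for k in names},
        "n_runs": n_runs,
        "n_reps": n_reps,
    }
    return summary, reps


# ---------------------------------------------------------------------------
# pipeline


class PipelineConfig(BaseModel):
    """Configuration of the end-to-end pipeline (all stages seeded from
    ``seed`` via named substreams)."""

    out_dir: str
    seed: int = 0
    n_runs: int = Field(47, ge=2)
    scheme: str = "by_q_B_T"
    model: dict = Field(default_factory=lambda: DEFAULT_POPULATION_MODEL.as_dict())
    n_boot: int = Field(50, ge=0)
    run_loocv: bool = True


def run_pipeline(config: PipelineConfig) -> dict:
    """Generate -> estimate -> fit -> validate -> predict, writing a
    machine-readable report bundle under ``config.out_dir``."""
    import logging

    logger = logging.getLogger("evacdyn.pipeline")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    model = SixParamModel(**config.model)

    logger.info("generating %d runs", config.n_runs)
    pool = default_trajectory_pool(seed=config.seed)
    design = make_design(n_runs=config.n_runs, trajectory_pool=pool, seed=config.seed)
    logs, manifest = generate_experiment(design, model, rng_seed=config.seed)
    write_run_logs(logs, out / "logs")

    panel = build_indicators(logs)
    report: dict = {"config": config.model_dump(), "stages": {}}
    for scheme, fit_op in (
        ("by_q", fit_hill),
        ("by_q_B", fit_capacity_model),
        ("by_q_B_T", fit_six_param),
    ):
        cells = aggregate_counts(panel, scheme)
        cells.to_csv(out / f"rates_{scheme}.csv", index=False)
        fit = fit_op(cells)
        report["stages"][scheme] = {
            "params": _params_as_dict(fit.params),
            "log_likelihood": fit.log_likelihood,
            "n_cells": fit.n_cells,
            "converged": fit.converged,
        }

    if config.n_boot >= 2:
        sds, reps = bootstrap_params(
            logs, fit_six_param, n_boot=config.n_boot, rng_seed=config.seed
        )
        reps.to_csv(out / "bootstrap_replicates.csv")
        report["stages"]["by_q_B_T"]["bootstrap_sd"] = sds
    else:
        logger.warning("n_boot < 2: skipping bootstrap SDs")

    if config.run_loocv:
        curves = loocv(logs, fit_six_param)
        curves.to_csv(out / "loocv_curves.csv", index=False)
        gap = (curves["heldout"] - curves["full_model"]).abs().mean()
        rng = curves.groupby("run_id")["full_model"].agg(lambda s: s.max() - s.min())
        report["stages"]["loocv"] = {
            "mean_abs_gap": float(gap),
            "mean_curve_range": float(rng.mean()),
        }

    fitted = SixParamModel(**report["stages"]["by_q_B_T"]["params"])
    pred_rows, metrics = [], []
    scores = np.zeros(50)
    for cfg, log in zip(design, logs):
        pred = expected_at_home(fitted, log)
        cmp = compare_runs(pred, log)
        metrics.append({"run_id": log.run_id, "rmse": cmp["rmse"], "max_deviation": cmp["max_deviation"]})
        observed = log.at_home_count()
        for t in range(log.end_time + 1):
            pred_rows.append(
                {
                    "run_id": log.run_id,
                    "t": t,
                    "expected_at_home": pred.at_home[t],
                    "observed_at_home": int(observed[t]),
                    "residual": pred.at_home[t] - observed[t],
                }
            )
        scores += score_run(log)
    pd.DataFrame(pred_rows).to_csv(out / "predictions.csv", index=False)
    report["stages"]["prediction"] = {
        "median_rmse": float(np.median([m["rmse"] for m in metrics])),
        "max_deviation": float(max(m["max_deviation"] for m in metrics)),
    }
    report["cumulative_scores"] = {"mean": float(scores.mean()), "min": float(scores.min()), "max": float(scores.max())}

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report
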