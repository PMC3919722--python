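"""Forward prediction of collective evacuation and threshold payoffs.

Given a fitted rate model and a run's likelihood trajectory, the expected
number of participants still at home follows the deterministic recursion

    H_{t+1} = H_t * (1 - r(q_t; B, T(t))),    H_0 = 50,

whose complement 50 - H_t is the expected cumulative number of
evacuation decisions.  The recursion predicts decisions, not bed
assignment: shelter capacity enters only through the rate law, never as a
truncation of the predicted counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .experiment import (
    AT_HOME,
    IN_SHELTER,
    N_PARTICIPANTS,
    STAKE_POINTS,
    RunConfig,
    RunLog,
    time_window,
)
from .fitting import HillParams, SixParamModel, _hill
from .threat import Outcome, Regime

__all__ = [
    "PredictionSeries",
    "as_rate_model",
    "expected_at_home",
    "compare_runs",
    "strict_threshold_payoff",
]


@dataclass
class PredictionSeries:
    """Expected at-home counts per interval start (length end_time + 1)."""

    run_id: str
    at_home: np.ndarray

    @property
    def cumulative_evacuations(self) -> np.ndarray:
        return self.at_home[0] - self.at_home

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"run_id": self.run_id, "t": np.arange(len(self.at_home)), "expected_at_home": self.at_home}
        )


class _CapacityLinearModel:
    """Rate law with capacity-linear threshold but a single max rate."""

    def __init__(self, r_max: float, h: float, theta0: float, c: float):
        self.r_max, self.h, self.theta0, self.c = r_max, h, theta0, c

    def rate(self, q, capacity, window=None):
        return _hill(q, self.r_max, self.theta0 + self.c * capacity, self.h)


def as_rate_model(model):
    """Coerce fitted parameters into an object with
    ``rate(q, capacity, window)``; accepts SixParamModel, HillParams,
    capacity-model dicts, or anything already exposing ``rate``."""
    if isinstance(model, (SixParamModel, HillParams)):
        return model
    if isinstance(model, dict):
        if {"r_max", "h", "theta0", "c"} <= set(model):
            return _CapacityLinearModel(model["r_max"], model["h"], model["theta0"], model["c"])
        if {"r_max", "theta", "h"} <= set(model):
            return HillParams(model["r_max"], model["theta"], model["h"])
        raise ValueError(f"unrecognized parameter dict with keys {sorted(model)}")
    if hasattr(model, "rate"):
        return model
    raise TypeError(f"cannot interpret {type(model)} as a rate model")


def _run_attributes(run):
    """Extract (run_id, q_display, regime, capacity, end_time) from a
    RunConfig or RunLog."""
    if isinstance(run, RunConfig):
        traj = run.trajectory
        return run.run_id, traj.q_display, traj.regime, run.shelter_capacity, traj.end_time
    if isinstance(run, RunLog):
        return run.run_id, run.q_display, run.regime, run.shelter_capacity, run.end_time
    raise TypeError("run must be a RunConfig or RunLog")


def expected_at_home(model, run, n_agents: float = N_PARTICIPANTS) -> PredictionSeries:
    """Deterministic forward recursion for the expected at-home count.

    The rate switches windows at the 30 s mark in VariableTime runs; the
    recursion is linear in the initial count, so predicting for a
    different population size simply rescales the curve.
    """
    rate_model = as_rate_model(model)
    run_id, q_display, regime, capacity, end_time = _run_attributes(run)
    H = np.empty(end_time + 1)
    H[0] = n_agents
    for t in range(end_time):
        r = float(rate_model.rate(q_display[t], capacity, time_window(t, regime)))
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"model rate {r} outside [0, 1]")
        H[t + 1] = H[t] * (1.0 - r)
    return PredictionSeries(run_id=run_id, at_home=H)


def compare_runs(pred: PredictionSeries, log: RunLog) -> dict:
    """Residual metrics between an expected and an observed run.

    Residuals are (expected - observed) cumulative evacuations per
    second; returns RMSE, maximum absolute deviation and the residual
    series."""
    if pred.run_id != log.run_id:
        raise ValueError(f"run_id mismatch: {pred.run_id!r} vs {log.run_id!r}")
    observed = log.at_home_count().astype(float)
    if len(observed) != len(pred.at_home):
        raise ValueError("prediction and log cover different horizons")
    residuals = (pred.at_home[0] - pred.at_home) - (observed[0] - observed)
    return {
        "run_id": log.run_id,
        "rmse": float(np.sqrt(np.mean(residuals**2))),
        "max_deviation": float(np.max(np.abs(residuals))),
        "residuals": residuals,
    }


def strict_threshold_payoff(
    theta_grid, runs: list[RunConfig] | list[RunLog]
) -> pd.DataFrame:
    """Expected cumulative score of a solo strict-threshold player.

    For each threshold the player evacuates at the first second the
    displayed likelihood strictly exceeds it (entering the shelter:
    capacity and competition are deliberately ignored) and otherwise
    stays home; each run is scored from its own loss matrix and the
    scores summed.  The curve is piecewise constant with breakpoints only
    at the 11 display levels.
    """
    thetas = np.atleast_1d(np.asarray(theta_grid, dtype=float))
    if thetas.size == 0:
        raise ValueError("theta grid must be non-empty")
    totals = np.zeros(thetas.size)
    for run in runs:
        if isinstance(run, RunConfig):
            q, outcome, loss = (
                run.trajectory.q_display,
                run.trajectory.outcome,
                run.loss_matrix,
            )
        else:
            q, outcome, loss = run.q_display, run.outcome, run.loss_matrix
        q_max = q.max() if len(q) else 0.0
        for j, th in enumerate(thetas):
            state = IN_SHELTER if q_max > th else AT_HOME
            totals[j] += STAKE_POINTS - loss.loss(state, outcome)
    return pd.DataFrame({"theta": thetas, "expected_score": totals})
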