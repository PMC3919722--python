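"""Hill-function decision models and their count-level maximum likelihood.

The population's per-second evacuation rate as a function of the displayed
disaster likelihood q is modelled as a Hill function

    r(q) = r_max * q^h / (q^h + theta^h)

with maximum rate r_max, half-maximum threshold theta and steepness h
(large h approximates a strict threshold policy).  Two extensions tie the
threshold to shelter capacity B (theta(B) = theta0 + c * B, so scarcer
shelters lower the threshold and shift the rate curve left) and split
r_max by time-urgency window:

    r(q; B, T) = r_T * q^h / (q^h + theta(B)^h),   T in {1, 2, 3}

giving a six-parameter model (h, r_T1, r_T2, r_T3, theta0, c).

All fits maximize the Bernoulli-count log-likelihood over partition cells

    l = sum_k [ m_k ln r(q_k) + (n_k - m_k) ln(1 - r(q_k)) ]

i.e. a fit directly to the event/exposure counts (m, n), not to the
measured rates; this is the likelihood whose conjugate posterior is the
Beta(m+1, n-m+1) used for rate measurement.  Optimization is a
deterministic multi-start lattice refined by L-BFGS-B.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .experiment import RunLog
from .rates import aggregate_counts, build_indicators

__all__ = [
    "HillParams",
    "SixParamModel",
    "FitResult",
    "DEFAULT_POPULATION_MODEL",
    "hill_rate",
    "count_log_likelihood",
    "fit_hill",
    "fit_capacity_model",
    "fit_six_param",
    "bootstrap_params",
    "loocv",
    "fit_individuals",
    "score_parameter_correlations",
]

_EPS = 1e-9  # rate clamp inside logs
_H_BOUNDS = (0.5, 40.0)  # steepness beyond ~40 is unidentifiable on 11 q levels
_FIT_SEED = 20120518


@dataclass(frozen=True)
class HillParams:
    """Three-parameter population rate law."""

    r_max: float
    theta: float
    h: float

    def __post_init__(self) -> None:
        if not 0.0 < self.r_max <= 1.0:
            raise ValueError("r_max must lie in (0, 1]")
        if not 0.0 < self.theta < 1.0:
            raise ValueError("theta must lie in (0, 1)")
        if self.h <= 0.0:
            raise ValueError("h must be positive")

    def rate(self, q, capacity=None, window=None):
        return hill_rate(q, self)


@dataclass(frozen=True)
class SixParamModel:
    """Capacity- and urgency-dependent rate law.

    Windows: 1 = VariableTime before 30 s, 2 = VariableTime at/after
    30 s, 3 = CertainTime.  theta(B) = theta0 + c * B must stay inside
    (0, 1) over the capacity range 10-50.
    """

    h: float
    r_t1: float
    r_t2: float
    r_t3: float
    theta0: float
    c: float

    def __post_init__(self) -> None:
        if self.h <= 0.0:
            raise ValueError("h must be positive")
        for name in ("r_t1", "r_t2", "r_t3"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for B in (10, 50):
            if not 0.0 < self.theta(B) < 1.0:
                raise ValueError("theta(B) must stay inside (0, 1) for B in [10, 50]")

    def theta(self, capacity: float) -> float:
        return self.theta0 + self.c * capacity

    def r_max(self, window: int) -> float:
        return {1: self.r_t1, 2: self.r_t2, 3: self.r_t3}[int(window)]

    def rate(self, q, capacity, window):
        return _hill(q, self.r_max(window), self.theta(capacity), self.h)

    def as_dict(self) -> dict:
        return {
            "h": self.h,
            "r_t1": self.r_t1,
            "r_t2": self.r_t2,
            "r_t3": self.r_t3,
            "theta0": self.theta0,
            "c": self.c,
        }


#: Default generating model for synthetic experiments.  The values emulate
#: the population-level behavior measured in the laboratory evacuation
#: experiment this package's generator mimics: slow pre-deadline responses
#: (r_T1, r_T3), a fast response inside an uncertain strike window (r_T2),
#: and a likelihood threshold near 0.6 that rises slightly with shelter
#: capacity.
DEFAULT_POPULATION_MODEL = SixParamModel(
    h=9.3, r_t1=0.07, r_t2=0.37, r_t3=0.13, theta0=0.60, c=2e-3
)

_PARAM_NAMES = ("h", "r_t1", "r_t2", "r_t3", "theta0", "c")


def _hill(q, r_max, theta, h):
    q = np.asarray(q, dtype=float)
    qh = np.power(q, h, where=q > 0, out=np.zeros_like(q))
    out = r_max * qh / (qh + theta**h)
    return float(out) if out.ndim == 0 else out


def hill_rate(q, params: HillParams):
    """Evaluate the Hill rate law; q may be a scalar or array in [0, 1]."""
    if np.any(np.asarray(q) < 0) or np.any(np.asarray(q) > 1):
        raise ValueError("q must lie in [0, 1]")
    return _hill(q, params.r_max, params.theta, params.h)


def count_log_likelihood(model_rates, m, n) -> float:
    """Bernoulli-count log-likelihood of per-cell rates given event counts
    m out of exposures n.  Cells must have n > 0 (filter unobserved cells
    first); rates are clamped away from {0, 1} before taking logs."""
    r = np.clip(np.asarray(model_rates, dtype=float), _EPS, 1.0 - _EPS)
    m = np.asarray(m, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(n <= 0):
        raise ValueError("cells with zero exposure must be excluded from the likelihood")
    return float(np.sum(m * np.log(r) + (n - m) * np.log(1.0 - r)))


@dataclass
class FitResult:
    params: object
    log_likelihood: float
    n_cells: int
    converged: bool
    degenerate: bool = False
    bootstrap_sd: dict | None = None
    message: str = ""


def _observed(cells: pd.DataFrame) -> pd.DataFrame:
    if "unobserved" in cells.columns:
        return cells.loc[~cells["unobserved"]]
    return cells.loc[cells["n"] > 0]


def _maximize(objective, starts, bounds):
    """Deterministic multi-start L-BFGS-B maximization of `objective`."""
    best = None
    for x0 in starts:
        res = optimize.minimize(
            lambda x: -objective(x),
            x0=np.asarray(x0, dtype=float),
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": 1e-12, "gtol": 1e-10, "maxiter": 500},
        )
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    return best


def fit_hill(cells: pd.DataFrame) -> FitResult:
    """Fit the three-parameter Hill law to by-q cells by count MLE."""
    obs = _observed(cells)
    if len(obs) < 3:
        raise ValueError("need at least 3 observed cells to fit a Hill law")
    q = obs["q"].to_numpy(float)
    m = obs["m"].to_numpy(float)
    n = obs["n"].to_numpy(float)

    def objective(x):
        r_max, theta, h = x
        return count_log_likelihood(_hill(q, r_max, theta, h), m, n)

    starts = [
        (r0, t0, h0)
        for r0 in (0.05, 0.3, 0.8)
        for t0 in (0.3, 0.55, 0.8)
        for h0 in (1.0, 5.0, 15.0)
    ]
    bounds = [(1e-4, 1.0), (0.01, 0.99), _H_BOUNDS]
    best = _maximize(objective, starts, bounds)
    params = HillParams(r_max=best.x[0], theta=best.x[1], h=best.x[2])
    degenerate = m.sum() == 0 or params.r_max <= bounds[0][0] * 1.01
    return FitResult(
        params=params,
        log_likelihood=-best.fun,
        n_cells=len(obs),
        converged=bool(best.success),
        degenerate=bool(degenerate),
        message=str(best.message),
    )


def fit_capacity_model(cells: pd.DataFrame) -> FitResult:
    """Fit shared (r_max, h) with a capacity-linear threshold
    theta(B) = theta0 + c*B to by-(q, B) cells."""
    obs = _observed(cells)
    if "B" not in obs.columns:
        raise ValueError("capacity model needs by_q_B cells")
    if obs["B"].nunique() < 2:
        raise ValueError("only one capacity level observed; use fit_hill instead")
    q = obs["q"].to_numpy(float)
    B = obs["B"].to_numpy(float)
    m = obs["m"].to_numpy(float)
    n = obs["n"].to_numpy(float)

    def objective(x):
        r_max, h, theta0, c = x
        theta = np.clip(theta0 + c * B, 0.01, 0.99)
        return count_log_likelihood(_hill(q, r_max, theta, h), m, n)

    starts = [
        (r0, h0, t0, c0)
        for r0 in (0.05, 0.3, 0.8)
        for h0 in (1.0, 5.0, 15.0)
        for t0 in (0.35, 0.6, 0.8)
        for c0 in (-0.002, 0.0, 0.002)
    ]
    bounds = [(1e-4, 1.0), _H_BOUNDS, (0.01, 0.99), (-0.02, 0.02)]
    best = _maximize(objective, starts, bounds)
    params = {
        "r_max": float(best.x[0]),
        "h": float(best.x[1]),
        "theta0": float(best.x[2]),
        "c": float(best.x[3]),
    }
    return FitResult(
        params=params,
        log_likelihood=-best.fun,
        n_cells=len(obs),
        converged=bool(best.success),
        degenerate=bool(m.sum() == 0),
        message=str(best.message),
    )


def fit_six_param(cells: pd.DataFrame) -> FitResult:
    """Fit the six-parameter model (shared h, theta0, c; per-window max
    rates) to by-(q, B, T) cells."""
    obs = _observed(cells)
    for col in ("B", "T"):
        if col not in obs.columns:
            raise ValueError("six-parameter model needs by_q_B_T cells")
    windows = sorted(obs["T"].unique().tolist())
    if windows != [1, 2, 3]:
        raise ValueError(f"all three time windows must be observed, got {windows}")
    q = obs["q"].to_numpy(float)
    B = obs["B"].to_numpy(float)
    T = obs["T"].to_numpy(int)
    m = obs["m"].to_numpy(float)
    n = obs["n"].to_numpy(float)
    w_masks = [T == w for w in (1, 2, 3)]

    def objective(x):
        h, r1, r2, r3, theta0, c = x
        r_max = np.empty_like(q)
        for mask, r in zip(w_masks, (r1, r2, r3)):
            r_max[mask] = r
        theta = np.clip(theta0 + c * B, 0.01, 0.99)
        return count_log_likelihood(_hill(q, r_max, theta, h), m, n)

    # crude per-window saturation rates seed the rate starts
    r_seed = []
    for mask in w_masks:
        high = mask & (q >= 0.8) & (n > 0)
        r_seed.append(
            float(np.clip(m[high].sum() / max(n[high].sum(), 1.0), 0.02, 0.95))
            if high.any()
            else 0.2
        )
    starts = [
        (h0, *r_seed, t0, c0)
        for h0 in (2.0, 6.0, 12.0)
        for t0 in (0.45, 0.6, 0.75)
        for c0 in (-0.002, 0.0, 0.002)
    ] + [
        (h0, r0, r0, r0, 0.6, 0.0)
        for h0 in (4.0, 10.0)
        for r0 in (0.1, 0.4)
    ]
    bounds = [
        _H_BOUNDS,
        (1e-4, 1.0),
        (1e-4, 1.0),
        (1e-4, 1.0),
        (0.01, 0.99),
        (-0.02, 0.02),
    ]
    best = _maximize(objective, starts, bounds)
    params = SixParamModel(
        h=float(best.x[0]),
        r_t1=float(best.x[1]),
        r_t2=float(best.x[2]),
        r_t3=float(best.x[3]),
        theta0=float(best.x[4]),
        c=float(best.x[5]),
    )
    return FitResult(
        params=params,
        log_likelihood=-best.fun,
        n_cells=len(obs),
        converged=bool(best.success),
        degenerate=bool(m.sum() == 0),
        message=str(best.message),
    )


_SCHEME_FOR_FIT = {
    fit_hill: "by_q",
    fit_capacity_model: "by_q_B",
    fit_six_param: "by_q_B_T",
}


def _params_as_dict(params) -> dict:
    if isinstance(params, dict):
        return params
    if isinstance(params, SixParamModel):
        return params.as_dict()
    if isinstance(params, HillParams):
        return {"r_max": params.r_max, "theta": params.theta, "h": params.h}
    raise TypeError(f"cannot flatten params of type {type(params)}")


def bootstrap_params(
    logs: list[RunLog],
    fit_op=fit_six_param,
    n_boot: int = 200,
    rng_seed: int | None = _FIT_SEED,
    scheme: str | None = None,
) -> tuple[dict, pd.DataFrame]:
    """Bootstrap per-parameter SDs by resampling whole runs with
    replacement, re-aggregating and re-fitting.

    Returns (sd per parameter, DataFrame of replicate estimates).
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    scheme = scheme or _SCHEME_FOR_FIT.get(fit_op, "by_q_B_T")
    rng = np.random.default_rng(rng_seed)
    rows = []
    n_degenerate = 0
    for b in range(n_boot):
        picks = rng.integers(0, len(logs), size=len(logs))
        sample = [logs[i] for i in picks]
        cells = aggregate_counts(build_indicators(sample), scheme)
        try:
            fit = fit_op(cells)
        except ValueError:
            n_degenerate += 1
            continue
        if fit.degenerate:
            n_degenerate += 1
        row = _params_as_dict(fit.params)
        row["replicate"] = b
        rows.append(row)
    if not rows:
        raise RuntimeError("all bootstrap replicates were degenerate")
    reps = pd.DataFrame(rows).set_index("replicate")
    sds = {k: float(reps[k].std(ddof=1)) for k in reps.columns}
    sds["n_degenerate"] = n_degenerate
    return sds, reps


def loocv(
    logs: list[RunLog],
    fit_op=fit_six_param,
    scheme: str | None = None,
) -> pd.DataFrame:
    """Leave-one-out cross-validation of forward predictions.

    For each run, the model is refit on all other runs and used to
    forward-predict the held-out run's expected at-home curve; the
    full-model prediction and the observed curve accompany it.  Returns a
    tidy frame (run_id, t, observed, full_model, heldout).
    """
    from .prediction import expected_at_home

    if len(logs) < 2:
        raise ValueError("LOOCV needs at least 2 runs")
    scheme = scheme or _SCHEME_FOR_FIT.get(fit_op, "by_q_B_T")
    full_fit = fit_op(aggregate_counts(build_indicators(logs), scheme))
    rows = []
    for i, log in enumerate(logs):
        rest = logs[:i] + logs[i + 1 :]
        fold_fit = fit_op(aggregate_counts(build_indicators(rest), scheme))
        full_pred = expected_at_home(full_fit.params, log)
        fold_pred = expected_at_home(fold_fit.params, log)
        observed = log.at_home_count()
        for t in range(log.end_time + 1):
            rows.append(
                {
                    "run_id": log.run_id,
                    "t": t,
                    "observed": float(observed[t]),
                    "full_model": float(full_pred.at_home[t]),
                    "heldout": float(fold_pred.at_home[t]),
                }
            )
    return pd.DataFrame(rows)


def fit_individuals(logs: list[RunLog]) -> pd.DataFrame:
    """Independent Hill fits per participant on by-(q, participant) cells.

    Participants whose data cannot support a fit (e.g. zero evacuations)
    are returned with NaN parameters and ``degenerate=True``.
    """
    panel = build_indicators(logs)
    cells = aggregate_counts(panel, "by_q_individual")
    out = []
    for pid, sub in cells.groupby("participant"):
        row: dict = {"participant": int(pid)}
        obs = sub.loc[~sub["unobserved"]]
        try:
            fit = fit_hill(sub)
            row.update(_params_as_dict(fit.params))
            row["log_likelihood"] = fit.log_likelihood
            row["degenerate"] = fit.degenerate
        except ValueError:
            row.update({"r_max": np.nan, "theta": np.nan, "h": np.nan})
            row["log_likelihood"] = np.nan
            row["degenerate"] = True
        row["n_cells"] = int(len(obs))
        row["n_evacuations"] = int(obs["m"].sum())
        out.append(row)
    return pd.DataFrame(out).set_index("participant")


def score_parameter_correlations(
    individual_fits: pd.DataFrame, scores: np.ndarray
) -> pd.DataFrame:
    """Pearson correlations (with two-sided p-values) between fitted
    individual parameters and cumulative scores.

    ``scores`` is indexed by participant id; degenerate fits are skipped.
    No multiple-testing correction is applied (exploratory usage).
    """
    scores = np.asarray(scores, dtype=float)
    rows = []
    ok = ~individual_fits["degenerate"].astype(bool)
    for param in ("r_max", "theta", "h"):
        vals = individual_fits.loc[ok, param].to_numpy(float)
        sc = scores[individual_fits.index[ok]]
        keep = np.isfinite(vals)
        if keep.sum() < 3:
            rows.append({"parameter": param, "pearson_r": np.nan, "p_value": np.nan, "n": int(keep.sum())})
            continue
        r, p = stats.pearsonr(vals[keep], sc[keep])
        rows.append({"parameter": param, "pearson_r": float(r), "p_value": float(p), "n": int(keep.sum())})
    return pd.DataFrame(rows).set_index("parameter")
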