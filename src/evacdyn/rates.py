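"""Beta-posterior evacuation-rate estimation from run logs.

For every one-second interval we record two indicators per participant:
H = 1 if the participant was AtHome at the start of the interval, and
E = 1 if they evacuated during it (so H at the next interval equals
H - E).  Aggregating over a partition of the observed covariates
(likelihood level q, optionally shelter capacity B, time window T, or
participant) yields an exposure count n (at-home intervals) and an event
count m (evacuations) per cell.  Treating the m events among n exposures
as Bernoulli trials, the per-second rate has a Beta(m+1, n-m+1) posterior
under a uniform prior; cells report its mean and standard deviation:

    R  = (m + 1) / (n + 2)
    sd = sqrt((m + 1)(n - m + 1) / ((n + 2)^2 (n + 3)))

which converge to m/n and 0 with abundant data but avoid overconfidence
in sparse cells.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd

from .experiment import RunLog, time_window
from .threat import DISPLAY_LEVELS

__all__ = [
    "SCHEMES",
    "beta_rate",
    "build_indicators",
    "aggregate_counts",
]

#: Supported partition schemes and their grouping keys.
SCHEMES = {
    "by_q": ("q",),
    "by_q_B": ("q", "B"),
    "by_q_B_T": ("q", "B", "T"),
    "by_q_individual": ("q", "participant"),
}


def beta_rate(m, n):
    """Posterior mean and SD of a per-second rate from m events in n
    exposures (uniform prior).  Accepts scalars or arrays; requires
    0 <= m <= n."""
    m_arr = np.asarray(m, dtype=float)
    n_arr = np.asarray(n, dtype=float)
    if np.any(m_arr < 0) or np.any(n_arr < 0) or np.any(m_arr > n_arr):
        raise ValueError("need 0 <= m <= n")
    R = (m_arr + 1.0) / (n_arr + 2.0)
    sd = np.sqrt(
        (m_arr + 1.0) * (n_arr - m_arr + 1.0) / ((n_arr + 2.0) ** 2 * (n_arr + 3.0))
    )
    if np.isscalar(m) and np.isscalar(n):
        return float(R), float(sd)
    return R, sd


def build_indicators(logs: list[RunLog]) -> pd.DataFrame:
    """Dense per-(run, second, participant) indicator panel.

    Columns: run_id, t, participant, H, E, q (display level), B (shelter
    capacity), T (time window 1/2/3).  Intervals after a run's end carry
    no rows.  The H/E bookkeeping identity (H drops by exactly E each
    second) holds by construction here and is re-verified as a data
    integrity check on every log.
    """
    frames = []
    for log in logs:
        log.validate()
        n = log.n_participants
        T_run = log.end_time
        t_grid = np.repeat(np.arange(T_run), n)
        pid = np.tile(np.arange(n), T_run)
        evac = log.evac_time[pid]
        H = ((evac < 0) | (evac >= t_grid)).astype(np.int8)
        E = (evac == t_grid).astype(np.int8)
        # integrity: H_{i,t+1} == H_{i,t} - E_{i,t}
        H_mat = H.reshape(T_run, n)
        E_mat = E.reshape(T_run, n)
        if T_run > 1 and not np.array_equal(H_mat[1:], H_mat[:-1] - E_mat[:-1]):
            bad = np.argwhere(H_mat[1:] != H_mat[:-1] - E_mat[:-1])[0]
            raise ValueError(
                f"{log.run_id}: at-home indicator not conserved at "
                f"(participant={bad[1]}, t={bad[0]})"
            )
        windows = np.array([time_window(t, log.regime) for t in range(T_run)], dtype=np.int8)
        frames.append(
            pd.DataFrame(
                {
                    "run_id": log.run_id,
                    "t": t_grid,
                    "participant": pid,
                    "H": H,
                    "E": E,
                    "q": np.round(log.q_display[t_grid], 1),
                    "B": log.shelter_capacity,
                    "T": windows[t_grid],
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=["run_id", "t", "participant", "H", "E", "q", "B", "T"]
        )
    return pd.concat(frames, ignore_index=True)


def aggregate_counts(panel: pd.DataFrame, scheme: str = "by_q") -> pd.DataFrame:
    """Aggregate an indicator panel into per-cell counts and rates.

    Returns one row per partition cell with columns: the grouping keys,
    n (exposure), m (events), R, sd, and ``unobserved`` flagging cells of
    the full factor grid that collected no exposure (such cells carry the
    prior mean/SD and must be excluded from fitting).
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {sorted(SCHEMES)}")
    keys = list(SCHEMES[scheme])

    if len(panel) == 0:
        counts = pd.DataFrame(columns=[*keys, "n", "m"])
    else:
        grouped = panel.groupby(keys, as_index=False).agg(n=("H", "sum"), m=("E", "sum"))
        counts = grouped

    # complete the factor grid: all 11 q levels crossed with observed levels
    # of the other keys
    level_values = {"q": list(DISPLAY_LEVELS)}
    for key in keys[1:]:
        level_values[key] = sorted(panel[key].unique()) if len(panel) else []
    grid = pd.DataFrame(
        itertools.product(*(level_values[k] for k in keys)), columns=keys
    )
    cells = grid.merge(counts, on=keys, how="outer")
    for col in ("n", "m"):
        cells[col] = pd.to_numeric(cells[col], errors="coerce").fillna(0).astype(int)
    cells["unobserved"] = cells["n"] == 0
    R, sd = beta_rate(cells["m"].to_numpy(), cells["n"].to_numpy())
    cells["R"] = R
    cells["sd"] = sd
    cells.insert(0, "scheme", scheme)
    return cells.sort_values(keys).reset_index(drop=True)
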