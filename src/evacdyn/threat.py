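"""Stochastic threat trajectories and their per-second hit likelihoods.

A threat advances monotonically toward a target while drifting laterally as
a bounded integer random walk.  Each second the participant-facing display
shows the current probability that the threat will ultimately contact the
target, truncated to the eleven levels 0.0, 0.1, ..., 1.0.  The exact
likelihood is computed by backward recursion over the lateral walk, so the
displayed series is (before truncation) a martingale of the Hit/Miss
outcome.

Two timing regimes are supported.  In ``CertainTime`` the threat advances
one forward step per second and resolves at exactly the horizon (60 s).  In
``VariableTime`` each second the forward position advances by 1 or 2 steps
with fixed probability, so a 60-step approach resolves at an unpredictable
time between 30 and 60 seconds.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

__all__ = [
    "Regime",
    "Outcome",
    "ThreatConfig",
    "ThreatTrajectory",
    "DISPLAY_LEVELS",
    "display_level",
    "hit_likelihood",
    "likelihood_table",
    "simulate_threat",
]


class Regime(str, enum.Enum):
    """Timing regime: resolution at exactly 60 s, or anywhere in 30-60 s."""

    CERTAIN_TIME = "CertainTime"
    VARIABLE_TIME = "VariableTime"


class Outcome(str, enum.Enum):
    HIT = "Hit"
    MISS = "Miss"


#: The 11 likelihood levels shown to participants.
DISPLAY_LEVELS = tuple(round(k / 10, 1) for k in range(11))


class ThreatConfigError(ValueError):
    """Raised for inconsistent threat-process configurations."""


@dataclass(frozen=True)
class ThreatConfig:
    """Parameters of the threat process.

    Parameters
    ----------
    regime:
        Timing regime (CertainTime or VariableTime).
    horizon:
        Scenario length in seconds; the forward distance of the threat.
        The experiment used 60 s runs.
    lateral_volatility:
        Maximum lateral step size ``v``; each second the lateral position
        moves by an integer drawn uniformly from ``{-v, ..., +v}``.  The
        degenerate ``v = 0`` (no lateral motion) is allowed for testing
        deterministic collisions.
    target_halfwidth:
        Half-width ``w`` of the target interval; the threat Hits iff its
        final lateral position lies in ``[-w, w]``.
    lateral_extent:
        Grid bound ``E``; the lateral walk is clamped to ``[-E, E]``.
    start_lateral:
        Initial lateral offset of the threat from the target centre.
    fast_step_prob:
        VariableTime only: probability that the forward position advances
        by 2 (rather than 1) in a given second.  With a forward distance
        equal to ``horizon`` this lands the end time in
        ``[horizon/2, horizon]`` with no further conditioning.
    """

    regime: Regime = Regime.CERTAIN_TIME
    horizon: int = 60
    lateral_volatility: int = 1
    target_halfwidth: int = 4
    lateral_extent: int = 40
    start_lateral: int = 0
    fast_step_prob: float = 0.5

    def __post_init__(self) -> None:
        if self.horizon < 1:
            raise ThreatConfigError("horizon must be a positive number of seconds")
        if self.lateral_volatility < 0:
            raise ThreatConfigError("lateral_volatility must be >= 0")
        if self.target_halfwidth < 0:
            raise ThreatConfigError("target_halfwidth must be >= 0")
        if self.lateral_extent < self.target_halfwidth:
            raise ThreatConfigError("lateral_extent must cover the target")
        if abs(self.start_lateral) > self.lateral_extent:
            raise ThreatConfigError("start_lateral lies outside the lateral grid")
        if not 0.0 <= self.fast_step_prob <= 1.0:
            raise ThreatConfigError("fast_step_prob must be a probability")
        if not isinstance(self.regime, Regime):
            object.__setattr__(self, "regime", Regime(self.regime))


@dataclass
class ThreatTrajectory:
    """A realized threat trajectory as seen from the participants' side.

    ``q_display[t]`` / ``q_exact[t]`` give the displayed / exact hit
    likelihood during the one-second interval ``[t, t+1)``; the series has
    length ``end_time``.
    """

    q_display: np.ndarray
    q_exact: np.ndarray
    end_time: int
    outcome: Outcome
    regime: Regime
    trajectory_id: str = ""
    seed: int | None = None
    config: ThreatConfig | None = None

    def __post_init__(self) -> None:
        self.q_display = np.asarray(self.q_display, dtype=float)
        self.q_exact = np.asarray(self.q_exact, dtype=float)
        if len(self.q_display) != self.end_time or len(self.q_exact) != self.end_time:
            raise ValueError("likelihood series must have length end_time")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "t": np.arange(self.end_time),
                "q_display": self.q_display,
                "q_exact": self.q_exact,
            }
        )


def display_level(q_exact: float) -> float:
    """Truncate an exact likelihood to the lower of the 11 display levels.

    The display never overstates the likelihood: 0.437 shows as 0.4.  Exact
    multiples of 0.1 map to themselves, and 1.0 maps to 1.0.
    """
    q = float(q_exact)
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"likelihood must lie in [0, 1], got {q}")
    # tolerance guards against values like 0.7 stored as 0.6999999999999999
    level = math.floor(q * 10 + 1e-9)
    return min(level, 10) / 10


def _display_levels(q_exact: np.ndarray) -> np.ndarray:
    q = np.asarray(q_exact, dtype=float)
    return np.minimum(np.floor(q * 10 + 1e-9), 10) / 10


@lru_cache(maxsize=64)
def _table_cached(
    regime: Regime,
    forward_distance: int,
    volatility: int,
    halfwidth: int,
    extent: int,
    fast_step_prob: float,
) -> np.ndarray:
    """Backward-recursion table L[d, x+extent] = P(Hit | d forward steps
    remaining, lateral position x).

    Each second the lateral position moves first (uniform step in
    ``{-v..v}``, clamped to the grid) and the forward distance then drops by
    the forward step; the outcome is resolved the moment the remaining
    distance reaches zero or below.
    """
    width = 2 * extent + 1
    xs = np.arange(-extent, extent + 1)
    table = np.zeros((forward_distance + 1, width))
    table[0] = (np.abs(xs) <= halfwidth).astype(float)

    v = volatility
    # transition matrix of one clamped lateral step applied to a value vector
    def lateral_mean(values: np.ndarray) -> np.ndarray:
        if v == 0:
            return values.copy()
        acc = np.zeros(width)
        for s in range(-v, v + 1):
            idx = np.clip(xs + s, -extent, extent) + extent
            acc += values[idx]
        return acc / (2 * v + 1)

    p2 = fast_step_prob if regime is Regime.VARIABLE_TIME else 0.0
    for d in range(1, forward_distance + 1):
        if regime is Regime.CERTAIN_TIME:
            after = table[d - 1]
        else:
            after = (1.0 - p2) * table[d - 1] + p2 * table[max(d - 2, 0)]
        table[d] = lateral_mean(after)
    return table


def likelihood_table(config: ThreatConfig) -> np.ndarray:
    """Full hit-likelihood table for a configuration (rows: remaining
    forward distance 0..horizon; columns: lateral position -E..E)."""
    return _table_cached(
        config.regime,
        config.horizon,
        config.lateral_volatility,
        config.target_halfwidth,
        config.lateral_extent,
        config.fast_step_prob,
    )


def hit_likelihood(
    state: tuple[int, int], config: ThreatConfig
) -> float:
    """P(threat ultimately contacts the target | current state).

    ``state`` is ``(lateral_position, remaining_forward_steps)``.
    """
    x, d = state
    if d < 0:
        raise ThreatConfigError("remaining_forward_steps must be >= 0")
    if abs(x) > config.lateral_extent:
        raise ThreatConfigError(f"lateral position {x} lies off the grid")
    if d > config.horizon:
        raise ThreatConfigError("remaining forward distance exceeds the horizon")
    return float(likelihood_table(config)[d, x + config.lateral_extent])


def simulate_threat(
    config: ThreatConfig,
    rng: np.random.Generator | int | None = None,
    trajectory_id: str = "",
) -> ThreatTrajectory:
    """Draw one threat trajectory and record the per-second likelihoods.

    ``q_exact[t]`` is the hit likelihood of the state at the start of
    second ``t`` and ``q_display[t]`` its truncation to the 11 display
    levels.  CertainTime trajectories resolve at exactly ``horizon``
    seconds; VariableTime trajectories resolve in
    ``[horizon/2, horizon]``.
    """
    seed = rng if isinstance(rng, (int, np.integer)) else None
    gen = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    table = likelihood_table(config)
    E = config.lateral_extent
    v = config.lateral_volatility
    horizon = config.horizon

    # lateral path (clamped walk), one step per second
    if v > 0:
        steps = gen.integers(-v, v + 1, size=horizon)
    else:
        steps = np.zeros(horizon, dtype=int)
    path = config.start_lateral + np.cumsum(steps)
    if np.abs(path).max(initial=0) > E:  # rare: re-walk with clamping
        x = config.start_lateral
        for i in range(horizon):
            x = int(np.clip(x + steps[i], -E, E))
            path[i] = x
    positions = np.concatenate(([config.start_lateral], path))  # x at start of each second

    # forward distances at the start of each second
    if config.regime is Regime.CERTAIN_TIME:
        fsteps = np.ones(horizon, dtype=int)
    else:
        fsteps = 1 + (gen.random(horizon) < config.fast_step_prob).astype(int)
    remaining = horizon - np.concatenate(([0], np.cumsum(fsteps)))
    end_candidates = np.nonzero(remaining <= 0)[0]
    end_time = int(end_candidates[0])

    q_exact = np.array(
        [table[remaining[t], positions[t] + E] for t in range(end_time)]
    )
    outcome = (
        Outcome.HIT if abs(int(positions[end_time])) <= config.target_halfwidth else Outcome.MISS
    )
    return ThreatTrajectory(
        q_display=_display_levels(q_exact),
        q_exact=q_exact,
        end_time=end_time,
        outcome=outcome,
        regime=config.regime,
        trajectory_id=trajectory_id,
        seed=seed,
        config=config,
    )
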