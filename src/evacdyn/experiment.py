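"""Synthetic evacuation experiments: networks, designs, agent decisions.

Each run places 50 networked agents in front of a threat trajectory with a
limited-capacity shelter.  Every second, each agent still at home
evacuates with a per-second probability given by a rate model evaluated at
the displayed likelihood, the shelter capacity and the time-urgency
window.  Evacuees claim beds in random within-second order until the
shelter fills; later evacuees are stranded in transit.  Losses are
assessed from a 3x2 loss matrix (final state x Hit/Miss) against a
100-point stake per run.

Social networks are generated and logged for interface completeness: the
decision law itself depends only on broadcast information (likelihood,
capacity, timing), mirroring the observation that essentially all
evacuation decisions were taken while viewing broadcast information.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np

from .threat import (
    Outcome,
    Regime,
    ThreatConfig,
    ThreatTrajectory,
    simulate_threat,
)

__all__ = [
    "N_PARTICIPANTS",
    "SHELTER_CAPACITIES",
    "STAKE_POINTS",
    "VARIABLE_DEGREE_SEQUENCE",
    "AT_HOME",
    "IN_TRANSIT",
    "IN_SHELTER",
    "NetworkSpec",
    "LossMatrix",
    "RunConfig",
    "RunLog",
    "default_loss_matrices",
    "default_network_specs",
    "default_trajectory_pool",
    "build_network",
    "make_design",
    "simulate_run",
    "score_run",
    "generate_experiment",
    "time_window",
]

N_PARTICIPANTS = 50
SHELTER_CAPACITIES = (50, 40, 30, 20, 10)
STAKE_POINTS = 100

#: Degree sequence of the "variable" random graphs (50 nodes, 100 edges,
#: mean degree 4): ten nodes of degree 1, eight of degree 2, and so on.
VARIABLE_DEGREE_SEQUENCE = tuple(
    itertools.chain(
        [1] * 10, [2] * 8, [3] * 7, [4] * 6, [5] * 5, [6] * 4, [7] * 4, [8] * 3, [9] * 2, [10] * 1
    )
)

AT_HOME = "AtHome"
IN_TRANSIT = "InTransit"
IN_SHELTER = "InShelter"
STATES = (AT_HOME, IN_TRANSIT, IN_SHELTER)


@dataclass(frozen=True)
class NetworkSpec:
    """Specification of the social network topology for a run."""

    kind: str = "ring_lattice"  # or "degree_sequence_random"
    lattice_distance: int = 1
    degree_sequence: tuple[int, ...] = VARIABLE_DEGREE_SEQUENCE
    n_nodes: int = N_PARTICIPANTS

    def __post_init__(self) -> None:
        if self.kind not in ("ring_lattice", "degree_sequence_random"):
            raise ValueError(f"unknown network kind {self.kind!r}")
        if self.kind == "ring_lattice" and self.lattice_distance < 1:
            raise ValueError("lattice_distance must be >= 1")


@dataclass(frozen=True)
class LossMatrix:
    """Points lost by (final state, outcome).

    Staying home is free on a Miss and maximally costly on a Hit; the
    shelter is the safest place in a Hit but the most wasteful in a Miss,
    with InTransit strictly between in both columns.
    """

    home_miss: float = 0.0
    transit_miss: float = 20.0
    shelter_miss: float = 30.0
    home_hit: float = 100.0
    transit_hit: float = 60.0
    shelter_hit: float = 30.0
    label: str = "baseline"

    def __post_init__(self) -> None:
        if self.home_miss != 0.0:
            raise ValueError("loss for (AtHome, Miss) must be 0")
        if not (self.home_miss < self.transit_miss < self.shelter_miss):
            raise ValueError("Miss losses must increase AtHome < InTransit < InShelter")
        if not (self.shelter_hit < self.transit_hit < self.home_hit):
            raise ValueError("Hit losses must increase InShelter < InTransit < AtHome")

    def loss(self, state: str, outcome: Outcome | str) -> float:
        outcome = Outcome(outcome)
        key = {AT_HOME: "home", IN_TRANSIT: "transit", IN_SHELTER: "shelter"}[state]
        return getattr(self, f"{key}_{'hit' if outcome is Outcome.HIT else 'miss'}")

    def as_dict(self) -> dict:
        return {
            "home_miss": self.home_miss,
            "transit_miss": self.transit_miss,
            "shelter_miss": self.shelter_miss,
            "home_hit": self.home_hit,
            "transit_hit": self.transit_hit,
            "shelter_hit": self.shelter_hit,
            "label": self.label,
        }


def default_loss_matrices() -> list[LossMatrix]:
    """Three loss matrices emulating mild, moderate and severe disasters.

    The experiment's actual loss values were never published; these
    fixtures respect the required orderings and scale a baseline matrix to
    vary severity.
    """
    out = []
    for scale, label in ((1.0, "severe"), (0.7, "moderate"), (0.4, "mild")):
        out.append(
            LossMatrix(
                home_miss=0.0,
                transit_miss=20.0 * scale,
                shelter_miss=30.0 * scale,
                home_hit=100.0 * scale,
                transit_hit=60.0 * scale,
                shelter_hit=30.0 * scale,
                label=label,
            )
        )
    return out


def default_network_specs() -> list[NetworkSpec]:
    """The eight topologies used per experiment: ring lattices at
    distances 1-3 plus five fixed-degree-sequence random graphs."""
    lattices = [NetworkSpec(kind="ring_lattice", lattice_distance=d) for d in (1, 2, 3)]
    randoms = [NetworkSpec(kind="degree_sequence_random") for _ in range(5)]
    return lattices + randoms


def build_network(spec: NetworkSpec, rng_seed: int | None = None) -> nx.Graph:
    """Realize a network spec as a simple undirected graph on 50 nodes."""
    if spec.kind == "ring_lattice":
        return nx.circulant_graph(spec.n_nodes, list(range(1, spec.lattice_distance + 1)))
    seq = list(spec.degree_sequence)
    if len(seq) != spec.n_nodes:
        raise ValueError("degree sequence length must equal n_nodes")
    if not nx.is_graphical(seq):
        raise ValueError("degree sequence is not graphical")
    return nx.random_degree_sequence_graph(seq, seed=rng_seed, tries=50)


# ---------------------------------------------------------------------------
# run configuration and design


@dataclass
class RunConfig:
    run_id: str
    trajectory: ThreatTrajectory
    shelter_capacity: int
    network: NetworkSpec
    loss_matrix: LossMatrix
    node_assignment: np.ndarray  # permutation: participant i sits at node_assignment[i]

    def __post_init__(self) -> None:
        if not 0 < self.shelter_capacity <= N_PARTICIPANTS:
            raise ValueError("shelter capacity must lie in (0, 50]")
        perm = np.asarray(self.node_assignment)
        if sorted(perm.tolist()) != list(range(N_PARTICIPANTS)):
            raise ValueError("node_assignment must be a permutation of 0..49")


def default_trajectory_pool(
    seed: int | None = None,
    n_per_regime: int = 12,
    volatility: int = 1,
    halfwidth: int = 4,
) -> dict[Regime, list[ThreatTrajectory]]:
    """A pool of threat trajectories per regime with varied difficulty.

    Difficulty is varied through the initial lateral offset of the threat
    from the target, cycling over a fixed ladder of offsets, so the pool
    mixes near-certain hits, near-certain misses and ambiguous approaches.
    """
    offsets = (0, 3, -5, 7, 2, -8, 5, -3, 8, -6, 1, 6)
    ss = np.random.SeedSequence(seed, spawn_key=(101,))
    children = ss.spawn(2 * n_per_regime)
    pool: dict[Regime, list[ThreatTrajectory]] = {r: [] for r in Regime}
    k = 0
    for regime in (Regime.CERTAIN_TIME, Regime.VARIABLE_TIME):
        for j in range(n_per_regime):
            cfg = ThreatConfig(
                regime=regime,
                lateral_volatility=volatility,
                target_halfwidth=halfwidth,
                start_lateral=offsets[j % len(offsets)],
            )
            traj = simulate_threat(
                cfg,
                np.random.default_rng(children[k]),
                trajectory_id=f"{regime.value[:3].lower()}-{j:02d}",
            )
            pool[regime].append(traj)
            k += 1
    return pool


def make_design(
    n_runs: int = 47,
    capacities: tuple[int, ...] = SHELTER_CAPACITIES,
    regimes: tuple[Regime, ...] = (Regime.CERTAIN_TIME, Regime.VARIABLE_TIME),
    loss_matrices: list[LossMatrix] | None = None,
    network_specs: list[NetworkSpec] | None = None,
    trajectory_pool: dict[Regime, list[ThreatTrajectory]] | None = None,
    seed: int | None = None,
) -> list[RunConfig]:
    """Deterministic nested crossing of design factors, cycled to n_runs.

    Capacity varies fastest, then regime, then loss matrix, then network,
    so every capacity level and both regimes appear even in short designs.
    Trajectories are drawn from a per-regime pool smaller than the number
    of runs, so trajectories repeat across runs with different settings.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    for name, levels in (
        ("capacities", capacities),
        ("regimes", regimes),
    ):
        if len(levels) == 0:
            raise ValueError(f"factor {name} has no levels")
    if loss_matrices is None:
        loss_matrices = default_loss_matrices()
    if network_specs is None:
        network_specs = default_network_specs()
    if not loss_matrices or not network_specs:
        raise ValueError("loss matrices and network specs must be non-empty")
    if trajectory_pool is None:
        trajectory_pool = default_trajectory_pool(seed=seed)
    for regime in regimes:
        if not trajectory_pool.get(regime):
            raise ValueError(f"trajectory pool has no {regime.value} trajectories")

    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(202,)))
    per_regime_counter: dict[Regime, int] = {r: 0 for r in regimes}
    configs = []
    for i in range(n_runs):
        capacity = capacities[i % len(capacities)]
        regime = regimes[(i // len(capacities)) % len(regimes)]
        loss = loss_matrices[(i // (len(capacities) * len(regimes))) % len(loss_matrices)]
        net = network_specs[i % len(network_specs)]
        pool = trajectory_pool[regime]
        traj = pool[per_regime_counter[regime] % len(pool)]
        per_regime_counter[regime] += 1
        configs.append(
            RunConfig(
                run_id=f"run{i + 1:03d}",
                trajectory=traj,
                shelter_capacity=capacity,
                network=net,
                loss_matrix=loss,
                node_assignment=rng.permutation(N_PARTICIPANTS),
            )
        )
    return configs


# ---------------------------------------------------------------------------
# run simulation


def time_window(t: int, regime: Regime) -> int:
    """Time-urgency window index: 1 = VariableTime before 30 s,
    2 = VariableTime at/after 30 s, 3 = any time in CertainTime."""
    if Regime(regime) is Regime.CERTAIN_TIME:
        return 3
    return 1 if t < 30 else 2


@dataclass
class RunLog:
    """Per-run outcome panel in compact form.

    ``evac_time[i]`` is the second in which participant ``i`` evacuated
    (-1 if never); ``bed_index[i]`` the shelter bed claimed (-1 if none).
    Per-second states and the at-home/evacuation indicator panels are
    derived views.
    """

    run_id: str
    regime: Regime
    end_time: int
    outcome: Outcome
    q_display: np.ndarray
    shelter_capacity: int
    loss_matrix: LossMatrix
    evac_time: np.ndarray
    bed_index: np.ndarray

    @property
    def n_participants(self) -> int:
        return len(self.evac_time)

    def final_states(self) -> np.ndarray:
        states = np.full(self.n_participants, AT_HOME, dtype=object)
        evacuated = self.evac_time >= 0
        states[evacuated] = IN_TRANSIT
        states[self.bed_index >= 0] = IN_SHELTER
        return states

    def at_home_count(self) -> np.ndarray:
        """Number of participants AtHome at the start of each interval
        t = 0..end_time (length end_time + 1)."""
        counts = np.empty(self.end_time + 1, dtype=int)
        for t in range(self.end_time + 1):
            counts[t] = int(np.sum((self.evac_time < 0) | (self.evac_time >= t)))
        return counts

    def validate(self) -> None:
        if len(self.q_display) != self.end_time:
            raise ValueError(f"{self.run_id}: q_display length != end_time")
        n_beds = int(np.sum(self.bed_index >= 0))
        if n_beds > self.shelter_capacity:
            raise ValueError(f"{self.run_id}: shelter occupancy exceeds capacity")
        beds = sorted(self.bed_index[self.bed_index >= 0].tolist())
        if beds != list(range(len(beds))):
            raise ValueError(f"{self.run_id}: bed indices are not 0..k-1")
        bad = (self.bed_index >= 0) & (self.evac_time < 0)
        if bad.any():
            raise ValueError(f"{self.run_id}: sheltered participant never evacuated")
        if self.evac_time.max(initial=-1) >= self.end_time:
            raise ValueError(f"{self.run_id}: evacuation after run end")


def simulate_run(
    config: RunConfig,
    model,
    rng: np.random.Generator | int | None = None,
) -> RunLog:
    """Simulate one run: per-second Bernoulli evacuation decisions from a
    rate model, bed filling in random within-second order.

    ``model`` must expose ``rate(q, capacity, window) -> float or
    per-agent array`` with values in [0, 1]; evacuation decisions do not
    depend on current shelter occupancy, only bed assignment does.
    """
    gen = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    traj = config.trajectory
    n = N_PARTICIPANTS
    evac_time = np.full(n, -1, dtype=int)
    bed_index = np.full(n, -1, dtype=int)
    occupancy = 0
    B = config.shelter_capacity

    for t in range(traj.end_time):
        at_home = evac_time < 0
        if not at_home.any():
            break
        q = traj.q_display[t]
        r = np.asarray(model.rate(q, B, time_window(t, traj.regime)), dtype=float)
        if np.any(r < 0) or np.any(r > 1):
            raise ValueError("model rate outside [0, 1]")
        draws = gen.random(n) < r
        movers = np.nonzero(at_home & draws)[0]
        if movers.size == 0:
            continue
        evac_time[movers] = t
        order = gen.permutation(movers)
        free = B - occupancy
        for agent in order[:free]:
            bed_index[agent] = occupancy
            occupancy += 1

    return RunLog(
        run_id=config.run_id,
        regime=traj.regime,
        end_time=traj.end_time,
        outcome=traj.outcome,
        q_display=traj.q_display.copy(),
        shelter_capacity=B,
        loss_matrix=config.loss_matrix,
        evac_time=evac_time,
        bed_index=bed_index,
    )


def score_run(log: RunLog) -> np.ndarray:
    """Points retained per participant: 100 minus the loss for their final
    (state, outcome) combination."""
    log.validate()
    losses = np.array(
        [log.loss_matrix.loss(s, log.outcome) for s in log.final_states()]
    )
    return STAKE_POINTS - losses


def generate_experiment(
    design: list[RunConfig],
    model,
    rng_seed: int | None = None,
) -> tuple[list[RunLog], dict]:
    """Simulate every run in a design with per-run derived seeds.

    Returns the run logs and a manifest recording the master seed, per-run
    seeds and run-level metadata; identical (design, model, seed) inputs
    reproduce identical logs.
    """
    ss = np.random.SeedSequence(rng_seed, spawn_key=(303,))
    children = ss.spawn(len(design))
    logs = []
    manifest: dict = {"master_seed": rng_seed, "n_runs": len(design), "runs": []}
    for config, child in zip(design, children):
        log = simulate_run(config, model, np.random.default_rng(child))
        logs.append(log)
        manifest["runs"].append(
            {
                "run_id": config.run_id,
                "trajectory_id": config.trajectory.trajectory_id,
                "regime": config.trajectory.regime.value,
                "end_time": config.trajectory.end_time,
                "outcome": config.trajectory.outcome.value,
                "shelter_capacity": config.shelter_capacity,
                "loss_matrix": config.loss_matrix.label,
                "network_kind": config.network.kind,
                "seed_entropy": int(child.entropy) if isinstance(child.entropy, int) else str(child.entropy),
            }
        )
    return logs, manifest
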