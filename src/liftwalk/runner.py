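"""Scenario configuration, the published scenario library, and fixtures.

A :class:`ScenarioConfig` captures everything one run needs — topology,
angles, initial opinions, stopping tolerance and mode — and round-trips
through JSON or YAML.  ``SCENARIOS`` bundles the worked examples: the three
line-graph propagation settings (no disinfection, stubborn middle,
compliant middle), ring propagation at sizes 3-5, the five-member ring
group decision, and the mid-walk measurement interference experiment.
``generate_fixture`` draws small random scenarios for the property-test
suites.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .decision import OpinionState, run_decision, run_with_midway_measurement
from .engine import WalkConfig, all_ones_projector, run, trajectory_to_csv
from .line3 import BlockUnitary, Line3Angles, build_line3
from .ring import Ring3Angles, RingAngles, build_ring3, build_ring_n

__all__ = [
    "ScenarioConfig",
    "Fixture",
    "SCENARIOS",
    "get_scenario",
    "load_config",
    "build_blocks",
    "run_scenario",
    "generate_fixture",
    "logger",
]

logger = logging.getLogger("liftwalk")

_MODES = ("propagation", "decision", "interference")
_FIELDS: dict[str, Any] = {
    "name": "scenario",
    "mode": "propagation",
    "topology": "line",
    "n_agents": 3,
    "angles": {},
    "initial": None,            # bit string, or list of [c, d] pairs
    "opinion_mode": "probabilities_sqrt",
    "epsilon": 0.01,            # stopping tolerance of the cumulative rule
    "max_steps": 20000,
    "initializing": True,       # all-zero block seeds the idea (propagation)
    "include_wrap": False,      # count the A1-An pair as an interaction
    "measure_step": None,
    "measured_agents": (1, 2),
    "horizon": None,
    "seed": None,               # fixtures only
}


@dataclass(frozen=True)
class ScenarioConfig:
    """One fully specified run; see module docstring for the fields."""

    name: str = _FIELDS["name"]
    mode: str = _FIELDS["mode"]
    topology: str = _FIELDS["topology"]
    n_agents: int = _FIELDS["n_agents"]
    angles: dict = field(default_factory=dict)
    initial: Any = None
    opinion_mode: str = _FIELDS["opinion_mode"]
    epsilon: float = _FIELDS["epsilon"]
    max_steps: int = _FIELDS["max_steps"]
    initializing: bool = _FIELDS["initializing"]
    include_wrap: bool = _FIELDS["include_wrap"]
    measure_step: int | None = None
    measured_agents: tuple[int, int] = (1, 2)
    horizon: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}")
        if self.topology not in ("line", "ring"):
            raise ValueError("topology must be 'line' or 'ring'")
        if self.topology == "line" and self.n_agents != 3:
            raise ValueError("line topology is defined for 3 agents")
        if self.mode == "interference" and (self.measure_step is None or self.horizon is None):
            raise ValueError("interference mode requires measure_step and horizon")

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["measured_agents"] = list(self.measured_agents)
        return out

    @classmethod
    def from_dict(cls, raw: dict) -> "ScenarioConfig":
        unknown = set(raw) - set(_FIELDS)
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        kw = dict(raw)
        if "measured_agents" in kw and kw["measured_agents"] is not None:
            kw["measured_agents"] = tuple(kw["measured_agents"])
        return cls(**kw)

    def opinions(self) -> OpinionState:
        if self.initial is None:
            return OpinionState.from_bits("0" * self.n_agents)
        if isinstance(self.initial, str):
            if len(self.initial) != self.n_agents:
                raise ValueError("initial bit string length must equal n_agents")
            return OpinionState.from_bits(self.initial)
        pairs = tuple((float(c), float(d)) for c, d in self.initial)
        return OpinionState(pairs, mode=self.opinion_mode)  # type: ignore[arg-type]


def load_config(path: str | Path) -> ScenarioConfig:
    """Load and validate a JSON or YAML scenario file (unknown keys rejected)."""
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ValueError(f"{path} does not contain a mapping")
    return ScenarioConfig.from_dict(raw)


def build_blocks(cfg: ScenarioConfig) -> BlockUnitary:
    """Compile the scenario's walk operator blocks."""
    if cfg.topology == "line":
        return build_line3(Line3Angles(**cfg.angles))
    if cfg.n_agents == 3:
        if set(cfg.angles) <= {"theta", "phi"}:
            return build_ring3(
                Ring3Angles.homogeneous(
                    cfg.angles.get("theta", 0.0),
                    cfg.angles.get("phi", 0.0),
                    initializing=cfg.initializing,
                )
            )
        return build_ring3(Ring3Angles(**cfg.angles))
    return build_ring_n(
        cfg.n_agents,
        RingAngles(theta=cfg.angles.get("theta", 0.0), phi=cfg.angles.get("phi", 0.0)),
        initializing=cfg.initializing,
        include_wrap=cfg.include_wrap,
    )


def walk_config(cfg: ScenarioConfig, blocks: BlockUnitary | None = None) -> WalkConfig:
    """Walk configuration for a propagation scenario (stop on all-infected)."""
    from .decision import product_initial_state

    blocks = blocks if blocks is not None else build_blocks(cfg)
    psi0 = product_initial_state(cfg.opinions())
    return WalkConfig(
        blocks, psi0, psi0, all_ones_projector(cfg.n_agents),
        epsilon=cfg.epsilon, max_steps=cfg.max_steps,
    )


def _json_dump(obj: dict, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_scenario(cfg: ScenarioConfig, out_dir: str | Path) -> dict:
    """Execute a scenario and write its artifacts into ``out_dir``.

    Propagation and decision modes write ``trajectory.csv`` and
    ``summary.json``; interference mode writes ``interference.json``.
    Returns the summary dictionary (with a ``truncated`` flag when the step
    cap was hit before the stopping criterion).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    blocks = build_blocks(cfg)
    logger.info("scenario %s: %d-agent %s, mode=%s", cfg.name, cfg.n_agents, cfg.topology, cfg.mode)

    if cfg.mode == "interference":
        ens = run_with_midway_measurement(
            blocks, cfg.opinions(),
            measure_step=cfg.measure_step, horizon=cfg.horizon,
            agents=cfg.measured_agents, epsilon=cfg.epsilon,
        )
        summary = {
            "name": cfg.name,
            "u": [round(float(x), 12) for x in ens.u],
            "v": [round(float(x), 12) for x in ens.v],
            "composite": round(ens.composite, 12),
            "baseline": round(ens.baseline, 12),
            "measure_step": ens.measure_step,
            "horizon": ens.horizon,
            "measured_agents": list(ens.measured_agents),
        }
        _json_dump(summary, out / "interference.json")
        return summary

    if cfg.mode == "decision":
        result = run_decision(blocks, cfg.opinions(), epsilon=cfg.epsilon, max_steps=cfg.max_steps)
        traj = result.trajectory
        summary = {
            "name": cfg.name,
            "t_f": result.t_f,
            "P0": round(result.P0, 12),
            "P1": round(result.P1, 12),
            "epsilon": cfg.epsilon,
            "truncated": False,
        }
    else:
        traj = run(walk_config(cfg, blocks))
        summary = {
            "name": cfg.name,
            "t_f": traj.t_f,
            "cum_Ps": round(float(traj.cum_Ps[-1]), 12),
            "mean_infected_final": round(float(traj.mean_infected[-1]), 12),
            "epsilon": cfg.epsilon,
            "truncated": bool(traj.truncated),
        }
    (out / "trajectory.csv").write_text(trajectory_to_csv(traj))
    _json_dump(summary, out / "summary.json")
    every = max(1, traj.t_f // 10)
    for t in range(every, traj.t_f + 1, every):
        logger.info("step %d: cum_Ps=%.6f", t, traj.cum_Ps[t - 1])
    return summary


# ---------------------------------------------------------------------------
# Published scenario library (angle tables transcribed from the worked runs)

SCENARIOS: dict[str, ScenarioConfig] = {
    "no_disinfection": ScenarioConfig(
        name="no_disinfection", mode="propagation", topology="line", n_agents=3,
        angles={
            "u1": {"theta_x": 0.05, "theta_y": 0.01, "theta_z": 0.01},
            "u2": {"theta_x": 0.01, "theta_y": 0.05},
            "u3": {"theta_x": 0.05, "theta_z": 0.05, "theta_yx": 0.01, "theta_yz": 0.01},
            "u4": {"theta_z": 0.05, "theta_y": 0.01},
            "u5": {"theta_z": 0.01, "theta_y": 0.05},
            "u6": {"theta_x": 0.025, "theta_z": 0.025, "theta_xy": 0.01, "theta_zy": 0.01},
            "u7": {"theta_x": 0.05, "theta_y": 0.01},
        },
    ),
    "stubborn_middle": ScenarioConfig(
        name="stubborn_middle", mode="propagation", topology="line", n_agents=3,
        angles={
            "u1": {"theta_x": 0.05, "theta_y": 0.01, "theta_z": 0.05},
            "u2": {"theta_y": 0.01, "theta_x": -0.02},
            "u3": {"theta_x": 0.02, "theta_z": 0.02, "theta_yx": -0.01, "theta_yz": -0.01},
            "u4": {"theta_z": 0.02, "theta_y": -0.01},
            "u5": {"theta_y": 0.01, "theta_z": -0.02},
            "u6": {"theta_x": 0.01, "theta_z": 0.01, "theta_xy": -0.02, "theta_zy": -0.02},
            "u7": {"theta_y": -0.01, "theta_x": 0.02},
        },
    ),
    "compliant_middle": ScenarioConfig(
        name="compliant_middle", mode="propagation", topology="line", n_agents=3,
        angles={
            "u1": {"theta_x": 0.05, "theta_y": 0.05, "theta_z": 0.05},
            "u2": {"theta_y": 0.02, "theta_x": -0.01},
            "u3": {"theta_x": 0.02, "theta_z": 0.02, "theta_yx": -0.01, "theta_yz": -0.01},
            "u4": {"theta_z": 0.02, "theta_y": -0.01},
            "u5": {"theta_y": 0.01, "theta_z": -0.02},
            "u6": {"theta_x": 0.02, "theta_z": 0.02, "theta_xy": -0.01, "theta_zy": -0.01},
            "u7": {"theta_y": -0.01, "theta_x": 0.02},
        },
    ),
    "ring3_propagation": ScenarioConfig(
        name="ring3_propagation", mode="propagation", topology="ring", n_agents=3,
        angles={"theta": 0.05, "phi": -0.01}, initializing=True,
    ),
    "ring4_propagation": ScenarioConfig(
        name="ring4_propagation", mode="propagation", topology="ring", n_agents=4,
        angles={"theta": 0.05, "phi": -0.01}, initializing=True,
    ),
    "ring5_propagation": ScenarioConfig(
        name="ring5_propagation", mode="propagation", topology="ring", n_agents=5,
        angles={"theta": 0.05, "phi": -0.01}, initializing=True,
    ),
    "group_decision_ring5": ScenarioConfig(
        name="group_decision_ring5", mode="decision", topology="ring", n_agents=5,
        angles={"theta": 0.05, "phi": -0.05}, initializing=False,
        initial="00111",
    ),
    "interference_initial5": ScenarioConfig(
        name="interference_initial5", mode="interference", topology="ring", n_agents=5,
        angles={"theta": 0.05, "phi": -0.05}, initializing=False,
        initial=[[0.2, 0.8], [0.2, 0.8], [0.2, 0.8], [0.9, 0.1], [0.9, 0.1]],
        opinion_mode="probabilities_sqrt",
        measure_step=25, horizon=50, measured_agents=(1, 2),
    ),
}


def get_scenario(name: str) -> ScenarioConfig:
    try:
        return SCENARIOS[name]
    except KeyError:
        raise KeyError(f"unknown scenario {name!r}; choose from {sorted(SCENARIOS)}") from None


# ---------------------------------------------------------------------------
# Seeded random fixtures for the property-test suites

@dataclass(frozen=True)
class Fixture:
    """A reproducible random scenario plus the invariants it must satisfy."""

    seed: int
    config: ScenarioConfig
    manifest: dict = field(default_factory=dict)

    def blocks(self) -> BlockUnitary:
        return build_blocks(self.config)

    def walk(self) -> WalkConfig:
        return walk_config(self.config)


def generate_fixture(seed: int) -> Fixture:
    """Random small scenario: line-3 or ring-3/4/5, angles in [-0.1, 0.1]."""
    rng = np.random.default_rng(seed)
    kind = rng.choice(["line3", "ring3", "ring4", "ring5"])
    ang = lambda: float(rng.uniform(-0.1, 0.1))  # noqa: E731
    if kind == "line3":
        from .line3 import _ALLOWED_KEYS

        angles = {blk: {k: ang() for k in keys} for blk, keys in _ALLOWED_KEYS.items()}
        topology, n = "line", 3
    else:
        n = int(kind[4:])
        angles = {"theta": ang(), "phi": ang()}
        topology = "ring"
    probs = rng.uniform(0.05, 0.95, size=n)
    initial = [[1.0 - p, p] for p in probs]
    cfg = ScenarioConfig(
        name=f"fixture_{kind}_{seed}", mode="propagation", topology=topology,
        n_agents=n, angles=angles, initial=initial,
        opinion_mode="probabilities_sqrt", max_steps=300, seed=seed,
        initializing=bool(rng.integers(0, 2)) if topology == "ring" else True,
    )
    manifest = {"unitary_blocks": True, "telescoping": True, "density_invariants": True}
    return Fixture(seed, cfg, manifest)


def configure_logging(level: str = "INFO") -> None:
    """Log to standard error only; machine output goes to files/stdout."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(level.upper())
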