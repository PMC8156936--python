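"""Group decision making and mid-walk measurement interference.

In the decision setting every member starts with an opinion qubit
``c|0> + d|1>``; the walk stops when the group reaches consensus, i.e. on
either of the two stopping states ``|00...0>`` and ``|11...1>``.  At the
stopping step the stopped component of the reduced state is renormalized
into the final state ``rho_f`` and the two consensus probabilities are read
off its corner entries.

The interference experiment interrupts a fixed-horizon run half-way,
projectively measures one pair of members, continues each collapsed branch
separately, and compares the classically composed outcome probability
``u . v`` with the undisturbed run's outcome probability — the gap is the
quantum interference effect (violation of the classical law of total
probability).

Throughout this module "the probability of option 1 at step t" means the
decision probability read from the stopped component of the reduced state:
the consensus projector is applied to rho_T(t), the result renormalized,
and the all-ones corner traced out — the same formula the stopping-time
decision uses.  The raw corner entry of rho_T would instead be the small
per-step inflow, which is not a decision probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .engine import WalkConfig, WalkTrajectory, run, step
from .line3 import BlockUnitary
from .qlinalg import _slot_kron

__all__ = [
    "OpinionState",
    "DecisionResult",
    "BranchEnsemble",
    "product_initial_state",
    "consensus_projectors",
    "run_decision",
    "pair_measurement_ops",
    "run_with_midway_measurement",
]


@dataclass(frozen=True)
class OpinionState:
    """Per-member local opinion amplitudes over ``(|0>, |1>)``.

    ``mode="amplitudes_normalized"`` treats each pair as literal amplitudes
    and renormalizes it; ``mode="probabilities_sqrt"`` treats the entries as
    probabilities and takes square roots (so ``(0.2, 0.8)`` means "80% sure
    of option 1"), which is the convention the published scenarios use.
    """

    locals: tuple[tuple[float, float], ...]
    mode: Literal["amplitudes_normalized", "probabilities_sqrt"] = "probabilities_sqrt"

    @property
    def n_agents(self) -> int:
        return len(self.locals)

    def local_vector(self, k: int) -> np.ndarray:
        """Normalized local state of member ``k`` (1-based)."""
        c, d = self.locals[k - 1]
        if self.mode == "probabilities_sqrt":
            if c < 0 or d < 0:
                raise ValueError("probabilities must be nonnegative")
            v = np.array([np.sqrt(c), np.sqrt(d)], dtype=complex)
        else:
            v = np.array([c, d], dtype=complex)
        norm = np.linalg.norm(v)
        if norm < 1e-12:
            raise ValueError(f"member {k} has a zero-norm local state")
        return v / norm

    @classmethod
    def from_bits(cls, bits: str) -> "OpinionState":
        """Definite opinions from a bit string ``b_n .. b_1``."""
        n = len(bits)
        return cls(tuple((0.0, 1.0) if bits[n - k] == "1" else (1.0, 0.0) for k in range(1, n + 1)))


def product_initial_state(opinions: OpinionState) -> np.ndarray:
    """Tensor product of the member opinions (member 1 least significant)."""
    n = opinions.n_agents
    mats = {k: opinions.local_vector(k).reshape(2, 1) for k in range(1, n + 1)}
    vec = _slot_kron(n, mats).ravel()
    return vec / np.linalg.norm(vec)


def consensus_projectors(n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """``(Ms, M0, M1)``: stop on either consensus, or on each separately."""
    if n < 2:
        raise ValueError("need at least two members")
    d = 2**n
    Ms = np.zeros((d, d))
    Ms[0, 0] = Ms[-1, -1] = 1.0
    M0 = np.zeros((d, d))
    M0[0, 0] = 1.0
    M1 = np.zeros((d, d))
    M1[-1, -1] = 1.0
    return Ms, M0, M1


@dataclass
class DecisionResult:
    """Outcome of a group-decision walk.

    ``P0``/``P1`` are the probabilities that the agreement reached is
    all-zeros / all-ones, read from the renormalized stopped state
    ``rho_f`` at the stopping step ``t_f``.
    """

    t_f: int
    rho_f: np.ndarray
    P0: float
    P1: float
    trajectory: WalkTrajectory | None = None


def _decision_config(
    block_unitary: BlockUnitary,
    opinions: OpinionState,
    epsilon: float,
    max_steps: int,
) -> WalkConfig:
    n = block_unitary.n_agents
    if opinions.n_agents != n:
        raise ValueError("opinion count does not match the network size")
    psi0 = product_initial_state(opinions)
    Ms, _, _ = consensus_projectors(n)
    return WalkConfig(block_unitary, psi0, psi0, Ms, epsilon=epsilon, max_steps=max_steps)


def run_decision(
    block_unitary: BlockUnitary,
    opinions: OpinionState,
    *,
    epsilon: float = 0.01,
    max_steps: int = 20000,
) -> DecisionResult:
    """Run a consensus walk and compute the final decision probabilities.

    The block unitary should be built in group-decision mode (identity
    all-zero and all-one blocks): opinions pre-exist, so nothing seeds the
    idea.  An initial state already at a consensus stops at the first step
    with the corresponding probability equal to 1.
    """
    n = block_unitary.n_agents
    cfg = _decision_config(block_unitary, opinions, epsilon, max_steps)
    traj = run(cfg)
    if traj.truncated:
        raise RuntimeError(f"decision walk did not converge within {max_steps} steps")
    _, M0, M1 = consensus_projectors(n)
    rho_T = traj.rho_T_final
    ps = traj.ps_final
    if ps <= 0.0:
        raise RuntimeError("stopping probability vanished at the final step")
    Ms = cfg.stop_projector
    rho_f = Ms @ rho_T @ Ms / ps
    P0 = float(np.trace(M0 @ rho_f @ M0).real)
    P1 = float(np.trace(M1 @ rho_f @ M1).real)
    return DecisionResult(traj.t_f, rho_f, P0, P1, traj)


def consensus_split(rho_T: np.ndarray) -> tuple[float, float, float]:
    """Decision probabilities ``(P0, P1, ps)`` of a reduced state.

    ``ps`` is the total consensus (stopped) mass of ``rho_T``; ``P0`` and
    ``P1`` are the renormalized probabilities of the all-zeros / all-ones
    agreement given that the group stops now (the stopped-state formula of
    the decision rule, evaluated at an arbitrary step).
    """
    a = float(rho_T[0, 0].real)
    b = float(rho_T[-1, -1].real)
    ps = a + b
    if ps <= 0.0:
        return 0.0, 0.0, 0.0
    return a / ps, b / ps, ps


def pair_measurement_ops(n: int, agents: tuple[int, int] = (1, 2)) -> list[np.ndarray]:
    """Four projectors onto the joint basis states of one member pair.

    Outcomes are ordered ``|00>, |01>, |10>, |11>`` in the joint ``|b_hi
    b_lo>`` convention of the global basis (for the canonical pair (A1, A2)
    this is ``I (x) M_i`` with a 4x4 corner projector ``M_i``).  The four
    projectors sum to the identity.
    """
    a_lo, a_hi = sorted(agents)
    if a_lo == a_hi or not (1 <= a_lo <= n and 1 <= a_hi <= n):
        raise ValueError("agents must be two distinct indices in 1..n")
    d = 2**n
    ops = []
    idx = np.arange(d)
    bit_lo = (idx >> (a_lo - 1)) & 1
    bit_hi = (idx >> (a_hi - 1)) & 1
    for hi in (0, 1):
        for lo in (0, 1):
            mask = ((bit_hi == hi) & (bit_lo == lo)).astype(float)
            ops.append(np.diag(mask))
    return ops


@dataclass
class BranchEnsemble:
    """Result of a fixed-horizon run interrupted by one pair measurement.

    ``u`` holds the four branch probabilities at the measurement step, ``v``
    the per-branch all-ones probabilities at the horizon, ``composite`` the
    classical composition ``u . v``, and ``baseline`` the same horizon
    quantity for the undisturbed walk.  ``composite != baseline`` is the
    interference effect.
    """

    measured_agents: tuple[int, int]
    measure_step: int
    horizon: int
    u: np.ndarray
    v: np.ndarray
    composite: float
    baseline: float
    branch_states: list[np.ndarray | None] = field(default_factory=list)


def _evolve(sigma: np.ndarray, cfg: WalkConfig, n_steps: int) -> tuple[np.ndarray, np.ndarray]:
    """Run ``n_steps`` projected iterations; return (last rho_T, last sigma)."""
    rho_T = sigma
    for _ in range(n_steps):
        rho_T, _, _, sigma = step(sigma, cfg)
    return rho_T, sigma


def run_with_midway_measurement(
    block_unitary: BlockUnitary,
    opinions: OpinionState,
    *,
    measure_step: int,
    horizon: int,
    agents: tuple[int, int] = (1, 2),
    epsilon: float = 0.01,
) -> BranchEnsemble:
    """Interrupt a horizon run with one projective pair measurement.

    The walk evolves normally (with the per-step continue projection) to
    ``measure_step``; the pair projectors are applied to the pre-projection
    reduced state there, giving branch probabilities ``u``.  Each branch is
    renormalized, continue-projected, and evolved to ``horizon``, where the
    option-1 decision probability ``v_i`` is read from its reduced state
    via :func:`consensus_split`.  Branches with negligible probability are
    kept at weight 0.
    """
    if not 0 < measure_step < horizon:
        raise ValueError("need 0 < measure_step < horizon")
    n = block_unitary.n_agents
    cfg = _decision_config(block_unitary, opinions, epsilon, max_steps=horizon + 1)
    keep = ~np.diag(cfg.stop_projector).astype(bool)

    sigma = np.outer(cfg.initial_target, cfg.initial_target.conj())
    rho_T = None
    for _ in range(measure_step):
        rho_T, _, _, sigma = step(sigma, cfg)

    ops = pair_measurement_ops(n, agents)
    u = np.array([float(np.trace(P @ rho_T @ P).real) for P in ops])
    v = np.zeros(4)
    branch_states: list[np.ndarray | None] = []
    for i, P in enumerate(ops):
        if u[i] < 1e-12:
            branch_states.append(None)
            continue
        branch = P @ rho_T @ P / u[i]
        # continue projection so branch bookkeeping matches the baseline walk
        proj = branch.copy()
        proj[~keep, :] = 0.0
        proj[:, ~keep] = 0.0
        tr = np.trace(proj).real
        if tr < 1e-14:
            branch_states.append(None)
            continue
        proj /= tr
        rho_T_b, _ = _evolve(proj, cfg, horizon - measure_step)
        v[i] = consensus_split(rho_T_b)[1]
        branch_states.append(rho_T_b)

    sigma0 = np.outer(cfg.initial_target, cfg.initial_target.conj())
    rho_T_base, _ = _evolve(sigma0, cfg, horizon)
    baseline = consensus_split(rho_T_base)[1]
    return BranchEnsemble(
        measured_agents=tuple(sorted(agents)),
        measure_step=measure_step,
        horizon=horizon,
        u=u,
        v=v,
        composite=float(u @ v),
        baseline=baseline,
        branch_states=branch_states,
    )
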