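"""The lifted quantum walk: lift, evolve, reduce, measure, repeat.

Each step the reduced network state sigma (a ``2**n`` density operator) is
lifted to ``sigma (x) sigma``, the block-diagonal walk operator is applied,
and the controller factor is traced out again:

    rho_T = Tr_C( U (sigma (x) sigma) U^dag ) = sum_i sigma_ii U_i sigma U_i^dag

(the right-hand side follows from the block structure and is how the engine
actually evolves the state — verified against the dense ``4**n`` product).
A projective measurement then splits rho_T into stopped mass ``ps`` and
continuing mass ``pc``; the continuing part is renormalized and becomes the
next sigma.  The walk halts when the cumulative unconditional stopping
probability reaches ``1 - epsilon``.  By the telescoping identity the
cumulative stop probability after t steps equals ``1 - prod pc(tau)``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np

from .line3 import BlockUnitary, assemble
from .qlinalg import partial_trace, popcount_weights

__all__ = [
    "WalkConfig",
    "WalkTrajectory",
    "AbsorbedError",
    "all_ones_projector",
    "initialize",
    "step",
    "step_dense",
    "run",
    "mean_infected",
    "trajectory_to_csv",
]

_ABSORB_TOL = 1e-14


class AbsorbedError(RuntimeError):
    """Raised when the continuing probability vanishes (walk fully stopped).

    Carries the reduced state ``rho_T`` and ``ps`` of the absorbing step.
    """

    def __init__(self, message: str, rho_T: np.ndarray | None = None, ps: float = 1.0):
        super().__init__(message)
        self.rho_T = rho_T
        self.ps = ps


def all_ones_projector(n: int) -> np.ndarray:
    """Diagonal projector onto the all-infected state ``|11...1>``."""
    d = np.zeros(2**n)
    d[-1] = 1.0
    return np.diag(d)


@dataclass
class WalkConfig:
    """Inputs of one walk run.

    ``stop_projector`` is a diagonal 0/1 matrix (``Ms``); the continue
    projector is its complement.  ``epsilon`` is the stopping tolerance of
    the cumulative-probability rule, default 0.01; ``max_steps`` caps
    runaway configurations.
    """

    block_unitary: BlockUnitary
    initial_controller: np.ndarray
    initial_target: np.ndarray
    stop_projector: np.ndarray
    epsilon: float = 0.01
    max_steps: int = 20000

    def __post_init__(self) -> None:
        d = self.block_unitary.dim
        for name, v in (("controller", self.initial_controller), ("target", self.initial_target)):
            v = np.asarray(v, dtype=complex)
            if v.shape != (d,):
                raise ValueError(f"initial {name} must be a length-{d} vector")
            if abs(np.vdot(v, v).real - 1.0) > 1e-9:
                raise ValueError(f"initial {name} is not normalized")
        P = np.asarray(self.stop_projector)
        if P.shape != (d, d):
            raise ValueError("stop projector dimension mismatch")
        diag = np.diag(P)
        if not (np.allclose(P, np.diag(diag)) and np.all(np.isin(diag.real, (0.0, 1.0)))):
            raise ValueError("stop projector must be diagonal 0/1")
        if not 0.0 < self.epsilon < 1.0:
            raise ValueError("epsilon must lie in (0, 1)")
        if self.max_steps < 1:
            raise ValueError("max_steps must be positive")

    @property
    def stop_mask(self) -> np.ndarray:
        return np.diag(self.stop_projector).real.copy()


def initialize(cfg: WalkConfig) -> np.ndarray:
    """Rank-1 lifted density operator ``(aC aC^dag) (x) (aT aT^dag)``."""
    rc = np.outer(cfg.initial_controller, cfg.initial_controller.conj())
    rt = np.outer(cfg.initial_target, cfg.initial_target.conj())
    return np.kron(rc, rt)


def _reduced_step(sigma: np.ndarray, blocks: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """``sum_i w_i U_i sigma U_i^dag`` over the stacked block array."""
    return np.einsum("i,iab,bc,idc->ad", weights, blocks, sigma, blocks.conj(), optimize=True)


def step(
    sigma: np.ndarray,
    cfg: WalkConfig,
    controller_diag: np.ndarray | None = None,
) -> tuple[np.ndarray, float, float, np.ndarray]:
    """One lift/evolve/reduce/measure iteration.

    Returns ``(rho_T, ps, pc, sigma_next)``.  ``controller_diag`` overrides
    the controller populations (used only for a first step whose controller
    differs from the target); by default the lift uses ``sigma`` itself on
    both factors.  Raises :class:`AbsorbedError` when essentially all mass
    has stopped (``pc`` below 1e-14).
    """
    blocks = np.stack(cfg.block_unitary.blocks)
    w = np.diag(sigma).real if controller_diag is None else np.asarray(controller_diag).real
    rho_T = _reduced_step(sigma, blocks, w)
    mask = cfg.stop_mask
    diag = np.diag(rho_T).real
    ps = float(diag @ mask)
    pc = float(diag @ (1.0 - mask))
    if pc < _ABSORB_TOL:
        raise AbsorbedError(
            "continuing probability vanished; the walk has fully stopped", rho_T, ps
        )
    keep = (1.0 - mask).astype(bool)
    sigma_next = rho_T.copy()
    sigma_next[~keep, :] = 0.0
    sigma_next[:, ~keep] = 0.0
    sigma_next = sigma_next / np.trace(sigma_next).real  # exact unit trace each step
    return rho_T, ps, pc, sigma_next


def step_dense(sigma: np.ndarray, cfg: WalkConfig) -> np.ndarray:
    """Reference evolution through the dense ``4**n`` operator (tests only)."""
    U = assemble(cfg.block_unitary)
    rho = np.kron(sigma, sigma)
    d = cfg.block_unitary.dim
    return partial_trace(U @ rho @ U.conj().T, (d, d), "A")


@dataclass
class WalkTrajectory:
    """Per-step record of one walk run (arrays indexed by step ``t >= 1``).

    ``ps``/``pc`` are the conditional per-step stop/continue probabilities,
    ``Ps``/``Pc`` the unconditional ones (``Ps(t) = Pc(t-1) ps(t)``), and
    ``cum_Ps`` their running sum.  ``truncated`` flags a run that hit
    ``max_steps`` before the stopping criterion.
    """

    ps: np.ndarray
    pc: np.ndarray
    Ps: np.ndarray
    Pc: np.ndarray
    cum_Ps: np.ndarray
    mean_infected: np.ndarray
    t_f: int
    truncated: bool
    rho_T_final: np.ndarray
    rho_c_final: np.ndarray
    ps_final: float = 0.0

    def __len__(self) -> int:
        return self.t_f

    @property
    def steps(self) -> np.ndarray:
        return np.arange(1, self.t_f + 1)


def mean_infected(sigma: np.ndarray) -> float:
    """Expected number of infected agents, ``sum_i popcount(i-1) sigma_ii``."""
    d = sigma.shape[0]
    n = int(round(np.log2(d)))
    if 2**n != d:
        raise ValueError("density operator dimension is not a power of two")
    return float(popcount_weights(n) @ np.diag(sigma).real)


def run(cfg: WalkConfig, *, record_states: bool = False) -> WalkTrajectory:
    """Iterate the walk until ``cum_Ps >= 1 - epsilon`` or ``max_steps``.

    ``record_states`` additionally keeps every ``rho_c(t)`` on the returned
    trajectory (attribute ``rho_c_history``), used by diagnostics and tests.
    """
    sigma = np.outer(cfg.initial_target, cfg.initial_target.conj())
    controller_diag = np.abs(np.asarray(cfg.initial_controller)) ** 2
    ps_l, pc_l, Ps_l, Pc_l, cum_l, mi_l = [], [], [], [], [], []
    history: list[np.ndarray] = []
    Pc_prev = 1.0
    cum = 0.0
    truncated = True
    rho_T = None
    t = 0
    while t < cfg.max_steps:
        t += 1
        try:
            rho_T, ps, pc, sigma = step(sigma, cfg, controller_diag if t == 1 else None)
        except AbsorbedError as exc:
            # all remaining mass stops this step
            rho_T = exc.rho_T
            Ps_l.append(Pc_prev * exc.ps)
            Pc_l.append(0.0)
            ps_l.append(exc.ps)
            pc_l.append(0.0)
            cum += Ps_l[-1]
            cum_l.append(cum)
            mi_l.append(mi_l[-1] if mi_l else 0.0)
            Pc_prev = 0.0
            truncated = False
            break
        ps_l.append(ps)
        pc_l.append(pc)
        Ps_l.append(Pc_prev * ps)
        Pc_prev *= pc
        Pc_l.append(Pc_prev)
        cum += Ps_l[-1]
        cum_l.append(cum)
        mi_l.append(mean_infected(sigma))
        if record_states:
            history.append(sigma.copy())
        if cum >= 1.0 - cfg.epsilon:
            truncated = False
            break
    traj = WalkTrajectory(
        ps=np.array(ps_l),
        pc=np.array(pc_l),
        Ps=np.array(Ps_l),
        Pc=np.array(Pc_l),
        cum_Ps=np.array(cum_l),
        mean_infected=np.array(mi_l),
        t_f=t,
        truncated=truncated,
        rho_T_final=rho_T,
        rho_c_final=sigma,
        ps_final=ps_l[-1],
    )
    if record_states:
        traj.rho_c_history = history  # type: ignore[attr-defined]
    return traj


def trajectory_to_csv(traj: WalkTrajectory) -> str:
    """Serialize a trajectory (10 significant digits, one row per step)."""
    buf = io.StringIO()
    buf.write("step,ps,pc,Ps,Pc,cum_Ps,mean_infected\n")
    for i, t in enumerate(traj.steps):
        row = (traj.ps[i], traj.pc[i], traj.Ps[i], traj.Pc[i], traj.cum_Ps[i], traj.mean_infected[i])
        buf.write(str(t) + "," + ",".join(f"{x:.10g}" for x in row) + "\n")
    return buf.getvalue()
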