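"""Quantum linear-algebra primitives for multi-agent qubit networks.

Each agent in an ``n``-agent network carries one qubit: ``|0>`` (has not
adopted the idea) or ``|1>`` (has adopted it).  The global basis state is the
bit string ``b_n ... b_2 b_1`` with agent 1 on the *least* significant slot;
its 1-based basis index is the binary value plus one, so for three agents
``|101>`` is basis state ``|6>``.

This module provides the building blocks used by the gate factories and the
walk engine: computational basis states, real rotation gates, controlled
multi-target rotation gates, tensor assembly, partial traces and validation
helpers.  All agent and basis indices exposed here are 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

__all__ = [
    "UNITARY_ATOL",
    "HERMITIAN_ATOL",
    "PSD_EIG_FLOOR",
    "M0",
    "M1",
    "AgentNetwork",
    "GateStep",
    "InteractionScript",
    "basis_state",
    "rotation",
    "build_controlled_gate",
    "build_unconditional",
    "compile_script",
    "partial_trace",
    "validate_unitary",
    "validate_density",
    "popcount_weights",
]

# Numerical tolerances (double precision over at most ~10 qubits).
UNITARY_ATOL = 1e-10
HERMITIAN_ATOL = 1e-9
TRACE_ATOL = 1e-9
PSD_EIG_FLOOR = -1e-9

#: Projector onto the local ``|0>`` (idea not adopted) state.
M0 = np.array([[1.0, 0.0], [0.0, 0.0]])
#: Projector onto the local ``|1>`` (idea adopted) state.
M1 = np.array([[0.0, 0.0], [0.0, 1.0]])


@dataclass(frozen=True)
class AgentNetwork:
    """A labelled set of agents with line or ring adjacency.

    Agents are labelled ``A1 .. An``.  On the line graph ``Ak`` talks only to
    ``Ak-1`` and ``Ak+1``; the ring additionally joins ``A1`` and ``An``.
    """

    n_agents: int
    topology: Literal["line", "ring"]

    def __post_init__(self) -> None:
        if self.n_agents < 2:
            raise ValueError("a network needs at least two agents")
        if self.topology not in ("line", "ring"):
            raise ValueError(f"unknown topology {self.topology!r}")

    def neighbors(self, k: int, *, include_wrap: bool = True) -> tuple[int, ...]:
        """Neighbors of agent ``k`` (1-based), in increasing index order.

        ``include_wrap=False`` drops the ring's A1-An edge, which matters
        only for the interaction bookkeeping of ring scripts.
        """
        n = self.n_agents
        if not 1 <= k <= n:
            raise ValueError(f"agent index {k} out of range 1..{n}")
        out = set()
        if k > 1:
            out.add(k - 1)
        if k < n:
            out.add(k + 1)
        if self.topology == "ring" and include_wrap:
            if k == 1:
                out.add(n)
            if k == n:
                out.add(1)
        return tuple(sorted(out))


def basis_state(n: int, bits: str) -> np.ndarray:
    """Computational basis vector for the bit string ``b_n ... b_1``.

    The returned complex vector of length ``2**n`` has a single 1 at the
    1-based index ``int(bits, 2) + 1`` — e.g. ``basis_state(3, "101")`` is
    basis state 6 of the 3-agent network.
    """
    if len(bits) != n or any(c not in "01" for c in bits):
        raise ValueError(f"bits must be a length-{n} string of 0/1, got {bits!r}")
    vec = np.zeros(2**n, dtype=complex)
    vec[int(bits, 2)] = 1.0
    return vec


def rotation(theta: float) -> np.ndarray:
    """Real rotation gate ``[[cos t, -sin t], [sin t, cos t]]``.

    A small positive angle nudges ``|0>`` toward ``|1>`` (infection); a
    negative angle rotates back toward ``|0>`` (disinfection).  Angles are
    plain radians and are not wrapped.
    """
    if not np.isfinite(theta):
        raise ValueError("rotation angle must be finite")
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


def _slot_kron(n: int, factors: dict[int, np.ndarray]) -> np.ndarray:
    """Kronecker product over agent slots ``n`` down to ``1``.

    ``factors`` maps 1-based agent indices to 2x2 matrices; unspecified slots
    get the identity.  Agent 1 is the least significant (rightmost) factor.
    """
    out = np.array([[1.0 + 0.0j]])
    for k in range(n, 0, -1):
        out = np.kron(out, factors.get(k, np.eye(2)))
    return out


def build_controlled_gate(
    n: int,
    control_agent: int,
    control_value: int,
    targets: Sequence[tuple[int, float]],
) -> np.ndarray:
    """Controlled multi-target rotation on the ``2**n`` network space.

    When the control agent's qubit is in the basis state ``control_value``
    every target agent is rotated by its angle; on the opposite branch
    nothing happens.  In tensor form this is the two-branch operator
    ``(x) F_k + (x) G_k`` with the control slot carrying the projectors
    ``M_cv`` / ``M_(1-cv)`` and target slots carrying rotations / identities.
    The result is always unitary because the two branches live on orthogonal
    control subspaces.
    """
    if control_value not in (0, 1):
        raise ValueError("control_value must be 0 or 1")
    idx = [control_agent] + [a for a, _ in targets]
    if len(set(idx)) != len(idx):
        raise ValueError("control and target agents must be distinct")
    if any(not 1 <= a <= n for a in idx):
        raise ValueError(f"agent indices must lie in 1..{n}")
    proj = (M0, M1)
    active = {a: rotation(th) for a, th in targets}
    active[control_agent] = proj[control_value]
    idle = {control_agent: proj[1 - control_value]}
    return _slot_kron(n, active) + _slot_kron(n, idle)


def build_unconditional(n: int, rotations: Sequence[tuple[int, float]]) -> np.ndarray:
    """Unconditional product of single-agent rotations (identity elsewhere)."""
    idx = [a for a, _ in rotations]
    if len(set(idx)) != len(idx):
        raise ValueError("agents must be distinct")
    if any(not 1 <= a <= n for a in idx):
        raise ValueError(f"agent indices must lie in 1..{n}")
    return _slot_kron(n, {a: rotation(th) for a, th in rotations})


@dataclass(frozen=True)
class GateStep:
    """One sub-gate of an interaction script.

    ``control_agent is None`` means an unconditional rotation product;
    otherwise the rotations on ``targets`` fire only when the control agent
    is in ``control_value``.
    """

    targets: tuple[tuple[int, float], ...]
    control_agent: int | None = None
    control_value: int = 1

    def matrix(self, n: int) -> np.ndarray:
        if self.control_agent is None:
            return build_unconditional(n, self.targets)
        return build_controlled_gate(n, self.control_agent, self.control_value, self.targets)


@dataclass(frozen=True)
class InteractionScript:
    """Ordered list of gate steps defining one controller block.

    The first listed step is applied first (it is the rightmost factor of
    the compiled matrix product).
    """

    steps: tuple[GateStep, ...] = ()
    controller_basis_index: int | None = None  # 1-based, bookkeeping only

    @staticmethod
    def controlled(control_agent: int, control_value: int, targets: Iterable[tuple[int, float]]) -> GateStep:
        return GateStep(tuple(targets), control_agent, control_value)

    @staticmethod
    def unconditional(targets: Iterable[tuple[int, float]]) -> GateStep:
        return GateStep(tuple(targets))


def compile_script(script: InteractionScript, n: int) -> np.ndarray:
    """Compile a script to its ``2**n`` unitary (first step applied first)."""
    out = np.eye(2**n, dtype=complex)
    for step in script.steps:
        out = step.matrix(n) @ out
    return out


def partial_trace(rho: np.ndarray, dims: tuple[int, int], traced_factor: Literal["A", "B"]) -> np.ndarray:
    """Trace out one factor of a density operator on ``A (x) B``.

    ``dims = (dA, dB)`` with ``A`` the first (most significant) Kronecker
    factor.  Tracing preserves the total trace and Hermiticity.
    """
    dA, dB = dims
    if rho.shape != (dA * dB, dA * dB):
        raise ValueError(f"matrix shape {rho.shape} does not factor as {dA}x{dB}")
    r = rho.reshape(dA, dB, dA, dB)
    if traced_factor == "A":
        return np.einsum("abac->bc", r)
    if traced_factor == "B":
        return np.einsum("abcb->ac", r)
    raise ValueError("traced_factor must be 'A' or 'B'")


def validate_unitary(M: np.ndarray, atol: float = UNITARY_ATOL) -> bool:
    """True when ``max |M^dag M - I|`` is below ``atol``."""
    M = np.asarray(M)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        return False
    d = M.shape[0]
    return bool(np.max(np.abs(M.conj().T @ M - np.eye(d))) < atol)


def validate_density(rho: np.ndarray, atol: float = HERMITIAN_ATOL) -> bool:
    """Hermitian within ``atol``, unit trace, eigenvalues above the PSD floor."""
    rho = np.asarray(rho)
    if rho.ndim != 2 or rho.shape[0] != rho.shape[1]:
        return False
    if np.max(np.abs(rho - rho.conj().T)) >= atol:
        return False
    if abs(np.trace(rho) - 1.0) >= TRACE_ATOL:
        return False
    return bool(np.min(np.linalg.eigvalsh(0.5 * (rho + rho.conj().T))) >= PSD_EIG_FLOOR)


def popcount_weights(n: int) -> np.ndarray:
    """Number of adopted (``1``) agents for each basis index ``1 .. 2**n``."""
    return np.array([bin(i).count("1") for i in range(2**n)], dtype=float)
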