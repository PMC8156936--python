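"""Block-unitary factory for the 3-agent line network A1 - A2 - A3.

The walk operator is block diagonal, ``U = diag(U1 .. U8)``: block ``i``
acts on the mirror network whenever the controller occupies basis state
``|i>``.  Each block is an interaction script between the agents that the
controller marks as infected and their uninfected neighbors — the infected
agent lectures first, the uninfected neighbor then pushes back.  Angle names
follow the convention that a plain subscript (``theta_x``) is a rotation of
that agent and a double subscript (``theta_yx``) is a counter-rotation of
the first agent controlled by the second.

Model-level angles are expressed in half-turns (units of pi radians): an
angle of 0.5 flips ``|0>`` to ``|1>`` in one application.  The published
scenario tables (0.05, 0.01, ...) use this unit — it is what reproduces the
printed stopping times and final distributions — and the factories convert
to radians when compiling gates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .qlinalg import (
    InteractionScript,
    compile_script,
    validate_unitary,
)

__all__ = ["Line3Angles", "BlockUnitary", "build_line3", "assemble"]

_ALLOWED_KEYS = {
    "u1": {"theta_x", "theta_y", "theta_z"},
    "u2": {"theta_y", "theta_x"},
    "u3": {"theta_x", "theta_z", "theta_yx", "theta_yz"},
    "u4": {"theta_z", "theta_y"},
    "u5": {"theta_y", "theta_z"},
    "u6": {"theta_x", "theta_z", "theta_xy", "theta_zy"},
    "u7": {"theta_x", "theta_y"},
}


@dataclass(frozen=True)
class Line3Angles:
    """Named rotation angles per block, in half-turns; missing angles are 0.

    Negative angles model disinfection.  Keys per block: ``u1`` theta_x/y/z;
    ``u2`` theta_y (A1 infects A2), theta_x (A2 counteracts A1); ``u3``
    theta_x, theta_z (A2 infects its neighbors), theta_yx, theta_yz
    (neighbors counteract A2); ``u4`` theta_z, theta_y; ``u5`` theta_y,
    theta_z; ``u6`` theta_x, theta_z, theta_xy, theta_zy; ``u7`` theta_x,
    theta_y.
    """

    u1: dict = field(default_factory=dict)
    u2: dict = field(default_factory=dict)
    u3: dict = field(default_factory=dict)
    u4: dict = field(default_factory=dict)
    u5: dict = field(default_factory=dict)
    u6: dict = field(default_factory=dict)
    u7: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for block, allowed in _ALLOWED_KEYS.items():
            entries = getattr(self, block)
            unknown = set(entries) - allowed
            if unknown:
                raise ValueError(f"unknown angle keys for {block}: {sorted(unknown)}")
            if any(not np.isfinite(v) for v in entries.values()):
                raise ValueError(f"non-finite angle in {block}")

    def get(self, block: str, key: str) -> float:
        """Angle in radians (stored values are half-turns)."""
        return np.pi * float(getattr(self, block).get(key, 0.0))


@dataclass(frozen=True)
class BlockUnitary:
    """The walk operator stored as its ``2**n`` diagonal blocks."""

    blocks: tuple[np.ndarray, ...]
    n_agents: int

    def __post_init__(self) -> None:
        d = 2**self.n_agents
        if len(self.blocks) != d:
            raise ValueError(f"expected {d} blocks, got {len(self.blocks)}")
        for i, b in enumerate(self.blocks):
            if b.shape != (d, d):
                raise ValueError(f"block {i + 1} has shape {b.shape}, expected {(d, d)}")
            if not validate_unitary(b):
                raise ValueError(f"block {i + 1} is not unitary")

    @property
    def dim(self) -> int:
        return 2**self.n_agents


def line3_scripts(angles: Line3Angles) -> tuple[InteractionScript, ...]:
    """The eight interaction scripts of the line-graph walk operator."""
    ctrl = InteractionScript.controlled
    unc = InteractionScript.unconditional
    a = angles.get
    return (
        # controller |000>: idea initialization, every mirror nudged at once
        InteractionScript((unc([(1, a("u1", "theta_x")), (2, a("u1", "theta_y")), (3, a("u1", "theta_z"))]),), 1),
        # controller |001>: A1 lectures A2, A2 pushes back on A1
        InteractionScript(
            (ctrl(1, 1, [(2, a("u2", "theta_y"))]), ctrl(2, 0, [(1, a("u2", "theta_x"))])), 2
        ),
        # controller |010>: A2 lectures both neighbors, each pushes back on A2
        InteractionScript(
            (
                ctrl(2, 1, [(1, a("u3", "theta_x"))]),
                ctrl(2, 1, [(3, a("u3", "theta_z"))]),
                ctrl(3, 0, [(2, a("u3", "theta_yz"))]),
                ctrl(1, 0, [(2, a("u3", "theta_yx"))]),
            ),
            3,
        ),
        # controller |011>: only the A2-A3 pair disagrees
        InteractionScript(
            (ctrl(2, 1, [(3, a("u4", "theta_z"))]), ctrl(3, 0, [(2, a("u4", "theta_y"))])), 4
        ),
        # controller |100>: only the A3-A2 pair disagrees
        InteractionScript(
            (ctrl(3, 1, [(2, a("u5", "theta_y"))]), ctrl(2, 0, [(3, a("u5", "theta_z"))])), 5
        ),
        # controller |101>: both neighbors lecture A2, A2 pushes back on both
        InteractionScript(
            (
                ctrl(1, 1, [(2, a("u6", "theta_x"))]),
                ctrl(3, 1, [(2, a("u6", "theta_z"))]),
                ctrl(2, 0, [(1, a("u6", "theta_xy"))]),
                ctrl(2, 0, [(3, a("u6", "theta_zy"))]),
            ),
            6,
        ),
        # controller |110>: A2 lectures A1, A1 pushes back on A2
        InteractionScript(
            (ctrl(2, 1, [(1, a("u7", "theta_x"))]), ctrl(1, 0, [(2, a("u7", "theta_y"))])), 7
        ),
        # controller |111>: everyone agrees, nothing left to do
        InteractionScript((), 8),
    )


def build_line3(angles: Line3Angles) -> BlockUnitary:
    """Compile the eight line-graph blocks from a named angle setting."""
    blocks = tuple(compile_script(s, 3) for s in line3_scripts(angles))
    return BlockUnitary(blocks, 3)


def assemble(bu: BlockUnitary) -> np.ndarray:
    """Dense ``4**n`` block-diagonal walk operator ``diag(U1 .. U_2^n)``."""
    d = bu.dim
    out = np.zeros((d * d, d * d), dtype=complex)
    for i, b in enumerate(bu.blocks):
        out[i * d : (i + 1) * d, i * d : (i + 1) * d] = b
    return out
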