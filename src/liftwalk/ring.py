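"""Block-unitary factories for ring networks.

For three agents the ring is the complete graph and four of the eight line
blocks change: the printed gate recipes are transcribed literally (see
``ring3_scripts``).  For ``n > 3`` the blocks are produced by a script
generator that follows the stated interaction rules: only adjacent agents
with different opinions interact; the infected agent lectures all of its
uninfected neighbors jointly, then each of those neighbors pushes back in
increasing index order; infected agents take their turns in increasing
index order.  Two conventions are configurable and frozen at the defaults
that reproduce the published group-decision numbers: the A1-An wrap edge is
excluded from the interaction bookkeeping (matching the worked five-agent
example), and neighbor infection status is read off the controller bit
string once per block rather than re-evaluated mid-script.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .line3 import BlockUnitary, Line3Angles, line3_scripts
from .qlinalg import InteractionScript, compile_script, rotation, _slot_kron

__all__ = [
    "Ring3Angles",
    "RingAngles",
    "build_ring3",
    "build_ring_n",
    "interaction_pairs",
    "ring_script",
]

_RING3_KEYS = {
    "u2": {"theta_y", "theta_z", "theta_xy", "theta_xz"},
    "u4": {"theta_y", "theta_z", "theta_x"},
    "u5": {"theta_y", "theta_x", "theta_zy", "theta_zx"},
    "u7": {"theta_xy", "theta_xz", "theta_y", "theta_z"},
}


@dataclass(frozen=True)
class Ring3Angles:
    """Named angles for the 3-agent ring; blocks u1/u3/u6 as on the line.

    The replaced blocks: ``u2`` theta_y/theta_z (A1's joint lecture of
    A2, A3) and theta_xy/theta_xz (their feedback on A1); ``u4`` theta_z
    (A2's and A1's lectures of A3), theta_y/theta_x (A3's feedback); ``u5``
    theta_y/theta_x (A3's lectures), theta_zy/theta_zx (feedback on A3);
    ``u7`` theta_xy/theta_xz (lectures of A1), theta_y/theta_z (A1's
    feedback).
    """

    u1: dict = field(default_factory=dict)
    u2: dict = field(default_factory=dict)
    u3: dict = field(default_factory=dict)
    u4: dict = field(default_factory=dict)
    u5: dict = field(default_factory=dict)
    u6: dict = field(default_factory=dict)
    u7: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        line_keys = {"u1": {"theta_x", "theta_y", "theta_z"},
                     "u3": {"theta_x", "theta_z", "theta_yx", "theta_yz"},
                     "u6": {"theta_x", "theta_z", "theta_xy", "theta_zy"}}
        for block, allowed in {**line_keys, **_RING3_KEYS}.items():
            entries = getattr(self, block)
            unknown = set(entries) - allowed
            if unknown:
                raise ValueError(f"unknown angle keys for {block}: {sorted(unknown)}")

    @classmethod
    def homogeneous(cls, theta: float, phi: float, *, initializing: bool = True) -> "Ring3Angles":
        """All infections at ``theta``, all counteractions at ``phi``."""
        init = {"theta_x": theta, "theta_y": theta, "theta_z": theta} if initializing else {}
        return cls(
            u1=init,
            u2={"theta_y": theta, "theta_z": theta, "theta_xy": phi, "theta_xz": phi},
            u3={"theta_x": theta, "theta_z": theta, "theta_yx": phi, "theta_yz": phi},
            u4={"theta_z": theta, "theta_y": phi, "theta_x": phi},
            u5={"theta_y": theta, "theta_x": theta, "theta_zy": phi, "theta_zx": phi},
            u6={"theta_x": theta, "theta_z": theta, "theta_xy": phi, "theta_zy": phi},
            u7={"theta_xy": theta, "theta_xz": theta, "theta_y": phi, "theta_z": phi},
        )

    def get(self, block: str, key: str) -> float:
        """Angle in radians (stored values are half-turns)."""
        return np.pi * float(getattr(self, block).get(key, 0.0))


def ring3_scripts(angles: Ring3Angles) -> tuple[InteractionScript, ...]:
    """The eight 3-agent ring scripts; u1/u3/u6/u8 shared with the line."""
    line = line3_scripts(
        Line3Angles(u1=angles.u1, u3=angles.u3, u6=angles.u6)
    )
    ctrl = InteractionScript.controlled
    a = angles.get
    u2 = InteractionScript(
        (
            ctrl(1, 1, [(2, a("u2", "theta_y")), (3, a("u2", "theta_z"))]),
            ctrl(2, 0, [(1, a("u2", "theta_xy"))]),
            ctrl(3, 0, [(1, a("u2", "theta_xz"))]),
        ),
        2,
    )
    u4 = InteractionScript(
        (
            ctrl(2, 1, [(3, a("u4", "theta_z"))]),
            ctrl(3, 0, [(2, a("u4", "theta_y"))]),
            ctrl(3, 0, [(1, a("u4", "theta_x"))]),
            ctrl(1, 1, [(3, a("u4", "theta_z"))]),
        ),
        4,
    )
    u5 = InteractionScript(
        (
            ctrl(3, 1, [(2, a("u5", "theta_y"))]),
            ctrl(2, 0, [(3, a("u5", "theta_zy"))]),
            ctrl(3, 1, [(1, a("u5", "theta_x"))]),
            ctrl(1, 0, [(3, a("u5", "theta_zx"))]),
        ),
        5,
    )
    u7 = InteractionScript(
        (
            ctrl(2, 1, [(1, a("u7", "theta_xy"))]),
            ctrl(1, 0, [(2, a("u7", "theta_y"))]),
            ctrl(3, 1, [(1, a("u7", "theta_xz"))]),
            ctrl(1, 0, [(3, a("u7", "theta_z"))]),
        ),
        7,
    )
    return (line[0], u2, line[2], u4, u5, line[5], u7, line[7])


def build_ring3(angles: Ring3Angles) -> BlockUnitary:
    """Compile the eight 3-agent ring blocks."""
    return BlockUnitary(tuple(compile_script(s, 3) for s in ring3_scripts(angles)), 3)


@dataclass(frozen=True)
class RingAngles:
    """Pairwise angles for the ``n``-agent ring generator.

    ``theta[(i, j)]`` is the infection rotation of Ai controlled by its
    infected neighbor Aj; ``phi[(i, j)]`` the counteraction rotation of Ai
    controlled by its uninfected neighbor Aj.  Angles are in half-turns
    (units of pi radians); scalars apply to every adjacent pair.
    ``theta_init`` feeds the optional all-zero-state initialization block
    (per-agent initial infection amount); it defaults to ``theta`` when
    that is scalar, else 0.
    """

    theta: float | dict = 0.0
    phi: float | dict = 0.0
    theta_init: float | dict | None = None

    def _lookup(self, table: float | dict, i: int, j: int) -> float:
        if isinstance(table, dict):
            return float(table.get((i, j), 0.0))
        return float(table)

    def infection(self, i: int, j: int) -> float:
        """Radians by which Aj's lecture rotates Ai."""
        return np.pi * self._lookup(self.theta, i, j)

    def counteraction(self, i: int, j: int) -> float:
        """Radians by which Aj's feedback rotates Ai."""
        return np.pi * self._lookup(self.phi, i, j)

    def initial(self, k: int) -> float:
        """Radians of Ak's initial-infection rotation (all-zero block)."""
        table = self.theta_init
        if table is None:
            table = self.theta if not isinstance(self.theta, dict) else 0.0
        if isinstance(table, dict):
            return np.pi * float(table.get(k, 0.0))
        return np.pi * float(table)


def _ring_neighbors(n: int, k: int, include_wrap: bool) -> tuple[int, ...]:
    out = {k - 1, k + 1} & set(range(1, n + 1))
    if include_wrap:
        if k == 1:
            out.add(n)
        if k == n:
            out.add(1)
    return tuple(sorted(out))


def interaction_pairs(bits: str, *, include_wrap: bool = False) -> list[tuple[int, int]]:
    """Ordered (infected, uninfected-neighbor) pairs for one controller state.

    ``bits`` is the controller bit string ``b_n .. b_1``.  Infected agents
    take their turns in increasing index order; within a turn the
    uninfected neighbors are listed in increasing index order.  The all-zero
    and all-one strings have no interactions.
    """
    n = len(bits)
    b = {k: int(bits[n - k]) for k in range(1, n + 1)}
    pairs: list[tuple[int, int]] = []
    for k in range(1, n + 1):
        if b[k] != 1:
            continue
        for j in _ring_neighbors(n, k, include_wrap):
            if b[j] == 0:
                pairs.append((k, j))
    return pairs


def ring_script(n: int, bits: str, angles: RingAngles, *, include_wrap: bool = False) -> InteractionScript:
    """Interaction script for one controller basis state of the ``n``-ring.

    For each infected agent in increasing order: one joint lecture rotating
    all of its uninfected neighbors (infection angles), then one feedback
    rotation on the lecturer per neighbor, lower-index neighbor first
    (counteraction angles).  Neighbor status is read from the controller bit
    string, not re-evaluated mid-script.
    """
    ctrl = InteractionScript.controlled
    b = {k: int(bits[n - k]) for k in range(1, n + 1)}
    steps = []
    for k in range(1, n + 1):
        if b[k] != 1:
            continue
        audience = [j for j in _ring_neighbors(n, k, include_wrap) if b[j] == 0]
        if not audience:
            continue
        steps.append(ctrl(k, 1, [(j, angles.infection(j, k)) for j in audience]))
        for j in audience:
            steps.append(ctrl(j, 0, [(k, angles.counteraction(k, j))]))
    return InteractionScript(tuple(steps), int(bits, 2) + 1)


def build_ring_n(
    n: int,
    angles: RingAngles,
    *,
    initializing: bool = False,
    include_wrap: bool = False,
) -> BlockUnitary:
    """Generate the ``2**n`` ring blocks for ``n > 3``.

    The all-one block is the identity (consensus reached).  The all-zero
    block is the tensor product of per-agent initial infection rotations
    when ``initializing`` (idea-propagation mode) and the identity otherwise
    (group-decision mode, where opinions pre-exist).
    """
    if n <= 3:
        raise ValueError("the ring generator requires n > 3; use build_ring3 for n = 3")
    d = 2**n
    blocks = []
    for i in range(d):
        bits = format(i, f"0{n}b")
        if i == 0:
            if initializing:
                blocks.append(_slot_kron(n, {k: rotation(angles.initial(k)) for k in range(1, n + 1)}))
            else:
                blocks.append(np.eye(d, dtype=complex))
        elif i == d - 1:
            blocks.append(np.eye(d, dtype=complex))
        else:
            blocks.append(compile_script(ring_script(n, bits, angles, include_wrap=include_wrap), n))
    return BlockUnitary(tuple(blocks), n)
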