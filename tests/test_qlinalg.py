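"""Unit and property tests for the quantum linear-algebra primitives."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from liftwalk.qlinalg import (
    M0,
    M1,
    AgentNetwork,
    InteractionScript,
    basis_state,
    build_controlled_gate,
    build_unconditional,
    compile_script,
    partial_trace,
    popcount_weights,
    rotation,
    validate_density,
    validate_unitary,
)

from conftest import random_density, random_pure

I2 = np.eye(2)


def brute_force_partial_trace(rho, dA, dB, traced):
    """Independent oracle: explicit double-index summation."""
    if traced == "B":
        out = np.zeros((dA, dA), dtype=complex)
        for a1 in range(dA):
            for a2 in range(dA):
                out[a1, a2] = sum(rho[a1 * dB + b, a2 * dB + b] for b in range(dB))
    else:
        out = np.zeros((dB, dB), dtype=complex)
        for b1 in range(dB):
            for b2 in range(dB):
                out[b1, b2] = sum(rho[a * dB + b1, a * dB + b2] for a in range(dA))
    return out


class TestBasisState:
    @pytest.mark.parametrize(
        "n,bits,index",
        [(3, "101", 6), (3, "000", 1), (1, "1", 2), (3, "111", 8), (5, "01101", 14)],
    )
    def test_single_one_at_binary_index(self, n, bits, index):
        v = basis_state(n, bits)
        assert v.shape == (2**n,)
        assert v[index - 1] == 1.0
        assert np.count_nonzero(v) == 1

    def test_malformed_bits_rejected(self):
        with pytest.raises(ValueError):
            basis_state(3, "10")
        with pytest.raises(ValueError):
            basis_state(3, "1a1")

    @given(st.integers(1, 6), st.integers(0, 63))
    @settings(deadline=None, max_examples=40, derandomize=True)
    def test_popcount_round_trip(self, n, raw):
        value = raw % 2**n
        bits = format(value, f"0{n}b")
        v = basis_state(n, bits)
        idx = int(np.argmax(np.abs(v))) + 1
        assert bin(idx - 1).count("1") == bits.count("1")


class TestRotation:
    def test_zero_angle_is_identity(self):
        assert np.allclose(rotation(0.0), I2)

    def test_quarter_turn_flips_qubit(self):
        assert np.allclose(rotation(np.pi / 2) @ np.array([1.0, 0.0]), [0.0, 1.0], atol=1e-15)

    def test_small_angle_entries(self):
        R = rotation(0.05)
        assert np.allclose(R, [[np.cos(0.05), -np.sin(0.05)], [np.sin(0.05), np.cos(0.05)]])

    @given(st.floats(-10, 10, allow_nan=False))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_always_orthogonal(self, theta):
        assert validate_unitary(rotation(theta))


class TestControlledGate:
    def test_matches_printed_two_qubit_form(self):
        # control on the least significant agent, rotate its neighbor
        th = 0.4
        expected = np.kron(I2, np.kron(I2, M0) + np.kron(rotation(th), M1))
        assert np.allclose(build_controlled_gate(3, 1, 1, [(2, th)]), expected)

    def test_control_value_zero_branch(self):
        th = -0.2
        expected = np.kron(I2, np.kron(M0, rotation(th)) + np.kron(M1, I2))
        assert np.allclose(build_controlled_gate(3, 2, 0, [(1, th)]), expected)

    def test_joint_two_target_lecture(self):
        ty, tz = 0.3, 0.7
        expected = np.kron(np.eye(4), M0) + np.kron(rotation(tz), np.kron(rotation(ty), M1))
        assert np.allclose(build_controlled_gate(3, 1, 1, [(2, ty), (3, tz)]), expected)

    def test_zero_angle_gives_identity(self):
        assert np.allclose(build_controlled_gate(4, 2, 1, [(3, 0.0)]), np.eye(16))

    def test_overlapping_indices_rejected(self):
        with pytest.raises(ValueError):
            build_controlled_gate(3, 1, 1, [(1, 0.1)])

    @given(st.integers(2, 5), st.integers(0, 1), st.floats(-3, 3, allow_nan=False))
    @settings(deadline=None, max_examples=40, derandomize=True)
    def test_unitary_and_branch_completeness(self, n, cv, th):
        G = build_controlled_gate(n, 1, cv, [(2, th)])
        assert validate_unitary(G)
        assert np.allclose(M0 + M1, I2)

    def test_opposite_control_values_compose_to_product(self):
        # gates conditioned on the two branches of the same control multiply
        # to the unconditional rotation on the target
        th = 0.31
        g1 = build_controlled_gate(2, 1, 1, [(2, th)])
        g0 = build_controlled_gate(2, 1, 0, [(2, th)])
        assert np.allclose(g1 @ g0, build_unconditional(2, [(2, th)]))


class TestUnconditional:
    def test_all_zero_angles(self):
        assert np.allclose(build_unconditional(3, [(1, 0.0), (2, 0.0), (3, 0.0)]), np.eye(8))

    def test_tensor_ordering_most_significant_last_agent(self):
        tx, ty, tz = 0.05, 0.01, 0.02
        expected = np.kron(rotation(tz), np.kron(rotation(ty), rotation(tx)))
        assert np.allclose(build_unconditional(3, [(1, tx), (2, ty), (3, tz)]), expected)

    def test_full_flips_map_all_zero_to_all_one(self):
        U = build_unconditional(2, [(1, np.pi / 2), (2, np.pi / 2)])
        assert np.allclose(np.abs(U @ basis_state(2, "00")), np.abs(basis_state(2, "11")), atol=1e-12)


class TestPartialTrace:
    def test_product_state_recovers_factor(self, rng):
        rA = random_density(rng, 4)
        rB = random_density(rng, 8)
        assert np.allclose(partial_trace(np.kron(rA, rB), (4, 8), "B"), rA, atol=1e-12)
        assert np.allclose(partial_trace(np.kron(rA, rB), (4, 8), "A"), rB, atol=1e-12)

    def test_bell_state_reduces_to_maximally_mixed(self):
        bell = (basis_state(2, "00") + basis_state(2, "11")) / np.sqrt(2)
        rho = np.outer(bell, bell.conj())
        assert np.allclose(partial_trace(rho, (2, 2), "B"), I2 / 2, atol=1e-12)

    def test_outer_product_rule(self, rng):
        a1, a2 = random_pure(rng, 3), random_pure(rng, 3)
        b1, b2 = random_pure(rng, 4), random_pure(rng, 4)
        rho = np.kron(np.outer(a1, a2.conj()), np.outer(b1, b2.conj()))
        expected = np.vdot(b2, b1) * np.outer(a1, a2.conj())
        assert np.allclose(partial_trace(rho, (3, 4), "B"), expected, atol=1e-12)

    @pytest.mark.parametrize("dims", [(2, 2), (4, 2), (2, 8), (8, 8)])
    @pytest.mark.parametrize("traced", ["A", "B"])
    def test_agrees_with_brute_force_oracle(self, rng, dims, traced):
        dA, dB = dims
        rho = random_density(rng, dA * dB)
        got = partial_trace(rho, dims, traced)
        want = brute_force_partial_trace(rho, dA, dB, traced)
        assert np.max(np.abs(got - want)) < 1e-12
        assert abs(np.trace(got) - np.trace(rho)) < 1e-12
        assert np.allclose(got, got.conj().T, atol=1e-12)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            partial_trace(np.eye(6), (2, 2), "A")


class TestCompileScript:
    def test_empty_script_is_identity(self):
        assert np.allclose(compile_script(InteractionScript(), 3), np.eye(8))

    def test_first_step_applied_first(self):
        # two-step pair interaction: lecture then push-back, matching the
        # printed product with the lecture as the rightmost factor
        ty, tx = 0.5, 0.2
        UY = build_controlled_gate(3, 1, 1, [(2, ty)])
        UX = build_controlled_gate(3, 2, 0, [(1, tx)])
        script = InteractionScript(
            (
                InteractionScript.controlled(1, 1, [(2, ty)]),
                InteractionScript.controlled(2, 0, [(1, tx)]),
            )
        )
        assert np.allclose(compile_script(script, 3), UX @ UY)

    def test_shared_control_steps_commute_and_merge(self, rng):
        # seeded random angles: sequential sub-gates sharing one control
        # equal the joint two-target gate in either order
        for _ in range(5):
            t1, t2 = rng.uniform(-1, 1, size=2)
            a = build_controlled_gate(3, 1, 1, [(2, t1)])
            b = build_controlled_gate(3, 1, 1, [(3, t2)])
            joint = build_controlled_gate(3, 1, 1, [(2, t1), (3, t2)])
            assert np.allclose(a @ b, b @ a, atol=1e-14)
            assert np.allclose(a @ b, joint, atol=1e-14)

    def test_compiled_script_is_unitary(self, rng):
        steps = tuple(
            InteractionScript.controlled(int(c), int(v), [(int(t), float(a))])
            for c, v, t, a in zip(
                rng.integers(1, 4, 6), rng.integers(0, 2, 6), rng.integers(1, 4, 6), rng.uniform(-1, 1, 6)
            )
            if c != t
        )
        assert validate_unitary(compile_script(InteractionScript(steps), 3))


class TestValidators:
    def test_unitary_accepts_identity_and_rotation(self):
        assert validate_unitary(np.eye(5))
        assert validate_unitary(rotation(0.3))

    def test_unitary_rejects_singular(self):
        M = np.eye(4)
        M[2, 2] = 0.0
        assert not validate_unitary(M)

    def test_density_checks(self, rng):
        assert validate_density(random_density(rng, 8))
        assert not validate_density(np.eye(4))          # trace 4
        assert not validate_density(1j * np.eye(2) / 2)  # not Hermitian


class TestAgentNetwork:
    def test_ring_wrap_neighbors(self):
        net = AgentNetwork(5, "ring")
        assert net.neighbors(1) == (2, 5)
        assert net.neighbors(1, include_wrap=False) == (2,)
        assert net.neighbors(3) == (2, 4)

    def test_line_endpoints(self):
        net = AgentNetwork(4, "line")
        assert net.neighbors(1) == (2,)
        assert net.neighbors(4) == (3,)

    def test_too_small_network_rejected(self):
        with pytest.raises(ValueError):
            AgentNetwork(1, "line")


def test_popcount_weights_three_agents():
    assert np.array_equal(popcount_weights(3), [0, 1, 1, 2, 1, 2, 2, 3])
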