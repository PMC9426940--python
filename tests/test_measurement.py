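"""Measurement channels, Kraus completeness, and trajectory unraveling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import variance
from spinwalk import (
    HADAMARD,
    ClassicalWalkSpec,
    DensityState,
    InitialSpec,
    StepOperator,
    WalkConfig,
    classical_distribution,
    decohere_evolve,
    decohere_step,
    density_step,
    evolve,
    fully_decohered_walk,
    kraus_set,
    make_point_state,
    position_distribution,
    sample_trajectory,
    spin_probabilities,
    trajectory_position_distribution,
)


class TestBasicObservables:
    def test_point_state_distribution(self):
        state = make_point_state(InitialSpec(x0=4))
        sites, probs = position_distribution(state)
        assert dict(zip(sites.tolist(), probs.tolist())) == {4: pytest.approx(1.0)}

    @pytest.mark.parametrize("eta", [0.0, 0.25, 1.0])
    def test_initial_spin_probabilities(self, eta):
        pl, pr = spin_probabilities(make_point_state(InitialSpec(eta=eta)))
        assert pl == pytest.approx(eta, abs=1e-12)
        assert pr == pytest.approx(1 - eta, abs=1e-12)

    def test_spin_mass_conserved_under_evolution(self, symmetric_state, hadamard_op):
        pl, pr = spin_probabilities(evolve(symmetric_state, hadamard_op, 30))
        assert pl + pr == pytest.approx(1.0, abs=1e-10)


class TestKrausSets:
    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(
        basis=st.sampled_from(["position", "spin", "both"]),
        p_m=st.floats(0.0, 1.0),
        n=st.integers(1, 6),
    )
    def test_completeness(self, basis, p_m, n):
        ops = kraus_set(basis, p_m).operators(n)
        total = sum(m.conj().T @ m for m in ops)
        assert np.allclose(total, np.eye(2 * n), atol=1e-12)

    def test_pm_zero_is_identity_channel(self, symmetric_state, hadamard_op):
        rho = DensityState.from_pure(evolve(symmetric_state, hadamard_op, 5))
        out = kraus_set("position", 0.0).apply(rho)
        assert np.allclose(out.matrix, rho.matrix, atol=1e-14)

    def test_full_position_measurement_dephases(self, symmetric_state, hadamard_op):
        """p_m=1 position channel: position-diagonal, unchanged marginal."""
        rho = DensityState.from_pure(evolve(symmetric_state, hadamard_op, 4))
        before = position_distribution(rho)[1]
        out = kraus_set("position", 1.0).apply(rho)
        n = out.n_sites
        r = out.matrix.reshape(2, n, 2, n)
        off = r.copy()
        ix = np.arange(n)
        off[:, ix, :, ix] = 0.0
        assert np.max(np.abs(off)) < 1e-12
        assert np.allclose(position_distribution(out)[1], before, atol=1e-12)

    def test_channel_matches_explicit_operator_sum(self, symmetric_state, hadamard_op):
        rho = DensityState.from_pure(evolve(symmetric_state, hadamard_op, 3))
        for basis in ("position", "spin", "both"):
            mset = kraus_set(basis, 0.3)
            explicit = sum(
                m @ rho.matrix @ m.conj().T for m in mset.operators(rho.n_sites)
            )
            assert np.allclose(mset.apply(rho).matrix, explicit, atol=1e-12)


class TestDecoherence:
    def test_pm_zero_equals_unitary_step(self, symmetric_state, hadamard_op):
        rho = DensityState.from_pure(symmetric_state)
        a = decohere_step(rho, hadamard_op, kraus_set("both", 0.0))
        b = density_step(rho, hadamard_op)
        assert np.allclose(a.matrix, b.matrix, atol=1e-14)

    def test_full_decoherence_equals_classical_walk(self, symmetric_state, hadamard_op):
        """p_m=1 both-bases Hadamard walk is the classical symmetric walk."""
        rho = DensityState.from_pure(symmetric_state)
        out = decohere_evolve(rho, hadamard_op, kraus_set("both", 1.0), 12)
        _, p_quantum = position_distribution(out)
        _, p_classical = classical_distribution(ClassicalWalkSpec(q=0.5), 12)
        assert np.allclose(p_quantum, p_classical, atol=1e-10)

    def test_position_only_full_measurement_classical_for_symmetric_config(
        self, symmetric_state, hadamard_op
    ):
        rho = DensityState.from_pure(symmetric_state)
        out = decohere_evolve(rho, hadamard_op, kraus_set("position", 1.0), 12)
        _, p_quantum = position_distribution(out)
        _, p_classical = classical_distribution(ClassicalWalkSpec(q=0.5), 12)
        assert np.allclose(p_quantum, p_classical, atol=1e-10)

    def test_fast_path_matches_full_channel(self, symmetric_state, hadamard_op):
        rho = DensityState.from_pure(symmetric_state)
        out = decohere_evolve(rho, hadamard_op, kraus_set("both", 1.0), 10)
        sites_d, p_d = position_distribution(out)
        sites_f, p_f = fully_decohered_walk(HADAMARD, InitialSpec(), 10)
        assert np.array_equal(sites_d, sites_f)
        assert np.allclose(p_d, p_f, atol=1e-12)

    def test_full_decoherence_variance_is_diffusive(self):
        sites, probs = fully_decohered_walk(HADAMARD, InitialSpec(), 50)
        assert variance(sites, probs) == pytest.approx(50.0, rel=0.1)

    @pytest.mark.parametrize("basis", ["position", "spin", "both"])
    def test_variance_strictly_decreasing_in_pm(self, symmetric_state, hadamard_op, basis):
        """More frequent measurement narrows the t=50 distribution, every basis."""
        variances = []
        rho0 = DensityState.from_pure(symmetric_state)
        for p_m in (0.0, 0.05, 0.15, 0.5, 1.0):
            out = decohere_evolve(rho0, hadamard_op, kraus_set(basis, p_m), 50)
            variances.append(variance(*position_distribution(out)))
        assert all(a > b for a, b in zip(variances, variances[1:]))


class TestTrajectories:
    def test_pm_zero_trajectory_is_pure_evolution(self, symmetric_state, hadamard_op):
        events, state = sample_trajectory(WalkConfig(p_m=0.0, T=15), 15, seed=3)
        assert events == []
        pure = evolve(symmetric_state, hadamard_op, 15)
        assert np.allclose(state.psi_l, pure.psi_l, atol=1e-12)
        assert np.allclose(state.psi_r, pure.psi_r, atol=1e-12)

    def test_same_seed_reproduces_path(self):
        cfg = WalkConfig(p_m=0.5, basis="both")
        events1, s1 = sample_trajectory(cfg, 25, seed=11)
        events2, s2 = sample_trajectory(cfg, 25, seed=11)
        assert events1 == events2
        assert np.allclose(s1.psi_l, s2.psi_l)

    def test_trajectory_average_matches_channel(self, symmetric_state, hadamard_op):
        """Monte-Carlo unraveling agrees with the density channel to 3 SE."""
        n_traj = 10_000
        cfg = WalkConfig(p_m=0.5, basis="position", seed=7)
        _, p_mc = trajectory_position_distribution(cfg, 20, n_traj, seed=7)
        rho0 = DensityState.from_pure(symmetric_state)
        out = decohere_evolve(rho0, hadamard_op, kraus_set("position", 0.5), 20)
        _, p_exact = position_distribution(out)
        se = np.sqrt(np.maximum(p_exact * (1 - p_exact), 1e-12) / n_traj)
        assert np.all(np.abs(p_mc - p_exact) <= 3 * se + 1e-12)
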