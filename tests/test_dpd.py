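import math

import numpy as np
import pytest

from platonet.config import ExperimentConfig
from platonet.dpd import (
    FLUID,
    MEMBRANE,
    BlowUpError,
    CouplingParams,
    FluidParams,
    NyquistError,
    ParticleState,
    check_nyquist,
    compute_all_forces,
    kinetic_temperature,
    nyquist_max_dt,
    pairwise_forces,
    step,
    velocity_profile,
    weight_conservative,
)
from platonet.simulate import create_couette_state, _coupling_params, _fluid_params


def make_state(pos, vel=None, species=None, box=(6.0, 6.0, 6.0), periodic_y=True,
               seed=11):
    pos = np.asarray(pos, dtype=float)
    n = len(pos)
    return ParticleState(
        positions=pos.copy(),
        velocities=np.zeros((n, 3)) if vel is None else np.asarray(vel, float).copy(),
        species=np.zeros(n, dtype=np.int8) if species is None
        else np.asarray(species, dtype=np.int8),
        mass=np.ones(n),
        box=box,
        n_fluid=int(np.sum(np.asarray(species) == FLUID)) if species is not None else n,
        n_membrane=int(np.sum(np.asarray(species) == MEMBRANE)) if species is not None else 0,
        periodic_y=periodic_y,
        noise_seed=seed,
    )


class TestWeightFunction:
    def test_at_cutoff_zero(self):
        assert weight_conservative(1.0, 1.0) == 0.0

    def test_at_contact_one(self):
        assert weight_conservative(0.0, 1.0) == 1.0

    def test_linear_midpoint(self):
        assert weight_conservative(0.5, 1.0) == pytest.approx(0.5)

    def test_beyond_cutoff_zero(self):
        assert weight_conservative(1.7, 1.0) == 0.0


class TestPairwiseForces:
    def test_beyond_cutoff_all_zero(self):
        st = make_state([[1.0, 3.0, 3.0], [2.5, 3.0, 3.0]])
        p = FluidParams(kBT=1.0)
        Fc, Fd, Fr = pairwise_forces(st, p, dt=0.02)
        assert np.all(Fc == 0) and np.all(Fd == 0) and np.all(Fr == 0)

    def test_dissipative_zero_at_rest(self):
        st = make_state([[1.0, 3.0, 3.0], [1.5, 3.0, 3.0]])
        Fc, Fd, Fr = pairwise_forces(st, FluidParams(), dt=0.02)
        assert np.all(Fd == 0)
        # repulsion pushes particle 0 away from its neighbour at larger x
        assert Fc[0, 0] < 0

    def test_conservative_magnitude(self):
        st = make_state([[1.0, 3.0, 3.0], [1.5, 3.0, 3.0]])
        p = FluidParams(kBT=1.0, rho_f=3.0)  # alpha = 25
        Fc, _, _ = pairwise_forces(st, p, dt=0.02)
        assert Fc[0, 0] == pytest.approx(-25.0 * 0.5)  # e_ij points from j to i
        assert np.allclose(Fc[0], -Fc[1])

    def test_newtons_third_law_total_zero(self):
        rng = np.random.default_rng(0)
        st = make_state(rng.uniform(0, 6, (150, 3)), vel=rng.normal(0, 1, (150, 3)))
        Fc, Fd, Fr = pairwise_forces(st, FluidParams(), dt=0.02)
        for F in (Fc, Fd, Fr):
            assert np.abs(F.sum(axis=0)).max() < 1e-10

    def test_random_force_symmetric_noise(self):
        # zeta_ij = zeta_ji: the random pair force is antisymmetric
        st = make_state([[1.0, 3.0, 3.0], [1.6, 3.0, 3.0]])
        _, _, Fr = pairwise_forces(st, FluidParams(), dt=0.02)
        assert np.allclose(Fr[0], -Fr[1])
        assert np.any(Fr[0] != 0)

    def test_cell_list_matches_bruteforce(self):
        # <= 500 particles, identical noise streams, agreement to 1e-12
        rng = np.random.default_rng(42)
        pos = rng.uniform(0, 6, (400, 3))
        vel = rng.normal(0, 1, (400, 3))
        st1 = make_state(pos, vel=vel)
        st2 = make_state(pos, vel=vel)
        p = FluidParams()
        F1 = pairwise_forces(st1, p, dt=0.02)
        F2 = pairwise_forces(st2, p, dt=0.02, brute_force=True)
        for a, b in zip(F1, F2):
            scale = max(1.0, np.abs(b).max())
            assert np.abs(a - b).max() / scale < 1e-12

    def test_galilean_invariance(self):
        rng = np.random.default_rng(7)
        pos = rng.uniform(0, 6, (100, 3))
        vel = rng.normal(0, 1, (100, 3))
        st1 = make_state(pos, vel=vel)
        st2 = make_state(pos, vel=vel + np.array([3.0, -1.0, 0.5]))
        p = FluidParams()
        Fc1, Fd1, Fr1 = pairwise_forces(st1, p, dt=0.02)
        Fc2, Fd2, Fr2 = pairwise_forces(st2, p, dt=0.02)
        assert np.allclose(Fc1, Fc2, atol=1e-12)
        assert np.allclose(Fd1, Fd2, atol=1e-10)
        assert np.allclose(Fr1, Fr2, atol=1e-12)

    def test_coincident_particles_capped(self):
        st = make_state([[1.0, 3.0, 3.0], [1.0, 3.0, 3.0]])
        p = FluidParams(kBT=1.0, rho_f=3.0)
        Fc, _, _ = pairwise_forces(st, p, dt=0.02)
        assert np.isfinite(Fc).all()
        assert np.abs(Fc[0]).max() <= p.alpha_hat + 1e-12
        assert st.n_capped == 1


class TestFluidParams:
    def test_fluctuation_dissipation_link(self):
        p = FluidParams(gamma_hat=4.5, kBT=0.7)
        assert p.sigma_hat**2 == pytest.approx(2 * 4.5 * 0.7, rel=1e-12)

    def test_alpha_rule(self):
        p = FluidParams(kBT=1.0, rho_f=3.0, r_c=1.0)
        assert p.alpha_hat == pytest.approx(25.0)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            FluidParams(kBT=-1.0)


class TestIntegrator:
    def test_free_streaming(self):
        vel = np.array([[0.3, -0.2, 0.1], [0.3, -0.2, 0.1]])
        st = make_state([[1.0, 1.0, 1.0], [4.0, -2.0, 4.0]], vel=vel)
        p = FluidParams(alpha_hat=0.0, gamma_hat=1e-12, kBT=1e-24)
        x0 = st.positions.copy()
        for _ in range(10):
            step(st, p, 0.05)
        assert np.allclose(st.positions, x0 + 10 * 0.05 * vel, atol=1e-9)

    def test_two_body_bond_energy_conservation(self):
        # single harmonic bond, no fluid: symplectic integrator keeps the
        # mechanical energy drift below 1% over 1e4 steps
        from platonet.geometry import PlateletGeometry
        from platonet.membrane import harmonic_bond_forces

        K = 5.0
        geom = PlateletGeometry(
            positions=np.array([[2.0, 0.0, 2.0], [3.0, 0.0, 2.0]]),
            semi_axes=(1, 1, 1),
            bonds=np.array([[0, 1]]),
            rest_lengths=np.array([1.0]),
        )
        pos = np.array([[2.0, 0.0, 2.0], [3.2, 0.0, 2.0]])  # stretched by 0.2
        st = make_state(
            pos, species=[MEMBRANE, MEMBRANE], box=(6.0, 6.0, 6.0), periodic_y=True
        )
        st.bond_exclusions = np.array([[1], [0]]) + st.n_fluid
        p = FluidParams(alpha_hat=0.0, gamma_hat=1e-12, kBT=1e-24)
        # well below the two-body resonance (reduced mass halves the period;
        # the bounded Verlet energy oscillation scales as (omega*dt)^2)
        dt = 0.02 * nyquist_max_dt(K, 1, 1.0)

        def energy():
            _, e = harmonic_bond_forces(st.positions, geom, K)
            ke = 0.5 * np.sum(st.velocities**2)
            return e + ke

        e0 = energy()
        for _ in range(10_000):
            step(st, p, dt, bonds=geom.bonds, rest_lengths=geom.rest_lengths, K=K)
        assert abs(energy() - e0) / e0 < 0.01

    def test_nyquist_guard(self):
        assert nyquist_max_dt(0.0, 6, 1.0) == math.inf
        dt_max = nyquist_max_dt(3.0, 8, 1.0)
        with pytest.raises(NyquistError, match="maximum admissible dt"):
            check_nyquist(dt_max * 1.01, 3.0, 8, 1.0)
        check_nyquist(dt_max * 0.5, 3.0, 8, 1.0)  # admissible: no raise

    def test_velocity_ceiling_raises(self):
        st = make_state([[1.0, 3.0, 3.0], [1.001, 3.0, 3.0]])
        p = FluidParams(kBT=1.0)
        with pytest.raises(BlowUpError):
            for _ in range(100):
                step(st, p, 0.5, velocity_ceiling=5.0)

    def test_momentum_conserved_fully_periodic(self):
        rng = np.random.default_rng(1)
        st = make_state(rng.uniform(0, 6, (300, 3)), vel=rng.normal(0, 1, (300, 3)))
        p = FluidParams()
        p0 = st.velocities.sum(axis=0)
        for _ in range(1000):
            step(st, p, 0.02)
        drift = np.abs(st.velocities.sum(axis=0) - p0).max()
        assert drift < 1e-8


class TestTemperature:
    def test_all_zero_velocities(self):
        st = make_state(np.random.default_rng(0).uniform(0, 6, (50, 3)))
        assert kinetic_temperature(st) == 0.0

    def test_maxwell_boltzmann_sampling(self):
        rng = np.random.default_rng(2)
        st = make_state(
            rng.uniform(0, 6, (4000, 3)), vel=rng.normal(0, 1.0, (4000, 3))
        )
        assert kinetic_temperature(st) == pytest.approx(1.0, rel=0.05)

    def test_pure_shear_reports_zero(self):
        rng = np.random.default_rng(3)
        pos = rng.uniform(0, 6, (2000, 3))
        pos[:, 1] -= 3.0
        vel = np.zeros((2000, 3))
        vel[:, 0] = 0.5 * pos[:, 1]  # pure streaming, no thermal part
        st = make_state(pos, vel=vel, box=(6, 6, 6))
        assert kinetic_temperature(st, n_bins=24) < 1e-3

    def test_too_few_particles_rejected(self):
        st = make_state([[1.0, 0.0, 1.0]])
        with pytest.raises(ValueError):
            kinetic_temperature(st)


class TestVelocityProfile:
    def test_quiescent_profile_flat(self):
        rng = np.random.default_rng(4)
        states = []
        for _ in range(20):
            pos = rng.uniform(0, 6, (500, 3))
            pos[:, 1] -= 3.0  # y is centred on the gap
            st = make_state(pos, vel=rng.normal(0, 0.3, (500, 3)))
            states.append(st)
        prof = velocity_profile(states, n_bins=10)
        se = 0.3 / np.sqrt(prof["counts"])
        assert np.all(np.abs(prof["v_x"]) < 3.5 * se)

    def test_empty_bins_flagged(self):
        st = make_state([[1.0, 2.9, 1.0], [2.0, 2.8, 2.0]])
        prof = velocity_profile(st, n_bins=6)
        assert prof["empty"].any()
        assert np.isnan(prof["v_x"][prof["empty"]]).all()

    def test_no_penetration_gap_at_membrane(self, tiny_config, small_shell):
        # the LJ core keeps a clear solvent gap on both sides of the
        # membrane surface (the depleted band around the shell)
        from scipy.spatial import cKDTree

        from platonet.simulate import _coupling_params, _fluid_params

        st = create_couette_state(tiny_config, small_shell, seed=1)
        params = _fluid_params(tiny_config)
        coup = _coupling_params(tiny_config, small_shell)
        K_red = tiny_config.stiffness_reduced(0.0015)
        for _ in range(100):
            step(st, params, tiny_config.dt, coup, small_shell.bonds,
                 small_shell.rest_lengths, K_red, velocity_ceiling=50.0)
        mem = st.positions[st.species == MEMBRANE]
        flu = st.positions[st.species == FLUID]
        d, _ = cKDTree(mem).query(flu)
        assert d.min() > 0.5 * tiny_config.sigma_lj
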