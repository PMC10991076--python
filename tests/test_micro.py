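"""Particle model: forces, CAM kinetics, stepping, turning, binning."""

import numpy as np
import pytest

from adhesim.kernels import DensityField1D, FiberDistribution, ForceLaw
from adhesim.micro import (
    MicroParams,
    MicroState,
    adhesion_acceleration,
    adhesion_accelerations,
    cam_rate,
    empirical_density,
    simulate_micro,
    step_deterministic,
    step_turning,
)
from adhesim.cam import BindingKinetics
from adhesim.fixtures import make_particle_cloud, two_cell_attracting


def const_kinetics(kp, km, r=1.0):
    return BindingKinetics(
        kplus=lambda S, rho, _v=kp: np.where(np.asarray(rho) < r, _v, 0.0),
        kminus=lambda S, rho, _v=km: np.where(np.asarray(rho) < r, _v, 0.0),
        r=r,
    )


class TestAdhesionForce:
    def test_two_cell_mutual_attraction(self):
        st = two_cell_attracting()
        assert adhesion_acceleration(st, 0) == pytest.approx(0.25, abs=1e-14)
        assert adhesion_acceleration(st, 1) == pytest.approx(-0.25, abs=1e-14)

    def test_out_of_range_pair_feels_nothing(self):
        p = MicroParams()
        st = MicroState(t=0.0, x=np.array([0.0, 1.5]), v=np.zeros(2), params=p)
        assert adhesion_acceleration(st, 0) == 0.0

    def test_unbound_cell_feels_nothing_in_cam_mode(self):
        p = MicroParams(kinetics=const_kinetics(1.0, 1.0), S=1.0)
        st = MicroState(t=0.0, x=np.array([0.0, 0.5]), v=np.zeros(2), params=p,
                        y=np.array([0.0, 0.8]))
        assert adhesion_acceleration(st, 0) == 0.0
        assert adhesion_accelerations(st)[0] == 0.0

    def test_batch_matches_per_particle_sum(self):
        rng = np.random.default_rng(3)
        p = MicroParams(chi=0.7)
        st = MicroState(t=0.0, x=rng.uniform(0, 3, 40), v=np.zeros(40), params=p)
        batch = adhesion_accelerations(st)
        direct = np.array([adhesion_acceleration(st, i) for i in range(40)])
        assert np.allclose(batch, direct, atol=1e-13)

    def test_counting_shortcut_matches_direct_sum(self):
        from adhesim.micro import _pair_gradient_sum_1d, _pair_gradient_sum_1d_constF

        rng = np.random.default_rng(11)
        x = rng.uniform(0, 6, 500)
        law = ForceLaw.constant()
        assert np.allclose(
            _pair_gradient_sum_1d(x, law), _pair_gradient_sum_1d_constF(x, law),
            atol=1e-12,
        )


class TestCamRate:
    def test_pure_binding_pair(self):
        p = MicroParams(kinetics=const_kinetics(2.0, 0.0), S=1.0)
        st = MicroState(t=0.0, x=np.array([0.0, 0.5]), v=np.zeros(2), params=p,
                        y=np.zeros(2))
        # (1/N) * (k0/|B_r|) * 1 * 1 = 2/(2*2)
        assert cam_rate(st, 0) == pytest.approx(0.5, abs=1e-14)

    def test_mixed_saturation_vanishes(self):
        p = MicroParams(kinetics=const_kinetics(0.0, 7.0), S=1.0)
        st = MicroState(t=0.0, x=np.array([0.0, 0.5]), v=np.zeros(2), params=p,
                        y=np.array([0.0, 1.0]))
        assert cam_rate(st, 0) == 0.0  # (1-y_i)(1-y_j) = 0 and y_i y_j = 0

    def test_distant_pair_vanishes(self):
        p = MicroParams(kinetics=const_kinetics(5.0, 5.0), S=1.0)
        st = MicroState(t=0.0, x=np.array([0.0, 1.2]), v=np.zeros(2), params=p,
                        y=np.array([0.5, 0.5]))
        assert cam_rate(st, 0) == 0.0


class TestDeterministicStep:
    def test_isolated_resting_cell_is_stationary(self):
        p = MicroParams()
        st = MicroState(t=0.0, x=np.array([2.0]), v=np.zeros(1), params=p)
        out = step_deterministic(st, 0.05)
        assert out.x[0] == 2.0 and out.v[0] == 0.0

    def test_free_cell_velocity_decays_exponentially(self):
        p = MicroParams(a=1.0, chi=0.0)
        st = MicroState(t=0.0, x=np.array([3.0]), v=np.array([0.5]), params=p)
        for _ in range(100):
            st = step_deterministic(st, 0.01)
        assert st.v[0] == pytest.approx(0.5 * np.exp(-1.0), rel=1e-8)

    def test_mirror_symmetry_preserved(self):
        st = two_cell_attracting()
        mid = st.x.mean()
        for _ in range(50):
            st = step_deterministic(st, 0.01)
            assert st.x[0] + st.x[1] == pytest.approx(2 * mid, abs=1e-9)
            assert st.v[0] == pytest.approx(-st.v[1], abs=1e-9)

    def test_speed_cap_violation_refused(self):
        p = MicroParams(a=0.1, chi=1.0)  # 0.5 > 0.1
        st = MicroState(t=0.0, x=np.array([0.0, 0.5]), v=np.zeros(2), params=p)
        with pytest.raises(ValueError, match="speed-cap"):
            step_deterministic(st, 0.01)

    def test_large_population_matches_fine_step_oracle(self):
        # attraction dynamics at dt agrees with the same dynamics at dt/10
        p = MicroParams(a=1.0, chi=1.0)
        st = make_particle_cloud(5000, region=(0.0, 6.0), seed=3, params=p)
        coarse = simulate_micro(st, T=1.0, dt=0.02)
        fine = simulate_micro(st, T=1.0, dt=0.002)
        assert np.max(np.abs(coarse.states[-1].x - fine.states[-1].x)) < 1e-5
        grid = DensityField1D(np.zeros(61), h=0.1)
        e1 = empirical_density(coarse.states[-1], grid)
        e2 = empirical_density(fine.states[-1], grid)
        assert np.sum(np.abs(e1.values - e2.values)) * 0.1 < 1e-3


class TestTurning:
    def test_turn_fraction_matches_exponential_thinning(self):
        p = MicroParams()
        st = make_particle_cloud(40000, speed_cap=0.5, seed=9, params=p)
        rng = np.random.default_rng(1)
        dt = 0.05
        out = step_turning(st, dt, FiberDistribution.isotropic_1d(), rng)
        frac = np.mean(out.v != st.v)
        expected = -np.expm1(-dt)
        # binomial 4-sigma band (re-draws of the same speed/direction are rare)
        assert abs(frac - expected) < 4 * np.sqrt(expected / st.N) + 2e-3

    def test_isotropic_turns_have_zero_mean_velocity(self):
        p = MicroParams()
        st = make_particle_cloud(50000, speed_cap=0.0, seed=2, params=p)
        out = step_turning(st, 50.0, FiberDistribution.isotropic_1d(),
                           np.random.default_rng(4))
        sigma = np.sqrt(1.0 / 3.0) / np.sqrt(st.N)  # E[v^2] = 1/3 for the mixture
        assert abs(out.v.mean()) < 3 * sigma

    def test_fully_aligned_fibers_give_positive_velocities(self):
        p = MicroParams()
        st = make_particle_cloud(2000, speed_cap=0.9, seed=5, params=p)
        q = FiberDistribution(d=1, q_plus=1.0, q_minus=0.0)
        out = step_turning(st, 60.0, q, np.random.default_rng(6))
        assert np.all(out.v > 0)


class TestEmpiricalDensity:
    def test_single_particle_single_bin(self):
        p = MicroParams()
        st = MicroState(t=0.0, x=np.array([0.005]), v=np.zeros(1), params=p)
        grid = DensityField1D(np.zeros(601), h=0.01)
        e = empirical_density(st, grid, total_mass=1.0)
        assert e.values[0] == pytest.approx(100.0)
        assert np.count_nonzero(e.values) == 1

    def test_bin_sum_reproduces_total_mass(self):
        p = MicroParams()
        st = make_particle_cloud(777, seed=8, params=p)
        grid = DensityField1D(np.zeros(601), h=0.01)
        e = empirical_density(st, grid, total_mass=4.5)
        assert np.sum(e.values) * 0.01 == pytest.approx(4.5, abs=1e-12)

    def test_uniform_cloud_is_flat_within_sampling_error(self):
        p = MicroParams()
        st = make_particle_cloud(100_000, seed=12, params=p)
        grid = DensityField1D(np.zeros(61), h=0.1)
        e = empirical_density(st, grid, total_mass=1.0)
        # last node owns only points at exactly x = L
        per_bin = st.N * 0.1 / 6.0
        se = np.sqrt(per_bin) / (st.N * 0.1)
        assert np.max(np.abs(e.values[:-1] - 1 / 6.0)) < 5 * se


class TestSimulate:
    def test_static_population_stays_static(self):
        p = MicroParams(chi=0.0)
        st = make_particle_cloud(20, seed=1, params=p)
        traj = simulate_micro(st, T=0.5, dt=0.01)
        assert np.array_equal(traj.states[-1].x, st.x)

    def test_attracting_pair_distance_decreases_until_collapse(self):
        st = two_cell_attracting()
        traj = simulate_micro(st, T=5.0, dt=0.01, snapshot_every=25)
        dists = np.array([abs(s.x[1] - s.x[0]) for s in traj.states])
        # distance decreases monotonically until the cells cross, after which
        # the damped pair oscillates through the common midpoint
        first_rise = int(np.argmax(np.diff(dists) > 1e-12))
        assert dists[first_rise] < 0.1  # only rises once essentially collapsed
        assert np.all(np.diff(dists[: first_rise + 1]) <= 1e-12)
        assert dists[-1] < 0.1 < dists[0]

    def test_identical_seeds_identical_trajectories(self):
        p = MicroParams(a=1.0, chi=0.5)
        st = make_particle_cloud(50, speed_cap=0.5, seed=7, params=p)
        q = FiberDistribution.isotropic_1d()
        t1 = simulate_micro(st, T=0.5, dt=0.01, q=q, seed=123)
        t2 = simulate_micro(st, T=0.5, dt=0.01, q=q, seed=123)
        assert np.array_equal(t1.states[-1].x, t2.states[-1].x)
        assert np.array_equal(t1.states[-1].v, t2.states[-1].v)

    def test_velocity_and_bound_fraction_barriers(self):
        # under the speed-cap condition |v| stays in the unit ball and y in [0,1]
        kin = BindingKinetics(
            kplus=lambda S, rho: np.where(np.asarray(rho) < 1.0, 3.0, 0.0),
            kminus=lambda S, rho: np.where(np.asarray(rho) < 1.0, 1.0, 0.0),
            r=1.0,
        )
        p = MicroParams(a=1.0, chi=2.0, kinetics=kin, S=1.0)  # chi*sup|gradH| = 1 <= a? 2*0.5=1
        st = make_particle_cloud(60, region=(2.0, 4.0), speed_cap=0.99, seed=21,
                                 params=p, cam=True)
        traj = simulate_micro(st, T=2.0, dt=0.01, q=FiberDistribution.isotropic_1d(),
                              seed=5)
        for s in traj.states:
            assert np.max(np.abs(s.v)) <= 1 + 1e-9
            assert np.all(s.y >= -1e-12) and np.all(s.y <= 1 + 1e-12)

    def test_well_mixed_cloud_relaxes_to_sqrt_equilibrium(self):
        kin = BindingKinetics(
            kplus=lambda S, rho: np.where(np.asarray(rho) < 1.0, 4.0, 0.0),
            kminus=lambda S, rho: np.where(np.asarray(rho) < 1.0, 1.0, 0.0),
            r=1.0,
        )
        p = MicroParams(a=1.0, chi=0.0, kinetics=kin, S=1.0)
        st = make_particle_cloud(60, region=(2.9, 3.1), seed=11, params=p, cam=True)
        traj = simulate_micro(st, T=40.0, dt=0.05)
        y = traj.states[-1].y
        assert np.max(np.abs(y - 2.0 / 3.0)) < 1e-3  # sqrt(4)/(sqrt(4)+sqrt(1))

    def test_trajectory_table_layout(self, tmp_path):
        st = two_cell_attracting()
        traj = simulate_micro(st, T=0.1, dt=0.01, snapshot_every=5)
        tab = traj.to_table()
        assert tab.shape[1] == 5
        path = tmp_path / "traj.tsv"
        traj.save(path)
        assert path.read_text().splitlines()[0].split("\t") == ["t", "id", "x", "v", "y"]
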