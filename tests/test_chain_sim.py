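"""Brownian dynamics of chain formation: diffusion, merging, conservation."""

import numpy as np
import pytest

from mnph.chain_sim import (
    SimulationConfig,
    Trajectory,
    _take_snapshot,
    attraction_radius,
    brownian_step,
    compute_statistics,
    concentration_to_count,
    detect_and_merge,
    diffusion_coefficients,
    effective_time_step,
    init_configuration,
    run_simulation,
)
from mnph.errors import ConfigError
from mnph.synthetic_data import make_preset, scale_particle_count


class TestDiffusionCoefficients:
    def test_stokes_einstein_singleton(self, particle_40nm, env_water):
        d_par, d_perp = diffusion_coefficients(1, particle_40nm, env_water)
        assert d_par == d_perp == pytest.approx(1.0987e-11, rel=1e-3)

    def test_rod_limit_axial_over_transverse_tends_to_two(self, particle_40nm, env_water):
        ratios = []
        for s in (10, 1000, 10**9):
            d_par, d_perp = diffusion_coefficients(s, particle_40nm, env_water)
            ratios.append(d_par / d_perp)
        assert all(a < b < 2.0 for a, b in zip(ratios, ratios[1:]))
        assert ratios[-1] == pytest.approx(2.0, rel=0.05)

    def test_monotone_decrease_with_chain_length(self, particle_40nm, env_water):
        # the constant end corrections make the axial coefficient dip at
        # s = 2 before its asymptotic decay; monotone from s = 3 onward
        d_par = [diffusion_coefficients(s, particle_40nm, env_water)[0] for s in range(1, 101)]
        d_perp = [diffusion_coefficients(s, particle_40nm, env_water)[1] for s in range(1, 101)]
        assert d_par[0] > d_par[1] > 0
        assert all(a > b > 0 for a, b in zip(d_par[2:], d_par[3:]))
        assert all(a > b > 0 for a, b in zip(d_perp, d_perp[1:]))


class TestInitConfiguration:
    def test_deterministic_under_seed(self, particle_40nm, env_water):
        cfg = SimulationConfig(n_particles=380, box_d0_units=80.0, seed=11)
        a = init_configuration(cfg, particle_40nm, env_water)
        b = init_configuration(cfg, particle_40nm, env_water)
        np.testing.assert_array_equal(a.positions_m, b.positions_m)

    def test_minimum_pairwise_distance_one_diameter(self, particle_40nm, env_water):
        cfg = SimulationConfig(n_particles=200, box_d0_units=40.0, seed=3)
        state = init_configuration(cfg, particle_40nm, env_water)
        pos, box = state.positions_m, state.box_m
        d = pos[None, :, :] - pos[:, None, :]
        d -= box * np.round(d / box)
        r = np.sqrt((d**2).sum(-1))
        np.fill_diagonal(r, np.inf)
        assert r.min() >= particle_40nm.diameter_m

    def test_dense_packing_refused(self, particle_40nm, env_water):
        cfg = SimulationConfig(n_particles=5000, box_d0_units=15.0)
        with pytest.raises(ConfigError, match="packing"):
            init_configuration(cfg, particle_40nm, env_water)

    def test_single_particle(self, particle_40nm, env_water):
        cfg = SimulationConfig(n_particles=1)
        state = init_configuration(cfg, particle_40nm, env_water)
        assert state.mean_length == 1.0 and state.n_merges == 0


class TestBrownianStep:
    def test_zero_timestep_leaves_state_unchanged(self, particle_40nm, env_water, big_box_cfg):
        cfg = big_box_cfg(n=20, box_d0=80.0)
        state = init_configuration(cfg, particle_40nm, env_water)
        before = state.positions_m.copy()
        brownian_step(state, cfg, particle_40nm, env_water, dt_s=0.0)
        np.testing.assert_array_equal(state.positions_m, before)

    def test_particle_count_conserved_and_no_overlap_without_field(
        self, particle_40nm, env_water
    ):
        cfg = SimulationConfig(n_particles=60, box_d0_units=20.0, field_on=False, seed=5)
        state = init_configuration(cfg, particle_40nm, env_water)
        d0 = particle_40nm.diameter_m
        for _ in range(200):
            brownian_step(state, cfg, particle_40nm, env_water)
            assert state.total_particles == 60
        pos, box = state.positions_m, state.box_m
        d = pos[None, :, :] - pos[:, None, :]
        d -= box * np.round(d / box)
        r = np.sqrt((d**2).sum(-1))
        np.fill_diagonal(r, np.inf)
        assert r.min() >= d0 * (1 - 1e-6)

    def test_rms_step_clamp(self, particle_40nm, env_water):
        cfg = SimulationConfig(dt_s=1.0)  # absurdly large requested step
        dt = effective_time_step(cfg, particle_40nm, env_water)
        d1, _ = diffusion_coefficients(1, particle_40nm, env_water)
        assert np.sqrt(2 * d1 * dt) <= 0.1 * particle_40nm.diameter_m * (1 + 1e-12)


class TestDetectAndMerge:
    def test_coaxial_pair_inside_zone_merges(
        self, particle_40nm, env_water, line_state_factory, big_box_cfg
    ):
        r_a = attraction_radius(1, particle_40nm, env_water)
        d0 = particle_40nm.diameter_m
        state = line_state_factory([100.0, 100.0 + 0.99 * r_a / d0], [1, 1], particle_40nm)
        detect_and_merge(state, big_box_cfg(2), particle_40nm, env_water)
        assert list(state.lengths) == [2]
        # merged at the (equal-weight) centre of mass
        assert state.positions_m[0, 2] == pytest.approx((100.0 + 0.495 * r_a / d0) * d0)

    def test_pair_outside_zone_does_not_merge(
        self, particle_40nm, env_water, line_state_factory, big_box_cfg
    ):
        r_a = attraction_radius(1, particle_40nm, env_water)
        d0 = particle_40nm.diameter_m
        state = line_state_factory([100.0, 100.0 + 1.01 * r_a / d0], [1, 1], particle_40nm)
        detect_and_merge(state, big_box_cfg(2), particle_40nm, env_water)
        assert list(state.lengths) == [1, 1]

    def test_chain_lengths_add(self, particle_40nm, env_water, line_state_factory, big_box_cfg):
        state = line_state_factory([95.0, 100.0], [2, 3], particle_40nm)
        detect_and_merge(state, big_box_cfg(2), particle_40nm, env_water)
        assert list(state.lengths) == [5]

    def test_merged_position_is_length_weighted(
        self, particle_40nm, env_water, line_state_factory, big_box_cfg
    ):
        d0 = particle_40nm.diameter_m
        state = line_state_factory([95.0, 100.0], [2, 3], particle_40nm)
        detect_and_merge(state, big_box_cfg(2), particle_40nm, env_water)
        assert state.positions_m[0, 2] == pytest.approx((95 + 3 / 5 * 5) * d0)

    def test_zero_field_is_noop(self, particle_40nm, env_water, line_state_factory, big_box_cfg):
        state = line_state_factory([100.0, 101.0], [1, 1], particle_40nm)
        detect_and_merge(state, big_box_cfg(2, field_on=False), particle_40nm, env_water)
        assert list(state.lengths) == [1, 1]

    def test_weak_coupling_is_noop(self, particle_10nm, env_water, line_state_factory, big_box_cfg):
        state = line_state_factory([100.0, 101.0], [1, 1], particle_10nm)
        detect_and_merge(state, big_box_cfg(2), particle_10nm, env_water)
        assert list(state.lengths) == [1, 1]


def brute_force_cascade(z_d0, lengths, p, env):
    """Independent event-driven enumeration of the merge rule on a line.

    Objects are (z_center, s) tuples; repeatedly merge the closest
    qualifying pair (nearest tips inside r_a of the longer chain) until
    none qualifies. Pure-python reference for small instances.
    """
    d0 = p.diameter_m
    objs = [(z * d0, int(s)) for z, s in zip(z_d0, lengths)]
    while True:
        best = None
        for i in range(len(objs)):
            for j in range(i + 1, len(objs)):
                zi, si = objs[i]
                zj, sj = objs[j]
                hi, hj = (si - 1) * d0 / 2, (sj - 1) * d0 / 2
                dz = zj - zi
                tip = min(
                    abs(dz + a * hj - b * hi) for a in (-1, 1) for b in (-1, 1)
                )
                if tip < attraction_radius(max(si, sj), p, env):
                    if best is None or tip < best[0]:
                        best = (tip, i, j)
        if best is None:
            return sorted(s for _, s in objs)
        _, i, j = best
        zi, si = objs[i]
        zj, sj = objs[j]
        merged = ((zi * si + zj * sj) / (si + sj), si + sj)
        objs = [o for k, o in enumerate(objs) if k not in (i, j)] + [merged]


class TestMergeCascadeOracle:
    @pytest.mark.parametrize("seed", range(8))
    def test_small_instances_match_brute_force(
        self, seed, particle_40nm, env_water, line_state_factory, big_box_cfg
    ):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 6))
        z = np.sort(rng.uniform(50.0, 150.0, size=n))
        # enforce non-overlap on the line
        z += np.arange(n) * 1.5
        state = line_state_factory(z, np.ones(n, int), particle_40nm, box_d0=400.0)
        detect_and_merge(state, big_box_cfg(n, box_d0=400.0), particle_40nm, env_water)
        expected = brute_force_cascade(z, np.ones(n, int), particle_40nm, env_water)
        assert sorted(state.lengths.tolist()) == expected


class TestRunSimulation:
    def test_deterministic_trajectories(self, particle_40nm, env_water):
        pre = scale_particle_count(make_preset("paper_40nm_4mgml"), 60)
        cfg = SimulationConfig(
            n_particles=60,
            box_d0_units=pre.simulation.box_d0_units,
            total_time_s=3e-5,
            seed=9,
        )
        r1 = run_simulation(cfg, particle_40nm, env_water)
        r2 = run_simulation(cfg, particle_40nm, env_water)
        np.testing.assert_array_equal(
            r1.final_state.positions_m, r2.final_state.positions_m
        )
        np.testing.assert_array_equal(r1.final_state.lengths, r2.final_state.lengths)

    def test_conservation_and_monotone_growth(self, particle_40nm, env_water):
        cfg = SimulationConfig(
            n_particles=80, box_d0_units=25.0, total_time_s=2e-4, seed=2
        )
        res = run_simulation(cfg, particle_40nm, env_water)
        for snap in res.trajectory.snapshots:
            assert int(snap.lengths.sum()) == 80
        assert np.all(np.diff(res.statistics.mean_length) >= 0)
        assert res.statistics.mean_length[0] == 1.0

    def test_weak_coupling_never_forms_chains(self, particle_10nm, env_water):
        cfg = SimulationConfig(
            n_particles=50, box_d0_units=30.0, total_time_s=5e-7, seed=0
        )
        res = run_simulation(cfg, particle_10nm, env_water)
        assert res.final_state.mean_length == 1.0
        assert res.final_state.n_merges == 0

    def test_growth_then_plateau(self, particle_40nm, env_water):
        """Strong-coupling growth stabilizes: late increments are small."""
        pre = scale_particle_count(make_preset("paper_40nm_4mgml"), 200)
        cfg = SimulationConfig(
            n_particles=200,
            box_d0_units=pre.simulation.box_d0_units,
            total_time_s=1e-3,
            seed=3,
            snapshot_interval_s=1e-5,
        )
        res = run_simulation(cfg, particle_40nm, env_water)
        st = res.statistics
        late = st.mean_length[st.time_s >= 0.9 * st.time_s[-1]]
        assert np.all(np.diff(st.mean_length) >= 0)
        assert late[-1] - late[0] <= 0.05 * st.mean_length[-1]


class TestConcentrationToCount:
    def test_published_box_and_density(self, particle_40nm):
        cfg = SimulationConfig(box_d0_units=80.0)
        # 1 mg/mL = 1 kg/m^3 with bulk magnetite density
        assert concentration_to_count(1.0, cfg, particle_40nm) == 189

    def test_linear_in_concentration(self, particle_40nm):
        cfg = SimulationConfig(box_d0_units=80.0)
        n1 = concentration_to_count(1.0, cfg, particle_40nm)
        n2 = concentration_to_count(2.0, cfg, particle_40nm)
        assert abs(n2 - 2 * n1) <= 1

    def test_nonpositive_rejected(self, particle_40nm):
        with pytest.raises(ValueError):
            concentration_to_count(0.0, SimulationConfig(), particle_40nm)


class TestComputeStatistics:
    def _traj_of(self, state, p):
        return Trajectory(
            snapshots=(_take_snapshot(state),),
            box_m=state.box_m,
            diameter_m=p.diameter_m,
        )

    def test_two_chain_fixture(self, particle_40nm, line_state_factory):
        from mnph.synthetic_data import synthetic_chain_snapshot

        state = synthetic_chain_snapshot([3, 5], spacing_d0=10.0, particle=particle_40nm)
        st = compute_statistics(self._traj_of(state, particle_40nm))
        assert st.final_mean_length == pytest.approx(4.0)
        assert st.mean_spacing_m[-1] == pytest.approx(10.0 * particle_40nm.diameter_m)
        assert st.order_parameter[-1] == 1.0
        assert st.final_length_counts[2] == 1 and st.final_length_counts[4] == 1

    def test_all_singletons_have_undefined_spacing(self, particle_40nm, line_state_factory):
        state = line_state_factory([50.0, 100.0, 150.0], [1, 1, 1], particle_40nm)
        st = compute_statistics(self._traj_of(state, particle_40nm))
        assert st.final_mean_length == 1.0
        assert np.isnan(st.mean_spacing_m[-1])
        assert np.isnan(st.order_parameter[-1])

    def test_empty_trajectory_rejected(self, particle_40nm):
        with pytest.raises(ValueError):
            compute_statistics(
                Trajectory(snapshots=(), box_m=1.0, diameter_m=particle_40nm.diameter_m)
            )
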