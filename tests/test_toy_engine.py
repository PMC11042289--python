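"""Langevin toy engine: potentials, hill bookkeeping, escape dynamics."""

import math

import numpy as np
import pytest

from resikit import toy_engine as te


def far_pair(depth=5.0, width=1.0):
    """A well at the origin plus a second so remote it contributes nothing."""
    return te.ToyPotential(
        wells=(te.Well((0.0, 0.0), depth, width), te.Well((100.0, 100.0), 1.0, 1.0))
    )


class TestPotential:
    def test_energy_at_well_center_is_minus_depth(self):
        assert te.potential_energy(far_pair(depth=5.0), (0.0, 0.0)) == pytest.approx(-5.0)

    def test_energy_vanishes_far_from_all_wells(self):
        assert te.potential_energy(far_pair(), (50.0, -50.0)) == pytest.approx(0.0, abs=1e-12)

    def test_energy_matches_term_by_term_sum(self, rng):
        pot = te.ToyPotential(
            wells=(
                te.Well((0.3, -0.2), 4.0, 0.7),
                te.Well((1.5, 0.8), 2.5, 0.4),
                te.Well((-1.1, 0.5), 6.0, 1.2),
            )
        )
        for _ in range(20):
            x = rng.uniform(-3, 3, size=2)
            expected = sum(
                -w.depth * math.exp(-((x[0] - w.center[0]) ** 2 + (x[1] - w.center[1]) ** 2)
                                    / (2 * w.width**2))
                for w in pot.wells
            )
            assert te.potential_energy(pot, x) == pytest.approx(expected, rel=1e-12)

    def test_gradient_consistent_with_finite_differences(self, rng):
        pot = te.triple_well()
        h = 1e-6
        for _ in range(10):
            x = rng.uniform(-1, 2, size=2)
            g = te.potential_gradient(pot, x)
            for d in range(2):
                e = np.zeros(2)
                e[d] = h
                num = (te.potential_energy(pot, x + e) - te.potential_energy(pot, x - e)) / (2 * h)
                assert g[d] == pytest.approx(num, rel=1e-5, abs=1e-8)

    def test_confinement_adds_harmonic_term(self):
        pot = te.ToyPotential(
            wells=far_pair().wells, confinement_k=2.0, confinement_center=(1.0, 0.0)
        )
        base = te.potential_energy(far_pair(), (3.0, 4.0))
        assert te.potential_energy(pot, (3.0, 4.0)) == pytest.approx(
            base + 0.5 * 2.0 * (2.0**2 + 4.0**2)
        )

    def test_fewer_than_two_wells_rejected(self):
        with pytest.raises(ValueError):
            te.ToyPotential(wells=(te.Well((0, 0), 1.0, 1.0),))


class TestHills:
    def test_empty_hill_list_has_zero_bias(self):
        assert te.evaluate_bias(te.HillList.empty(2), (0.3, 0.4)) == 0.0

    def test_bias_at_hill_center_equals_height(self):
        sched = te.MetadSchedule(pace=10, height0=1.3, sigma=(0.5, 0.5))
        hills = te.deposit_hill(te.HillList.empty(2), (0.2, -0.1), 1.0, sched, kBT=1.0)
        assert te.evaluate_bias(hills, (0.2, -0.1)) == pytest.approx(1.3)

    def test_bias_matches_per_hill_brute_force(self, rng):
        sched = te.MetadSchedule(pace=1, height0=0.8, sigma=(0.4, 0.6),
                                 bias_factor=math.inf)
        hills = te.HillList.empty(2)
        for t in range(1, 51):
            hills = te.deposit_hill(hills, rng.uniform(-2, 2, 2), float(t), sched, 1.0)
        for _ in range(10):
            x = rng.uniform(-2, 2, 2)
            brute = sum(
                hills.heights[i]
                * math.exp(-0.5 * (((x[0] - hills.centers[i, 0]) / hills.sigmas[i, 0]) ** 2
                                   + ((x[1] - hills.centers[i, 1]) / hills.sigmas[i, 1]) ** 2))
                for i in range(len(hills))
            )
            assert te.evaluate_bias(hills, x) == pytest.approx(brute, rel=1e-12)

    def test_first_hill_deposits_full_height(self):
        sched = te.MetadSchedule(pace=10, height0=2.0, sigma=(0.3,), bias_factor=5.0)
        hills = te.deposit_hill(te.HillList.empty(1), (0.0,), 1.0, sched, kBT=1.0)
        assert hills.heights[0] == pytest.approx(2.0)

    def test_tempering_halves_height_at_ln2_bias(self):
        gamma, kBT = 5.0, 1.3
        sched = te.MetadSchedule(pace=10, height0=2.0, sigma=(0.3,), bias_factor=gamma)
        # pre-existing bias at the deposition point of exactly (gamma-1) kBT ln 2
        pre = te.HillList(
            times=np.array([1.0]),
            centers=np.array([[0.0]]),
            sigmas=np.array([[0.3]]),
            heights=np.array([(gamma - 1) * kBT * math.log(2.0)]),
        )
        hills = te.deposit_hill(pre, (0.0,), 2.0, sched, kBT=kBT)
        assert hills.heights[-1] == pytest.approx(1.0)

    def test_repeated_deposition_matches_recursion_and_decreases(self):
        gamma, kBT, h0 = 6.0, 1.0, 1.5
        sched = te.MetadSchedule(pace=10, height0=h0, sigma=(0.4,), bias_factor=gamma)
        hills = te.HillList.empty(1)
        v = 0.0
        expected = []
        for t in range(1, 8):
            h = h0 * math.exp(-v / ((gamma - 1) * kBT))
            expected.append(h)
            v += h  # all hills at the same point: bias there is the plain sum
            hills = te.deposit_hill(hills, (0.0,), float(t), sched, kBT)
        assert hills.heights == pytest.approx(expected, rel=1e-12)
        assert np.all(np.diff(hills.heights) < 0)

    def test_non_increasing_time_rejected(self):
        sched = te.MetadSchedule(pace=10, height0=1.0, sigma=(0.3,))
        hills = te.deposit_hill(te.HillList.empty(1), (0.0,), 2.0, sched, 1.0)
        with pytest.raises(ValueError, match="increase"):
            te.deposit_hill(hills, (0.0,), 2.0, sched, 1.0)

    def test_bias_nonnegative_and_monotone_in_hill_count(self, rng):
        sched = te.MetadSchedule(pace=1, height0=1.0, sigma=(0.5, 0.5))
        hills = te.HillList.empty(2)
        x = np.array([0.7, -0.3])
        prev = 0.0
        for t in range(1, 30):
            hills = te.deposit_hill(hills, rng.uniform(-1, 1, 2), float(t), sched, 1.0)
            v = te.evaluate_bias(hills, x)
            assert v >= prev >= 0.0
            prev = v


class TestSimulation:
    def test_no_bias_high_barrier_short_run_stays_bound(self):
        pot = te.triple_well(barrier=10.0)
        cfg = te.LangevinConfig(n_steps=5_000, seed=7)
        traj = te.simulate_escape(pot, cfg)
        assert not traj.escaped and traj.escape_step is None

    def test_recorded_bias_nonnegative_everywhere(self):
        pot = te.triple_well(barrier=5.0)
        sched = te.MetadSchedule(pace=200, height0=1.0, sigma=(0.3, 0.3), bias_factor=8.0)
        traj = te.simulate_escape(pot, te.LangevinConfig(n_steps=50_000, seed=3), sched=sched)
        assert np.all(traj.bias_values >= 0.0)

    def test_well_tempered_heights_capped_and_untempered_constant(self):
        pot = te.triple_well(barrier=5.0)
        cfg = te.LangevinConfig(n_steps=60_000, seed=5)
        wt = te.MetadSchedule(pace=300, height0=1.0, sigma=(0.3, 0.3), bias_factor=6.0)
        traj = te.simulate_escape(pot, cfg, sched=wt)
        assert len(traj.hills) > 3
        assert np.all(traj.hills.heights <= 1.0 + 1e-12)
        flat = te.MetadSchedule(pace=300, height0=1.0, sigma=(0.3, 0.3),
                                bias_factor=math.inf)
        traj2 = te.simulate_escape(pot, cfg, sched=flat)
        assert np.allclose(traj2.hills.heights, 1.0)

    def test_bias_deposition_accelerates_escape_in_distribution(self):
        pot = te.triple_well(barrier=6.0)
        sched = te.MetadSchedule(pace=200, height0=1.0, sigma=(0.3, 0.3), bias_factor=8.0)
        n_steps = 150_000
        unbiased_steps, biased_steps = [], []
        for seed in range(20):
            cfg = te.LangevinConfig(n_steps=n_steps, seed=seed)
            t_u = te.simulate_escape(pot, cfg, record_stride=1000)
            t_b = te.simulate_escape(pot, cfg, sched=sched, record_stride=1000)
            unbiased_steps.append(t_u.escape_step or n_steps)
            biased_steps.append(t_b.escape_step or n_steps)
        assert np.mean(biased_steps) < np.mean(unbiased_steps)

    def test_hot_system_escapes_on_diffusive_timescale(self):
        pot = te.triple_well(barrier=5.0)
        cfg = te.LangevinConfig(n_steps=500_000, seed=0, kBT=3.0)
        res = te.unbiased_mfpt(pot, cfg, n_runs=100, seed=2)
        assert np.isfinite(res.mean) and res.mean < 20.0

    def test_identical_seed_gives_bit_identical_trajectory(self):
        pot = te.triple_well(barrier=5.0)
        cfg = te.LangevinConfig(n_steps=30_000, seed=42)
        sched = te.MetadSchedule(pace=250, height0=0.8, sigma=(0.3, 0.3), bias_factor=7.0)
        a = te.simulate_escape(pot, cfg, sched=sched)
        b = te.simulate_escape(pot, cfg, sched=sched)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.bias_values, b.bias_values)
        assert np.array_equal(a.hills.heights, b.hills.heights)

    def test_oversized_timestep_raises_naming_dt(self):
        # the harmonic confinement makes the Euler update diverge at huge dt
        pot = te.three_state_potential()
        cfg = te.LangevinConfig(dt=1e4, n_steps=10_000, seed=0)
        never = te.HalfPlaneEscape((0.0, 1.0), math.inf)
        with pytest.raises(RuntimeError, match="dt"):
            te.simulate_escape(pot, cfg, escape_test=never)

    def test_custom_escape_predicate_truncates_at_first_hit(self):
        pot = te.triple_well(barrier=3.0)
        cfg = te.LangevinConfig(n_steps=100_000, seed=9)
        crossing = lambda x: x[0] ** 2 + x[1] ** 2 > 1.5**2  # noqa: E731
        traj = te.simulate_escape(pot, cfg, escape_test=crossing, record_stride=1)
        ref = te.simulate_escape(
            pot, cfg, escape_test=te.RadialEscape((0.0, 0.0), 1.5), record_stride=1
        )
        assert traj.escaped and ref.escaped
        assert traj.escape_step == ref.escape_step


class TestUnbiasedMFPT:
    def test_single_run_mean_equals_its_first_passage_time(self):
        pot = te.triple_well(barrier=3.0)
        cfg = te.LangevinConfig(n_steps=500_000, seed=0)
        res = te.unbiased_mfpt(pot, cfg, n_runs=1, seed=4)
        assert res.mean == res.times[0] and res.stderr == 0.0

    def test_independent_batches_agree_within_three_stderr(self):
        pot = te.triple_well(barrier=4.0)
        cfg = te.LangevinConfig(n_steps=1_000_000, seed=0)
        a = te.unbiased_mfpt(pot, cfg, n_runs=200, seed=1)
        b = te.unbiased_mfpt(pot, cfg, n_runs=200, seed=2)
        assert abs(a.mean - b.mean) <= 3.0 * math.hypot(a.stderr, b.stderr)

    def test_mfpt_increases_monotonically_with_barrier(self):
        cfg = te.LangevinConfig(n_steps=2_000_000, seed=0)
        means = [
            te.unbiased_mfpt(te.triple_well(barrier=bar), cfg, n_runs=200, seed=3).mean
            for bar in (4.0, 5.0, 6.0)
        ]
        assert means[0] < means[1] < means[2]

    def test_non_escaping_run_raises_with_advice(self):
        pot = te.triple_well(barrier=9.0)
        cfg = te.LangevinConfig(n_steps=2_000, seed=0)
        with pytest.raises(RuntimeError, match="n_steps"):
            te.unbiased_mfpt(pot, cfg, n_runs=3, seed=0)
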