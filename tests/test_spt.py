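import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from xcdyn.core_io import ValidationError
from xcdyn.simulate import SimCamera, SimGeometry, SimKinetics, simulate_trajectories
from xcdyn.spt import (
    angle_distribution,
    axial_escape_fraction,
    classify_msrd,
    compare_flux,
    compute_jumps,
    compute_msd,
    compute_vac,
    detect_entering,
    forward_backward_ratio,
    scale_concentration_by_fraction,
)
from tests.conftest import make_table


class TestComputeJumps:
    def test_displacements_at_each_dt(self):
        t = make_table({0: [(0, 0.0, 0.0), (1, 0.1, 0.0), (2, 0.3, 0.0)]})
        jumps = compute_jumps(t, max_dt=2)
        d1 = sorted(jumps.at_dt(1)["length"])
        assert d1 == pytest.approx([0.1, 0.2])
        assert list(jumps.at_dt(2)["length"]) == pytest.approx([0.3])

    def test_gap_breaks_jump_chain(self):
        t = make_table({0: [(0, 0.0, 0.0), (1, 0.1, 0.0), (3, 0.3, 0.0)]})
        jumps = compute_jumps(t, max_dt=2)
        assert len(jumps.at_dt(1)) == 1  # only frames 0→1
        assert len(jumps.at_dt(2)) == 0  # 1→3 crosses the missing frame

    def test_jump_cap_keeps_first_three(self):
        pts = [(f, 0.1 * f, 0.0) for f in range(10)]
        t = make_table({0: pts})
        jumps = compute_jumps(t, max_dt=1, max_jumps_per_traj=3)
        assert len(jumps.at_dt(1)) == 3
        assert list(jumps.at_dt(1)["frame0"]) == [0, 1, 2]

    def test_long_jumps_discarded(self):
        t = make_table({0: [(0, 0.0, 0.0), (1, 5.0, 0.0), (2, 5.1, 0.0)]})
        jumps = compute_jumps(t, max_jump_length=2.0)
        assert list(jumps.at_dt(1)["length"]) == pytest.approx([0.1])


class TestClassifyMsrd:
    def test_three_way_classification(self):
        t = make_table(
            {
                0: [(0, 1.0, 1.0), (1, 1.0, 1.0)],  # stationary → bound
                1: [(0, 1.0, 1.0), (1, 1.5, 1.0)],  # 0.5 μm jumps → free
                2: [(0, 1.0, 1.0), (1, 1.15, 1.0)],  # 0.15 μm → neither
            }
        )
        cls = classify_msrd(t)
        assert cls[0] == "bound"
        assert cls[1] == "free"
        assert cls[2] == "unclassified"


class TestMsdVac:
    def test_straight_line_msd(self):
        t = make_table({0: [(0, 0.0, 0.0), (1, 1.0, 0.0), (2, 2.0, 0.0)]})
        with pytest.warns(UserWarning, match="bootstrap"):
            curve = compute_msd(t, max_lag=2, n_boot=5, boot_size=10, seed=0)
        assert curve.msd[0] == pytest.approx(1.0)
        assert curve.msd[1] == pytest.approx(4.0)

    def test_free_brownian_msd_matches_linear_law(self):
        geom = SimGeometry(shape=(512, 512), nucleus_semiaxes=(25.0, 25.0), xc_radius=2.0)
        kin = SimKinetics(d_free=3.8, f_bound_nucleoplasm=0.0, f_bound_xc=0.0)
        cam = SimCamera(localization_error=0.028, bleach_probability=0.05,
                        n_frames=400)
        table, _ = simulate_trajectories(geom, kin, cam, seed=5, n_molecules=6000)
        curve = compute_msd(table, max_lag=4, n_boot=30, boot_size=3000, seed=1)
        for k, (msd, sd) in enumerate(zip(curve.msd, curve.boot_sd), start=1):
            expected = 4 * 3.8 * k * cam.frame_interval + 4 * 0.028**2
            assert abs(msd - expected) < 3 * sd

    def test_ballistic_vac_is_one(self):
        t = make_table({0: [(f, 0.5 * f, 0.0) for f in range(8)]})
        vac = compute_vac(t, max_lag=3)
        np.testing.assert_allclose(vac, 1.0)

    def test_noise_free_brownian_vac_near_zero(self):
        geom = SimGeometry(shape=(512, 512), nucleus_semiaxes=(25.0, 25.0), xc_radius=2.0)
        kin = SimKinetics(d_free=3.8, f_bound_nucleoplasm=0.0, f_bound_xc=0.0)
        cam = SimCamera(localization_error=0.0, bleach_probability=0.05, n_frames=400)
        table, _ = simulate_trajectories(geom, kin, cam, seed=6, n_molecules=4000)
        vac = compute_vac(table, max_lag=2)
        assert abs(vac[1]) < 0.02
        assert abs(vac[2]) < 0.02

    def test_localization_noise_induces_negative_vac1(self):
        geom = SimGeometry(shape=(512, 512), nucleus_semiaxes=(25.0, 25.0), xc_radius=2.0)
        kin = SimKinetics(d_free=1.0, f_bound_nucleoplasm=0.0, f_bound_xc=0.0)
        cam = SimCamera(localization_error=0.05, bleach_probability=0.05, n_frames=400)
        table, _ = simulate_trajectories(geom, kin, cam, seed=7, n_molecules=4000)
        vac = compute_vac(table, max_lag=1)
        # expected VAC(1) = -2σ² / <|v|²>, <|v|²> = 4(DΔt+σ²) + ... ≈ negative
        assert vac[1] < -0.05


class TestAngles:
    def test_forward_jump_zero_degrees(self):
        t = make_table({0: [(0, 0.0, 0.0), (1, 1.0, 0.0), (2, 2.0, 0.0)]})
        dist = angle_distribution(t, min_jump=0.0, max_jump=5.0)
        assert dist.angles == pytest.approx([0.0])

    def test_backtrack_180_degrees(self):
        t = make_table({0: [(0, 0.0, 0.0), (1, 1.0, 0.0), (2, 0.0, 0.0)]})
        dist = angle_distribution(t, min_jump=0.0, max_jump=5.0)
        assert dist.angles == pytest.approx([180.0])

    def test_length_window_filters_pairs(self):
        t = make_table({0: [(0, 0.0, 0.0), (1, 0.05, 0.0), (2, 1.0, 0.0)]})
        dist = angle_distribution(t, min_jump=0.2, max_jump=3.0)
        assert dist.n == 0

    def test_isotropic_walk_has_uniform_histogram(self, random_walk_table):
        dist = angle_distribution(
            random_walk_table, min_jump=0.0, max_jump=10.0, max_jumps_per_traj=None
        )
        assert dist.n > 4000
        expected = dist.n / len(dist.counts)
        # multinomial fluctuation: 5 sd of sqrt(n·p·(1-p))
        tol = 5 * np.sqrt(expected * (1 - 1 / len(dist.counts)))
        assert np.all(np.abs(dist.counts - expected) < tol)

    def test_histogram_covers_0_to_180(self, random_walk_table):
        dist = angle_distribution(random_walk_table, min_jump=0.0, max_jump=10.0)
        assert dist.bin_edges[0] == 0.0
        assert dist.bin_edges[-1] == 180.0
        assert dist.counts.sum() == dist.n


class TestForwardBackwardRatio:
    def test_isotropic_ratio_near_one(self, random_walk_table):
        dist = angle_distribution(
            random_walk_table, min_jump=0.0, max_jump=10.0, max_jumps_per_traj=None
        )
        res = forward_backward_ratio(dist, n_boot=50, seed=0)
        assert res.defined
        assert abs(res.ratio - 1.0) < 3 * res.boot_sd

    def test_zero_backward_flagged_undefined(self):
        t = make_table({0: [(0, 0.0, 0.0), (1, 1.0, 0.0), (2, 2.0, 0.0)]})
        dist = angle_distribution(t, min_jump=0.0, max_jump=5.0)
        res = forward_backward_ratio(dist)
        assert not res.defined
        assert np.isnan(res.ratio)

    def test_bootstrap_reproducible(self, random_walk_table):
        dist = angle_distribution(random_walk_table, min_jump=0.0, max_jump=10.0)
        a = forward_backward_ratio(dist, seed=3)
        b = forward_backward_ratio(dist, seed=3)
        assert a.boot_sd == b.boot_sd


class TestDetectEntering:
    def _region(self):
        yy, xx = np.mgrid[:64, :64]
        return (yy - 32) ** 2 + (xx - 32) ** 2 <= 8**2

    def test_fully_inside_no_events(self):
        px = 0.106
        t = make_table({0: [(f, 32 * px, 32 * px) for f in range(4)]})
        ev = detect_entering(t, self._region(), free_only=False)
        assert len(ev) == 0

    def test_single_transition_detected(self):
        px = 0.106
        out, inside = (5 * px, 5 * px), (32 * px, 32 * px)
        t = make_table({0: [(0, *out), (1, *out), (2, *inside), (3, *inside)]})
        ev = detect_entering(t, self._region(), free_only=False)
        assert len(ev) == 1
        assert ev.iloc[0]["frame"] == 1  # the 2nd→3rd localization transition

    def test_trajectory_counted_once(self):
        px = 0.106
        out, inside = (5 * px, 5 * px), (32 * px, 32 * px)
        t = make_table({0: [(0, *out), (1, *inside), (2, *out), (3, *inside)]})
        ev = detect_entering(t, self._region(), free_only=False)
        assert len(ev) == 1

    def test_free_filter_drops_slow_trajectories(self):
        px = 0.106
        # boundary of the disc is 8 px from center: hop one pixel across it
        out, inside = (23.5 * px, 32.5 * px), (24.5 * px, 32.5 * px)
        # one-pixel hop: MSRD ~ 0.1 μm → not free
        t = make_table({0: [(0, *out), (1, *inside)]})
        assert len(detect_entering(t, self._region(), free_only=True)) == 0
        assert len(detect_entering(t, self._region(), free_only=False)) == 1

    def test_angle_to_following_jump_reported(self):
        px = 0.106
        t = make_table(
            {0: [(0, 5 * px, 32 * px), (1, 32 * px, 32 * px), (2, 5 * px, 32 * px)]}
        )
        ev = detect_entering(t, self._region(), free_only=False)
        assert ev.iloc[0]["angle_to_next"] == pytest.approx(180.0)


class TestCompareFlux:
    def test_identical_samples_no_difference(self):
        counts = np.array([5.0, 7, 9, 11, 13])
        res = compare_flux(counts, [counts.copy() for _ in range(5)][:1] * 5)
        assert res.statistic == 0.0
        assert res.pvalue == 1.0

    def test_per_cell_pairs_reported(self):
        res = compare_flux(
            np.array([5, 10]), [np.array([4, 6]), np.array([9, 11])]
        )
        assert list(res.per_cell["mean_control_count"]) == [5.0, 10.0]

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValidationError):
            compare_flux(np.array([5.0]), [np.array([4.0])])


class TestAxialEscape:
    def test_no_diffusion_no_escape(self):
        assert axial_escape_fraction(0.0, 0.005477) == 1.0

    def test_fast_diffusion_escapes_completely(self):
        assert axial_escape_fraction(1000.0, 1.0, dz=0.7) < 1e-6

    def test_monotone_in_diffusion_time(self):
        vals = [axial_escape_fraction(d, 0.005477, 0.7) for d in (0.1, 1, 3.8, 10, 20)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_invalid_dz_rejected(self):
        with pytest.raises(ValidationError):
            axial_escape_fraction(1.0, 0.01, dz=0.0)

    @given(st.floats(0.01, 50.0), st.floats(1e-4, 0.1))
    @settings(max_examples=25, deadline=None)
    def test_always_a_probability(self, D, dt):
        z = axial_escape_fraction(D, dt, 0.7)
        assert 0.0 <= z <= 1.0


class TestDeltaMethod:
    def test_worked_example(self):
        out = scale_concentration_by_fraction(300.0, 10.0, 0.4, 0.02)
        assert out.value == pytest.approx(120.0)
        assert out.sd == pytest.approx(np.sqrt(0.16 * 100 + 90000 * 0.0004))
        assert out.ci95 == pytest.approx(1.96 * out.sd)

    def test_exact_fraction_keeps_concentration_sd(self):
        out = scale_concentration_by_fraction(300.0, 10.0, 1.0, 0.0)
        assert out.value == 300.0
        assert out.sd == pytest.approx(10.0)

    def test_zero_fraction_gives_zero(self):
        out = scale_concentration_by_fraction(300.0, 10.0, 0.0, 0.0)
        assert out.value == 0.0
        assert out.sd == 0.0

    def test_negative_sd_rejected(self):
        with pytest.raises(ValidationError):
            scale_concentration_by_fraction(300.0, -1.0, 0.4, 0.02)
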