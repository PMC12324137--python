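import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from jointcoord import (
    CRPCurve,
    MovementRepetition,
    crp,
    crp_curve,
    estimate_velocity,
    jsvcrp,
    jsvcrp_all_pairs,
    mean_crp,
    noise_ratio_guard,
    phase_angle,
    phase_portrait,
    range_normalize,
    time_normalize,
)
from jointcoord.jsvcrp import dtw_align
from .conftest import make_dataset


def sine_rep(shifts=(0.0, 0.5), duration=2 * np.pi, fs=200.0, amp=None):
    if amp is None:
        amp = (1.0,) * len(shifts)
    t = np.arange(0.0, duration, 1.0 / fs)
    ang = np.column_stack([a * np.sin(t + s) for a, s in zip(amp, shifts)])
    return MovementRepetition(t, ang, [f"j{i}" for i in range(len(shifts))])


class TestRangeNormalize:
    def test_linear_ramp(self):
        np.testing.assert_allclose(
            range_normalize(np.linspace(0, 10, 11)), np.linspace(-1, 1, 11),
            atol=1e-12,
        )

    def test_already_normalized_unchanged(self):
        x = np.array([-1.0, 0.3, 1.0, -0.2])
        np.testing.assert_allclose(range_normalize(x), x, atol=1e-12)

    def test_endpoints_exact(self, rng):
        y = range_normalize(rng.normal(size=50))
        assert y.min() == -1.0 and y.max() == 1.0

    def test_constant_input_errors(self):
        with pytest.raises(ValueError, match="constant"):
            range_normalize(np.full(10, 3.0))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        hnp.arrays(
            np.float64,
            st.integers(3, 40),
            elements=st.floats(-100, 100, allow_nan=False),
        ).filter(lambda x: x.max() - x.min() > 1e-6)
    )
    def test_sign_reversal_symmetry(self, x):
        np.testing.assert_allclose(
            range_normalize(x), -range_normalize(-x), atol=1e-9
        )


class TestVelocity:
    def test_linear_position_constant_velocity(self):
        t = np.linspace(0, 1, 50)
        rep = MovementRepetition(t, (3.5 * t)[:, None], ["a"])
        np.testing.assert_allclose(estimate_velocity(rep, "a"), 3.5, atol=1e-9)

    def test_sine_at_1khz_matches_cosine(self):
        t = np.arange(0, 2 * np.pi, 0.001)
        rep = MovementRepetition(t, np.sin(t)[:, None], ["a"])
        v = estimate_velocity(rep, "a")
        assert np.max(np.abs(v - np.cos(t))) < 1e-4

    def test_too_short_errors(self):
        rep = MovementRepetition(np.array([0.0, 0.1]), np.zeros((2, 1)), ["a"])
        with pytest.raises(ValueError, match="3 samples"):
            estimate_velocity(rep, "a")

    def test_duplicated_timestamps_rejected_at_construction(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            MovementRepetition(np.array([0.0, 0.1, 0.1, 0.2]), np.zeros((4, 1)), ["a"])


class TestNoiseGuard:
    def test_large_rom_kept(self):
        x = np.linspace(0, 40, 100)  # 40 deg range of motion
        assert noise_ratio_guard(x, 0.5) == "keep"

    def test_noise_dominated_joint_zeroed(self):
        x = np.linspace(0, 0.2, 100)  # 0.2 deg ROM, 1 deg noise
        assert noise_ratio_guard(x, 1.0) == "zero_substitute"

    def test_zeroed_joint_pairs_as_negated_other_phase(self):
        """A zero-substituted joint has phase identically 0, so the
        pair's CRP is just (+/-) the other joint's phase."""
        rep = sine_rep(shifts=(0.0, 0.0), amp=(1.0, 1e-6))
        pp1 = phase_portrait(rep, "j0", noise_range=0.5)
        pp2 = phase_portrait(rep, "j1", noise_range=0.5)
        assert pp1.contributing and not pp2.contributing
        np.testing.assert_array_equal(pp2.phase, 0.0)
        np.testing.assert_allclose(
            crp(pp1.phase, pp2.phase), -pp1.phase, atol=1e-12
        )


class TestPhaseAngle:
    def test_cardinal_points(self):
        assert phase_angle(np.array([1.0]), np.array([0.0]))[0] == 0.0
        assert phase_angle(np.array([0.0]), np.array([1.0]))[0] == pytest.approx(
            np.pi / 2
        )
        assert phase_angle(np.array([0.0]), np.array([0.0]))[0] == 0.0

    def test_range_half_open(self):
        phi = phase_angle(np.array([-1.0, -1.0]), np.array([0.0, -0.0]))
        assert np.all((phi > -np.pi) & (phi <= np.pi))

    def test_cosine_full_period_gives_minus_t(self):
        """theta = cos t spans [-1, 1] over a whole period and its
        normalized velocity is -sin t, so phi(t) = atan2(-sin, cos)
        = -t wrapped into (-pi, pi]."""
        t = np.arange(0, 2 * np.pi, 0.001)
        phi = phase_angle(np.cos(t), -np.sin(t))
        expected = np.mod(-t + np.pi, 2 * np.pi) - np.pi
        expected = np.where(expected == -np.pi, np.pi, expected)
        np.testing.assert_allclose(phi, expected, atol=1e-12)

    def test_sinusoid_phase_advances_monotonically(self):
        """The phase-portrait angle of a pure sinusoid moves steadily
        around the circle: successive wrapped increments all have the
        same sign and magnitude equal to the time step."""
        rep = sine_rep()
        pp = phase_portrait(rep, "j0")
        inc = np.diff(pp.phase)
        inc = np.mod(inc + np.pi, 2 * np.pi) - np.pi
        np.testing.assert_allclose(inc, -1.0 / 200.0, atol=1e-6)


class TestCRP:
    def test_identical_joints_zero(self):
        rep = sine_rep(shifts=(0.3, 0.3))
        c = crp_curve(rep, ("j0", "j1"))
        np.testing.assert_allclose(c.values, 0.0, atol=1e-12)

    def test_constant_lag_gives_constant_crp(self):
        """Second joint lagging by delta = 0.5 rad over whole periods:
        phases of pure sinusoids after range normalization differ by a
        constant, so the CRP is +delta throughout."""
        delta = 0.5
        rep = sine_rep(shifts=(0.0, -delta))
        c = crp_curve(rep, ("j0", "j1"))
        np.testing.assert_allclose(c.values, delta, atol=1e-4)

    def test_antisymmetry(self, rng):
        phi_i = rng.uniform(-np.pi, np.pi, 100)
        phi_j = rng.uniform(-np.pi, np.pi, 100)
        np.testing.assert_allclose(
            crp(phi_i, phi_j), -crp(phi_j, phi_i), atol=1e-12
        )

    def test_unwrap_mode_no_jumps(self):
        rep = sine_rep(shifts=(0.0, -2.5), duration=4 * np.pi)
        pp0 = phase_portrait(rep, "j0")
        pp1 = phase_portrait(rep, "j1")
        un = crp(pp0.phase, pp1.phase, unwrap=True)
        np.testing.assert_allclose(un, un[0], atol=1e-4)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            crp(np.zeros(5), np.zeros(4))


class TestTimeNormalize:
    def test_already_on_grid_unchanged(self):
        grid = np.linspace(0, 1.0, 101)
        c = CRPCurve(grid, np.sin(grid * 3), ("a", "b"))
        out = time_normalize(c, 101)
        np.testing.assert_allclose(out.values, c.values, atol=1e-12)
        assert out.grid[0] == 0.0 and out.grid[-1] == 100.0

    def test_constant_curve_any_duration(self):
        c = CRPCurve(np.linspace(0, 3.7, 55), np.full(55, 0.8), ("a", "b"))
        out = time_normalize(c, 101)
        np.testing.assert_allclose(out.values, 0.8, atol=1e-12)

    def test_linear_curve_duration_invariant(self):
        for dur, n in ((1.0, 40), (5.0, 333)):
            c = CRPCurve(np.linspace(0, dur, n), np.linspace(-1, 2, n), ("a", "b"))
            out = time_normalize(c, 101)
            np.testing.assert_allclose(out.values, np.linspace(-1, 2, 101), atol=1e-12)

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            time_normalize(CRPCurve(np.array([0.0]), np.array([1.0]), ("a", "b")))


class TestDTW:
    def test_identical_curves_fixed_point(self):
        x = np.sin(np.linspace(0, 3, 60))
        np.testing.assert_allclose(dtw_align(x, x), x, atol=1e-12)

    def test_warped_copy_recovered(self):
        """A monotone time distortion of a curve is undone (approximately)
        by aligning it back to the original."""
        s = np.linspace(0, 1, 80)
        ref = np.sin(2 * np.pi * s)
        warped = np.sin(2 * np.pi * s**1.6)
        aligned = dtw_align(warped, ref)
        assert np.abs(aligned - ref).mean() < np.abs(warped - ref).mean() / 3


class TestMeanCRP:
    def test_single_repetition_mean_is_curve_sd_zero(self):
        ds = make_dataset([sine_rep(shifts=(0.0, -0.4)).angles], ["j0", "j1"],
                          dt=1 / 200)
        m = mean_crp(ds, ("j0", "j1"))
        single = time_normalize(crp_curve(ds.repetitions[0], ("j0", "j1")))
        np.testing.assert_allclose(m.values, single.values, atol=1e-12)
        np.testing.assert_allclose(m.sd, 0.0, atol=1e-12)

    def test_mirror_repetitions_average_to_zero(self):
        """Swapping the joint columns negates a repetition's CRP, so a
        dataset holding a repetition and its mirror has mean CRP 0."""
        rep = sine_rep(shifts=(0.0, -0.4))
        ds = make_dataset([rep.angles, rep.angles[:, ::-1]], ["j0", "j1"],
                          dt=1 / 200)
        m = mean_crp(ds, ("j0", "j1"))
        np.testing.assert_allclose(m.values, 0.0, atol=1e-9)

    def test_identical_shapes_different_durations(self):
        fast = sine_rep(duration=2 * np.pi, fs=200)
        slow_t = np.arange(0.0, 2 * np.pi, 1 / 200.0) * 3.0
        slow = MovementRepetition(slow_t, fast.angles.copy(), ["j0", "j1"])
        ds = make_dataset([fast.angles], ["j0", "j1"], dt=1 / 200)
        ds.repetitions.append(slow)
        m = mean_crp(ds, ("j0", "j1"))
        np.testing.assert_allclose(m.sd, 0.0, atol=1e-9)

    def test_per_target_restriction(self):
        rep = sine_rep()
        ds = make_dataset([rep.angles, rep.angles], ["j0", "j1"], dt=1 / 200)
        ds.repetitions[0].meta["target"] = "hi"
        ds.repetitions[1].meta["target"] = "lo"
        m = mean_crp(ds, ("j0", "j1"), targets="hi")
        assert m.sd.max() == 0.0
        with pytest.raises(ValueError, match="no repetitions"):
            mean_crp(ds, ("j0", "j1"), targets="nope")


class TestJsvCRP:
    def test_self_comparison_zero(self):
        ds = make_dataset([sine_rep(shifts=(0.0, -0.7)).angles], ["j0", "j1"],
                          dt=1 / 200)
        assert jsvcrp(ds, ds) == 0.0

    def test_symmetry_and_nonnegativity(self, rng):
        a = make_dataset([sine_rep(shifts=(0.0, -0.5)).angles], ["j0", "j1"],
                         dt=1 / 200, name="a")
        b = make_dataset([sine_rep(shifts=(0.0, -1.2)).angles], ["j0", "j1"],
                         dt=1 / 200, name="b")
        ab = jsvcrp(a, b)
        ba = jsvcrp(b, a)
        assert ab >= 0
        assert ab == pytest.approx(ba, abs=1e-12)

    def test_constant_curves_rectangle_area(self):
        """Two constant-lag datasets: mean CRP curves are constants c1,
        c2, and the area over an axis of length L is |c1 - c2| * L."""
        a = make_dataset([sine_rep(shifts=(0.0, -0.5)).angles], ["j0", "j1"],
                         dt=1 / 200, name="a", unit="rad")
        b = make_dataset([sine_rep(shifts=(0.0, -1.2)).angles], ["j0", "j1"],
                         dt=1 / 200, name="b", unit="rad")
        area = jsvcrp(a, b, pair=("j0", "j1"))
        assert area == pytest.approx(0.7 * 100.0, rel=1e-4)
        dur = a.repetitions[0].time[-1]
        area_s = jsvcrp(a, b, pair=("j0", "j1"), normalize_time=False)
        assert area_s == pytest.approx(0.7 * dur, rel=1e-3)

    def test_degree_output_scaling(self):
        a = make_dataset([sine_rep(shifts=(0.0, -0.5)).angles], ["j0", "j1"],
                         dt=1 / 200, name="a", unit="deg")
        b = make_dataset([sine_rep(shifts=(0.0, -1.2)).angles], ["j0", "j1"],
                         dt=1 / 200, name="b", unit="deg")
        rad = jsvcrp(a, b, degrees=False)
        deg = jsvcrp(a, b)  # unit defaults from the dataset
        assert deg == pytest.approx(rad * 180 / np.pi, rel=1e-12)

    def test_grid_refinement_convergence(self):
        a = make_dataset([sine_rep(shifts=(0.0, -0.5)).angles], ["j0", "j1"],
                         dt=1 / 200, name="a")
        b = make_dataset([sine_rep(shifts=(0.3, -1.0)).angles], ["j0", "j1"],
                         dt=1 / 200, name="b")
        a1 = jsvcrp(a, b, G=101)
        a2 = jsvcrp(a, b, G=1001)
        assert abs(a1 - a2) / a2 < 0.01

    def test_area_against_riemann_oracle(self, rng):
        """Trapezoidal areas vs a high-resolution Riemann sum on random
        piecewise-linear curve pairs."""
        for _ in range(5):
            nodes = np.linspace(0, 100, 12)
            va = rng.uniform(-2, 2, nodes.size)
            vb = rng.uniform(-2, 2, nodes.size)
            G = 2001
            grid = np.linspace(0, 100, G)
            ia, ib = np.interp(grid, nodes, va), np.interp(grid, nodes, vb)
            got = np.trapezoid(np.abs(ib - ia), grid)
            fine = np.linspace(0, 100, 400_001)
            riemann = np.abs(
                np.interp(fine, nodes, vb) - np.interp(fine, nodes, va)
            ).sum() * (100 / (fine.size - 1))
            assert got == pytest.approx(riemann, rel=2e-3)

    def test_all_pairs_shape(self):
        rep = sine_rep(shifts=(0.0, -0.4, 0.9))
        a = make_dataset([rep.angles], ["j0", "j1", "j2"], dt=1 / 200, name="a")
        b = make_dataset([rep.angles[::1] * 1.0], ["j0", "j1", "j2"],
                         dt=1 / 200, name="b")
        res = jsvcrp_all_pairs(a, b)
        assert set(res.areas) == {("j0", "j1"), ("j0", "j2"), ("j1", "j2")}
        assert all(v >= 0 for v in res.areas.values())
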