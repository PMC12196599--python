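import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fallfsm import features
from fallfsm.features import (
    ImuTrace,
    InvalidSampleError,
    UndefinedOrientationError,
    WindowError,
    asvm,
    gsvm,
    inclination_angles,
    mean_psi,
    window_mean,
    window_std,
)

finite_mg = st.floats(min_value=-8000, max_value=8000, allow_nan=False)
nonzero_vec = st.tuples(finite_mg, finite_mg, finite_mg).filter(
    lambda v: math.sqrt(v[0] ** 2 + v[1] ** 2 + v[2] ** 2) > 1e-6
)


class TestSignalVectorMagnitude:
    @pytest.mark.parametrize("vec,expected", [
        ((0, 0, 1000), 1000.0),   # gravity only
        ((300, 400, 0), 500.0),   # 3-4-5 triple
        ((0, 0, 0), 0.0),
    ])
    def test_asvm_examples(self, vec, expected):
        assert asvm(*vec) == expected

    @pytest.mark.parametrize("vec,expected", [
        ((0, 0, 0), 0.0),
        ((10, 0, 0), 10.0),
        ((3, 4, 12), 13.0),       # Pythagorean quadruple
    ])
    def test_gsvm_examples(self, vec, expected):
        assert gsvm(*vec) == expected

    @pytest.mark.parametrize("bad", [math.nan, math.inf, -math.inf])
    def test_nonfinite_rejected(self, bad):
        with pytest.raises(InvalidSampleError):
            asvm(bad, 0, 0)
        with pytest.raises(InvalidSampleError):
            gsvm(0, bad, 0)

    @settings(deadline=None)
    @given(v=nonzero_vec, k_exp=st.integers(min_value=-8, max_value=8))
    def test_homogeneity_exact_for_power_of_two_scale(self, v, k_exp):
        # scaling by 2**k is exact in binary floating point
        k = 2.0 ** k_exp
        assert asvm(k * v[0], k * v[1], k * v[2]) == k * asvm(*v)

    @settings(deadline=None)
    @given(v=nonzero_vec,
           k=st.floats(min_value=-100, max_value=100).filter(
               lambda k: abs(k) > 1e-3))
    def test_homogeneity_general_scale(self, v, k):
        assert asvm(k * v[0], k * v[1], k * v[2]) == pytest.approx(
            abs(k) * asvm(*v), rel=1e-12)

    @settings(deadline=None)
    @given(v=st.tuples(finite_mg, finite_mg, finite_mg),
           perm=st.permutations([0, 1, 2]),
           signs=st.tuples(*[st.sampled_from([-1.0, 1.0])] * 3))
    def test_sign_and_permutation_invariance(self, v, perm, signs):
        w = [signs[i] * v[perm[i]] for i in range(3)]
        assert asvm(*w) == pytest.approx(asvm(*v), rel=1e-12, abs=1e-12)


class TestInclinationAngles:
    @pytest.mark.parametrize("vec,expected", [
        ((0, 1000, 0), (0, 90, 0)),    # upright standing, y-axis vertical
        ((1000, 0, 0), (90, 0, 0)),    # x-axis vertical
    ])
    def test_cardinal_orientations(self, vec, expected):
        ang = inclination_angles(*vec)
        assert ang == pytest.approx(expected, abs=1e-12)

    def test_equal_components(self):
        # atan(1/sqrt(2)) for each axis, from direct evaluation
        expected = math.degrees(math.atan(1 / math.sqrt(2)))
        ang = inclination_angles(577.35, 577.35, 577.35)
        assert ang == pytest.approx((expected,) * 3, rel=1e-12)
        assert expected == pytest.approx(35.264, abs=5e-4)

    def test_zero_vector_rejected(self):
        with pytest.raises(UndefinedOrientationError):
            inclination_angles(0, 0, 0)

    @settings(deadline=None)
    @given(v=nonzero_vec)
    def test_sin_squares_sum_to_one(self, v):
        th, ps, ph = inclination_angles(*v)
        s = sum(math.sin(math.radians(a)) ** 2 for a in (th, ps, ph))
        assert s == pytest.approx(1.0, rel=1e-9)
        assert all(-90 <= a <= 90 for a in (th, ps, ph))


class TestWindowedStats:
    def test_constant_window_has_zero_std(self):
        assert window_std([980.0] * 50, (1, 50)) == 0.0

    def test_alternating_window(self):
        series = [0.0, 2.0] * 25
        assert window_std(series, (1, 50)) == 1.0
        assert window_mean(series, (1, 50)) == 1.0

    def test_matches_direct_population_computation(self):
        rng = np.random.default_rng(7)
        series = rng.normal(1000, 50, 80)
        got = window_std(series, (11, 60))
        sl = series[10:60]
        mu = sum(sl) / len(sl)
        expected = math.sqrt(sum((x - mu) ** 2 for x in sl) / len(sl))
        assert got == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("window", [(0, 10), (5, 4), (1, 100)])
    def test_bad_windows_rejected(self, window):
        with pytest.raises(WindowError):
            window_std(np.ones(50), window)

    @settings(deadline=None)
    @given(vals=st.lists(
        st.integers(-10**6, 10**6).map(lambda k: k / 4.0),
        min_size=2, max_size=60))
    def test_zero_iff_constant(self, vals):
        # grid-valued floats: the iff direction is a real-arithmetic fact
        # and must not be confounded by squared-deviation underflow
        s = window_std(vals, (1, len(vals)))
        if len(set(vals)) == 1:
            assert s == 0.0
        else:
            assert s > 0.0

    @pytest.mark.parametrize("series,expected", [
        ([90.0] * 20, 90.0),
        ([-30.0] * 20, -30.0),
        ([0.0] * 10 + [50.0] * 10, 25.0),
    ])
    def test_mean_psi_examples(self, series, expected):
        assert mean_psi(series, (1, 20)) == expected

    @settings(deadline=None)
    @given(vals=st.lists(st.floats(-90, 90), min_size=1, max_size=40))
    def test_mean_psi_bounded_by_extremes(self, vals):
        m = mean_psi(vals, (1, len(vals)))
        assert min(vals) - 1e-9 <= m <= max(vals) + 1e-9


class TestImuTrace:
    def test_nonmonotone_time_rejected(self):
        t = np.array([0.0, 0.01, 0.01])
        with pytest.raises(ValueError, match="increasing"):
            ImuTrace(t=t, acc=np.ones((3, 3)), gyro=np.zeros((3, 3)))

    def test_spacing_inconsistent_with_fs_rejected(self):
        t = np.array([0.0, 0.5, 1.0])  # 2 Hz data declared as 100 Hz
        with pytest.raises(ValueError, match="spacing"):
            ImuTrace(t=t, acc=np.ones((3, 3)), gyro=np.zeros((3, 3)), fs=100)

    def test_out_of_range_flagged_not_clipped(self):
        acc = np.array([[0, 1000, 0], [0, 9000, 0]], dtype=float)
        tr = ImuTrace.from_arrays(acc, np.zeros((2, 3)))
        assert list(tr.out_of_range_mask()) == [False, True]
        assert tr.acc[1, 1] == 9000.0  # value preserved

    def test_derived_channels_match_scalar_functions(self):
        rng = np.random.default_rng(3)
        acc = rng.normal(0, 500, (20, 3))
        gyro = rng.normal(0, 50, (20, 3))
        tr = ImuTrace.from_arrays(acc, gyro)
        for i in range(20):
            assert tr.asvm()[i] == pytest.approx(asvm(*acc[i]), rel=1e-14)
            assert tr.gsvm()[i] == pytest.approx(gsvm(*gyro[i]), rel=1e-14)
            assert tr.psi()[i] == pytest.approx(
                inclination_angles(*acc[i]).psi, rel=1e-12)


def test_one_based_slice_convention():
    # the single conversion point: window samples 151-200 -> indices 150..199
    assert features.one_based_slice((151, 200)) == slice(150, 200)
    assert features.one_based_slice((181, 200)) == slice(180, 200)
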