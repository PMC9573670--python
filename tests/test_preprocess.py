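"""Averaging, background subtraction and the filter bank."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gelshot import (
    CTVolume,
    FilterSpec,
    GeometryError,
    SeriesSet,
    UsageError,
    apply_filter,
    average_series,
    simulate_phantom,
    subtract_background,
    voi_stats,
)
from gelshot.preprocess import FFT_WINDOWS
from gelshot.qa import VOICylinder

from conftest import small_star_spec


def _vol(arr, **kw):
    kw.setdefault("spacing", (1, 1, 1))
    kw.setdefault("origin", (0, 0, 0))
    return CTVolume(voxels=np.asarray(arr, float), **kw)


def _series(arrays):
    return SeriesSet(volumes=[_vol(a) for a in arrays], label="background")


# -- averaging and subtraction ---------------------------------------------

def test_average_identical_and_arithmetic():
    base = np.arange(60.0).reshape(3, 4, 5)
    s = _series([base, base, base])
    np.testing.assert_array_equal(average_series(s).voxels, base)
    s2 = _series([np.zeros((2, 3, 3)), np.full((2, 3, 3), 10.0)])
    np.testing.assert_array_equal(average_series(s2).voxels, 5.0)


def test_average_empty_subset_is_usage_error():
    s = _series([np.zeros((2, 2, 2))])
    with pytest.raises(UsageError):
        average_series(s, subset=[])


def test_average_five_series_reduces_voi_std_by_sqrt5():
    spec = small_star_spec(
        beams=[], n_background_series=5, hardening_amp_hu=0.0, seed=21
    )
    bg, _, _ = simulate_phantom(spec)
    voi = VOICylinder(center=(0, 0, 0), diameter_mm=24, length_mm=24)
    _, std1, n = voi_stats(bg[0], voi)
    _, std5, _ = voi_stats(average_series(bg), voi)
    assert n >= 1000
    assert std5 / std1 == pytest.approx(1 / np.sqrt(5), rel=0.10)


def test_subtract_self_is_zero_and_mismatch_is_error():
    v = _vol(np.random.default_rng(0).normal(size=(3, 4, 4)))
    np.testing.assert_array_equal(subtract_background(v, v).voxels, 0.0)
    shifted = CTVolume(voxels=v.voxels, spacing=(1, 1, 1), origin=(1, 0, 0))
    with pytest.raises(GeometryError):
        subtract_background(v, shifted)


def test_noisy_subtraction_residual_mean_is_zero_within_error():
    spec = small_star_spec(seed=3)
    bg, irr, _ = simulate_phantom(spec)
    residual = subtract_background(irr[0], bg[0])
    # VOI in gel, clear of all four track ribbons
    voi = VOICylinder(center=(-20, -10, 0), diameter_mm=12, length_mm=16)
    mean, std, n = voi_stats(residual, voi)
    assert abs(mean) <= 3 * std / np.sqrt(n)


# -- filter bank ------------------------------------------------------------

def test_mean_filter_leaves_constant_unchanged():
    v = _vol(np.full((4, 8, 8), 37.0))
    out = apply_filter(v, FilterSpec("mean", kernel=3, iterations=3))
    np.testing.assert_allclose(out.voxels, 37.0)
    assert out.is_coregistered(v)


def test_median_removes_isolated_impulse():
    arr = np.zeros((3, 9, 9))
    arr[1, 4, 4] = 1000.0
    out = apply_filter(_vol(arr), FilterSpec("median", kernel=3))
    assert out.voxels.max() == 0.0


def test_adaptive_median_removes_impulse_but_keeps_edges():
    arr = np.zeros((1, 12, 12))
    arr[0, :, 6:] = 100.0  # step edge
    arr[0, 3, 2] = 1000.0  # impulse
    out = apply_filter(_vol(arr), FilterSpec("adaptive_median", kernel=5))
    assert out.voxels[0, 3, 2] < 50.0
    np.testing.assert_array_equal(out.voxels[0, :, 8], 100.0)


def test_savitzky_golay_preserves_quadratic_ramp():
    x = np.arange(20.0)
    arr = np.tile((0.5 * x**2 - 3 * x + 7)[None, None, :], (3, 20, 1))
    out = apply_filter(_vol(arr), FilterSpec("savitzky_golay", kernel=5, polyorder=2))
    np.testing.assert_allclose(out.voxels, arr, atol=1e-6)


@pytest.mark.parametrize("name", ["mean", "median", "kuwahara", "envelope"])
@pytest.mark.parametrize("mode", ["2D", "3D"])
def test_rank_like_filters_are_contractive(name, mode):
    rng = np.random.default_rng(7)
    arr = rng.normal(0, 50, size=(4, 12, 12))
    out = apply_filter(_vol(arr), FilterSpec(name, kernel=3, kernel_mode=mode))
    assert out.voxels.min() >= arr.min() - 1e-9
    assert out.voxels.max() <= arr.max() + 1e-9


@pytest.mark.parametrize("name", ["mean", "fft_window", "savitzky_golay"])
def test_linear_filters_commute_with_subtraction(name):
    rng = np.random.default_rng(8)
    a = _vol(rng.normal(0, 30, size=(4, 16, 16)))
    b = _vol(rng.normal(0, 30, size=(4, 16, 16)))
    spec = FilterSpec(name, kernel=5, iterations=2)
    lhs = subtract_background(apply_filter(a, spec), apply_filter(b, spec))
    rhs = apply_filter(subtract_background(a, b), spec)
    np.testing.assert_allclose(lhs.voxels, rhs.voxels, atol=1e-6)


def test_all_twelve_fft_windows_run():
    assert len(FFT_WINDOWS) == 12
    v = _vol(np.random.default_rng(9).normal(size=(2, 8, 8)))
    for w in FFT_WINDOWS:
        out = apply_filter(v, FilterSpec("fft_window", window_name=w))
        assert out.voxels.shape == v.voxels.shape


def test_envelope_smooths_but_respects_range():
    rng = np.random.default_rng(10)
    arr = rng.normal(0, 10, size=(1, 24, 24))
    out = apply_filter(_vol(arr), FilterSpec("envelope", kernel=3, iterations=3))
    assert out.voxels.std() < arr.std()
    assert arr.min() - 1e-9 <= out.voxels.min()
    assert out.voxels.max() <= arr.max() + 1e-9


@given(
    kernel=st.sampled_from([2, 1, -3]),
    iterations=st.sampled_from([0, -1]),
)
@settings(max_examples=10, deadline=None, derandomize=True)
def test_invalid_filter_parameters_rejected(kernel, iterations):
    with pytest.raises(UsageError):
        FilterSpec("mean", kernel=kernel)
    with pytest.raises(UsageError):
        FilterSpec("mean", iterations=iterations)


def test_unknown_filter_and_bad_polyorder_rejected():
    with pytest.raises(UsageError):
        FilterSpec("sharpen")
    with pytest.raises(UsageError):
        FilterSpec("savitzky_golay", kernel=5, polyorder=5)
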