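"""Series averaging, background subtraction, and the filter bank.

The processing chain before track detection is deliberately simple:
average the (co-registered) scan series, subtract the non-irradiated
background, and optionally filter.  Filtering, when used, should be
applied identically to the background and the irradiated images before
subtraction — filtering only one side leaves the container's radial
structure (rings) in the difference image.  For the linear filters
(mean, frequency-domain window, Savitzky-Golay) the symmetric scheme is
exactly equivalent to filtering the difference.

Available filters (``FilterSpec.name``): ``mean``, ``median``,
``adaptive_mean`` (local-variance-weighted, Lee-style), ``adaptive_median``
(window grows up to the kernel size before passing the center pixel
through), ``kuwahara``, ``fft_window`` (per-slice frequency-domain
multiplication by one of 12 named separable windows), ``savitzky_golay``
and ``envelope``.  The envelope filter is the midpoint of the grayscale
morphological upper (dilation) and lower (erosion) envelopes computed
with a square structuring element; this reproduces the
smoothing-with-edge-respect behaviour the name suggests, but the exact
algorithm of the commercial package it is named after is unpublished, so
it should be treated as an approximation.

All kernels use reflect padding (no rim artifacts inside the container),
operate either per transversal slice (``kernel_mode="2D"``) or on the
full volume (``"3D"``), and preserve geometry.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage, signal

from .errors import UsageError
from .volume_io import CTVolume, SeriesSet, assert_coregistered

__all__ = [
    "FFT_WINDOWS",
    "FilterSpec",
    "average_series",
    "subtract_background",
    "apply_filter",
]

FILTER_NAMES = (
    "mean",
    "median",
    "adaptive_mean",
    "adaptive_median",
    "kuwahara",
    "fft_window",
    "savitzky_golay",
    "envelope",
)

# The 12 named frequency-domain windows.
FFT_WINDOWS = (
    "hann",
    "hamming",
    "blackman",
    "nuttall",
    "blackman-nuttall",
    "blackman-harris",
    "flat-top",
    "bartlett",
    "welch",
    "cosine",
    "tukey",
    "rectangular",
)

_SCIPY_WINDOW = {
    "hann": "hann",
    "hamming": "hamming",
    "blackman": "blackman",
    "nuttall": "nuttall",
    "blackman-harris": "blackmanharris",
    "flat-top": "flattop",
    "bartlett": "bartlett",
    "cosine": "cosine",
    "tukey": "tukey",
    "rectangular": "boxcar",
}


@dataclass(frozen=True)
class FilterSpec:
    """One filter application: name, kernel and mode.

    ``kernel`` is the odd window size in pixels; ``iterations`` repeats
    the same filter; ``window_name`` selects the frequency-domain window
    (``fft_window`` only); ``polyorder`` the polynomial order
    (``savitzky_golay`` only, must be < kernel); ``inner_stat`` how the
    two morphological envelopes are combined (``envelope`` only);
    ``noise_var`` the noise variance used by ``adaptive_mean`` (HU^2;
    estimated from the data when omitted).
    """

    name: str
    kernel: int = 3
    kernel_mode: str = "2D"
    iterations: int = 1
    window_name: str = "nuttall"
    polyorder: int = 2
    inner_stat: str = "mean"
    noise_var: float | None = None

    def __post_init__(self) -> None:
        if self.name not in FILTER_NAMES:
            raise UsageError(f"unknown filter {self.name!r}; choose from {FILTER_NAMES}")
        if self.kernel < 3 or self.kernel % 2 == 0:
            raise UsageError("kernel must be odd and >= 3")
        if self.iterations < 1:
            raise UsageError("iterations must be >= 1")
        if self.kernel_mode not in ("2D", "3D"):
            raise UsageError("kernel_mode must be '2D' or '3D'")
        if self.name == "savitzky_golay" and self.polyorder >= self.kernel:
            raise UsageError("polyorder must be < kernel")
        if self.name == "fft_window" and self.window_name not in FFT_WINDOWS:
            raise UsageError(
                f"unknown window {self.window_name!r}; choose from {FFT_WINDOWS}"
            )
        if self.name == "envelope" and self.inner_stat not in ("mean", "midpoint"):
            raise UsageError("inner_stat must be 'mean' (midpoint of the envelopes)")


# ---------------------------------------------------------------------------
# Series arithmetic
# ---------------------------------------------------------------------------

def average_series(series: SeriesSet, subset: Sequence[int] | None = None) -> CTVolume:
    """Voxelwise arithmetic mean over a subset of the series.

    ``subset`` holds indices into the series (default: all); the result
    keeps the geometry of the first member.
    """
    idx = list(range(len(series))) if subset is None else list(subset)
    if not idx:
        raise UsageError("subset must be non-empty")
    vols = [series[i] for i in idx]
    for v in vols[1:]:
        assert_coregistered(vols[0], v)
    mean = np.mean([v.voxels for v in vols], axis=0)
    return vols[0].with_voxels(mean)


def subtract_background(irradiated: CTVolume, background: CTVolume) -> CTVolume:
    """Voxelwise ``irradiated - background`` (co-registration enforced).

    Removes everything present in both scans — container, beam-hardening
    parabola, ring artifacts — leaving the radiation-induced increments.
    """
    assert_coregistered(irradiated, background)
    return irradiated.with_voxels(irradiated.voxels - background.voxels)


# ---------------------------------------------------------------------------
# Filter bank
# ---------------------------------------------------------------------------

def apply_filter(volume: CTVolume, spec: FilterSpec) -> CTVolume:
    """Apply a named filter ``spec.iterations`` times; geometry unchanged."""
    fn = _FILTERS[spec.name]
    out = volume.voxels
    for _ in range(spec.iterations):
        if spec.kernel_mode == "2D" and spec.name != "savitzky_golay":
            out = np.stack([fn(sl, spec) for sl in out], axis=0)
        elif spec.name == "savitzky_golay":
            out = _savgol(out, spec)
        else:
            out = fn(out, spec)
    return volume.with_voxels(out)


def _mean(arr: np.ndarray, spec: FilterSpec) -> np.ndarray:
    return ndimage.uniform_filter(arr, size=spec.kernel, mode="reflect")


def _median(arr: np.ndarray, spec: FilterSpec) -> np.ndarray:
    return ndimage.median_filter(arr, size=spec.kernel, mode="reflect")


def _adaptive_mean(arr: np.ndarray, spec: FilterSpec) -> np.ndarray:
    """Lee filter: shrink towards the local mean where the local variance
    is close to the noise variance, keep edges where it is much larger."""
    m = ndimage.uniform_filter(arr, size=spec.kernel, mode="reflect")
    m2 = ndimage.uniform_filter(arr * arr, size=spec.kernel, mode="reflect")
    var = np.maximum(m2 - m * m, 0.0)
    nv = spec.noise_var if spec.noise_var is not None else float(np.median(var))
    gain = np.maximum(var - nv, 0.0) / np.maximum(var, 1e-12)
    return m + gain * (arr - m)


def _adaptive_median(arr: np.ndarray, spec: FilterSpec) -> np.ndarray:
    """Classic adaptive median: per pixel, the window grows (3, 5, ...)
    until the local median is not an extreme of the window, up to
    ``kernel``; then the center value passes through unless it is itself
    an extreme, in which case the median replaces it."""
    out = arr.copy()
    decided = np.zeros(arr.shape, dtype=bool)
    for size in range(3, spec.kernel + 1, 2):
        med = ndimage.median_filter(arr, size=size, mode="reflect")
        lo = ndimage.minimum_filter(arr, size=size, mode="reflect")
        hi = ndimage.maximum_filter(arr, size=size, mode="reflect")
        med_ok = (med > lo) & (med < hi)
        last = size == spec.kernel
        here = ~decided & (med_ok | last)
        center_ok = (arr > lo) & (arr < hi)
        out[here] = np.where(center_ok[here] & med_ok[here], arr[here], med[here])
        decided |= here
        if decided.all():
            break
    return out


def _kuwahara(arr: np.ndarray, spec: FilterSpec) -> np.ndarray:
    """Mean of the least-variance corner sub-window (edge-preserving).

    For kernel k the corner sub-windows have size (k+1)//2 per axis and
    all include the center pixel (the classic 2x2 quadrants for k=3)."""
    q = (spec.kernel + 1) // 2  # sub-window size
    m = ndimage.uniform_filter(arr, size=q, mode="nearest")
    m2 = ndimage.uniform_filter(arr * arr, size=q, mode="nearest")

    def shifted(f: np.ndarray, signs) -> np.ndarray:
        out = f
        for ax, s in enumerate(signs):
            # window of uniform_filter at j covers [j - q//2, j + (q-1)//2];
            # corner windows end (-1) or start (+1) at the center pixel
            off = -((q - 1) // 2) if s < 0 else q // 2
            idx = np.clip(np.arange(out.shape[ax]) + off, 0, out.shape[ax] - 1)
            out = np.take(out, idx, axis=ax)
        return out

    means, varis = [], []
    for signs in _corner_signs(arr.ndim):
        mm = shifted(m, signs)
        means.append(mm)
        varis.append(np.maximum(shifted(m2, signs) - mm * mm, 0.0))
    means = np.stack(means)
    pick = np.argmin(np.stack(varis), axis=0)
    return np.take_along_axis(means, pick[None], axis=0)[0]


def _corner_signs(ndim: int):
    if ndim == 2:
        return [(-1, -1), (-1, 1), (1, -1), (1, 1)]
    return [
        (i, j, k) for i in (-1, 1) for j in (-1, 1) for k in (-1, 1)
    ]


def _window_1d(name: str, n: int) -> np.ndarray:
    if name == "welch":
        k = np.arange(n)
        return 1.0 - ((k - (n - 1) / 2.0) / ((n - 1) / 2.0)) ** 2
    if name == "blackman-nuttall":
        a = (0.3635819, 0.4891775, 0.1365995, 0.0106411)
        k = np.arange(n)
        t = 2.0 * np.pi * k / (n - 1)
        return a[0] - a[1] * np.cos(t) + a[2] * np.cos(2 * t) - a[3] * np.cos(3 * t)
    return signal.windows.get_window(_SCIPY_WINDOW[name], n, fftbins=False)


def _fft_window(arr: np.ndarray, spec: FilterSpec) -> np.ndarray:
    """Frequency-domain multiplication by a separable window centered at DC
    (a smooth low-pass; the kernel size is not used)."""
    win = 1.0
    shape = arr.shape
    for ax, n in enumerate(shape):
        w = _window_1d(spec.window_name, n)
        w = w / w.max()
        win = np.multiply.outer(win, w) if ax else w
    f = np.fft.fftshift(np.fft.fftn(arr))
    return np.real(np.fft.ifftn(np.fft.ifftshift(f * win)))


def _savgol(arr: np.ndarray, spec: FilterSpec) -> np.ndarray:
    """Separable Savitzky-Golay smoothing; exact on polynomials up to
    ``polyorder`` along each filtered axis."""
    axes = (1, 2) if spec.kernel_mode == "2D" else (0, 1, 2)
    out = arr
    for ax in axes:
        out = signal.savgol_filter(
            out, window_length=spec.kernel, polyorder=spec.polyorder,
            axis=ax, mode="interp",
        )
    return out


def _envelope(arr: np.ndarray, spec: FilterSpec) -> np.ndarray:
    size = (spec.kernel,) * arr.ndim
    upper = ndimage.grey_dilation(arr, size=size, mode="reflect")
    lower = ndimage.grey_erosion(arr, size=size, mode="reflect")
    return 0.5 * (upper + lower)


_FILTERS = {
    "mean": _mean,
    "median": _median,
    "adaptive_mean": _adaptive_mean,
    "adaptive_median": _adaptive_median,
    "kuwahara": _kuwahara,
    "fft_window": _fft_window,
    "savitzky_golay": _savgol,
    "envelope": _envelope,
}
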