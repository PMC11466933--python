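"""The demonstration image-processing op collection.

Numerical conventions (normative for this package): Gaussian kernels are
truncated at half-width ``ceil(4*sigma)`` and normalized to sum 1; borders
are mirrored; accumulation happens in float64 with a final cast to the
output element kind (uint8 rounds half-up and clamps).  Coordinates are
0-based, axes ordered slowest to fastest, intervals half-open.

Composite ops (Difference of Gaussians, Otsu, the significance mask) receive
their helpers as engine-resolved dependencies — keyword arguments injected
at instantiation — never as hard links, so registering a better helper
implementation upgrades them automatically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import convolve1d
from scipy.special import ndtr

from .errors import DimensionError, ParameterError
from .images import DenseImage

# ---------------------------------------------------------------------------
# Gaussian filtering
# ---------------------------------------------------------------------------

def gaussian_kernel(sigma: float) -> np.ndarray:
    """Discrete Gaussian, half-width ceil(4*sigma), normalized to sum 1."""
    if sigma <= 0:
        raise ParameterError(f"sigma must be positive, got {sigma}")
    r = math.ceil(4.0 * sigma)
    x = np.arange(-r, r + 1, dtype=np.float64)
    k = np.exp(-(x ** 2) / (2.0 * sigma ** 2))
    return k / k.sum()


def _as_sigmas(sigma, ndim: int) -> list[float]:
    if isinstance(sigma, (list, tuple)):
        if len(sigma) != ndim:
            raise ParameterError(
                f"per-axis sigma needs {ndim} entries, got {len(sigma)}")
        return [float(s) for s in sigma]
    return [float(sigma)] * ndim


def gauss(input: DenseImage, sigma, output: DenseImage) -> None:
    """Separable Gaussian blur (computer): overwrites the container."""
    if input.shape != output.shape:
        raise DimensionError(
            f"input and container shapes differ: {input.shape} vs {output.shape}")
    data = input.values.astype(np.float64)
    for axis, s in enumerate(_as_sigmas(sigma, data.ndim)):
        data = convolve1d(data, gaussian_kernel(s), axis=axis, mode="mirror")
    if output.element_kind == "uint8":
        data = np.clip(np.floor(data + 0.5), 0, 255)
    output.values[...] = data.astype(output.values.dtype)


def dog(input: DenseImage, sigma1, sigma2, *, gauss1, gauss2, sub) -> DenseImage:
    """Difference of Gaussians: blur at sigma1 minus blur at sigma2.

    The two blurs and the subtraction are engine-matched dependencies."""
    return sub(gauss1(input, sigma1), gauss2(input, sigma2))


# ---------------------------------------------------------------------------
# Histogram and Otsu threshold
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Histogram:
    bin_edges: tuple[float, ...]  # k+1 edges for k bins
    counts: tuple[int, ...]

    @property
    def n_bins(self) -> int:
        return len(self.counts)


def histogram(input: DenseImage, bins: int = 256) -> Histogram:
    """Counting histogram; floor bin assignment, last bin right-closed.

    uint8 images bin over [0, 256); float images over [min, max]."""
    bins = int(bins)
    if bins < 2:
        raise ParameterError(f"bins must be >= 2, got {bins}")
    v = input.values.astype(np.float64).ravel()
    if input.element_kind == "uint8":
        lo, hi = 0.0, 256.0
    else:
        lo, hi = float(v.min()), float(v.max())
    if hi == lo:
        counts = np.zeros(bins, dtype=np.int64)
        counts[0] = v.size
        edges = np.linspace(lo, lo + 1.0, bins + 1)
        return Histogram(tuple(edges.tolist()), tuple(counts.tolist()))
    width = (hi - lo) / bins
    idx = np.floor((v - lo) / width).astype(np.int64)
    idx[idx == bins] = bins - 1  # last bin inclusive
    counts = np.bincount(idx, minlength=bins)
    edges = lo + width * np.arange(bins + 1)
    return Histogram(tuple(edges.tolist()), tuple(counts.tolist()))


@dataclass(frozen=True)
class ThresholdResult:
    threshold: float
    mask: DenseImage  # uint8, 1 where input > threshold


def otsu(input: DenseImage, *, histogram) -> ThresholdResult:
    """Threshold maximizing between-class variance over a 256-bin histogram.

    Ties break toward the lowest maximizing threshold; the mask is strictly
    ``input > threshold``.  A constant image is a degenerate input."""
    if np.unique(input.values).size < 2:
        raise ParameterError("threshold.otsu: image has fewer than 2 distinct values")
    h = histogram(input, 256)
    counts = np.asarray(h.counts, dtype=np.float64)
    edges = np.asarray(h.bin_edges)
    total = counts.sum()
    centers = np.arange(counts.size, dtype=np.float64)
    w0 = np.cumsum(counts)
    m0 = np.cumsum(counts * centers)
    best_t, best_var = None, -1.0
    for t in range(counts.size - 1):
        n0, n1 = w0[t], total - w0[t]
        if n0 == 0 or n1 == 0:
            continue
        mu0 = m0[t] / n0
        mu1 = (m0[-1] - m0[t]) / n1
        var = n0 * n1 * (mu0 - mu1) ** 2
        if var > best_var:  # strict: ties keep the lowest threshold
            best_var, best_t = var, t
    if best_t is None:
        raise ParameterError("threshold.otsu: degenerate histogram")
    if input.element_kind == "uint8":
        thr = float(best_t)  # bin t holds exactly the value t
    else:
        thr = float(edges[best_t + 1])
    mask = DenseImage((input.values > thr).astype(np.uint8))
    return ThresholdResult(threshold=thr, mask=mask)


# ---------------------------------------------------------------------------
# FFT with optional parameters
# ---------------------------------------------------------------------------

def next_fast_len_2357(n: int) -> int:
    """Smallest m >= n whose prime factors are all in {2, 3, 5, 7}."""
    m = n
    while True:
        k = m
        for p in (2, 3, 5, 7):
            while k % p == 0:
                k //= p
        if k == 1:
            return m
        m += 1


def fft_layout(shape, border_size, fast: bool):
    """Padded shape and per-axis (before, after) pad widths for filter.fft."""
    if isinstance(border_size, (list, tuple)):
        borders = [int(b) for b in border_size]
        if len(borders) != len(shape):
            raise ParameterError(
                f"borderSize needs {len(shape)} entries, got {len(borders)}")
    else:
        borders = [int(border_size)] * len(shape)
    if any(b < 0 for b in borders):
        raise ParameterError("borderSize must be non-negative")
    pads = []
    for n, b in zip(shape, borders):
        target = n + 2 * b
        if fast:
            target = next_fast_len_2357(target)
        pads.append((b, target - n - b))
    return tuple(n + sum(p) for n, p in zip(shape, pads)), tuple(pads)


def fft(input: DenseImage, fftType: str, borderSize=0, fast: bool = True) -> np.ndarray:
    """Discrete Fourier transform of the mirror-padded image.

    ``borderSize`` pads each axis (mirror); with ``fast`` each padded axis is
    rounded up to the next length factorable into {2, 3, 5, 7}."""
    if fftType != "real_to_complex":
        raise ParameterError(f"unknown fftType {fftType!r}")
    _, pads = fft_layout(input.shape, borderSize, fast)
    data = np.pad(input.values.astype(np.float64), pads, mode="reflect")
    return np.fft.fftn(data)


def ifft_crop(spectrum: np.ndarray, original_shape, borderSize=0,
              fast: bool = True) -> DenseImage:
    """Inverse of :func:`fft`: inverse transform, then crop the padding."""
    _, pads = fft_layout(original_shape, borderSize, fast)
    data = np.fft.ifftn(spectrum).real
    slices = tuple(slice(b, b + n) for (b, _), n in zip(pads, original_shape))
    return DenseImage(data[slices])


# ---------------------------------------------------------------------------
# Normal CDF and significance mask
# ---------------------------------------------------------------------------

def pnorm(x: float) -> float:
    """Standard normal cumulative distribution function."""
    return float(ndtr(x))


def pnorm_image(x: DenseImage) -> DenseImage:
    """Standard normal CDF applied element-wise to an image of z-scores."""
    return DenseImage(ndtr(x.values.astype(np.float64)))


def sig_mask(zscores: DenseImage, alpha: float = 0.05, *, pnorm) -> DenseImage:
    """Binary mask of pixels significant at level alpha, one-sided upper tail.

    ``mask[i] = (1 - pnorm(z[i])) < alpha``; the CDF is an engine-resolved
    dependency.  No multiple-testing adjustment is applied."""
    if not 0.0 < alpha < 1.0:
        raise ParameterError(f"alpha must be in (0, 1), got {alpha}")
    p_upper = 1.0 - pnorm(zscores).values
    return DenseImage((p_upper < alpha).astype(np.uint8))


# ---------------------------------------------------------------------------
# Synthetic fixture generator
# ---------------------------------------------------------------------------

SPOT_AMPLITUDE = 200.0  # peak height of one synthetic fluorescence spot


def synthetic_image(shape, n_spots: int, spot_sigma: float, noise_sd: float,
                    seed: int, element_kind: str = "float64") -> DenseImage:
    """Sum of seeded-random Gaussian spots plus Gaussian noise.

    Emulates a fluorescence spot image: ``n_spots`` isotropic Gaussian peaks
    of amplitude 200 at uniform random positions, plus pixel noise of
    standard deviation ``noise_sd``.  The same seed always yields the same
    image; uint8 output rounds half-up and clamps to [0, 255]."""
    shape = tuple(int(s) for s in shape)
    if any(s <= 0 for s in shape):
        raise ParameterError(f"shape must be positive, got {shape}")
    rng = np.random.default_rng(int(seed))
    grid = np.indices(shape, dtype=np.float64)
    img = np.zeros(shape, dtype=np.float64)
    for _ in range(int(n_spots)):
        pos = [rng.uniform(0, s) for s in shape]
        d2 = sum((g - p) ** 2 for g, p in zip(grid, pos))
        img += SPOT_AMPLITUDE * np.exp(-d2 / (2.0 * float(spot_sigma) ** 2))
    if noise_sd > 0:
        img += rng.normal(0.0, float(noise_sd), size=shape)
    if element_kind == "uint8":
        return DenseImage(np.clip(np.floor(img + 0.5), 0, 255).astype(np.uint8))
    return DenseImage(img)
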