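"""Procedural complex phantoms used as simulation ground truth.

Real FPM studies typically use natural photographs as amplitude and phase
maps; these generators stand in with procedural fields so simulations need no
external images.  A phantom is a complex field amplitude * exp(j phase) with
amplitude mapped into ``amplitude_range`` (default [0.1, 1], keeping it away
from the zero-amplitude degeneracy) and phase into ``phase_range`` (default
[0, pi]).
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter

from .optics import fft2c, ifft2c

KINDS = ("flat", "smooth", "bars", "disks", "image")


def _rescale(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    xmin, xmax = x.min(), x.max()
    if xmax == xmin:
        return np.full_like(x, (lo + hi) / 2.0)
    return lo + (hi - lo) * (x - xmin) / (xmax - xmin)


def _load_gray(path: str, n: int) -> np.ndarray:
    import imageio.v3 as iio
    from skimage.transform import resize

    img = np.asarray(iio.imread(path), dtype=float)
    if img.ndim == 3:
        img = img.mean(axis=-1)
    if img.shape[0] != img.shape[1]:
        raise ValueError(f"phantom image {path} must be square, got {img.shape}")
    return resize(img, (n, n), order=3, mode="edge", anti_aliasing=True, preserve_range=True)


def make_phantom(
    kind: str = "smooth",
    n: int = 64,
    seed: int = 0,
    amplitude_range: tuple[float, float] = (0.1, 1.0),
    phase_range: tuple[float, float] = (0.0, np.pi),
    smoothness: float | None = None,
    amplitude_path: str | None = None,
    phase_path: str | None = None,
) -> np.ndarray:
    """Build an n x n complex phantom field.

    Kinds: ``flat`` (unit amplitude, zero phase), ``smooth`` (independent
    Gaussian-filtered random fields for amplitude and phase; ``smoothness``
    is the filter sigma in pixels, default n/16), ``bars`` (amplitude bars
    along x, phase bars along y, period n//8 each), ``disks`` (a 3x3 grid of
    amplitude disks with phase disks offset by half a cell), and ``image``
    (user-supplied grayscale amplitude/phase files).  Same seed, same field.
    """
    if kind not in KINDS:
        raise ValueError(f"unknown phantom kind {kind!r}; one of {KINDS}")
    lo_a, hi_a = amplitude_range
    lo_p, hi_p = phase_range

    if kind == "flat":
        return np.ones((n, n), dtype=complex)

    if kind == "smooth":
        sigma = n / 16.0 if smoothness is None else smoothness
        rng = np.random.default_rng(seed)
        amp = _rescale(gaussian_filter(rng.standard_normal((n, n)), sigma), lo_a, hi_a)
        pha = _rescale(gaussian_filter(rng.standard_normal((n, n)), sigma), lo_p, hi_p)
        return amp * np.exp(1j * pha)

    if kind == "bars":
        period = max(n // 8, 1)
        ix = np.arange(n)
        amp_1d = np.where((ix // period) % 2 == 0, hi_a, lo_a)
        pha_1d = np.where((ix // period) % 2 == 0, hi_p, lo_p)
        amp = np.tile(amp_1d, (n, 1))          # vertical bars: vary along x
        pha = np.tile(pha_1d[:, None], (1, n))  # horizontal bars: vary along y
        return amp * np.exp(1j * pha)

    if kind == "disks":
        iy, ix = np.mgrid[0:n, 0:n]
        r = max(n // 10, 1)
        amp = np.full((n, n), lo_a)
        pha = np.full((n, n), lo_p)
        centers = [(n * (2 * i + 1) // 6, n * (2 * j + 1) // 6) for i in range(3) for j in range(3)]
        for cy, cx in centers:
            amp[(iy - cy) ** 2 + (ix - cx) ** 2 <= r**2] = hi_a
            # phase disks shifted by half a cell so the two maps differ
            pha[(iy - (cy + n // 6) % n) ** 2 + (ix - (cx + n // 6) % n) ** 2 <= r**2] = hi_p
        return amp * np.exp(1j * pha)

    # kind == "image"
    if amplitude_path is None or phase_path is None:
        raise ValueError("image phantom needs amplitude_path and phase_path")
    amp = _rescale(_load_gray(amplitude_path, n), lo_a, hi_a)
    pha = _rescale(_load_gray(phase_path, n), lo_p, hi_p)
    return amp * np.exp(1j * pha)


def bandlimit(field: np.ndarray, radius_px: float) -> np.ndarray:
    """Hard circular low-pass of a complex field in the centered Fourier
    domain (radius in frequency pixels, inclusive).

    Used so that simulation ground truths carry no energy beyond the
    synthetic-NA coverage, where no algorithm could recover it.
    """
    n = field.shape[0]
    c = n // 2
    iy, ix = np.mgrid[0:n, 0:n]
    mask = (iy - c) ** 2 + (ix - c) ** 2 <= radius_px**2
    return ifft2c(fft2c(np.asarray(field, dtype=complex)) * mask)
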