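"""Coherent image formation for Fourier ptychographic microscopy (FPM).

An FPM acquisition illuminates a thin sample with tilted plane waves from an
LED array.  Each tilt shifts the sample's spatial spectrum across the
objective pupil, so every low-resolution (LR) capture is the intensity of the
inverse Fourier transform of one pupil-masked window of the high-resolution
(HR) spectrum:

    c_i = |a_i z|^2,   A = (inverse DFT) . (binary pupil) . (window shift)

with ``z`` the vectorized HR spectrum.  This module fixes the geometry and
transform conventions used everywhere else in the package and provides both
the fast FFT-based operator and an explicit dense-matrix rendition of ``A``
used as a brute-force oracle in the test suite.

Conventions
-----------
* Spectra are stored centered: the DC bin sits at index ``n // 2`` along each
  axis, and transforms are the centered unitary FFT (``fft2c``/``ifft2c``).
* An LED displaced towards +x illuminates the sample so that the extracted
  frequency window moves towards -x (field convention exp(+j 2*pi f.x)).
* LR fields carry the fixed amplitude scale ``s = n_lr / n_hr`` so that a
  unit-amplitude object produces unit-intensity bright-field captures.
* Window positions are rounded to the nearest frequency pixel; a window that
  would leave the HR grid is an error, never a wrap-around.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg


class WindowOutOfBoundsError(ValueError):
    """The requested sub-spectrum window leaves the HR grid.

    Raised when the LED geometry is too aggressive for the configured grid
    sizes; physical spectra do not wrap around.
    """


# ---------------------------------------------------------------------------
# Centered unitary transforms
# ---------------------------------------------------------------------------

_AXES = (-2, -1)


def fft2c(x: np.ndarray) -> np.ndarray:
    """Centered unitary 2-D FFT (DC at ``n // 2``) over the last two axes."""
    return np.fft.fftshift(
        np.fft.fft2(np.fft.ifftshift(x, axes=_AXES), norm="ortho", axes=_AXES),
        axes=_AXES,
    )


def ifft2c(x: np.ndarray) -> np.ndarray:
    """Inverse of :func:`fft2c`."""
    return np.fft.fftshift(
        np.fft.ifft2(np.fft.ifftshift(x, axes=_AXES), norm="ortho", axes=_AXES),
        axes=_AXES,
    )


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OpticalConfig:
    """Optics and sampling geometry of the simulated microscope.

    Parameters
    ----------
    na_objective : float
        Numerical aperture of the objective, in (0, 1).
    wavelength_um : float
        Illumination wavelength in micrometres.
    pixel_size_lr_um : float
        Detector pixel pitch referred to the sample plane, micrometres.
    n_hr, n_lr : int
        High-resolution and low-resolution grid sides in pixels; ``n_hr``
        must be an integer multiple of ``n_lr``.
    """

    na_objective: float
    wavelength_um: float
    pixel_size_lr_um: float
    n_hr: int
    n_lr: int

    def __post_init__(self) -> None:
        if not 0.0 < self.na_objective < 1.0:
            raise ValueError(f"na_objective must be in (0, 1), got {self.na_objective}")
        if self.wavelength_um <= 0:
            raise ValueError("wavelength must be positive")
        if self.pixel_size_lr_um <= 0:
            raise ValueError("pixel size must be positive")
        if self.n_lr < 2 or self.n_hr < self.n_lr:
            raise ValueError("need n_hr >= n_lr >= 2")
        if self.n_hr % self.n_lr != 0:
            raise ValueError(
                f"n_hr ({self.n_hr}) must be an integer multiple of n_lr ({self.n_lr})"
            )

    @property
    def ratio(self) -> int:
        """HR/LR magnification ratio r = n_hr / n_lr."""
        return self.n_hr // self.n_lr

    @property
    def pixel_size_hr_um(self) -> float:
        return self.pixel_size_lr_um / self.ratio

    @property
    def delta_f(self) -> float:
        """Frequency-pixel pitch in cycles/um (same on the HR and LR grids)."""
        return 1.0 / (self.n_lr * self.pixel_size_lr_um)

    @property
    def f_cutoff(self) -> float:
        """Pupil cutoff frequency NA / lambda, cycles/um."""
        return self.na_objective / self.wavelength_um

    @property
    def amplitude_scale(self) -> float:
        """Fixed LR-field amplitude scale s = n_lr / n_hr."""
        return self.n_lr / self.n_hr


@dataclass(frozen=True)
class LEDGeometry:
    """Planar LED grid below the sample.

    ``pitch_mm`` is the spacing between adjacent LEDs, ``height_mm`` the
    distance from the LED plane to the sample plane, and ``center_offset_mm``
    a lateral (x, y) offset of the grid centre from the optical axis.
    """

    rows: int
    cols: int
    pitch_mm: float
    height_mm: float
    center_offset_mm: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError("LED grid needs at least one LED")
        if self.pitch_mm <= 0:
            raise ValueError("LED pitch must be positive")
        if self.height_mm <= 0:
            raise ValueError("LED height must be positive")

    @property
    def n_leds(self) -> int:
        return self.rows * self.cols

    def offsets_mm(self) -> np.ndarray:
        """(n_leds, 2) lateral LED offsets (dx, dy) in mm, raster order."""
        ox, oy = self.center_offset_mm
        cx = (self.cols - 1) / 2.0
        cy = (self.rows - 1) / 2.0
        cols = np.arange(self.cols)
        rows = np.arange(self.rows)
        dx = (cols - cx) * self.pitch_mm + ox
        dy = (rows - cy) * self.pitch_mm + oy
        dxg, dyg = np.meshgrid(dx, dy)  # raster: row-major over (row, col)
        return np.column_stack([dxg.ravel(), dyg.ravel()])


@dataclass(frozen=True)
class Pupil:
    """Ideal binary circular pupil on the LR frequency grid."""

    radius_px: float
    mask: np.ndarray = field(repr=False)

    @property
    def n_lr(self) -> int:
        return self.mask.shape[0]


@dataclass
class CaptureStack:
    """An ordered stack of LR intensity captures with their illumination.

    ``images`` has shape (n_leds, n_lr, n_lr) and is nonnegative;
    ``wavevectors`` holds one (fx, fy) row per capture, in cycles/um;
    ``ordering`` optionally maps capture index -> LED grid (row, col).
    """

    images: np.ndarray
    wavevectors: np.ndarray
    pupil: Pupil
    ordering: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=float)
        self.wavevectors = np.asarray(self.wavevectors, dtype=float)
        if self.images.ndim != 3:
            raise ValueError("images must be (n_leds, n_lr, n_lr)")
        if len(self.wavevectors) != len(self.images):
            raise ValueError("one wavevector per image required")
        if np.any(self.images < 0):
            raise ValueError("intensities must be nonnegative")

    @property
    def n_leds(self) -> int:
        return len(self.images)

    def replace_images(self, images: np.ndarray) -> "CaptureStack":
        return CaptureStack(images, self.wavevectors, self.pupil, self.ordering)


# ---------------------------------------------------------------------------
# Illumination geometry
# ---------------------------------------------------------------------------


def led_wavevectors(geometry: LEDGeometry, optics: OpticalConfig) -> np.ndarray:
    """Illumination wavevectors (fx, fy) in cycles/um, one row per LED.

    For an LED at lateral offset (dx, dy) and height h the incident plane
    wave carries fx = -(dx / sqrt(dx^2 + dy^2 + h^2)) / lambda (direction
    cosine over wavelength; the sign follows the package convention that an
    LED at +x shifts the sampled window towards -x in frequency).
    """
    if geometry.height_mm <= 0:
        raise ValueError("LED height must be positive")
    off = geometry.offsets_mm() * 1000.0  # mm -> um
    h = geometry.height_mm * 1000.0
    rho = np.sqrt(off[:, 0] ** 2 + off[:, 1] ** 2 + h**2)
    return -off / (rho[:, None] * optics.wavelength_um)


def illumination_na(geometry: LEDGeometry, optics: OpticalConfig) -> float:
    """Maximum illumination NA (= max |sin theta|) over the LED grid."""
    wv = led_wavevectors(geometry, optics)
    return float(np.max(np.hypot(wv[:, 0], wv[:, 1])) * optics.wavelength_um)


def synthetic_na(geometry: LEDGeometry, optics: OpticalConfig) -> float:
    """Synthetic NA of the stitched reconstruction: objective + illumination."""
    return optics.na_objective + illumination_na(geometry, optics)


def combined_na(illumination: float, objective: float) -> float:
    """Synthetic NA from already-known illumination and objective NAs."""
    return illumination + objective


# ---------------------------------------------------------------------------
# Pupil
# ---------------------------------------------------------------------------


def pupil_mask(optics: OpticalConfig) -> Pupil:
    """Ideal binary pupil: ones inside the NA circle (inclusive), zeros out.

    The cutoff radius in frequency pixels is (NA/lambda) / delta_f with
    delta_f = 1 / (n_lr * pixel_size_lr).  Warns when the pupil is degenerate
    (radius < 1 px) or fills the grid (radius >= n_lr / 2, no low-pass).
    """
    n = optics.n_lr
    radius_px = optics.f_cutoff / optics.delta_f
    if radius_px < 1.0:
        warnings.warn(
            f"pupil radius {radius_px:.3g} px < 1: pupil is degenerate", stacklevel=2
        )
    if radius_px >= n / 2:
        warnings.warn(
            f"pupil radius {radius_px:.3g} px >= n_lr/2: no low-pass effect",
            stacklevel=2,
        )
    c = n // 2
    iy, ix = np.mgrid[0:n, 0:n]
    dist_sq = (iy - c) ** 2 + (ix - c) ** 2
    mask = dist_sq <= radius_px**2
    return Pupil(radius_px=float(radius_px), mask=mask)


def pupil_overlap_fraction(step_px: float, radius_px: float) -> float:
    """Area overlap fraction of two pupil circles whose centres are
    ``step_px`` apart, relative to one pupil area (lens-area formula)."""
    d, r = float(step_px), float(radius_px)
    if d >= 2 * r:
        return 0.0
    lens = 2 * r**2 * np.arccos(d / (2 * r)) - (d / 2) * np.sqrt(4 * r**2 - d**2)
    return float(lens / (np.pi * r**2))


# ---------------------------------------------------------------------------
# Sub-spectrum windows
# ---------------------------------------------------------------------------


def freq_pixel_shifts(wavevectors: np.ndarray, optics: OpticalConfig) -> np.ndarray:
    """Round wavevectors to integer frequency-pixel shifts (sx, sy)."""
    wv = np.atleast_2d(np.asarray(wavevectors, dtype=float))
    return np.rint(wv / optics.delta_f).astype(int)


def _window_starts(shifts: np.ndarray, optics: OpticalConfig) -> tuple[np.ndarray, np.ndarray]:
    """Top-left (row, col) of each window on the HR grid; bounds-checked."""
    c_hr = optics.n_hr // 2
    half = optics.n_lr // 2
    col0 = c_hr + shifts[:, 0] - half  # sx moves columns (x <-> fx)
    row0 = c_hr + shifts[:, 1] - half  # sy moves rows (y <-> fy)
    bad = (
        (row0 < 0)
        | (col0 < 0)
        | (row0 + optics.n_lr > optics.n_hr)
        | (col0 + optics.n_lr > optics.n_hr)
    )
    if np.any(bad):
        i = int(np.flatnonzero(bad)[0])
        raise WindowOutOfBoundsError(
            f"sub-spectrum window for capture {i} (pixel shift "
            f"{tuple(shifts[i])}) leaves the {optics.n_hr}x{optics.n_hr} HR grid"
        )
    return row0, col0


def extract_subspectrum(
    spectrum: np.ndarray, wavevector: np.ndarray, pupil: Pupil, optics: OpticalConfig
) -> np.ndarray:
    """Pupil-masked n_lr x n_lr window of the centered HR spectrum.

    The window is centered at the frequency pixel nearest to (fx, fy).
    """
    shifts = freq_pixel_shifts(wavevector, optics)
    row0, col0 = _window_starts(shifts, optics)
    r0, c0 = int(row0[0]), int(col0[0])
    n = optics.n_lr
    return spectrum[r0 : r0 + n, c0 : c0 + n] * pupil.mask


def embed_subspectrum(
    sub: np.ndarray, wavevector: np.ndarray, pupil: Pupil, optics: OpticalConfig
) -> np.ndarray:
    """Adjoint of :func:`extract_subspectrum`: place the masked window into an
    otherwise-zero HR spectrum."""
    if sub.shape != (optics.n_lr, optics.n_lr):
        raise ValueError("sub-spectrum dimensions must match the LR grid")
    shifts = freq_pixel_shifts(wavevector, optics)
    row0, col0 = _window_starts(shifts, optics)
    r0, c0 = int(row0[0]), int(col0[0])
    n = optics.n_lr
    out = np.zeros((optics.n_hr, optics.n_hr), dtype=complex)
    out[r0 : r0 + n, c0 : c0 + n] = sub * pupil.mask
    return out


# ---------------------------------------------------------------------------
# Vectorized forward / adjoint operator
# ---------------------------------------------------------------------------


class OperatorPlan:
    """Precomputed gather indices and scales for one acquisition geometry.

    Used by the forward model and by the reconstruction inner loops so that
    all captures are processed with batched FFTs instead of per-LED Python
    loops.
    """

    def __init__(self, wavevectors: np.ndarray, pupil: Pupil, optics: OpticalConfig):
        self.optics = optics
        self.pupil = pupil
        self.wavevectors = np.atleast_2d(np.asarray(wavevectors, dtype=float))
        shifts = freq_pixel_shifts(self.wavevectors, optics)
        row0, col0 = _window_starts(shifts, optics)
        n = optics.n_lr
        rng = np.arange(n)
        self.rows = row0[:, None] + rng[None, :]  # (m, n_lr)
        self.cols = col0[:, None] + rng[None, :]
        self.mask = pupil.mask
        self.scale = optics.amplitude_scale

    @property
    def n_leds(self) -> int:
        return len(self.rows)

    def windows(self, spectrum: np.ndarray) -> np.ndarray:
        """(m, n_lr, n_lr) pupil-masked windows of the HR spectrum."""
        return spectrum[self.rows[:, :, None], self.cols[:, None, :]] * self.mask

    def fields(self, spectrum: np.ndarray) -> np.ndarray:
        """LR complex fields A z, shape (m, n_lr, n_lr)."""
        return self.scale * ifft2c(self.windows(spectrum))

    def adjoint(self, lr_fields: np.ndarray) -> np.ndarray:
        """A^H applied to a stack of LR fields; returns an HR spectrum."""
        sub = self.scale * fft2c(lr_fields) * self.mask
        out = np.zeros((self.optics.n_hr, self.optics.n_hr), dtype=complex)
        np.add.at(out, (self.rows[:, :, None], self.cols[:, None, :]), sub)
        return out

    def coverage(self) -> np.ndarray:
        """Integer map: how many pupil windows cover each HR frequency pixel."""
        cov = np.zeros((self.optics.n_hr, self.optics.n_hr), dtype=int)
        np.add.at(
            cov,
            (self.rows[:, :, None], self.cols[:, None, :]),
            np.broadcast_to(self.mask.astype(int), (self.n_leds, *self.mask.shape)),
        )
        return cov

    def operator_norm_sq(self) -> float:
        """lambda_max(sum_i a_i^H a_i) = s^2 * max coverage (exact: the frame
        operator is diagonal in the centered frequency basis)."""
        return float(self.scale**2 * self.coverage().max())


def forward_fields(
    spectrum: np.ndarray,
    wavevectors: np.ndarray,
    pupil: Pupil,
    optics: OpticalConfig,
) -> np.ndarray:
    """Complex LR fields A z for every capture."""
    return OperatorPlan(wavevectors, pupil, optics).fields(spectrum)


def forward_capture(
    spectrum: np.ndarray,
    wavevectors: np.ndarray,
    pupil: Pupil,
    optics: OpticalConfig,
    ordering: np.ndarray | None = None,
) -> CaptureStack:
    """Ideal capture stack b = |A z|^2 for an HR spectrum ``z``."""
    fields = forward_fields(spectrum, wavevectors, pupil, optics)
    return CaptureStack(
        images=np.abs(fields) ** 2,
        wavevectors=np.atleast_2d(wavevectors),
        pupil=pupil,
        ordering=ordering,
    )


# ---------------------------------------------------------------------------
# Dense oracle
# ---------------------------------------------------------------------------


def _perm_matrix(idx: np.ndarray) -> np.ndarray:
    return np.eye(len(idx))[idx]


def dense_operator(
    wavevectors: np.ndarray, pupil: Pupil, optics: OpticalConfig
) -> np.ndarray:
    """Explicit measurement matrix A of shape (m * n_lr^2, n_hr^2).

    Built from explicit DFT and permutation matrices (independent of the FFT
    pipeline); intended as the brute-force oracle on toy problems.  Refuses
    n_hr > 16 as a memory guard.
    """
    if optics.n_hr > 16:
        raise ValueError("dense_operator is an oracle for toy grids (n_hr <= 16)")
    n_lr, n_hr = optics.n_lr, optics.n_hr
    # Centered unitary inverse DFT along one axis: fftshift . IDFT . ifftshift
    f = scipy.linalg.dft(n_lr) / np.sqrt(n_lr)  # unitary forward DFT
    idft = f.conj().T
    p_shift = _perm_matrix(np.fft.fftshift(np.arange(n_lr)))
    p_ishift = _perm_matrix(np.fft.ifftshift(np.arange(n_lr)))
    g = p_shift @ idft @ p_ishift
    ifft2c_mat = np.kron(g, g)  # acts on row-major vectorized n_lr x n_lr grids

    wv = np.atleast_2d(np.asarray(wavevectors, dtype=float))
    shifts = freq_pixel_shifts(wv, optics)
    row0, col0 = _window_starts(shifts, optics)
    masked = ifft2c_mat * pupil.mask.ravel()[None, :]

    rows_out = []
    rng = np.arange(n_lr)
    for r0, c0 in zip(row0, col0):
        win_rows = (r0 + rng)[:, None] * n_hr + (c0 + rng)[None, :]
        block = np.zeros((n_lr**2, n_hr**2), dtype=complex)
        block[:, win_rows.ravel()] = masked
        rows_out.append(block)
    return optics.amplitude_scale * np.vstack(rows_out)
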