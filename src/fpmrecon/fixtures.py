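"""Desk-scale simulation fixtures.

The default fixture is a deliberately small acquisition — 64 px HR grid,
16 px LR captures (ratio 4), a 7x7 LED grid whose adjacent pupil windows
overlap by ~62% in area — chosen so that a full reconstruction takes well
under a second while preserving the structure of a real acquisition: a
bright-field core of captures inside the objective NA surrounded by
dark-field captures, >60% spectral overlap between neighbours, and a
synthetic NA several times the objective NA.

Ground-truth phantoms are band-limited to the frequency region actually
covered by the synthetic aperture; energy outside that region is invisible
to every algorithm and would only add a constant floor to relative errors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .degrade import DegradationSpec, apply_degradation
from .optics import (
    CaptureStack,
    LEDGeometry,
    OpticalConfig,
    OperatorPlan,
    Pupil,
    fft2c,
    forward_capture,
    freq_pixel_shifts,
    led_wavevectors,
    pupil_mask,
    pupil_overlap_fraction,
)
from .phantom import bandlimit, make_phantom


def default_optics(n_hr: int = 64, ratio: int = 4) -> OpticalConfig:
    """0.1-NA objective at 0.64 um with a 2 um LR pixel: pupil radius is
    exactly 5 LR frequency pixels."""
    if n_hr % ratio:
        raise ValueError("n_hr must be a multiple of ratio")
    return OpticalConfig(
        na_objective=0.1,
        wavelength_um=0.64,
        pixel_size_lr_um=2.0,
        n_hr=n_hr,
        n_lr=n_hr // ratio,
    )


def default_geometry() -> LEDGeometry:
    """7x7 LEDs, 3 mm pitch, 50 mm height: adjacent captures step 3 frequency
    pixels, giving ~62% pupil overlap against the 5 px pupil."""
    return LEDGeometry(rows=7, cols=7, pitch_mm=3.0, height_mm=50.0)


def paper_scale_optics() -> OpticalConfig:
    """A larger configuration shaped like published FPM simulations
    (0.08-NA objective, 625 nm, 15x15 LED grid geometry in
    :func:`paper_scale_geometry`); 256 px HR grid with ratio 8."""
    return OpticalConfig(
        na_objective=0.08,
        wavelength_um=0.625,
        pixel_size_lr_um=3.5,
        n_hr=256,
        n_lr=32,
    )


def paper_scale_geometry() -> LEDGeometry:
    return LEDGeometry(rows=15, cols=15, pitch_mm=4.0, height_mm=84.8)


def covered_bandlimit_radius(
    wavevectors: np.ndarray, pupil: Pupil, optics: OpticalConfig, margin_px: float = 1.0
) -> float:
    """Radius of the largest centered frequency disk fully inside the
    synthetic-aperture coverage, minus a safety margin."""
    cov = OperatorPlan(wavevectors, pupil, optics).coverage() > 0
    n = optics.n_hr
    c = n // 2
    iy, ix = np.mgrid[0:n, 0:n]
    dist = np.hypot(iy - c, ix - c)
    uncovered = dist[~cov]
    r = float(uncovered.min()) - 1.0 if uncovered.size else float(dist.max())
    return max(r - margin_px, 1.0)


def min_adjacent_overlap(
    geometry: LEDGeometry, optics: OpticalConfig, pupil: Pupil
) -> float:
    """Smallest area-overlap fraction between spectrally adjacent pupils.

    "Adjacent" means nearest spectral neighbours: for every capture we find
    the closest distinct window centre and report the overlap fraction at the
    largest such spacing.
    """
    shifts = freq_pixel_shifts(led_wavevectors(geometry, optics), optics).astype(float)
    if len(shifts) < 2:
        return 1.0
    diff = shifts[:, None, :] - shifts[None, :, :]
    dist = np.hypot(diff[..., 0], diff[..., 1])
    np.fill_diagonal(dist, np.inf)
    nearest = dist.min(axis=1)
    nearest = nearest[np.isfinite(nearest)]
    return pupil_overlap_fraction(float(nearest.max()), pupil.radius_px)


@dataclass
class FixtureSet:
    """One synthetic acquisition: truth, ideal captures, degraded captures."""

    truth_field: np.ndarray
    truth_spectrum: np.ndarray
    ideal_stack: CaptureStack
    stack: CaptureStack
    optics: OpticalConfig
    geometry: LEDGeometry
    degradation: DegradationSpec
    seed: int
    overlap: float


def make_fixture(
    seed: int = 0,
    degradation: DegradationSpec = DegradationSpec(),
    kind: str = "smooth",
    optics: OpticalConfig | None = None,
    geometry: LEDGeometry | None = None,
    bandlimit_truth: bool = True,
) -> FixtureSet:
    """Generate a complete synthetic acquisition.

    The phantom is drawn from ``seed``, band-limited to the covered synthetic
    aperture (unless disabled), propagated through the ideal forward model,
    and finally degraded per ``degradation``.  Same seed, bit-identical
    output.
    """
    optics = optics or default_optics()
    geometry = geometry or default_geometry()
    pupil = pupil_mask(optics)
    wv = led_wavevectors(geometry, optics)

    field = make_phantom(kind, n=optics.n_hr, seed=seed)
    if bandlimit_truth:
        field = bandlimit(field, covered_bandlimit_radius(wv, pupil, optics))
    spectrum = fft2c(field)

    ordering = np.stack(
        np.unravel_index(np.arange(geometry.n_leds), (geometry.rows, geometry.cols)),
        axis=1,
    )
    ideal = forward_capture(spectrum, wv, pupil, optics, ordering=ordering)
    degraded = apply_degradation(degradation, ideal, optics, spectrum=spectrum)
    overlap = min_adjacent_overlap(geometry, optics, pupil)
    return FixtureSet(
        truth_field=field,
        truth_spectrum=spectrum,
        ideal_stack=ideal,
        stack=degraded,
        optics=optics,
        geometry=geometry,
        degradation=degradation,
        seed=seed,
        overlap=overlap,
    )
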