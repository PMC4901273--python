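"""Measurement degradation models for simulated FPM captures.

Four degradations are supported, mirroring what real acquisitions suffer:

* additive Gaussian read noise, parameterized by its standard deviation as a
  fraction of the brightest ideal pixel;
* Poisson shot noise, parameterized by the expected photon count at the
  brightest ideal pixel;
* multiplicative speckle from highly coherent (laser) illumination,
  c = b (1 + n) with n ~ Uniform(-amplitude, +amplitude);
* pupil-location error: Gaussian perturbation of the per-LED illumination
  wavevectors used to *synthesize* the data, while reconstruction still
  assumes the nominal geometry.

All operations take explicit seeds and are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .optics import CaptureStack, OpticalConfig, forward_capture

KINDS = ("none", "gaussian", "poisson", "speckle", "pupil_location")


@dataclass(frozen=True)
class DegradationSpec:
    """Which degradation to apply and how strongly.

    ``level`` means: relative std for ``gaussian``; peak photon count for
    ``poisson``; uniform-noise amplitude for ``speckle``; wavevector sigma in
    LR frequency pixels for ``pupil_location``; ignored for ``none``.
    """

    kind: str = "none"
    level: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown degradation kind {self.kind!r}; one of {KINDS}")
        if self.level < 0:
            raise ValueError("degradation level must be >= 0")


def add_gaussian(stack: CaptureStack, level: float, seed: int) -> CaptureStack:
    """Additive Gaussian noise with std = level * max(b), clipped at zero.

    Clipping keeps intensities physical (sensors report nonnegative counts)
    and keeps the downstream Poisson log-likelihood well defined.
    """
    b = stack.images
    rng = np.random.default_rng(seed)
    sigma = level * (b.max() if b.size else 0.0)
    c = b + rng.normal(0.0, 1.0, size=b.shape) * sigma
    return stack.replace_images(np.clip(c, 0.0, None))


def add_poisson(stack: CaptureStack, photon_peak: float, seed: int) -> CaptureStack:
    """Poisson shot noise at a given expected photon count for the brightest
    ideal pixel; the returned stack is rescaled back to the input units."""
    if photon_peak <= 0:
        raise ValueError("photon_peak must be positive")
    b = stack.images
    bmax = b.max()
    if bmax == 0:
        return stack.replace_images(b.copy())
    rng = np.random.default_rng(seed)
    gain = photon_peak / bmax
    counts = rng.poisson(b * gain)
    return stack.replace_images(counts / gain)


def add_speckle(stack: CaptureStack, amplitude: float, seed: int) -> CaptureStack:
    """Multiplicative speckle c = b (1 + n), n ~ Uniform(-amplitude, amplitude).

    ``amplitude`` must lie in [0, 1] so intensities stay nonnegative.
    """
    if not 0.0 <= amplitude <= 1.0:
        raise ValueError("speckle amplitude must be in [0, 1]")
    b = stack.images
    rng = np.random.default_rng(seed)
    n = rng.uniform(-amplitude, amplitude, size=b.shape)
    return stack.replace_images(b * (1.0 + n))


def perturb_wavevectors(
    wavevectors: np.ndarray, sigma_px: float, optics: OpticalConfig, seed: int
) -> np.ndarray:
    """Gaussian perturbation of illumination wavevectors.

    ``sigma_px`` is expressed in LR frequency pixels (scale-free across grid
    sizes); each (fx, fy) component receives i.i.d. N(0, (sigma_px*delta_f)^2).
    """
    if sigma_px < 0:
        raise ValueError("sigma_px must be >= 0")
    wv = np.atleast_2d(np.asarray(wavevectors, dtype=float))
    rng = np.random.default_rng(seed)
    return wv + rng.normal(0.0, sigma_px * optics.delta_f, size=wv.shape)


def apply_degradation(
    spec: DegradationSpec,
    stack: CaptureStack,
    optics: OpticalConfig,
    spectrum: np.ndarray | None = None,
) -> CaptureStack:
    """Apply ``spec`` to an ideal stack.

    ``pupil_location`` re-synthesizes the captures from ``spectrum`` with
    perturbed wavevectors while keeping the nominal wavevectors in the
    returned stack (the reconstruction will assume the wrong geometry, which
    is the point of that degradation).
    """
    if spec.kind == "none":
        return stack.replace_images(stack.images.copy())
    if spec.kind == "gaussian":
        return add_gaussian(stack, spec.level, spec.seed)
    if spec.kind == "poisson":
        return add_poisson(stack, spec.level, spec.seed)
    if spec.kind == "speckle":
        return add_speckle(stack, spec.level, spec.seed)
    if spec.kind == "pupil_location":
        if spectrum is None:
            raise ValueError("pupil_location degradation needs the true HR spectrum")
        wrong = perturb_wavevectors(stack.wavevectors, spec.level, optics, spec.seed)
        degraded = forward_capture(spectrum, wrong, stack.pupil, optics)
        return stack.replace_images(degraded.images)
    raise AssertionError("unreachable")
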