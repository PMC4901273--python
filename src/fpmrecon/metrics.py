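"""Evaluation of reconstructed complex fields against ground truth.

Intensity measurements |a_i z|^2 cannot distinguish z from e^{j phi} z, so
any sensible distance must first align the global phase.  The headline
metric is the relative error

    RE(z, z_ref) = min_phi || z e^{-j phi} - z_ref ||_2 / || z_ref ||_2,

zero exactly when the two fields agree up to a global phase.  Under the
package's unitary transform convention the RE of two spectra equals the RE
of their spatial fields.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def align_global_phase(z: np.ndarray, z_ref: np.ndarray) -> float:
    """Phase phi* minimizing ||z e^{-j phi} - z_ref||, i.e. arg <z_ref, z>.

    Returns 0 when the inner product vanishes (orthogonal fields: every phase
    is equally good).
    """
    inner = np.vdot(np.asarray(z_ref), np.asarray(z))
    if inner == 0:
        return 0.0
    return float(np.angle(inner))


def relative_error(z: np.ndarray, z_ref: np.ndarray) -> float:
    """Global-phase-invariant normalized distance between complex arrays."""
    z = np.asarray(z)
    z_ref = np.asarray(z_ref)
    if z.shape != z_ref.shape:
        raise ValueError(f"shape mismatch: {z.shape} vs {z_ref.shape}")
    ref_norm = np.linalg.norm(z_ref)
    if ref_norm == 0:
        raise ValueError("reference field has zero norm")
    phi = align_global_phase(z, z_ref)
    return float(np.linalg.norm(z * np.exp(-1j * phi) - z_ref) / ref_norm)


@dataclass(frozen=True)
class EvalReport:
    """Relative errors of a reconstruction in both domains, plus the aligning
    global phase (radians)."""

    re_spectrum: float
    re_field: float
    aligned_phase: float

    def as_dict(self) -> dict:
        return {
            "re_spectrum": self.re_spectrum,
            "re_field": self.re_field,
            "aligned_phase_rad": self.aligned_phase,
        }


def evaluate_spectra(z: np.ndarray, z_ref: np.ndarray) -> EvalReport:
    """Score a recovered HR spectrum against the ground-truth spectrum."""
    from .optics import ifft2c  # local import to avoid a cycle

    return EvalReport(
        re_spectrum=relative_error(z, z_ref),
        re_field=relative_error(ifft2c(z), ifft2c(z_ref)),
        aligned_phase=align_global_phase(z, z_ref),
    )
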