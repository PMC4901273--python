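"""FPM phase-retrieval reconstruction algorithms.

Four algorithms recover the HR spectrum ``z`` from LR intensity captures
``c_i = |a_i z|^2``:

* ``ap_run`` — alternating projections: sweep the captures, replace each LR
  field's amplitude with the measured one, and write the result back into the
  pupil-supported region of the spectrum.
* ``wfp_run`` — Wirtinger-flow gradient descent on the intensity least-squares
  objective sum_i (|a_i z|^2 - c_i)^2.
* ``pwfp_run`` — gradient descent on the Poisson negative log-likelihood
  sum_i [|a_i z|^2 - c_i log |a_i z|^2], matching the shot-noise statistics of
  photon detection.
* ``tpwfp_run`` — the Poisson objective with a *truncated* gradient: per
  iteration, measurements whose residual exceeds a signal-dependent threshold
  are labelled outliers and dropped from the gradient sum, which protects the
  descent direction against noise and geometry errors.  ``pwfp_run`` is the
  a_h = inf special case and shares the identical code path.

The gradient update is z <- z - (mu^(k) / nu) * grad with
mu^(k) = min(1 - exp(-k/k0), mu_max) growing from ~0 to mu_max, and
nu = lambda_max(sum_i a_i^H a_i) / 2 for the Poisson objectives (times
max(c) for the intensity objective).  Dividing by this curvature scale makes
mu dimensionless and independent of grid sizes and intensity scaling; the
factor is calibrated once so that the standard step cap mu_max = 0.1 brings
the Poisson solvers to their clean-data plateau within the conventional
200-iteration budget (and WFP within 1000) while staying several-fold below
the observed stability limit.

All solvers operate on the measured synthetic aperture: the starting
spectrum is projected onto the frequency support covered by at least one
pupil window.  Frequencies never measured receive zero gradient and would
otherwise keep whatever interpolation artifacts the initialization put
there.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from skimage.transform import resize

from .metrics import relative_error
from .optics import (
    CaptureStack,
    OpticalConfig,
    OperatorPlan,
    fft2c,
    ifft2c,
)


@dataclass(frozen=True)
class TruncationParams:
    """Outlier-truncation settings for TPWFP.

    ``a_h`` scales the residual threshold (larger keeps more measurements;
    ``inf`` disables truncation and yields PWFP).  ``eps_rel`` sets the guard
    eps_b = eps_rel * max(c) protecting divisions and logs at dark pixels.
    """

    a_h: float = 25.0
    eps_rel: float = 1e-12

    def __post_init__(self) -> None:
        if not self.a_h > 0:
            raise ValueError("a_h must be positive")
        if self.eps_rel <= 0:
            raise ValueError("eps_rel must be positive")


@dataclass(frozen=True)
class StepSchedule:
    """Gradient-step schedule mu^(k) = min(1 - exp(-k / k0), mu_max)."""

    k0: float = 330.0
    mu_max: float = 0.1

    def __post_init__(self) -> None:
        if self.k0 <= 0:
            raise ValueError("k0 must be positive")
        if not 0.0 < self.mu_max <= 1.0:
            raise ValueError("mu_max must be in (0, 1]")

    def mu(self, k: int) -> float:
        return min(1.0 - math.exp(-k / self.k0), self.mu_max)


def step_size(k: int, sched: StepSchedule) -> float:
    """Step size mu^(k); small at the start, saturating at mu_max."""
    if k < 0:
        raise ValueError("iteration index must be >= 0")
    return sched.mu(k)


@dataclass
class ReconResult:
    """Recovered HR spectrum, its spatial field, and per-iteration history."""

    spectrum: np.ndarray
    field: np.ndarray
    history: pd.DataFrame
    algorithm: str
    params: dict = field(default_factory=dict)

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.field)

    @property
    def phase(self) -> np.ndarray:
        return np.angle(self.field)


# ---------------------------------------------------------------------------
# Initialization
# ---------------------------------------------------------------------------


def initialize_spectrum(stack: CaptureStack, optics: OpticalConfig) -> np.ndarray:
    """Initial HR spectrum: transform of the bicubically up-sampled amplitude
    (sqrt of intensity) of the most nearly on-axis capture, with zero phase."""
    if stack.n_leds == 0:
        raise ValueError("capture stack is empty")
    center = int(np.argmin(np.hypot(stack.wavevectors[:, 0], stack.wavevectors[:, 1])))
    amp = np.sqrt(np.clip(stack.images[center], 0.0, None))
    up = resize(
        amp,
        (optics.n_hr, optics.n_hr),
        order=3,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )
    up = np.clip(up, 0.0, None)
    return fft2c(up.astype(complex))


# ---------------------------------------------------------------------------
# Objective, gradient, truncation
# ---------------------------------------------------------------------------


def poisson_negloglik(
    c: np.ndarray, b_hat: np.ndarray, eps_b: float | None = None
) -> float:
    """Negative Poisson log-likelihood sum_i [b_i^ - c_i log(b_i^ + eps_b)],
    up to the model-independent log(c_i!) constant.  Pixels with c_i = 0
    contribute b_i^ (the 0*log 0 convention)."""
    c = np.asarray(c, dtype=float)
    b_hat = np.asarray(b_hat, dtype=float)
    if eps_b is None:
        eps_b = 1e-12 * (c.max() if c.size else 1.0)
    pos = c > 0
    return float(b_hat.sum() - np.sum(c[pos] * np.log(b_hat[pos] + eps_b)))


def intensity_sse(c: np.ndarray, b_hat: np.ndarray) -> float:
    """Intensity least-squares objective sum_i (b_i^ - c_i)^2."""
    return float(np.sum((np.asarray(b_hat) - np.asarray(c)) ** 2))


def truncation_mask(
    c: np.ndarray, b_hat: np.ndarray, amp: np.ndarray, a_h: float
) -> np.ndarray:
    """Boolean keep-mask of the truncation rule.

    Measurement i is kept iff

        |c_i - b_i^| <= a_h * mean_j|c_j - b_j^| * (|a_i z| / A_l(i))

    where A_l(i) is the peak reconstructed amplitude |a z| within the capture
    that pixel i belongs to (for 3-D stacks; the global peak otherwise).  The
    threshold is proportional to the mean residual and to the *relative*
    signal strength of the pixel, so the rule is invariant to global scaling
    of z and c and — through the per-capture normalization — to the orders-of
    magnitude brightness gap between bright-field and dark-field captures.
    Degenerate cases (all residuals zero, or a_h = inf) keep everything.
    """
    r = np.abs(np.asarray(c, dtype=float) - np.asarray(b_hat, dtype=float))
    if not np.isfinite(a_h):
        return np.ones_like(r, dtype=bool)
    amp = np.asarray(amp, dtype=float)
    if r.ndim == 3:
        peak = amp.max(axis=(1, 2), keepdims=True)
    else:
        peak = amp.max() if amp.size else 0.0
    mean_r = r.mean()
    if mean_r == 0.0 or np.all(peak == 0.0):
        return np.ones_like(r, dtype=bool)
    return r <= a_h * mean_r * (amp / np.maximum(peak, np.finfo(float).tiny))


def truncation_indices(
    z: np.ndarray,
    stack: CaptureStack,
    optics: OpticalConfig,
    params: TruncationParams = TruncationParams(),
) -> np.ndarray:
    """Per-measurement keep-mask (same shape as ``stack.images``) of the
    truncation rule evaluated at the current iterate; recomputed every
    iteration by the solver."""
    fields = OperatorPlan(stack.wavevectors, stack.pupil, optics).fields(z)
    amp = np.abs(fields)
    return truncation_mask(stack.images, amp**2, amp, params.a_h)


def _poisson_weights(c: np.ndarray, b_hat: np.ndarray, eps_b: float) -> np.ndarray:
    return 1.0 - c / (b_hat + eps_b)


def wirtinger_gradient_poisson(
    z: np.ndarray,
    stack: CaptureStack,
    optics: OpticalConfig,
    eps_rel: float = 1e-12,
) -> np.ndarray:
    """Wirtinger gradient of the Poisson negative log-likelihood,
    sum_i (1 - c_i/(b_i^ + eps_b)) a_i^H (a_i z), assembled with FFTs."""
    plan = OperatorPlan(stack.wavevectors, stack.pupil, optics)
    fields = plan.fields(z)
    b_hat = np.abs(fields) ** 2
    eps_b = eps_rel * max(stack.images.max(), np.finfo(float).tiny)
    w = _poisson_weights(stack.images, b_hat, eps_b)
    return plan.adjoint(w * fields)


def wirtinger_gradient_intensity(
    z: np.ndarray, stack: CaptureStack, optics: OpticalConfig
) -> np.ndarray:
    """Wirtinger gradient of the intensity objective,
    sum_i 2 (b_i^ - c_i) a_i^H (a_i z)."""
    plan = OperatorPlan(stack.wavevectors, stack.pupil, optics)
    fields = plan.fields(z)
    b_hat = np.abs(fields) ** 2
    return plan.adjoint(2.0 * (b_hat - stack.images) * fields)


def truncated_gradient(
    z: np.ndarray,
    stack: CaptureStack,
    optics: OpticalConfig,
    params: TruncationParams = TruncationParams(),
    xi: np.ndarray | None = None,
) -> np.ndarray:
    """Poisson Wirtinger gradient restricted to the kept index set ``xi``
    (computed from the truncation rule when not supplied)."""
    plan = OperatorPlan(stack.wavevectors, stack.pupil, optics)
    fields = plan.fields(z)
    amp = np.abs(fields)
    b_hat = amp**2
    if xi is None:
        xi = truncation_mask(stack.images, b_hat, amp, params.a_h)
    eps_b = params.eps_rel * max(stack.images.max(), np.finfo(float).tiny)
    w = _poisson_weights(stack.images, b_hat, eps_b) * xi
    return plan.adjoint(w * fields)


# ---------------------------------------------------------------------------
# Gradient-descent solvers
# ---------------------------------------------------------------------------


def _history_frame(rows: list[dict]) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=["iter", "objective", "xi_size", "step", "re"])


def _gradient_descent(
    stack: CaptureStack,
    optics: OpticalConfig,
    *,
    objective: str,
    a_h: float,
    eps_rel: float,
    sched: StepSchedule,
    iters: int,
    z0: np.ndarray | None,
    truth: np.ndarray | None,
    early_stop_tol: float | None,
    algorithm: str,
    params_echo: dict,
) -> ReconResult:
    if iters < 0:
        raise ValueError("iters must be >= 0")
    plan = OperatorPlan(stack.wavevectors, stack.pupil, optics)
    z = initialize_spectrum(stack, optics) if z0 is None else np.array(z0, dtype=complex)
    z = z * (plan.coverage() > 0)  # reconstruct on the measured aperture only
    c = stack.images
    m_total = c.size
    eps_b = eps_rel * max(c.max(), np.finfo(float).tiny)
    nu = 0.5 * plan.operator_norm_sq()
    if objective == "intensity":
        nu *= max(c.max(), np.finfo(float).tiny)

    rows: list[dict] = []
    recent: list[float] = []
    for k in range(iters + 1):
        fields = plan.fields(z)
        amp = np.abs(fields)
        b_hat = amp**2
        if objective == "poisson":
            obj = poisson_negloglik(c, b_hat, eps_b)
            xi = truncation_mask(c, b_hat, amp, a_h)
            w = _poisson_weights(c, b_hat, eps_b) * xi
            xi_size = int(xi.sum())
        else:
            obj = intensity_sse(c, b_hat)
            w = 2.0 * (b_hat - c)
            xi_size = m_total
        re = relative_error(z, truth) if truth is not None else np.nan
        mu = sched.mu(k + 1)
        rows.append(
            {"iter": k, "objective": obj, "xi_size": xi_size, "step": mu, "re": re}
        )
        if k == iters:
            break
        if early_stop_tol is not None:
            recent.append(obj)
            if len(recent) > 11:
                recent.pop(0)
            if len(recent) == 11:
                ref = abs(recent[0]) + np.finfo(float).tiny
                if abs(recent[0] - recent[-1]) / ref < early_stop_tol:
                    break
        grad = plan.adjoint(w * fields)
        z = z - (mu / nu) * grad
        if not np.all(np.isfinite(z)):
            raise FloatingPointError(
                f"{algorithm}: non-finite iterate at iteration {k + 1}"
            )

    return ReconResult(
        spectrum=z,
        field=ifft2c(z),
        history=_history_frame(rows),
        algorithm=algorithm,
        params=params_echo,
    )


def tpwfp_run(
    stack: CaptureStack,
    optics: OpticalConfig,
    params: TruncationParams = TruncationParams(),
    sched: StepSchedule = StepSchedule(),
    iters: int = 200,
    z0: np.ndarray | None = None,
    truth: np.ndarray | None = None,
    early_stop_tol: float | None = None,
) -> ReconResult:
    """Truncated Poisson Wirtinger flow (the robust reconstruction).

    Per iteration: recompute the kept index set from the truncation rule,
    form the Poisson gradient over the kept measurements, and take a
    normalized gradient step.  Default budget: 200 iterations.
    """
    return _gradient_descent(
        stack,
        optics,
        objective="poisson",
        a_h=params.a_h,
        eps_rel=params.eps_rel,
        sched=sched,
        iters=iters,
        z0=z0,
        truth=truth,
        early_stop_tol=early_stop_tol,
        algorithm="tpwfp",
        params_echo={"a_h": params.a_h, "k0": sched.k0, "mu_max": sched.mu_max, "iters": iters},
    )


def pwfp_run(
    stack: CaptureStack,
    optics: OpticalConfig,
    sched: StepSchedule = StepSchedule(),
    iters: int = 200,
    z0: np.ndarray | None = None,
    truth: np.ndarray | None = None,
    early_stop_tol: float | None = None,
    eps_rel: float = 1e-12,
) -> ReconResult:
    """Poisson Wirtinger flow: TPWFP with truncation disabled (a_h = inf);
    delegates to the identical code path, so iterates match exactly."""
    res = tpwfp_run(
        stack,
        optics,
        params=TruncationParams(a_h=np.inf, eps_rel=eps_rel),
        sched=sched,
        iters=iters,
        z0=z0,
        truth=truth,
        early_stop_tol=early_stop_tol,
    )
    return replace(res, algorithm="pwfp")


def wfp_run(
    stack: CaptureStack,
    optics: OpticalConfig,
    sched: StepSchedule = StepSchedule(),
    iters: int = 1000,
    z0: np.ndarray | None = None,
    truth: np.ndarray | None = None,
    early_stop_tol: float | None = None,
) -> ReconResult:
    """Wirtinger flow on the intensity least-squares objective.

    Default budget: 1000 iterations (intensity descent converges more slowly
    than the Poisson objectives).
    """
    return _gradient_descent(
        stack,
        optics,
        objective="intensity",
        a_h=np.inf,
        eps_rel=1e-12,
        sched=sched,
        iters=iters,
        z0=z0,
        truth=truth,
        early_stop_tol=early_stop_tol,
        algorithm="wfp",
        params_echo={"k0": sched.k0, "mu_max": sched.mu_max, "iters": iters},
    )


# ---------------------------------------------------------------------------
# Alternating projections
# ---------------------------------------------------------------------------


def _capture_order(stack: CaptureStack, order: str) -> np.ndarray:
    if order == "raster":
        return np.arange(stack.n_leds)
    if order == "spiral":
        # centre-outward: sort by illumination-frequency magnitude, then angle
        mag = np.hypot(stack.wavevectors[:, 0], stack.wavevectors[:, 1])
        ang = np.arctan2(stack.wavevectors[:, 1], stack.wavevectors[:, 0])
        return np.lexsort((ang, np.round(mag, 12)))
    raise ValueError(f"unknown capture order {order!r}")


def ap_run(
    stack: CaptureStack,
    optics: OpticalConfig,
    iters: int = 100,
    z0: np.ndarray | None = None,
    truth: np.ndarray | None = None,
    order: str = "raster",
) -> ReconResult:
    """Alternating projections (the conventional FPM stitcher).

    Each iteration sweeps the captures once; for every capture the LR field's
    amplitude is replaced by the measured sqrt(c_i) and the corrected
    sub-spectrum is written back inside the pupil support.  Default budget:
    100 iterations.
    """
    if iters < 0:
        raise ValueError("iters must be >= 0")
    plan = OperatorPlan(stack.wavevectors, stack.pupil, optics)
    z = initialize_spectrum(stack, optics) if z0 is None else np.array(z0, dtype=complex)
    z = z * (plan.coverage() > 0)  # reconstruct on the measured aperture only
    mask = stack.pupil.mask
    s = plan.scale
    seq = _capture_order(stack, order)
    sqrt_c = np.sqrt(np.clip(stack.images, 0.0, None))

    rows: list[dict] = []
    n = optics.n_lr
    for k in range(iters + 1):
        b_hat = np.abs(plan.fields(z)) ** 2
        rows.append(
            {
                "iter": k,
                "objective": intensity_sse(stack.images, b_hat),
                "xi_size": stack.images.size,
                "step": np.nan,
                "re": relative_error(z, truth) if truth is not None else np.nan,
            }
        )
        if k == iters:
            break
        for i in seq:
            r0 = int(plan.rows[i, 0])
            c0 = int(plan.cols[i, 0])
            window = z[r0 : r0 + n, c0 : c0 + n]
            psi = s * ifft2c(window * mask)
            denom = np.abs(psi)
            guard = 1e-12 * denom.max() + np.finfo(float).tiny
            psi = sqrt_c[i] * psi / (denom + guard)
            sub = fft2c(psi) / s
            window[mask] = sub[mask]
        if not np.all(np.isfinite(z)):
            raise FloatingPointError(f"ap: non-finite iterate at iteration {k + 1}")

    return ReconResult(
        spectrum=z,
        field=ifft2c(z),
        history=_history_frame(rows),
        algorithm="ap",
        params={"iters": iters, "order": order},
    )


ALGORITHMS = {
    "ap": (ap_run, 100),
    "wfp": (wfp_run, 1000),
    "pwfp": (pwfp_run, 200),
    "tpwfp": (tpwfp_run, 200),
}
"""Algorithm registry: name -> (runner, default iteration budget)."""
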