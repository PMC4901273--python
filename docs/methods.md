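# Methods

## Image formation model

Fourier ptychographic microscopy (FPM) acquires a sequence of low-resolution
(LR) intensity images of a thin sample under tilted coherent plane-wave
illumination from an LED array.  For an LED at lateral offset (dx, dy) and
height h below the sample, the illumination carries spatial frequency

    fx = -(dx / sqrt(dx^2 + dy^2 + h^2)) / lambda,   fy analogously,

which translates the sample's spatial spectrum across the objective pupil.
With an ideal binary pupil of cutoff NA/lambda, each capture is

    c_i = | F^-1 [ P . S_i (Phi) ] |^2 ,

where Phi is the high-resolution (HR) spectrum, S_i extracts the n_lr x n_lr
window centred on the frequency pixel nearest the illumination frequency,
and P is the pupil mask.  Stacking all captures gives the phase-retrieval
problem b = |A z|^2 with z the vectorized HR spectrum and A a linear
operator (window extraction, pupil masking, inverse Fourier transform).

**Conventions.**  Spectra are stored centred (DC at index n//2); transforms
are the centred unitary FFT.  LR fields carry the fixed amplitude scale
s = n_lr/n_hr, so a unit-amplitude object yields unit-intensity bright-field
captures.  An LED at +x moves the sampled window to -x in frequency.  Window
positions are rounded to the nearest frequency pixel; windows leaving the HR
grid raise an error (physical spectra do not wrap).  The HR/LR ratio must be
integral.  Only the self-consistency of these choices is observable; the
dense-matrix oracle (`dense_operator`) bakes in the identical conventions so
FFT and matrix paths agree to 1e-10.

## Reconstruction algorithms

All four algorithms start from the spectrum of the bicubically up-sampled
amplitude (sqrt of intensity) of the most nearly on-axis capture, with zero
phase, projected onto the *measured support* — the set of frequency pixels
covered by at least one pupil window.  Frequencies never measured receive
zero gradient under every objective; without the projection they would
permanently retain bicubic interpolation artifacts (about 13% of the
residual squared error on the default fixture).

* **AP** (alternating projections): sweep the captures; replace each LR
  field's amplitude by the measured sqrt(c_i); write the corrected
  sub-spectrum back inside the pupil support.  Capture order is raster by
  default, with an optional centre-outward spiral.
* **WFP**: Wirtinger gradient descent on the intensity least squares
  sum_i (|a_i z|^2 - c_i)^2.
* **PWFP**: Wirtinger descent on the Poisson negative log-likelihood
  sum_i [ |a_i z|^2 - c_i log |a_i z|^2 ] (the log c_i! term is constant and
  dropped), matching the photon-counting statistics of real detectors.
* **TPWFP**: PWFP with a per-iteration truncated gradient (below).  PWFP is
  exactly TPWFP with a_h = inf and shares the same code path, so the two are
  identical iterate-for-iterate.

### Truncation rule

At each iteration, measurement i enters the gradient only if

    |c_i - b^_i|  <=  a_h * mean_j |c_j - b^_j| * ( |a_i z| / A_l(i) ),

with b^_i = |a_i z|^2 and A_l(i) the peak reconstructed amplitude within the
capture that pixel i belongs to.  The threshold is proportional to the mean
residual and to the pixel's *relative* signal strength, so it is invariant
to global rescaling of z and c.  Two normalizer details are deliberate
choices, since the absolute scale of a signal-proportional threshold is
convention-dependent:

* Normalizing |a_i z| per capture (rather than globally) prevents dark-field
  captures — orders of magnitude dimmer than bright-field ones, yet the sole
  carriers of high-frequency information — from being systematically
  truncated.
* The constant is calibrated so the published operating point a_h = 25 is
  the useful default: on clean data at convergence it keeps >99% of
  measurements, while under geometry errors it rejects the gross outliers.
  With a global mean or rms normalizer the useful range of a_h sits near
  5-10 instead.

Degenerate inputs (all residuals zero, a_h = inf, or an all-zero iterate)
keep every measurement.

### Step size

Updates are z <- z - (mu_k / nu) * grad with the standard ramp
mu_k = min(1 - exp(-k/k0), mu_max), defaults k0 = 330 and mu_max = 0.1: tiny
steps early (where the Poisson weights 1 - c_i/b^_i can be large and
erratic), saturating after ~35 iterations.

nu makes mu dimensionless.  Because the frame operator sum_i a_i^H a_i is
diagonal in the centred frequency basis, its largest eigenvalue is exactly
s^2 * (maximum pupil-coverage count); nu is half that value for the Poisson
objectives and additionally scaled by max(c) for the intensity objective
(whose curvature is proportional to the intensity scale).  The factor is
calibrated once on clean data so that the conventional iteration budgets —
200 for TPWFP/PWFP, 1000 for WFP, 100 for AP — land at the objective
plateau, and it leaves several-fold margin to the empirically observed
stability limit under every degradation model.  Poisson weights are guarded
by eps_b = 1e-12 * max(c) against division by exactly-zero model
intensities at dark pixels.

Budgets are fixed iteration counts; an optional early stop halts when the
relative objective change over 10 iterations falls below a tolerance
(default off, so runs are exactly reproducible).  Non-finite iterates raise
immediately with the iteration index.

## Degradation models

* **Gaussian**: c = max(b + N(0, (level * max b)^2), 0).  The level is the
  std as a fraction of the brightest ideal pixel.  Clipping keeps
  intensities physical; it also means heavy Gaussian noise violates the
  Poisson model at dark pixels, which is why the intensity objective (WFP)
  wins in that regime — a behaviour this package reproduces.
* **Poisson**: c = Poisson(b * g)/g with gain g = peak / max(b);
  parameterized by the expected photon count at the brightest pixel so
  sweeps are monotone in SNR.
* **Speckle**: c = b(1 + n), n ~ Uniform(-amplitude, +amplitude), the
  multiplicative fluctuation of highly coherent (laser) illumination.
  Amplitudes above 1 are rejected (they would produce negative intensity).
* **Pupil-location error**: each illumination wavevector used to
  *synthesize* the data is perturbed by N(0, (sigma_px * delta_f)^2) per
  component, while reconstruction assumes the nominal geometry.  sigma_px is
  expressed in LR frequency pixels.  Note that a given sigma_px is a larger
  *relative* pupil displacement on a small grid than on a full-scale one
  (1 px is 20% of the default fixture's 5 px pupil radius but only ~7% of a
  full-scale ~14 px pupil); robustness comparisons here use 1 px, the
  threshold sweep the scale-matched 0.5 px.

All randomness flows through explicit integer seeds; equal seeds give
bit-identical outputs.

## Evaluation

Intensity data determine z only up to a global phase, so the quality metric
is the relative error

    RE(z, z_ref) = min_phi || z e^{-j phi} - z_ref || / || z_ref || ,

with the minimizing phase available in closed form as arg <z_ref, z>.  The
denominator is the ground truth's norm; no amplitude rescaling is applied
(the forward model fixes the scale).  Under the unitary transform convention
RE is identical in the spectrum and spatial domains.

## Synthetic data

The default fixture is a deliberately small acquisition that preserves the
structure of a published simulation while running in well under a second:
64 px HR grid, 16 px LR captures (ratio 4), 7x7 LEDs, pupil radius exactly
5 frequency px, LED spectral step 3 px.  Adjacent pupils overlap by 62.4% in
area — essentially the ~64% of the reference 15x15-LED geometry and above
the ~60% commonly quoted as the minimum for reliable stitching.  The grid
mixes 9 bright-field with 40 dark-field captures.  Physical parameters
(NA 0.1, lambda 0.64 um, 2 um LR pixel, 3 mm pitch, 50 mm height) realize
those pixel values exactly.

Phantoms are procedural (smooth Gaussian-filtered random fields by default;
flat, bar, disk and user-image variants), with amplitude in [0.1, 1] —
avoiding the zero-amplitude degeneracy — and phase in [0, pi].  Fixture
ground truths are band-limited to the largest centred disk fully inside the
synthetic-aperture coverage: energy outside the measured band is invisible
to every algorithm and would only add a constant floor to all REs.

What the generator does *not* emulate: aberrated or estimated pupils,
LED-position search, sample thickness/3-D scattering, partial coherence,
detector MTF and quantization, compound noise.  Passing tests therefore
demonstrate correctness of the operators and the comparative robustness of
the algorithms under the modelled degradations, not end-to-end performance
on real microscope data.

## Problem sizes used in the shipped checks

The test suite and the results script use the 64 px default fixture with
default budgets; robustness comparisons average 10 noise realizations per
condition (the full-scale protocol in the literature uses 20 on a 512 px
grid) and the threshold sweep 12.  Oracle comparisons (dense matrix, finite
differences, adjoint/Parseval identities) run on 8 px toys where the dense
operator is exact and cheap.

## Known limitations

* The truncation threshold's absolute scale is a package convention (see
  above); reconstructions match the published *behaviour* at a_h = 25, but
  the numerical value of a_h is not transferable to other implementations.
* Gradient methods converge noticeably more slowly than AP on clean data
  (consistent with published runtime tables); their value is robustness, not
  speed.
* With zero-clipped heavy Gaussian noise the Poisson methods are at a model
  disadvantage; WFP is the right tool there.
* Sub-pixel illumination frequencies are rounded to the nearest frequency
  pixel in the forward model; pupil-location robustness is therefore probed
  through the synthesis/reconstruction geometry mismatch, not through
  sub-pixel interpolation.
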