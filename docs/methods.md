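# Methods

## Problem and model

Multi-echo T2-weighted imaging acquires one k-space dataset per echo time
TE_i; the tissue parameter of interest is the transverse relaxation time
T2(x), which links the magnitude images through mono-exponential decay
f(x, TE_i) = f(x, TE_0)·exp(−(TE_i−TE_0)/T2(x)).  The conventional
pipeline reconstructs each echo independently and fits the decay afterwards,
so per-echo noise propagates straight into the T2 map.  The joint solver
treats all echoes and the T2 map as one inverse problem: a data-fidelity
term per echo, a plug-and-play spatial regularizer, and the decay relation
imposed as a hard constraint, solved by ADMM.

Assumptions worth stating explicitly:

- **Mono-exponential decay.**  No stimulated-echo, B1, or multi-compartment
  effects; a 3-parameter model is out of scope.
- **Known phase.**  The phase image A(x, TE_i) is estimated once from the
  zero-filled reconstruction (`exp(i·angle(IFFT g))`, unit phase at
  zero-magnitude pixels) and held fixed through all iterations.
- **Magnitude images are real and non-negative.**  Each image update solves
  its complex normal equations and then projects (real part, negatives
  clipped).  The projection is exact whenever the phase model is consistent
  with the data.
- **Gaussian image noise.**  Complex Gaussian k-space noise gives
  near-Gaussian magnitude noise at SNR ≳ 3; the denoisers and the fit
  weights assume this regime.  At very low SNR the magnitude floor (Rician
  regime) biases the fit — see "Conditioning limits".

## Fourier and sampling conventions

The 2D DFT is unitary and centered (`fftshift(fft2(ifftshift(·),
norm="ortho"))`), so Parseval holds with constant 1 and the k-space noise
standard deviation equals the image-domain one.  Undersampling acts on
whole phase-encode lines (rows).  `make_mask` always keeps the central 10%
of lines (round-half-to-even count; block centered, ties toward the lower
index) and removes a fraction of the remaining lines uniformly at random;
the same convention decides the discard count (0.25·90 = 22.5 → 22 lines of
100).

## ADMM updates

With penalty ρ, multipliers y_i (decay constraint, i > 0) and z_i
(denoising constraint), one sweep per iteration runs:

1. **Echo images i > 0.**  `(EᴴE + 2ρ)f_i = Eᴴg_i − y_i + ρ d_i + z_i + ρ v_i`
   with E = S F A_i and d_i the decay prediction from the current f_0 and
   T2.  The image-domain coefficient is the constant 2ρ, so the system
   diagonalizes in the transform domain and is solved exactly with two
   FFTs.
2. **First echo.**  Later echoes back-project expectations of f_0; the
   normal equations gain the pixelwise coefficient ρ(1 + Σ e_i²),
   e_i = exp(−ΔTE_i/T2).  With full sampling EᴴE = I and the solve is
   pixelwise; with undersampling the operator mixes a k-space-diagonal and
   an image-diagonal part and is **not** jointly diagonalizable, so the
   Hermitian positive-definite system is solved by conjugate gradients
   (rtol 1e−12, warm-started from the current iterate) — still the exact
   minimizer to numerical tolerance.
3. **T2 map.**  Pixelwise weighted least squares on the log-linear decay
   with the intercept pinned at the first echo (the i = 0 residual is
   identically zero, so only i > 0 contributes):
   `1/T2 = −Σ w_i ΔTE_i log(f_i/f_0) / Σ w_i ΔTE_i²`.
   The weight of echo i is the inverse of its first-order log-domain
   uncertainty scaled by 1/ΔTE_i:
   `w_i ∝ ΔTE_i / (log(f_i+σ) − log(f_i−σ))`, normalized to sum to one per
   pixel.  (As printed in the source formulation the bracketed difference
   is negative; the evident intent — inverse width of the interval
   [log(f−σ), log(f+σ)] — is implemented.)  In the σ→0 limit this reduces
   to w_i ∝ ΔTE_i·f_i.  Echoes with f_i ≤ σ fall back to unit weight.
   Numerics: values are floored at 1e−6 of the peak first-echo intensity
   before logs; pixels with all echoes at the floor are flagged and set to
   the clamp maximum; non-decaying fits (rate ≤ 0) clamp to the maximum.
   Clamp default (1, 5000) ms covers the phantom range and CSF.
4. **Denoising (plug-and-play).**  v_i = D(f_i, σ) by default — the
   shortcut that feeds the current image directly to the denoiser.  The
   full augmented-Lagrangian form v_i = D(f_i + z_i/ρ, σ) is available via
   `pnp_shift=True`; the shortcut is the default for fidelity to the
   published scheme.
5. **Multipliers.**  y_i += ρ·(f_i − f_0 e_i) with the fresh T2;
   z_i += ρ·(v_i − f_i).

Stopping: the mean relative intensity change
`mean |f_new − f_old| / (|f_old| + floor)` over foreground pixels (Otsu
mask of the first-echo initialization) and echoes, floor 1e−3 of the peak
intensity.  The MRC typically rises over the first sweeps, so it is checked
from iteration 4; convergence of PnP-ADMM is not guaranteed in theory and
`max_iter` (default 50) is always enforced, with a warning on
non-convergence.  ρ = 0.5 is robust across all the shipped experiments.

## Noise-level estimation

σ serves both as the denoiser strength and as the fit uncertainty.  The
estimator segments the foreground with Otsu's threshold (parameter-free),
tiles it with non-overlapping 5×5 patches fully inside the mask, and takes
the mode (tallest Freedman–Diaconis histogram bin) of the patch standard
deviations — the mode is robust against patches straddling edges.  The
`conservative` variant halves the estimate to preserve fine detail.  σ is
estimated once from the first-echo zero-filled image and held fixed.

**Undersampled data:** aliasing in the zero-filled initialization inflates
the patch statistics (measured ≈2.7× at 25% line discard on the vial
phantom), which over-drives the denoiser and can wash out small
structures.  The recommended setting for undersampled reconstructions is
`conservative_sigma=True`; the tests and shipped experiments use it.

## Denoisers

Registered under `jkte.denoisers`: `nlm` (non-local means, patch-based
collaborative averaging — the default and the strongest Gaussian denoiser
available here), `tv` (Chambolle), `gaussian` (noise-proportional blur;
fast, but it trades edge sharpness for noise and is intended for smoke
tests), and `identity` (exact no-op, used for the exact fixed-point tests).
Every denoiser is an exact no-op at σ = 0.

## Baselines

- **two_step**: per-echo inverse-FFT magnitudes, then the same WLS fitter
  as the joint method — differences between the two isolate the
  reconstruction stage.
- **cs_tv**: per-echo `½‖SFAf − g‖² + w·TV_1D(f)` with the TV penalty along
  the phase-encode axis only, minimized by FISTA-style proximal gradient
  (unit step — the encoding operator has unit spectral norm under the
  unitary convention) with a monotone safeguard.  The default weight
  w = 2.0 came from a small grid search on the striped synthetic phantom
  (w ∈ {0.1, 0.5, 2, 5}).
- **kspace_only**: the joint machinery with the decay constraint removed.
  Without the TE coupling the MRC stopping statistic does not fall below
  the threshold; following the published protocol the iteration is cut at
  the check iteration (4) in that case.

## Synthetic phantoms

`make_vial_phantom` lays 14 circular vials (5 + 9 on two concentric rings,
deterministic geometry) with uniform proton density 100 and the
manufacturer-calibrated T2 ladder 8.75–853 ms; `make_brain_like_phantom`
nests three smooth regions with CSF/GM/WM-like T2 (1700/118/95 ms).
`simulate_acquisition` composes decay, an optional smooth phase pattern
(planar ramp or seeded low-order polynomial), the unitary encoding, and
complex Gaussian k-space noise with an independent seeded substream per
echo.  The default echo ladder is 11 echoes, 11–176 ms in 11 ms steps; a
32-echo ladder (14.4–461.6 ms) is available as `TE_GRASE_MS`.  The default
noise level is 2.0 = 2% of the peak proton density (moderate noise; under
the unitary convention this is also the image-domain noise sd).

What the generator does *not* emulate: echo-train artifacts (stimulated
echoes, T2 blur along the train), B1 inhomogeneity, motion, multi-coil
sensitivity profiles, and Rician statistics at very low SNR beyond what
magnitude-taking induces.  Passing tests therefore demonstrate correctness
of the estimator pipeline under the stated model, not robustness to those
scanner effects.

Experiments in the test suite run at 128×128 (64×64 for unit-level checks)
with the 11-echo ladder — small enough to iterate comfortably while keeping
every vial several patches wide.

## Conditioning limits of the protocol (known limitations)

- **Short T2 vs the echo ladder.**  With TEs from 11 ms and a noise floor
  around 1.25σ, vials with T2 below ~4–5 echo spacings have most echoes at
  the floor; the ΔTE-scaled weights still give those echoes appreciable
  weight, biasing T2 upward (the 8.75 ms vial reads ≈18 ms at 2% noise).
  This is a property of magnitude-domain log-linear fitting with this
  weighting, shared by all methods here.
- **Long T2 vs the TE range.**  The 853 ms vial decays only ~18% across the
  whole 176 ms ladder, so its slope is noise-limited (≈1–6% bias depending
  on noise).  Accuracy claims in the tests are therefore asserted on the
  well-conditioned 50–700 ms range; outside it only precision (std) is
  compared across methods.
- **Undersampling with a shared mask.**  All echoes share one sampling
  mask, so aliasing of decaying structures is itself approximately
  decay-consistent and the TE-space constraint cannot fully reject it;
  short-T2 vials drift several percent between fully sampled and 25%
  undersampled joint reconstructions (the long-T2 vials agree within
  ~2–3%).
- **Determinism.**  All solvers are deterministic given inputs and config;
  randomness exists only in the simulator and mask generation, driven by
  explicit seeds.
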