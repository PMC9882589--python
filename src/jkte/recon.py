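"""Joint reconstruction of multi-echo images and the T2 map by ADMM.

The solver estimates all T2-weighted magnitude images f(x, TE_i) and the
pixelwise T2 map simultaneously from (possibly undersampled) multi-echo
k-space data by minimizing

    1/2 Σ_i |S F A_i f_i − g_i|²  +  R(v_i)
    s.t.  f_i = f_0 · exp(−(TE_i − TE_0)/T2)   for i > 0,
          v_i = f_i,

via the augmented Lagrangian / ADMM with penalty ρ.  The spatial regularizer
R is realized as a plug-and-play denoising step with noise level σ estimated
once from the zero-filled reconstruction of the first echo.  The T2
subproblem is a pixelwise weighted least-squares fit of the log-linear decay
model; the image subproblems are quadratic and solved exactly.

Iterations stop when the mean relative intensity change (MRC) of the image
series between successive iterations falls below ``epsilon``, checked from
``check_from_iter`` onward (the MRC typically rises over the first few
sweeps); ``max_iter`` is always enforced because convergence of the PnP-ADMM
scheme is not guaranteed in theory.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.linalg import LinearOperator, cg

from .denoisers import get_denoiser
from .forward import estimate_phase, fft2c, ifft2c
from .noise import estimate_sigma, foreground_mask
from .types import ImageSeries, KSpaceSeries, PhaseMap, T2Map

__all__ = [
    "ReconConfig",
    "ADMMState",
    "update_f_i",
    "update_f_0",
    "fit_t2_wls",
    "update_v",
    "update_multipliers",
    "mrc",
    "joint_reconstruct",
]

# positivity floor factor before logarithms in the T2 fit
_LOG_FLOOR_FACTOR = 1e-6
# MRC denominator floor factor
_MRC_FLOOR_FACTOR = 1e-3


@dataclass
class ReconConfig:
    """Solver configuration.

    rho : ADMM penalty parameter (robust; 0.5 works across applications).
    epsilon : relative-change stopping threshold (0.01 = 1%).
    max_iter : hard iteration cap.
    check_from_iter : first iteration at which the stopping rule is applied.
    sigma : noise standard deviation override; estimated from the data when None.
    conservative_sigma : halve the estimated sigma to preserve fine detail.
    denoiser : registered denoiser name for the plug-and-play step.
    pnp_shift : include the scaled multiplier z/rho in the denoiser input
        (the full augmented-Lagrangian form); the default applies the
        denoiser to f directly.
    t2_clamp : (min, max) clamp of fitted T2 in ms.
    seed : recorded for provenance; the solver itself is deterministic.
    """

    rho: float = 0.5
    epsilon: float = 0.01
    max_iter: int = 50
    check_from_iter: int = 4
    sigma: float | None = None
    conservative_sigma: bool = False
    denoiser: str = "nlm"
    pnp_shift: bool = False
    t2_clamp: tuple[float, float] = (1.0, 5000.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rho <= 0:
            raise ValueError("rho must be positive")
        if not 0 < self.epsilon < 1:
            raise ValueError("epsilon must lie in (0, 1)")
        if self.check_from_iter < 1:
            raise ValueError("check_from_iter must be >= 1")


@dataclass
class ADMMState:
    """Iterate of the joint solver.

    ``y`` are the decay-constraint multipliers (slot 0 unused, kept for
    aligned indexing), ``z`` the denoising-constraint multipliers, ``v`` the
    auxiliary denoised images.
    """

    f: ImageSeries
    t2: T2Map
    v: ImageSeries
    y: np.ndarray
    z: np.ndarray
    k: int = 0
    mrc_history: list = field(default_factory=list)


def _project_magnitude(img: np.ndarray) -> np.ndarray:
    # magnitude images are real and non-negative
    return np.clip(img.real, 0.0, None)


def _decay_factors(t2: np.ndarray, te: np.ndarray) -> np.ndarray:
    dte = (te - te[0])[:, None, None]
    return np.exp(-dte / t2[None])


def update_f_i(
    state: ADMMState, g: KSpaceSeries, A: PhaseMap, i: int, cfg: ReconConfig
) -> np.ndarray:
    """Exact minimizer of the echo-i (i > 0) quadratic image subproblem.

    The normal equations ``(EᴴE + 2ρ)f = Eᴴg − y_i + ρd_i + z_i + ρv_i`` with
    ``E = S F A_i`` diagonalize in the transform domain because the
    image-domain coefficient 2ρ is constant: with ``h = F A f`` the system
    reads ``(s + 2ρ)h = F A·rhs`` for the 0/1 line-sampling vector ``s``.
    ``d_i`` is the decay prediction from the current f_0 and T2.
    """
    if i <= 0:
        raise ValueError("update_f_i handles echoes with i > 0")
    rho = cfg.rho
    te = g.te
    d_i = state.f.data[0] * np.exp(-(te[i] - te[0]) / state.t2.data)
    Ai = A.data[i]
    rhs = np.conj(Ai) * ifft2c(g.data[i]) + (
        rho * d_i - state.y[i] + state.z[i] + rho * state.v.data[i]
    )
    s = g.mask.astype(float)[:, None]
    denom = s + 2.0 * rho
    if not np.all(denom > 0):  # cannot happen for rho > 0
        raise RuntimeError("singular normal equations in image update")
    f = np.conj(Ai) * ifft2c(fft2c(Ai * rhs) / denom)
    return _project_magnitude(f)


def update_f_0(
    state: ADMMState, g: KSpaceSeries, A: PhaseMap, cfg: ReconConfig
) -> np.ndarray:
    """Exact minimizer of the first-echo quadratic subproblem.

    Every later echo back-projects an expectation of the first-echo image
    through the decay model; the normal equations are

        (E₀ᴴE₀ + ρ(1 + Σ_{i>0} e_i²)) f = E₀ᴴg₀ + Σ_{i>0} e_i (y_i + ρ f_i)
                                          + z₀ + ρ v₀

    with pixelwise ``e_i = exp(−(TE_i−TE_0)/T2)``.  For full sampling
    ``E₀ᴴE₀ = I`` and the system solves pixelwise; with undersampling the
    image-domain coefficient varies across pixels, so the Hermitian
    positive-definite system is solved by conjugate gradients to machine
    tolerance.
    """
    rho = cfg.rho
    te = g.te
    e = _decay_factors(state.t2.data, te)  # e[0] = 1, unused
    A0 = A.data[0]
    rhs = np.conj(A0) * ifft2c(g.data[0]) + state.z[0] + rho * state.v.data[0]
    coeff = np.ones_like(state.t2.data)  # Σ e_i² + 1, the rho multiplier
    for i in range(1, g.n_echo):
        rhs = rhs + e[i] * (state.y[i] + rho * state.f.data[i])
        coeff = coeff + e[i] ** 2
    c = rho * coeff

    if g.mask.all():
        f = rhs / (1.0 + c)
        return _project_magnitude(f)

    ny, nx = g.grid
    s = g.mask.astype(float)[:, None]

    def apply(vec: np.ndarray) -> np.ndarray:
        x = vec.reshape(ny, nx)
        data = np.conj(A0) * ifft2c(s * fft2c(A0 * x))
        return (data + c * x).ravel()

    op = LinearOperator(
        (ny * nx, ny * nx), matvec=apply, dtype=complex
    )
    x0 = state.f.data[0].astype(complex).ravel()
    sol, info = cg(op, rhs.ravel(), x0=x0, rtol=1e-12, atol=0.0, maxiter=500)
    if info != 0:
        raise RuntimeError(f"conjugate gradients failed to converge (info={info})")
    return _project_magnitude(sol.reshape(ny, nx))


def _wls_weights(fpos: np.ndarray, dte: np.ndarray, sigma: float) -> np.ndarray:
    """First-order uncertainty weights for the log-linear decay fit.

    The weight of echo i is inversely proportional to the width of the
    log-domain interval [log(f_i−σ), log(f_i+σ)] divided by (TE_i−TE_0):
    ``w_i ∝ ΔTE_i / (log(f_i+σ) − log(f_i−σ))``.  In the σ→0 limit the
    interval width is 2σ/f_i, giving the classical ``w_i ∝ ΔTE_i·f_i``.
    Echoes with f_i ≤ σ (log undefined) fall back to unit weight.
    """
    d = dte[:, None, None]
    if sigma <= 1e-12 * np.max(fpos):
        return d * fpos
    w = np.ones_like(fpos)
    ok = fpos > sigma
    width = np.where(ok, np.log(fpos + sigma) - np.log(np.maximum(fpos - sigma, 1e-300)), 1.0)
    np.copyto(w, d / width, where=ok)
    return w


def fit_t2_wls(
    f: ImageSeries, sigma: float, clamp: tuple[float, float] = (1.0, 5000.0)
) -> T2Map:
    """Pixelwise weighted least-squares fit of the mono-exponential decay.

    Fits ``log f_i = log f_0 − (TE_i − TE_0)/T2`` with the intercept pinned at
    the first echo, so only echoes i > 0 contribute:

        1/T2 = −Σ_i w_i ΔTE_i log(f_i/f_0) / Σ_i w_i ΔTE_i²

    Weights are normalized to sum to one per pixel.  Values below a
    positivity floor of 1e−6 of the peak first-echo intensity are lifted to
    the floor; pixels where *all* echoes sit at the floor (no signal) are set
    to the clamp maximum and flagged.  Non-decaying pixels (fitted rate ≤ 0)
    are likewise clamped to the maximum.
    """
    if f.n_echo < 2:
        raise ValueError("T2 fitting requires at least 2 echoes")
    lo, hi = clamp
    if not 0 < lo < hi:
        raise ValueError("clamp range must satisfy 0 < min < max")
    floor = _LOG_FLOOR_FACTOR * max(float(f.data[0].max()), 1e-300)
    flagged = np.all(f.data <= floor, axis=0)
    fpos = np.maximum(f.data, floor)
    dte = f.te - f.te[0]

    w = _wls_weights(fpos[1:], dte[1:], sigma)
    w = w / np.sum(w, axis=0, keepdims=True)
    logratio = np.log(fpos[1:] / fpos[0])
    d = dte[1:, None, None]
    num = -np.sum(w * d * logratio, axis=0)
    den = np.sum(w * d * d, axis=0)
    rate = num / den  # 1/T2

    t2 = np.full(rate.shape, hi, dtype=float)
    pos = rate > 0
    t2[pos] = 1.0 / rate[pos]
    t2 = np.clip(t2, lo, hi)
    t2[flagged] = hi
    return T2Map(data=t2, flags=flagged)


def update_v(state: ADMMState, sigma: float, cfg: ReconConfig) -> ImageSeries:
    """Plug-and-play denoising of each echo image.

    Default form applies the denoiser to f directly, ``v_i = D(f_i, σ)``;
    with ``pnp_shift`` the scaled multiplier enters, ``v_i = D(f_i + z_i/ρ, σ)``
    as the full augmented Lagrangian implies.  Output is projected back to
    non-negative magnitudes.
    """
    denoise = get_denoiser(cfg.denoiser)
    out = np.empty_like(state.f.data)
    for i in range(state.f.n_echo):
        x = state.f.data[i]
        if cfg.pnp_shift:
            x = x + state.z[i] / cfg.rho
        out[i] = denoise(x, sigma)
    return ImageSeries(data=_project_magnitude(out), te=state.f.te)


def update_multipliers(
    state: ADMMState, cfg: ReconConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Dual ascent on both constraint residuals.

    ``y_i += ρ·(f_i − f_0·e_i)`` for i > 0 (decay constraint, using the
    freshly updated T2) and ``z_i += ρ·(v_i − f_i)`` for all echoes.
    """
    rho = cfg.rho
    e = _decay_factors(state.t2.data, state.f.te)
    y = state.y.copy()
    z = state.z.copy()
    for i in range(1, state.f.n_echo):
        y[i] += rho * (state.f.data[i] - state.f.data[0] * e[i])
    z += rho * (state.v.data - state.f.data)
    return y, z


def mrc(
    f_new: ImageSeries,
    f_old: ImageSeries,
    foreground: np.ndarray | None = None,
    floor: float | None = None,
) -> float:
    """Mean relative intensity change between successive iterates.

    Mean over foreground pixels and echoes of ``|f_new − f_old|/(|f_old| +
    floor)``; the floor (default 1e−3 of the peak old intensity) guards the
    division at empty pixels.
    """
    if f_new.data.shape != f_old.data.shape:
        raise ValueError("image series shapes must match")
    if floor is None:
        floor = _MRC_FLOOR_FACTOR * max(float(np.abs(f_old.data).max()), 1e-300)
    rel = np.abs(f_new.data - f_old.data) / (np.abs(f_old.data) + floor)
    if foreground is not None:
        rel = rel[:, foreground]
    return float(np.mean(rel))


def _check_finite(arr: np.ndarray, step: str, k: int) -> None:
    if not np.all(np.isfinite(arr)):
        raise FloatingPointError(
            f"non-finite values produced by {step} at iteration {k}"
        )


def initialize_state(
    g: KSpaceSeries, cfg: ReconConfig, sigma: float
) -> ADMMState:
    """Zero-filled initialization: magnitudes of the inverse transform,
    T2 fitted on them, v = f, multipliers zero."""
    f0 = np.abs(ifft2c(g.data))
    f = ImageSeries(data=f0, te=g.te)
    t2 = fit_t2_wls(f, sigma, cfg.t2_clamp)
    v = ImageSeries(data=f0.copy(), te=g.te)
    zeros = np.zeros_like(f0)
    return ADMMState(f=f, t2=t2, v=v, y=zeros.copy(), z=zeros.copy())


def joint_reconstruct(
    g: KSpaceSeries, cfg: ReconConfig | None = None
) -> tuple[ImageSeries, T2Map, dict]:
    """Run the full joint ADMM reconstruction.

    Returns the final image series, the T2 map, and a convergence log with
    the per-iteration MRC values, the iteration count, the noise level used,
    and a convergence flag.
    """
    cfg = cfg or ReconConfig()
    A = estimate_phase(g)
    init_mag = np.abs(ifft2c(g.data))
    if cfg.sigma is not None:
        sigma = float(cfg.sigma)
    else:
        sigma = estimate_sigma(init_mag[0], cfg.conservative_sigma).sigma
    fg = foreground_mask(init_mag[0])

    state = initialize_state(g, cfg, sigma)
    log = {"mrc": [], "converged": False, "sigma": sigma, "iterations": 0}
    if cfg.max_iter == 0:
        return state.f, state.t2, log

    for k in range(1, cfg.max_iter + 1):
        f_old = copy.deepcopy(state.f)
        new_f = state.f.data.copy()
        for i in range(1, g.n_echo):
            new_f[i] = update_f_i(state, g, A, i, cfg)
        state.f = ImageSeries(data=new_f, te=g.te)
        new_f[0] = update_f_0(state, g, A, cfg)
        state.f = ImageSeries(data=new_f, te=g.te)
        _check_finite(state.f.data, "image update", k)

        state.t2 = fit_t2_wls(state.f, sigma, cfg.t2_clamp)
        _check_finite(state.t2.data, "T2 fit", k)

        state.v = update_v(state, sigma, cfg)
        _check_finite(state.v.data, "denoising step", k)

        state.y, state.z = update_multipliers(state, cfg)
        _check_finite(state.y, "multiplier update", k)

        m = mrc(state.f, f_old, foreground=fg)
        state.k = k
        state.mrc_history.append(m)
        log["mrc"].append(m)
        log["iterations"] = k
        if k >= cfg.check_from_iter and m < cfg.epsilon:
            log["converged"] = True
            break

    if not log["converged"]:
        warnings.warn(
            f"joint reconstruction stopped at max_iter={cfg.max_iter} "
            f"with MRC={log['mrc'][-1]:.4g} >= epsilon={cfg.epsilon}",
            RuntimeWarning,
            stacklevel=2,
        )
    return state.f, state.t2, log
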