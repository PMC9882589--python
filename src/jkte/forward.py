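"""Encoding model linking magnitude images to sampled k-space.

The measurement model per echo is ``g = S F (A ∘ f) + n`` where ``F`` is the
unitary (orthonormal) 2D DFT, ``A`` the unit-modulus phase image and ``S`` a
diagonal 0/1 sampling operator acting on whole phase-encode lines.  K-space is
stored centered: ``fft2c`` wraps ``fftshift(fft2(ifftshift(.), norm="ortho"))``
so the DC component sits at ``(ny//2, nx//2)`` and "central lines" means low
spatial frequencies.
"""

from __future__ import annotations

import numpy as np

from .types import ImageSeries, KSpaceSeries, PhaseMap

__all__ = ["fft2c", "ifft2c", "encode", "estimate_phase", "decay_signal", "make_mask"]


def fft2c(img: np.ndarray) -> np.ndarray:
    """Centered unitary 2D FFT over the last two axes."""
    return np.fft.fftshift(
        np.fft.fft2(np.fft.ifftshift(img, axes=(-2, -1)), norm="ortho"),
        axes=(-2, -1),
    )


def ifft2c(ksp: np.ndarray) -> np.ndarray:
    """Centered unitary 2D inverse FFT over the last two axes."""
    return np.fft.fftshift(
        np.fft.ifft2(np.fft.ifftshift(ksp, axes=(-2, -1)), norm="ortho"),
        axes=(-2, -1),
    )


def encode(f: ImageSeries, A: PhaseMap, mask: np.ndarray) -> KSpaceSeries:
    """Apply the forward encoding ``S F (A ∘ f)`` per echo.

    Parameters
    ----------
    f : ImageSeries
        Magnitude images, one per echo.
    A : PhaseMap
        Phase factors on the same grid.
    mask : bool array, shape (ny,)
        Phase-encode-line sampling pattern; masked-out lines are zeroed.
    """
    if A.data.shape != f.data.shape:
        raise ValueError(
            f"phase map shape {A.data.shape} does not match images {f.data.shape}"
        )
    mask = np.asarray(mask).astype(bool)
    if mask.shape != (f.data.shape[1],):
        raise ValueError("mask must be 1D over the phase-encode (row) dimension")
    ksp = fft2c(A.data * f.data)
    ksp[:, ~mask, :] = 0.0
    return KSpaceSeries(data=ksp, te=f.te, mask=mask)


def estimate_phase(g: KSpaceSeries) -> PhaseMap:
    """Estimate per-echo phase factors from zero-filled reconstructions.

    The phase image is taken as ``exp(i·angle(IFFT(g_i)))`` and held fixed by
    the caller for all subsequent iterations.  Pixels with zero magnitude get
    phase 1 (arbitrary but fixed).
    """
    img = ifft2c(g.data)
    A = np.exp(1j * np.angle(img))
    A[img == 0] = 1.0
    return PhaseMap(data=A)


def decay_signal(f0: np.ndarray, t2: np.ndarray, te: np.ndarray) -> ImageSeries:
    """Mono-exponential decay ``f(x,TE_i) = f(x,TE_0)·exp(−(TE_i−TE_0)/T2(x))``.

    ``te[0]`` is the reference echo time TE_0; the first returned echo equals
    ``f0`` exactly.
    """
    f0 = np.asarray(f0, dtype=float)
    t2 = np.asarray(t2, dtype=float)
    te = np.asarray(te, dtype=float)
    if np.any(t2 <= 0):
        raise ValueError("T2 must be strictly positive everywhere")
    dte = (te - te[0])[:, None, None]
    data = f0[None] * np.exp(-dte / t2[None])
    data[0] = f0  # exact, avoids exp(0) rounding concerns
    return ImageSeries(data=data, te=te)


def _round_half_even(x: float) -> int:
    return int(np.round(x))


def make_mask(n_lines: int, discard_fraction: float, seed: int) -> np.ndarray:
    """Cartesian undersampling pattern over phase-encode lines.

    The central 10% of lines (round-half-to-even; block centered, ties toward
    the lower index) is always kept; of the remaining lines a fraction
    ``discard_fraction`` (again rounded half-to-even to a count) is removed
    uniformly at random.  Deterministic for a fixed ``seed``.
    """
    if n_lines < 10:
        raise ValueError("need at least 10 phase-encode lines")
    if not 0 <= discard_fraction < 1:
        raise ValueError("discard_fraction must lie in [0, 1)")
    n_central = _round_half_even(0.10 * n_lines)
    start = (n_lines - n_central) // 2
    central = np.zeros(n_lines, dtype=bool)
    central[start : start + n_central] = True

    mask = np.ones(n_lines, dtype=bool)
    outer = np.flatnonzero(~central)
    n_discard = _round_half_even(discard_fraction * outer.size)
    if n_discard:
        rng = np.random.default_rng(seed)
        drop = rng.choice(outer, size=n_discard, replace=False)
        mask[drop] = False
    return mask
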