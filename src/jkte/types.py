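"""Domain containers for multi-echo MRI reconstruction.

All arrays follow the layout (n_echo, ny, nx); the phase-encode direction is
axis -2 (rows), so a sampling mask is a boolean vector over the ny k-space
lines.  K-space arrays are stored *centered* (DC component at ``ny//2,
nx//2``) under a unitary Fourier convention; see :mod:`jkte.forward`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["KSpaceSeries", "ImageSeries", "PhaseMap", "T2Map"]

_UNIT_MODULUS_ATOL = 1e-9


def _check_te(te: np.ndarray) -> np.ndarray:
    te = np.asarray(te, dtype=float)
    if te.ndim != 1 or te.size == 0:
        raise ValueError("te must be a nonempty 1D array of echo times in ms")
    if np.any(np.diff(te) <= 0):
        raise ValueError("echo times must be strictly increasing")
    return te


@dataclass
class KSpaceSeries:
    """Measured k-space data g(z, TE_i) with its sampling pattern.

    Attributes
    ----------
    data : complex array, shape (n_echo, ny, nx)
        Centered k-space samples per echo; lines excluded by ``mask`` are
        identically zero.
    te : float array, shape (n_echo,)
        Echo times in ms, strictly increasing.
    mask : bool array, shape (ny,)
        Per phase-encode-line sampling indicator (True = acquired).
    """

    data: np.ndarray
    te: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=complex)
        self.te = _check_te(self.te)
        if self.data.ndim != 3:
            raise ValueError("k-space data must have shape (n_echo, ny, nx)")
        if self.data.shape[0] != self.te.size:
            raise ValueError(
                f"{self.data.shape[0]} echoes in data but {self.te.size} echo times"
            )
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.shape != (self.data.shape[1],):
            raise ValueError("mask must be a 1D boolean array over phase-encode lines")
        if np.any(self.data[:, ~self.mask, :] != 0):
            raise ValueError("masked-out k-space lines must be exactly zero")

    @property
    def n_echo(self) -> int:
        return self.data.shape[0]

    @property
    def grid(self) -> tuple[int, int]:
        return self.data.shape[1:]


@dataclass
class ImageSeries:
    """Real non-negative magnitude images f(x, TE_i), one per echo."""

    data: np.ndarray
    te: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.te = _check_te(self.te)
        if self.data.ndim != 3 or self.data.shape[0] != self.te.size:
            raise ValueError("image data must have shape (n_echo, ny, nx) matching te")
        if np.any(self.data < 0):
            raise ValueError("magnitude images must be non-negative")

    @property
    def n_echo(self) -> int:
        return self.data.shape[0]

    @property
    def grid(self) -> tuple[int, int]:
        return self.data.shape[1:]


@dataclass
class PhaseMap:
    """Unit-modulus complex phase factors A(x, TE_i)."""

    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=complex)
        if self.data.ndim != 3:
            raise ValueError("phase map must have shape (n_echo, ny, nx)")
        if not np.allclose(np.abs(self.data), 1.0, atol=_UNIT_MODULUS_ATOL):
            raise ValueError("phase map entries must have unit modulus")


@dataclass
class T2Map:
    """Pixelwise transverse relaxation time in ms.

    ``flags`` marks pixels where the decay fit degenerated (all echoes at the
    positivity floor) and the value was set to the clamp maximum.
    """

    data: np.ndarray
    flags: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("T2 map must be 2D")
        if np.any(self.data <= 0):
            raise ValueError("T2 values must be strictly positive")
        if self.flags is None:
            self.flags = np.zeros(self.data.shape, dtype=bool)
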