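"""Pluggable image denoisers for the plug-and-play regularization step.

Each denoiser maps ``(image, sigma) -> image`` where ``sigma`` is the Gaussian
noise standard deviation in image-intensity units.  ``sigma == 0`` is an exact
no-op for every denoiser (zero-noise contract).

Registered denoisers:

``nlm``
    Non-local means (patch-based collaborative averaging), the default; the
    strongest Gaussian denoiser available here and the same family of
    patch-based methods as BM3D.
``gaussian``
    Gaussian blur with noise-proportional bandwidth; fast, for smoke tests
    and quick runs.
``tv``
    Total-variation (Chambolle) denoising.
``identity``
    Exact pass-through; enables exact fixed-point tests of the ADMM sweep.
"""

from __future__ import annotations

from typing import Callable, Dict

import numpy as np
from skimage.restoration import denoise_nl_means, denoise_tv_chambolle
from scipy.ndimage import gaussian_filter

__all__ = ["get_denoiser", "register_denoiser", "available_denoisers"]

Denoiser = Callable[[np.ndarray, float], np.ndarray]

_REGISTRY: Dict[str, Denoiser] = {}


def register_denoiser(name: str, fn: Denoiser) -> None:
    _REGISTRY[name] = fn


def available_denoisers() -> list[str]:
    return sorted(_REGISTRY)


def get_denoiser(name: str) -> Denoiser:
    try:
        return _REGISTRY[name]
    except KeyError:
        raise ValueError(
            f"unknown denoiser {name!r}; registered: {', '.join(available_denoisers())}"
        ) from None


def _identity(image: np.ndarray, sigma: float) -> np.ndarray:
    return np.asarray(image, dtype=float)


def _gaussian(image: np.ndarray, sigma: float) -> np.ndarray:
    if sigma <= 0:
        return np.asarray(image, dtype=float)
    scale = max(np.ptp(image), 1e-12)
    # bandwidth grows with the noise level relative to the dynamic range
    width = 0.5 + 5.0 * sigma / scale
    return gaussian_filter(np.asarray(image, dtype=float), width)


def _nlm(image: np.ndarray, sigma: float) -> np.ndarray:
    if sigma <= 0:
        return np.asarray(image, dtype=float)
    return denoise_nl_means(
        np.asarray(image, dtype=float),
        h=0.8 * sigma,
        sigma=sigma,
        patch_size=5,
        patch_distance=6,
        fast_mode=True,
    )


def _tv(image: np.ndarray, sigma: float) -> np.ndarray:
    if sigma <= 0:
        return np.asarray(image, dtype=float)
    return denoise_tv_chambolle(np.asarray(image, dtype=float), weight=sigma)


register_denoiser("identity", _identity)
register_denoiser("gaussian", _gaussian)
register_denoiser("nlm", _nlm)
register_denoiser("tv", _tv)
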