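"""Digital relaxometry phantoms and simulated multi-echo acquisitions.

The vial phantom emulates a commercial relaxometry phantom: 14 cylindrical
vials of MnCl2 solution spanning T2 from about 8 to 850 ms, imaged with a
multi-echo spin-echo ladder (11 echoes, 11 to 176 ms in 11 ms steps).  The
simulator composes the mono-exponential decay model with the unitary Fourier
encoding and adds independent complex Gaussian noise to each echo's k-space.
Ground truth (proton density, T2 map, ROI labels) always travels with the
simulated data so every downstream check can close the loop
simulate → reconstruct → compare.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .forward import decay_signal, encode
from .types import ImageSeries, KSpaceSeries, PhaseMap

__all__ = [
    "VIAL_T2_MS",
    "TE_FSE_MS",
    "TE_GRASE_MS",
    "DigitalPhantom",
    "AcquisitionConfig",
    "make_vial_phantom",
    "make_brain_like_phantom",
    "simulate_acquisition",
]

# manufacturer-calibrated vial T2 values (ms) at 1.5 T / 20 C
VIAL_T2_MS = (
    8.75, 12.8, 17.9, 26.1, 34.3, 53.0, 82.2,
    116.0, 167.0, 194.0, 323.0, 479.0, 692.0, 853.0,
)

# multi-echo FSE ladder: 11 echoes, 11..176 ms in 11 ms steps
TE_FSE_MS = tuple(float(11 * i) for i in range(1, 12))
# GraSE-like ladder: 32 echoes, 14.4..461.6 ms in 14.4 ms steps
TE_GRASE_MS = tuple(round(14.4 * i, 1) for i in range(1, 33))

_DEFAULT_PD = 100.0


@dataclass
class DigitalPhantom:
    """Ground-truth phantom: proton density, T2 map, and labeled ROIs."""

    pd: np.ndarray
    t2_truth: np.ndarray
    roi_masks: dict[str, np.ndarray]
    grid: tuple[int, int]

    def __post_init__(self) -> None:
        occupied = np.zeros(self.grid, dtype=int)
        for m in self.roi_masks.values():
            occupied += m.astype(int)
        if occupied.max() > 1:
            raise ValueError("ROI masks must be disjoint")

    @property
    def support(self) -> np.ndarray:
        return self.pd > 0


@dataclass
class AcquisitionConfig:
    """Echo ladder, k-space noise level, phase pattern, and seed.

    The default noise level of 2.0 is 2% of the default peak proton density
    (100), i.e. moderate noise under the unitary Fourier convention where
    k-space noise sd carries over to the image domain unchanged.
    """

    te: tuple = TE_FSE_MS
    noise_sd: float = 2.0
    phase_pattern: str = "none"  # none | linear | smooth_random
    seed: int = 0

    def __post_init__(self) -> None:
        te = np.asarray(self.te, dtype=float)
        if np.any(np.diff(te) <= 0):
            raise ValueError("echo times must be strictly increasing")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.phase_pattern not in ("none", "linear", "smooth_random"):
            raise ValueError(f"unknown phase pattern {self.phase_pattern!r}")


def _vial_centers(grid: tuple[int, int]) -> np.ndarray:
    """Deterministic two-ring layout: 5 vials inner, 9 outer."""
    ny, nx = grid
    cy, cx = (ny - 1) / 2, (nx - 1) / 2
    centers = []
    for n, rfrac, offset in ((5, 0.17, 0.0), (9, 0.36, np.pi / 9)):
        r = rfrac * min(ny, nx)
        for k in range(n):
            th = 2 * np.pi * k / n + offset
            centers.append((cy + r * np.sin(th), cx + r * np.cos(th)))
    return np.asarray(centers)


def make_vial_phantom(
    grid: tuple[int, int] = (128, 128),
    t2_values: tuple = VIAL_T2_MS,
    vial_radius: float | None = None,
) -> DigitalPhantom:
    """Circular-vial phantom on a two-ring layout with uniform proton density.

    Raises if the requested radius makes vials overlap or leave the grid.
    """
    ny, nx = grid
    if vial_radius is None:
        vial_radius = 0.055 * min(ny, nx)
    centers = _vial_centers(grid)[: len(t2_values)]
    # overlap / bounds check
    for i in range(len(centers)):
        cy, cx = centers[i]
        if (cy - vial_radius < 0 or cy + vial_radius > ny - 1
                or cx - vial_radius < 0 or cx + vial_radius > nx - 1):
            raise ValueError("vials do not fit inside the grid at this radius")
        for j in range(i + 1, len(centers)):
            d = np.hypot(*(centers[i] - centers[j]))
            if d < 2 * vial_radius:
                raise ValueError("vials overlap at the requested radius")

    yy, xx = np.mgrid[0:ny, 0:nx]
    pd = np.zeros(grid)
    t2 = np.ones(grid)  # positive placeholder outside support
    rois: dict[str, np.ndarray] = {}
    for k, (t2v, (cy, cx)) in enumerate(zip(t2_values, centers), start=1):
        m = (yy - cy) ** 2 + (xx - cx) ** 2 <= vial_radius**2
        pd[m] = _DEFAULT_PD
        t2[m] = t2v
        rois[f"vial{k:02d}"] = m
    return DigitalPhantom(pd=pd, t2_truth=t2, roi_masks=rois, grid=grid)


def make_brain_like_phantom(
    grid: tuple[int, int] = (128, 128),
    t2_csf: float = 1700.0,
    t2_gm: float = 118.0,
    t2_wm: float = 95.0,
) -> DigitalPhantom:
    """Three nested smooth regions analogous to CSF / gray / white matter.

    An outer ellipse of white matter encloses a gray-matter ring which in
    turn encloses a CSF-like ventricle with long T2.
    """
    ny, nx = grid
    if ny < 64 or nx < 64:
        raise ValueError("brain-like phantom needs a grid of at least 64x64")
    yy, xx = np.mgrid[0:ny, 0:nx]
    cy, cx = (ny - 1) / 2, (nx - 1) / 2
    r2 = ((yy - cy) / (0.42 * ny)) ** 2 + ((xx - cx) / (0.36 * nx)) ** 2
    head = r2 <= 1.0
    gm_r2 = ((yy - cy) / (0.27 * ny)) ** 2 + ((xx - cx) / (0.22 * nx)) ** 2
    inner = gm_r2 <= 1.0
    csf_r2 = ((yy - cy) / (0.10 * ny)) ** 2 + ((xx - cx) / (0.08 * nx)) ** 2
    csf = csf_r2 <= 1.0

    wm = head & ~inner
    gm = inner & ~csf
    pd = np.zeros(grid)
    pd[wm] = 90.0
    pd[gm] = 100.0
    pd[csf] = 110.0
    t2 = np.ones(grid)
    t2[wm] = t2_wm
    t2[gm] = t2_gm
    t2[csf] = t2_csf
    return DigitalPhantom(
        pd=pd, t2_truth=t2, roi_masks={"wm": wm, "gm": gm, "csf": csf}, grid=grid
    )


def _phase_map(
    ph: DigitalPhantom, acq: AcquisitionConfig, n_echo: int
) -> PhaseMap:
    ny, nx = ph.grid
    yy, xx = np.mgrid[0:ny, 0:nx]
    u, v = yy / ny - 0.5, xx / nx - 0.5
    if acq.phase_pattern == "none":
        phi = np.zeros(ph.grid)
    elif acq.phase_pattern == "linear":
        phi = 2.0 * np.pi * (0.7 * u + 0.4 * v)
    else:  # smooth_random: low-order random polynomial
        rng = np.random.default_rng(np.random.SeedSequence([acq.seed, 0x9E37]))
        c = rng.normal(scale=1.2, size=6)
        phi = c[0] + c[1] * u + c[2] * v + c[3] * u * v + c[4] * u**2 + c[5] * v**2
    return PhaseMap(data=np.repeat(np.exp(1j * phi)[None], n_echo, axis=0))


def simulate_acquisition(
    ph: DigitalPhantom,
    acq: AcquisitionConfig,
    mask: np.ndarray | None = None,
) -> KSpaceSeries:
    """Simulate multi-echo k-space: decay, phase, encoding, complex noise.

    Noise is additive complex Gaussian with standard deviation ``noise_sd``
    per real/imaginary channel, drawn from an independent seeded substream
    per echo, and applied only on sampled lines.
    """
    te = np.asarray(acq.te, dtype=float)
    if mask is None:
        mask = np.ones(ph.grid[0], dtype=bool)
    f = decay_signal(ph.pd, ph.t2_truth, te)
    A = _phase_map(ph, acq, te.size)
    g = encode(f, A, mask)
    if acq.noise_sd > 0:
        streams = np.random.SeedSequence(acq.seed).spawn(te.size)
        for i, ss in enumerate(streams):
            rng = np.random.default_rng(ss)
            noise = acq.noise_sd * (
                rng.standard_normal(ph.grid) + 1j * rng.standard_normal(ph.grid)
            )
            noise[~mask, :] = 0.0
            g.data[i] = g.data[i] + noise
    return g
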