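"""ROI-based quantitative comparison of T2 maps.

Per-ROI mean and standard deviation of the fitted T2, optionally against a
ground-truth map, mirroring how relaxometry phantoms are scored vial by
vial.  Standard deviations use the population (ddof=0) convention.  By
default each ROI is eroded by one pixel before statistics to exclude
partial-volume rim pixels of the synthetic phantom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_erosion

from .types import T2Map

__all__ = ["RoiReport", "roi_stats", "compare_methods"]


@dataclass
class RoiReport:
    """Per-ROI summary: label -> dict(mean, std, n, truth, rel_error)."""

    stats: dict[str, dict]
    method: str = ""

    def labels(self) -> list[str]:
        return sorted(self.stats)


def roi_stats(
    t2: T2Map,
    rois: dict[str, np.ndarray],
    truth: T2Map | None = None,
    erode: bool = True,
    method: str = "",
) -> RoiReport:
    """Mean/std of T2 per labeled ROI; relative error if truth is given.

    Empty ROIs (after optional erosion) are dropped with a warning rather
    than raising, so a sparse label set still yields a report.
    """
    out: dict[str, dict] = {}
    for label, mask in rois.items():
        mask = np.asarray(mask).astype(bool)
        if mask.shape != t2.data.shape:
            raise ValueError(f"ROI {label!r} shape does not match the T2 map")
        if erode:
            mask = binary_erosion(mask)
        if not mask.any():
            warnings.warn(f"ROI {label!r} is empty; skipped", stacklevel=2)
            continue
        vals = t2.data[mask]
        entry = {
            "mean": float(np.mean(vals)),
            "std": float(np.std(vals)),  # population convention
            "n": int(vals.size),
        }
        if truth is not None:
            tv = float(np.mean(truth.data[mask]))
            entry["truth"] = tv
            entry["rel_error"] = abs(entry["mean"] - tv) / tv
        out[label] = entry
    return RoiReport(stats=out, method=method)


def compare_methods(reports: list[RoiReport]) -> dict[str, dict]:
    """Side-by-side table keyed by ROI x method, with std ratios.

    The ratio column divides each method's per-ROI std by the first
    (reference) report's std, so values below 1 mean lower pixelwise
    variation than the reference.
    """
    if not reports:
        raise ValueError("need at least one report")
    labels = reports[0].labels()
    for r in reports[1:]:
        if r.labels() != labels:
            raise ValueError("reports do not share ROI labels")
    ref = reports[0]
    table: dict[str, dict] = {}
    for label in labels:
        row = {}
        for idx, r in enumerate(reports):
            name = r.method or f"method{idx}"
            entry = dict(r.stats[label])
            ref_std = ref.stats[label]["std"]
            entry["std_ratio"] = (
                entry["std"] / ref_std if ref_std > 0 else float("nan")
            )
            row[name] = entry
        table[label] = row
    return table
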