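"""Dose-volume histogram construction and scalar dose metrics.

All scalar metrics are voxel-exact (sorted counting, no histogram binning):
D_q is the largest dose d with (volume receiving >= d) / total >= q/100;
V_x is the percent of structure volume receiving at least x.  DVH curves
are for reporting only.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "DVHCurve",
    "dose_at_volume",
    "volume_at_dose",
    "relative_difference",
    "acceptable_offset_range",
    "cumulative_dvh",
]


def _masked(dose_values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty structure mask")
    return np.asarray(dose_values)[mask].astype(float).ravel()


def dose_at_volume(dose_values: np.ndarray, mask: np.ndarray, q: float) -> float:
    """D_q: largest dose received by at least q% of the structure (Gy).

    Exact sorted-voxel counting: with n in-mask voxels sorted descending,
    D_q = v[ceil(q n / 100) - 1].  q = 100 gives the in-mask minimum.
    """
    if not 0 < q <= 100:
        raise ValueError("q must be in (0, 100]")
    v = np.sort(_masked(dose_values, mask))[::-1]
    k = int(np.ceil(q / 100.0 * v.size))
    return float(v[k - 1])


def volume_at_dose(dose_values: np.ndarray, mask: np.ndarray, threshold: float) -> float:
    """V_threshold: percent of structure volume receiving >= threshold."""
    v = _masked(dose_values, mask)
    return 100.0 * float((v >= threshold).sum()) / v.size


def relative_difference(d_epl: float, d_mc: float) -> float:
    """Symmetric relative difference 2 (d_epl - d_mc) / (d_epl + d_mc)."""
    if d_epl + d_mc <= 0:
        raise ValueError("relative difference undefined for non-positive sum")
    return 2.0 * (d_epl - d_mc) / (d_epl + d_mc)


def acceptable_offset_range(
    offsets, values, threshold: float = 95.0
) -> tuple[float, float]:
    """Maximal offset interval around zero keeping the metric >= threshold.

    Piecewise-linear interpolation of ``values`` over ``offsets`` (strictly
    increasing, containing 0 in range); endpoints found by linear inverse
    interpolation.  Returns (lo, hi); an empty interval (nan, nan) with a
    warning means the plan fails already at zero offset.
    """
    offsets = np.asarray(offsets, dtype=float)
    values = np.asarray(values, dtype=float)
    if offsets.ndim != 1 or offsets.size < 2 or np.any(np.diff(offsets) <= 0):
        raise ValueError("offsets must be strictly increasing with >= 2 points")
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite metric values")
    if offsets[0] > 0 or offsets[-1] < 0:
        raise ValueError("scanned interval must contain offset 0")

    v0 = float(np.interp(0.0, offsets, values))
    if v0 < threshold:
        import warnings

        warnings.warn("metric below threshold at zero offset: empty acceptable range",
                      stacklevel=2)
        return (float("nan"), float("nan"))

    def cross(x0, y0, x1, y1):
        return x0 + (threshold - y0) * (x1 - x0) / (y1 - y0)

    i0 = int(np.searchsorted(offsets, 0.0, side="right") - 1)
    # walk left from 0
    lo = offsets[0]
    x_prev, y_prev = 0.0, v0
    for i in range(i0, -1, -1):
        x, y = offsets[i], values[i]
        if y < threshold:
            lo = cross(x_prev, y_prev, x, y)
            break
        x_prev, y_prev = x, y
    # walk right from 0
    hi = offsets[-1]
    x_prev, y_prev = 0.0, v0
    for i in range(i0 + 1, offsets.size):
        x, y = offsets[i], values[i]
        if y < threshold:
            hi = cross(x_prev, y_prev, x, y)
            break
        x_prev, y_prev = x, y
    return (float(lo), float(hi))


@dataclass
class DVHCurve:
    """Cumulative DVH: volume fraction receiving at least each dose level."""

    dose: np.ndarray
    volume_fraction: np.ndarray

    def __post_init__(self) -> None:
        self.dose = np.asarray(self.dose, dtype=float)
        self.volume_fraction = np.asarray(self.volume_fraction, dtype=float)
        if self.dose.shape != self.volume_fraction.shape:
            raise ValueError("dose and volume axes must match")
        if np.any(np.diff(self.dose) <= 0):
            raise ValueError("dose axis must be strictly increasing")

    def to_csv(self, path: str | Path) -> None:
        arr = np.column_stack([self.dose, self.volume_fraction])
        np.savetxt(path, arr, delimiter=",", header="dose_gy,volume_fraction", comments="")


def cumulative_dvh(dose_values: np.ndarray, mask: np.ndarray, bin_width: float) -> DVHCurve:
    """Cumulative DVH sampled at multiples of ``bin_width`` from 0 past Dmax."""
    if bin_width <= 0:
        raise ValueError("bin width must be > 0")
    v = np.sort(_masked(dose_values, mask))
    edges = np.arange(0.0, v[-1] + 2 * bin_width, bin_width)
    # fraction of voxels with dose >= edge
    frac = 1.0 - np.searchsorted(v, edges, side="left") / v.size
    return DVHCurve(edges, frac)
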