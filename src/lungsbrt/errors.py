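"""Systematic and random geometric targeting errors for beam sets.

A systematic error is one rigid offset applied to every beam (source and
target both shifted, so direction and SAD are preserved) -- the model of a
tracking system following a consistently wrong target estimate.  A random
error assigns each beam its own rigid offset; the per-axis offsets are
centered uniform variates rescaled so the realized root-square-sum of the
per-axis SDs (sigma_tot) matches the requested magnitude exactly, with
equal per-axis allocation sigma_tot / sqrt(3).

Axis order everywhere: (LR, AP, CC); +CC is cranial, -CC caudal.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .beams import Beam, BeamSet

__all__ = [
    "SystematicOffset",
    "RandomErrorSet",
    "sigma_tot",
    "generate_random_errors",
    "apply_systematic",
    "apply_random",
]


@dataclass
class SystematicOffset:
    """Rigid 3-vector offset in mm, (LR, AP, CC); +CC = cranial."""

    shift: np.ndarray

    def __post_init__(self) -> None:
        self.shift = np.asarray(self.shift, dtype=float)
        if self.shift.shape != (3,) or not np.all(np.isfinite(self.shift)):
            raise ValueError("offset must be a finite 3-vector")

    @classmethod
    def cc(cls, mm: float) -> "SystematicOffset":
        """Craniocaudal offset (+ cranial, - caudal)."""
        return cls(np.array([0.0, 0.0, float(mm)]))


def sigma_tot(sigma_cc: float, sigma_lr: float, sigma_ap: float) -> float:
    """Overall error magnitude: root-square sum of the per-axis SDs (mm)."""
    if sigma_cc < 0 or sigma_lr < 0 or sigma_ap < 0:
        raise ValueError("per-axis SDs must be >= 0")
    return float(np.sqrt(sigma_cc**2 + sigma_lr**2 + sigma_ap**2))


@dataclass
class RandomErrorSet:
    """Per-beam offsets (n_beams x 3, mm) with their per-axis SDs."""

    offsets: np.ndarray
    sigma_axis: np.ndarray  # (LR, AP, CC) sample SDs
    sigma_total: float
    seed: int

    def __post_init__(self) -> None:
        self.offsets = np.asarray(self.offsets, dtype=float)
        self.sigma_axis = np.asarray(self.sigma_axis, dtype=float)
        if self.offsets.ndim != 2 or self.offsets.shape[1] != 3:
            raise ValueError("offsets must be (n_beams, 3)")
        rss = float(np.sqrt(np.sum(self.sigma_axis**2)))
        if abs(rss - self.sigma_total) > 1e-9:
            raise ValueError("sigma_total must equal the root-square sum of per-axis SDs")
        if self.sigma_total > 0:
            lo, hi = self.sigma_axis.min(), self.sigma_axis.max()
            if lo <= 0 or hi / lo > 1.2:
                raise ValueError("per-axis SDs must be approximately equal (max/min <= 1.2)")

    @property
    def n_beams(self) -> int:
        return self.offsets.shape[0]

    def to_csv(self, path: str | Path) -> None:
        buf = io.StringIO()
        buf.write(f"# seed={self.seed} sigma_tot_mm={float(self.sigma_total)!r}\n")
        buf.write(f"# sigma_axis_mm={self.sigma_axis.tolist()!r}\n")
        buf.write("beam,dLR_mm,dAP_mm,dCC_mm\n")
        for i, (dx, dy, dz) in enumerate(self.offsets):
            buf.write(f"{i},{float(dx)!r},{float(dy)!r},{float(dz)!r}\n")
        Path(path).write_text(buf.getvalue())

    @classmethod
    def from_csv(cls, path: str | Path) -> "RandomErrorSet":
        lines = Path(path).read_text().splitlines()
        seed = int(lines[0].split("seed=")[1].split()[0])
        stot = float(lines[0].split("sigma_tot_mm=")[1])
        sax = np.array(eval(lines[1].split("sigma_axis_mm=")[1]))  # noqa: S307 - own format
        rows = [[float(x) for x in ln.split(",")[1:]] for ln in lines[3:] if ln]
        return cls(np.array(rows), sax, stot, seed)


def generate_random_errors(n_beams: int, sigma_tot_target: float, seed: int = 0) -> RandomErrorSet:
    """Per-beam random offsets with realized sigma_tot exactly on target.

    Uniform [0, 1] draws per axis are centered by their sample mean and
    rescaled by their realized sample SD to sigma_tot / sqrt(3) per axis.
    sigma_tot_target = 0 is the explicit degenerate all-zero case.
    """
    if n_beams < 2:
        raise ValueError("need >= 2 beams for a defined per-axis SD")
    if sigma_tot_target < 0:
        raise ValueError("sigma_tot must be >= 0")
    if sigma_tot_target == 0:
        return RandomErrorSet(np.zeros((n_beams, 3)), np.zeros(3), 0.0, seed)
    rng = np.random.default_rng(seed)
    draws = rng.uniform(0.0, 1.0, size=(n_beams, 3))
    centered = draws - draws.mean(axis=0, keepdims=True)
    sd = centered.std(axis=0, ddof=0)
    if np.any(sd == 0):  # pathological; cannot rescale
        raise ValueError("degenerate draws with zero spread")
    target_axis = sigma_tot_target / np.sqrt(3.0)
    offsets = centered * (target_axis / sd)
    sigma_axis = np.full(3, target_axis)
    return RandomErrorSet(offsets, sigma_axis, float(sigma_tot_target), seed)


def _shifted(beam: Beam, delta: np.ndarray) -> Beam:
    return Beam(beam.source + delta, beam.target + delta, beam.diameter, beam.mu)


def apply_systematic(beams: BeamSet, offset: SystematicOffset) -> BeamSet:
    """Rigidly translate every beam by the offset (original set untouched)."""
    return BeamSet([_shifted(b, offset.shift) for b in beams], beams.sad)


def apply_random(beams: BeamSet, errs: RandomErrorSet) -> BeamSet:
    """Rigidly translate beam i by its own offset row."""
    if errs.n_beams != len(beams):
        raise ValueError(
            f"error set has {errs.n_beams} rows but beam set has {len(beams)} beams"
        )
    return BeamSet(
        [_shifted(b, errs.offsets[i]) for i, b in enumerate(beams)], beams.sad
    )
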