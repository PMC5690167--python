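"""Voxel grids, structure masks and NIfTI I/O.

Coordinate convention (fixed package-wide): 0-based voxel indices; the world
coordinate of the *center* of voxel (i, j, k) is ``origin + index * spacing``
in mm.  Axes are labelled (x, y, z) = (LR, AP, CC); +z is cranial, +y is
posterior (toward the couch), +x is patient-left.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "Grid3D",
    "DensityGrid",
    "DoseGrid",
    "StructureSet",
    "write_grid",
    "read_density",
    "read_dose",
    "read_mask",
]


@dataclass
class Grid3D:
    """A 3-D scalar field on a regular axis-aligned voxel lattice."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"grid values must be 3-D, got ndim={self.values.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        """Voxel volume in mm^3."""
        return float(np.prod(self.spacing))

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        """World (mm) coordinates of voxel-center indices (..., 3)."""
        return np.asarray(self.origin) + np.asarray(idx) * np.asarray(self.spacing)

    def world_axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis voxel-center coordinates."""
        return tuple(  # type: ignore[return-value]
            self.origin[a] + self.spacing[a] * np.arange(self.shape[a]) for a in range(3)
        )

    def same_geometry(self, other: "Grid3D", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )


@dataclass
class DensityGrid(Grid3D):
    """Water-equivalent density map (dimensionless rho_w); the phantom 'CT'."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if np.any(self.values < 0):
            raise ValueError("density values must be non-negative")


@dataclass
class DoseGrid(Grid3D):
    """Absorbed dose in Gy; ``meta`` carries engine bookkeeping."""

    meta: dict = field(default_factory=dict)

    def scaled(self, s: float) -> "DoseGrid":
        return DoseGrid(self.values * float(s), self.spacing, self.origin, dict(self.meta))


@dataclass
class StructureSet:
    """Named boolean masks sharing one grid geometry.

    Conventional names: GTV, PTV, lungs, cord, esophagus, heart.
    """

    masks: dict[str, np.ndarray]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        shapes = {m.shape for m in self.masks.values()}
        if len(shapes) > 1:
            raise ValueError(f"masks must share one shape, got {shapes}")
        for name, m in self.masks.items():
            if m.dtype != bool:
                self.masks[name] = m.astype(bool)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]

    def __contains__(self, name: str) -> bool:
        return name in self.masks

    @property
    def names(self) -> list[str]:
        return list(self.masks)

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def volume_cc(self, name: str) -> float:
        """Structure volume in cm^3 (voxel-center counting)."""
        return float(self.masks[name].sum()) * self.voxel_volume / 1000.0


def _affine(spacing, origin) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    aff[:3, 3] = origin
    return aff


def write_grid(path: str | Path, grid: Grid3D | np.ndarray, spacing=None, origin=None) -> None:
    """Write a grid (or a boolean mask) as NIfTI.

    Masks are stored as uint8, densities/doses as float32.  The affine is
    diagonal: spacing on the diagonal, origin in the translation column.
    """
    if isinstance(grid, Grid3D):
        values, spacing, origin = grid.values, grid.spacing, grid.origin
    else:
        values = np.asarray(grid)
        if spacing is None:
            raise ValueError("spacing required when writing a bare array")
        origin = origin if origin is not None else (0.0, 0.0, 0.0)
    if values.dtype == bool:
        data = values.astype(np.uint8)
    else:
        data = values.astype(np.float32)
    nib.save(nib.Nifti1Image(data, _affine(spacing, origin)), str(path))


def _read(path: str | Path) -> tuple[np.ndarray, tuple, tuple]:
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types for bad payloads
        raise ValueError(f"could not read NIfTI from {path}: {exc}") from exc
    aff = img.affine
    off_diag = aff[:3, :3] - np.diag(np.diag(aff[:3, :3]))
    if np.max(np.abs(off_diag)) > 1e-6:
        raise ValueError(f"non-axis-aligned affine in {path}; rotated/sheared grids unsupported")
    spacing = tuple(float(aff[a, a]) for a in range(3))
    if any(s <= 0 for s in spacing):
        raise ValueError(f"inconsistent affine in {path}: non-positive spacing {spacing}")
    origin = tuple(float(aff[a, 3]) for a in range(3))
    return np.asanyarray(img.dataobj), spacing, origin


def read_density(path: str | Path) -> DensityGrid:
    values, spacing, origin = _read(path)
    return DensityGrid(values.astype(np.float32), spacing, origin)


def read_dose(path: str | Path) -> DoseGrid:
    values, spacing, origin = _read(path)
    return DoseGrid(values.astype(np.float32), spacing, origin)


def read_mask(path: str | Path) -> tuple[np.ndarray, tuple, tuple]:
    """Read a boolean mask; returns (mask, spacing, origin)."""
    values, spacing, origin = _read(path)
    return values.astype(bool), spacing, origin
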