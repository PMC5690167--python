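"""Synthetic thorax phantoms for lung SBRT dosimetry studies.

The generator emulates the anatomy statistics of a lung SBRT cohort: a
soft-tissue body, two low-density lungs (rho_w ~ 0.3 +/- 0.18), a dense
spherical gross tumor volume (GTV, rho_w ~ 1.0 +/- 0.12) embedded in one
lung, and the organs at risk (spinal cord, esophagus, heart).  The planning
target volume (PTV) is the GTV expanded by a Euclidean margin (default 3 mm).
Density noise is i.i.d. Gaussian per voxel, truncated at zero; the GTV
boundary is blended into the surrounding lung by a partial-volume ramp, so
the 3 mm PTV-periphery shell realizes an intermediate density (~0.4) without
being painted as a separate region.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage

from .grids import DensityGrid, StructureSet

__all__ = ["PhantomSpec", "build_phantom", "dilate_mask", "DEFAULT_DENSITIES"]

# (mean, SD) of water-equivalent density per tissue class.
DEFAULT_DENSITIES: dict[str, tuple[float, float]] = {
    "body": (1.0, 0.05),
    "lung": (0.3, 0.18),
    "gtv": (1.0, 0.12),
    "heart": (1.1, 0.03),
    "cord": (1.0, 0.02),
    "esophagus": (1.0, 0.15),
}


@dataclass
class PhantomSpec:
    """Everything needed to build one phantom deterministically.

    gtv_volume_cc : requested GTV volume (study range 1.7-33.9 cc)
    ptv_margin_mm : isotropic Euclidean GTV->PTV expansion
    gtv_shape     : "sphere" or "ellipsoid" (axis ratios in gtv_aspect)
    gtv_offset_mm : GTV center offset from the host-lung center (LR, AP, CC),
                    the reduced stand-in for lobar placement
    densities     : per-tissue (mean, SD) of rho_w
    """

    gtv_volume_cc: float = 20.0
    ptv_margin_mm: float = 3.0
    gtv_shape: str = "sphere"
    gtv_aspect: tuple[float, float, float] = (1.0, 1.0, 1.0)
    gtv_offset_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (2.5, 2.5, 2.5)
    densities: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_DENSITIES)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gtv_volume_cc <= 0 or self.gtv_volume_cc > 200:
            raise ValueError(f"GTV volume {self.gtv_volume_cc} cc outside (0, 200]")
        if self.ptv_margin_mm < 0:
            raise ValueError("PTV margin must be >= 0")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"non-positive spacing {self.spacing}")
        if self.gtv_shape not in ("sphere", "ellipsoid"):
            raise ValueError(f"unknown gtv_shape {self.gtv_shape!r}")
        for name, (mu, sd) in self.densities.items():
            if mu < 0 or sd < 0:
                raise ValueError(f"negative density parameters for {name}")

    # -- YAML round trip ---------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PhantomSpec":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        for key in ("gtv_aspect", "gtv_offset_mm", "shape", "spacing"):
            if key in d:
                d[key] = tuple(d[key])
        if "densities" in d:
            d["densities"] = {k: tuple(v) for k, v in d["densities"].items()}
        return cls(**d)


def dilate_mask(
    mask: np.ndarray, margin_mm: float, spacing: tuple[float, float, float]
) -> np.ndarray:
    """Euclidean dilation of a boolean mask by a physical margin in mm.

    Every output voxel center lies within ``margin_mm`` (Euclidean, honoring
    anisotropic spacing) of some input voxel center.
    """
    mask = np.asarray(mask, dtype=bool)
    if margin_mm < 0:
        raise ValueError("margin must be >= 0")
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"invalid spacing {spacing}")
    if margin_mm == 0 or not mask.any():
        return mask.copy()
    dist = ndimage.distance_transform_edt(~mask, sampling=spacing)
    return mask | (dist <= margin_mm)


def _calibrate_radius(dist: np.ndarray, target_mm3: float, voxel_volume: float) -> float:
    """Radius such that the voxelized volume best matches the request."""
    r0 = (3.0 * target_mm3 / (4.0 * np.pi)) ** (1.0 / 3.0)
    lo, hi = 0.5 * r0, 1.6 * r0
    for _ in range(48):
        mid = 0.5 * (lo + hi)
        vol = float((dist <= mid).sum()) * voxel_volume
        if vol < target_mm3:
            lo = mid
        else:
            hi = mid
    # pick the endpoint with smaller volume error
    best = min((lo, hi), key=lambda r: abs(float((dist <= r).sum()) * voxel_volume - target_mm3))
    return best


def build_phantom(spec: PhantomSpec) -> tuple[DensityGrid, StructureSet]:
    """Build the voxel phantom and aligned structure masks.

    Deterministic per (spec, seed).  The GTV radius is calibrated against
    the voxelized volume so that the realized volume matches the request to
    well within 5% across the study range at 1-2.5 mm voxels.
    """
    nx, ny, nz = spec.shape
    sp = np.asarray(spec.spacing)
    # center the world frame on the grid center
    origin = tuple(-(np.asarray(spec.shape) - 1) / 2.0 * sp)
    x, y, z = (
        origin[0] + sp[0] * np.arange(nx),
        origin[1] + sp[1] * np.arange(ny),
        origin[2] + sp[2] * np.arange(nz),
    )
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")
    Lx, Ly, Lz = np.asarray(spec.shape) * sp

    # --- geometry (fractions of grid extent keep placements valid at any size)
    body = (X / (0.47 * Lx)) ** 2 + (Y / (0.42 * Ly)) ** 2 <= 1.0
    lung_centers = ((-0.23 * Lx, -0.02 * Ly, 0.0), (0.23 * Lx, -0.02 * Ly, 0.0))
    lung_semi = (0.18 * Lx, 0.26 * Ly, 0.46 * Lz)
    lungs_env = np.zeros(spec.shape, dtype=bool)
    for cx, cy, cz in lung_centers:
        lungs_env |= (
            ((X - cx) / lung_semi[0]) ** 2
            + ((Y - cy) / lung_semi[1]) ** 2
            + ((Z - cz) / lung_semi[2]) ** 2
            <= 1.0
        )
    lungs_env &= body
    heart = (
        (X / (0.14 * Lx)) ** 2
        + ((Y + 0.10 * Ly) / (0.14 * Ly)) ** 2
        + ((Z + 0.18 * Lz) / (0.22 * Lz)) ** 2
    ) <= 1.0
    heart &= body
    cord = (X**2 + (Y - 0.30 * Ly) ** 2) <= 5.0**2
    cord &= body
    eso = (X**2 + (Y - 0.16 * Ly) ** 2) <= 5.0**2
    eso &= body
    lungs_env &= ~(heart | cord | eso)

    # --- GTV: calibrated sphere/ellipsoid in the left lung
    gc = np.asarray(lung_centers[0]) + np.asarray(spec.gtv_offset_mm)
    aspect = np.asarray(spec.gtv_aspect, dtype=float)
    if spec.gtv_shape == "sphere":
        aspect = np.ones(3)
    aspect = aspect / np.prod(aspect) ** (1.0 / 3.0)  # unit-volume normalization
    dist = np.sqrt(
        ((X - gc[0]) / aspect[0]) ** 2
        + ((Y - gc[1]) / aspect[1]) ** 2
        + ((Z - gc[2]) / aspect[2]) ** 2
    )
    vv = float(np.prod(sp))
    r = _calibrate_radius(dist, spec.gtv_volume_cc * 1000.0, vv)
    gtv = dist <= r
    # reject tumors that do not fit inside the host lung with the PTV margin
    pad = spec.ptv_margin_mm + float(sp.max())
    if r * float(aspect.max()) + pad > min(lung_semi):
        raise ValueError(
            f"GTV radius {r:.1f} mm (+margin) exceeds the lung envelope {min(lung_semi):.1f} mm"
        )
    ptv = dilate_mask(gtv, spec.ptv_margin_mm, tuple(sp))

    # GTV fraction used only for density painting: 1 inside the mask, and a
    # half-ramp over ~one voxel outside it (partial-volume blend that gives the
    # PTV-periphery shell its intermediate lung/tumor density)
    h = float(sp.mean())
    frac = np.where(
        dist <= r, 1.0, 0.35 * np.clip(1.0 - (dist - r) / (0.8 * h), 0.0, 1.0)
    )
    frac[~ptv] = 0.0  # the blend is confined to the PTV-periphery shell

    # --- density painting, fixed order for determinism
    rng = np.random.default_rng(spec.seed)

    def sample(name: str, size) -> np.ndarray:
        mu, sd = spec.densities.get(name, spec.densities["body"])
        return rng.normal(mu, sd, size=size)

    rho = np.zeros(spec.shape, dtype=np.float64)
    rho[body] = sample("body", int(body.sum()))
    rho[lungs_env] = sample("lung", int(lungs_env.sum()))
    rho[heart] = sample("heart", int(heart.sum()))
    rho[cord] = sample("cord", int(cord.sum()))
    rho[eso] = sample("esophagus", int(eso.sum()))
    gtv_zone = frac > 0
    rho[gtv_zone] = (
        frac[gtv_zone] * sample("gtv", int(gtv_zone.sum())) + (1.0 - frac[gtv_zone]) * rho[gtv_zone]
    )
    np.clip(rho, 0.0, None, out=rho)

    grid = DensityGrid(rho.astype(np.float32), tuple(sp), origin)
    structures = StructureSet(
        masks={
            "GTV": gtv,
            "PTV": ptv,
            "lungs": lungs_env & ~gtv,
            "cord": cord,
            "esophagus": eso,
            "heart": heart,
            "body": body,
        },
        spacing=tuple(sp),
        origin=origin,
    )
    return grid, structures
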