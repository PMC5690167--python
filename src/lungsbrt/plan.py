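"""Beam-weight optimization, normalization and plan-quality statistics.

Planning criteria (SBRT, prescription 60 Gy / 3 fractions by default):
(i) the entire GTV and (ii) >= 95% of the PTV receive the prescription,
(iii) 99% of the PTV receives >= 95% of the prescription, (iv) organs at
risk stay under configurable limits, (v) the conformity index (prescription
isodose volume / PTV volume) stays <= 1.2.  Optimization runs on the
path-length (EPL) engine only, mirroring the clinical two-step workflow:
EPL optimization first, heterogeneity-aware recomputation afterwards.

The optimizer is a projected-gradient scheme on non-negative MU weights
against precomputed per-beam voxel dose matrices (dose linearity makes the
matrices exact), followed by a linear rescaling that pins PTV coverage.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .beams import BeamSet
from .dvh import dose_at_volume, volume_at_dose
from .epl import BeamDoseModel, beam_dose_matrix, compute_epl_dose
from .grids import DensityGrid, DoseGrid, StructureSet

__all__ = [
    "PlanCriteria",
    "PlanResult",
    "optimize_weights",
    "normalize_to_coverage",
    "conformity_index",
    "rx_isodose_line",
    "check_criteria",
    "metric_battery",
]

# default OAR limits, loosely set from typical SBRT magnitudes (configurable)
DEFAULT_OAR_LIMITS: dict[str, dict[str, float]] = {
    "cord": {"D1": 40.0},        # % of Rx
    "esophagus": {"D1": 50.0},   # % of Rx
    "heart": {"D1": 60.0},       # % of Rx
    "lungs": {"V20Gy": 20.0},    # % of lung volume
}


@dataclass
class PlanCriteria:
    rx: float = 60.0
    fractions: int = 3
    gtv_coverage: float = 100.0      # % of GTV at Rx
    ptv_coverage: float = 95.0       # % of PTV at Rx
    ptv_d99_pct: float = 95.0        # D99(PTV) >= this % of Rx
    ci_limit: float = 1.2
    idl_range: tuple[float, float] = (79.0, 85.0)
    oar_limits: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_OAR_LIMITS.items()}
    )

    def __post_init__(self) -> None:
        if self.rx <= 0:
            raise ValueError("prescription dose must be > 0")
        for v in (self.gtv_coverage, self.ptv_coverage, self.ptv_d99_pct):
            if not 0 <= v <= 100:
                raise ValueError("coverage requirements must be in [0, 100]%")

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["idl_range"] = list(d["idl_range"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PlanCriteria":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "idl_range" in d:
            d["idl_range"] = tuple(d["idl_range"])
        return cls(**d)


@dataclass
class PlanResult:
    beams: BeamSet                 # with optimized MUs
    dose: DoseGrid                 # EPL dose of the returned plan
    metrics: dict                  # achieved metric table
    feasible: bool
    violations: list[str]
    normalization_scale: float     # final linear MU scale applied
    engine: str = "epl"


def normalize_to_coverage(dose: DoseGrid, ptv: np.ndarray, rx: float,
                          coverage: float = 95.0) -> float:
    """Scale factor s with V_rx(PTV) = coverage after scaling.

    s = rx / D_coverage(PTV); exact to the voxel-counting convention.
    """
    d_cov = dose_at_volume(dose.values, ptv, coverage)
    if d_cov <= 0:
        raise ValueError("PTV dose is zero; cannot normalize")
    return float(rx / d_cov)


def conformity_index(dose: DoseGrid, ptv: np.ndarray, rx: float) -> float:
    """Prescription isodose volume / PTV volume (>= 1 means spillage)."""
    ptv = np.asarray(ptv, dtype=bool)
    if not ptv.any():
        raise ValueError("empty PTV")
    v_iso = int((np.asarray(dose.values) >= rx).sum())
    if v_iso == 0:
        warnings.warn("prescription isodose volume is empty; CI = 0", stacklevel=2)
        return 0.0
    return float(v_iso) / float(ptv.sum())


def rx_isodose_line(dose: DoseGrid, rx: float) -> float:
    """Prescription isodose line: 100 * rx / Dmax (%)."""
    dmax = float(np.max(dose.values))
    if dmax <= 0:
        raise ValueError("zero dose grid")
    return 100.0 * rx / dmax


def check_criteria(dose: DoseGrid, structures: StructureSet,
                   criteria: PlanCriteria) -> list[str]:
    """Named violations of the planning criteria for this dose (empty = pass)."""
    rx = criteria.rx
    out: list[str] = []
    v_gtv = volume_at_dose(dose.values, structures["GTV"], rx)
    if v_gtv < criteria.gtv_coverage - 1e-9:
        out.append(f"GTV coverage {v_gtv:.1f}% < {criteria.gtv_coverage:.0f}%")
    v_ptv = volume_at_dose(dose.values, structures["PTV"], rx)
    if v_ptv < criteria.ptv_coverage - 1e-9:
        out.append(f"PTV V_Rx {v_ptv:.1f}% < {criteria.ptv_coverage:.0f}%")
    d99 = dose_at_volume(dose.values, structures["PTV"], 99.0)
    if d99 < criteria.ptv_d99_pct / 100.0 * rx - 1e-9:
        out.append(f"PTV D99 {100 * d99 / rx:.1f}% of Rx < {criteria.ptv_d99_pct:.0f}%")
    ci = conformity_index(dose, structures["PTV"], rx)
    if ci > criteria.ci_limit + 1e-9:
        out.append(f"CI {ci:.2f} > {criteria.ci_limit:.2f}")
    for organ, limits in criteria.oar_limits.items():
        if organ not in structures:
            continue
        for metric, limit in limits.items():
            if metric.startswith("D"):
                q = float(metric[1:])
                val = 100.0 * dose_at_volume(dose.values, structures[organ], q) / rx
                if val > limit + 1e-9:
                    out.append(f"{organ} {metric} {val:.1f}% of Rx > {limit:.0f}%")
            elif metric.startswith("V"):
                thr = float(metric[1:].replace("Gy", ""))
                val = volume_at_dose(dose.values, structures[organ], thr)
                if val > limit + 1e-9:
                    out.append(f"{organ} {metric} {val:.1f}% > {limit:.0f}%")
    return out


def _optimization_voxels(structures: StructureSet, pad_mm: float = 20.0):
    """Voxel index lists for the optimizer: PTV, GTV, conformity shell, OARs."""
    sp = np.asarray(structures.spacing)
    ptv = structures["PTV"]
    gtv = structures["GTV"]
    ii = np.argwhere(ptv)
    pad = np.ceil(pad_mm / sp).astype(int)
    lo = np.maximum(ii.min(axis=0) - pad, 0)
    hi = np.minimum(ii.max(axis=0) + pad + 1, np.asarray(ptv.shape))
    box = np.zeros_like(ptv)
    box[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = True
    shell = box & ~ptv
    rng = np.random.default_rng(0)  # subsampling only; plan itself is deterministic

    def idx_of(mask, cap=6000):
        w = np.argwhere(mask)
        if w.shape[0] > cap:
            w = w[rng.choice(w.shape[0], cap, replace=False)]
        return w

    oars = {}
    for name in ("cord", "esophagus", "heart", "lungs"):
        if name in structures and structures[name].any():
            oars[name] = idx_of(structures[name] & ~ptv)
    return np.argwhere(ptv), np.argwhere(gtv), np.argwhere(shell), oars


def optimize_weights(
    grid: DensityGrid,
    structures: StructureSet,
    beams: BeamSet,
    criteria: PlanCriteria | None = None,
    model: BeamDoseModel | None = None,
    n_iter: int = 200,
    mu_init: np.ndarray | None = None,
) -> PlanResult:
    """EPL-based MU optimization against the planning criteria.

    Projected gradient on non-negative MUs: quadratic pull of PTV voxels to
    a uniform target a few percent above Rx, one-sided quadratic penalties
    on conformity-shell and OAR voxels, then a linear rescale pinning GTV
    coverage at 100% and PTV coverage at >= the required level.  If the
    returned plan still violates a criterion the result is declared
    infeasible with the binding constraint named (never silently relaxed).
    """
    criteria = criteria or PlanCriteria()
    model = model or BeamDoseModel()
    if not structures["PTV"].any():
        raise ValueError("PTV is empty")
    rx = criteria.rx

    ptv_idx, gtv_idx, shell_idx, oar_idx = _optimization_voxels(structures)
    a_ptv = beam_dose_matrix(grid, beams, ptv_idx, model)
    a_shell = beam_dose_matrix(grid, beams, shell_idx, model)
    a_oar = {k: beam_dose_matrix(grid, beams, v, model) for k, v in oar_idx.items()}
    if not np.any(a_ptv.sum(axis=1) > 0):
        raise ValueError("beams do not reach the PTV")

    target = 1.05 * rx            # uniform PTV goal slightly above Rx
    shell_cap = 0.80 * rx         # one-sided cap outside the PTV
    w_shell = 0.4
    oar_caps = {}
    for organ, limits in criteria.oar_limits.items():
        cap = min((v for m, v in limits.items() if m.startswith("D")), default=None)
        if organ in a_oar and cap is not None:
            oar_caps[organ] = 0.8 * cap / 100.0 * rx

    if mu_init is not None:
        mu = np.maximum(np.asarray(mu_init, dtype=float).copy(), 0.0)
    else:
        mu = np.full(len(beams), 1.0)
    scale0 = target / max(float((a_ptv @ mu).mean()), 1e-12)
    mu *= scale0
    # Lipschitz estimate for the step size via a few power iterations
    v = np.ones(len(beams))
    for _ in range(8):
        v = a_ptv.T @ (a_ptv @ v) + w_shell * (a_shell.T @ (a_shell @ v))
        v /= np.linalg.norm(v)
    lam = float(v @ (a_ptv.T @ (a_ptv @ v) + w_shell * (a_shell.T @ (a_shell @ v))))
    step = 1.0 / max(lam, 1e-12)

    for _ in range(n_iter):
        r_ptv = a_ptv @ mu - target
        g = a_ptv.T @ r_ptv
        r_shell = np.maximum(a_shell @ mu - shell_cap, 0.0)
        g += w_shell * (a_shell.T @ r_shell)
        for organ, cap in oar_caps.items():
            r_o = np.maximum(a_oar[organ] @ mu - cap, 0.0)
            g += a_oar[organ].T @ r_o
        mu = np.maximum(mu - step * g, 0.0)

    # linear rescale: GTV fully covered and PTV coverage at requirement
    d_ptv = a_ptv @ mu
    d_gtv = beam_dose_matrix(grid, beams, gtv_idx, model) @ mu
    s = 1.0
    if criteria.ptv_coverage > 0:
        k = int(np.ceil(criteria.ptv_coverage / 100.0 * d_ptv.size))
        d_cov = np.sort(d_ptv)[::-1][k - 1]
        if d_cov > 0:
            s = rx / d_cov
    if criteria.gtv_coverage >= 100.0 and d_gtv.size and d_gtv.min() > 0:
        s = max(s, rx / float(d_gtv.min()))
    s *= 1.0 + 1e-9  # keep the pinned quantile voxel on the >= Rx side of rounding
    mu = mu * s

    plan_beams = beams.with_mus(mu)
    dose = compute_epl_dose(grid, plan_beams, model)
    violations = check_criteria(dose, structures, criteria)
    metrics = metric_battery(dose, structures, rx).to_dict()
    return PlanResult(
        beams=plan_beams,
        dose=dose,
        metrics=metrics,
        feasible=not violations,
        violations=violations,
        normalization_scale=float(s),
    )


def metric_battery(dose: DoseGrid, structures: StructureSet, rx: float) -> pd.Series:
    """The scalar metric battery, doses in % of Rx, volumes in % of structure."""
    d = dose.values
    pct = 100.0 / rx
    vals = {}
    for s in ("GTV", "PTV"):
        m = structures[s]
        vals[f"{s}_D99"] = dose_at_volume(d, m, 99.0) * pct
        vals[f"{s}_Dmean"] = float(d[m].mean()) * pct
        vals[f"{s}_Dmax"] = float(d[m].max()) * pct
        vals[f"{s}_V{rx:.0f}Gy"] = volume_at_dose(d, m, rx)
    vals["PTV_CI"] = conformity_index(dose, structures["PTV"], rx)
    vals["Rx_IDL"] = rx_isodose_line(dose, rx)
    for s in ("lungs", "cord", "esophagus", "heart"):
        if s in structures and structures[s].any():
            vals[f"{s}_D1"] = dose_at_volume(d, structures[s], 1.0) * pct
    if "lungs" in structures and structures["lungs"].any():
        vals["lungs_V20Gy"] = volume_at_dose(d, structures["lungs"], 20.0)
    return pd.Series(vals)
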