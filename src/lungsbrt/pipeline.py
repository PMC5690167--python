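"""Full in-silico replication pipeline.

Staged workflow per replicate seed: build phantom -> EPL-optimize the beam
weights -> recompute with both engines -> renormalize the heterogeneity-
aware (MC-class) plan to 95% PTV coverage -> inject systematic craniocaudal
offsets and per-beam random errors -> recompute -> aggregate the metric
battery, offset-sweep curves, acceptable ranges and the random/systematic
equivalence ratio into a serializable report.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .beams import BeamSet, generate_beamset
from .dvh import acceptable_offset_range, dose_at_volume
from .epl import BeamDoseModel, compute_epl_dose
from .errors import SystematicOffset, apply_random, apply_systematic, generate_random_errors
from .grids import DoseGrid, write_grid
from .mc import McConfig, compute_mc_dose
from .phantom import PhantomSpec, build_phantom
from .plan import PlanCriteria, metric_battery, normalize_to_coverage, optimize_weights

__all__ = [
    "ExperimentConfig",
    "ExperimentReport",
    "run_experiment",
    "equivalence_ratio",
    "run_offset_coupling",
]


@dataclass
class ExperimentConfig:
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    n_beams: int = 100
    diameters: tuple[float, ...] = (20.0, 25.0, 30.0, 35.0, 40.0)
    criteria: PlanCriteria = field(default_factory=PlanCriteria)
    model: BeamDoseModel = field(default_factory=BeamDoseModel)
    mc: McConfig = field(default_factory=McConfig)
    systematic_sweep_mm: tuple[float, ...] = tuple(float(x) for x in range(-5, 6))
    random_sigma_mm: tuple[float, ...] = tuple(float(x) for x in range(1, 10))
    replicate_seeds: tuple[int, ...] = (0, 1, 2)
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.systematic_sweep_mm and 0.0 not in self.systematic_sweep_mm:
            raise ValueError("systematic sweep must include offset 0")
        if any(s <= 0 for s in self.random_sigma_mm):
            raise ValueError("random sigma_tot values must be positive")


@dataclass
class ExperimentReport:
    per_seed: list[dict]
    summary: dict

    def to_json(self, path: str | Path) -> None:
        payload = {"per_seed": self.per_seed, "summary": self.summary}
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def equivalence_ratio(sys_offsets, sys_d99, rand_sigmas, rand_d99):
    """Mean ratio sigma_tot / equivalent systematic offset at equal D99(GTV).

    The systematic curve is symmetrized by averaging the +/-offset values;
    each random-error D99 is inverted on the symmetrized curve by linear
    interpolation.  Random magnitudes whose D99 exceeds the curve maximum
    are excluded and counted.  Returns (mean_ratio, per_sigma, n_excluded).
    """
    sys_offsets = np.asarray(sys_offsets, dtype=float)
    sys_d99 = np.asarray(sys_d99, dtype=float)
    rand_sigmas = np.asarray(rand_sigmas, dtype=float)
    rand_d99 = np.asarray(rand_d99, dtype=float)

    mags = np.unique(np.abs(sys_offsets))
    sym = np.array([sys_d99[np.isclose(np.abs(sys_offsets), m)].mean() for m in mags])
    # require a usable monotone-decreasing symmetrized curve
    if sym.size < 2:
        raise ValueError("need at least two systematic magnitudes")
    ratios, per_sigma, excluded = [], {}, 0
    # invert d99 -> magnitude on the decreasing curve (flip for np.interp)
    order = np.argsort(sym)
    for sig, r in zip(rand_sigmas, rand_d99):
        if r > sym.max() or r < sym.min():
            excluded += 1
            per_sigma[float(sig)] = None
            continue
        m_eq = float(np.interp(r, sym[order], mags[order]))
        if m_eq <= 0:
            excluded += 1
            per_sigma[float(sig)] = None
            continue
        ratio = float(sig) / m_eq
        ratios.append(ratio)
        per_sigma[float(sig)] = ratio
    if not ratios:
        raise ValueError("no usable sigma_tot values: random curve outside systematic range")
    return float(np.mean(ratios)), per_sigma, excluded


def _d99_pct(dose: DoseGrid, mask, rx: float) -> float:
    return 100.0 * dose_at_volume(dose.values, mask, 99.0) / rx


def run_offset_coupling(
    cfg: ExperimentConfig,
    offsets_mm=(-3.0, 3.0),
    include_mc: bool = True,
) -> dict:
    """Offset-vs-planned D99 differences, the core coupling measurement.

    For each replicate seed: EPL-optimize, record the planned D99(PTV) per
    engine (the MC plan renormalized to the required PTV coverage), rigidly
    shift all beams along CC by each offset, recompute D99(GTV), and report
    per-engine means over signs and seeds of D99(GTV at offset) minus the
    planned D99(PTV), in percentage points of the prescription.
    """
    rx = cfg.criteria.rx
    per_seed = []
    for seed in cfg.replicate_seeds:
        spec = dataclasses.replace(cfg.phantom, seed=seed)
        grid, structures = build_phantom(spec)
        gtv_center = np.asarray(structures.spacing) * np.argwhere(structures["GTV"]).mean(axis=0)
        gtv_center = gtv_center + np.asarray(structures.origin)
        beams = generate_beamset(cfg.n_beams, gtv_center, cfg.diameters,
                                 sad=cfg.model.sad, seed=seed)
        plan = optimize_weights(grid, structures, beams, cfg.criteria, cfg.model)
        rec = {
            "seed": seed,
            "feasible": plan.feasible,
            "violations": plan.violations,
            "epl_planned_d99_ptv": _d99_pct(plan.dose, structures["PTV"], rx),
            "epl_planned_d99_gtv": _d99_pct(plan.dose, structures["GTV"], rx),
            "epl_offset_d99_gtv": {},
        }
        for off in offsets_mm:
            shifted = apply_systematic(plan.beams, SystematicOffset.cc(off))
            dose_off = compute_epl_dose(grid, shifted, cfg.model)
            rec["epl_offset_d99_gtv"][off] = _d99_pct(dose_off, structures["GTV"], rx)
        if include_mc:
            mc_cfg = dataclasses.replace(cfg.mc, seed=seed)
            mc_dose, _ = compute_mc_dose(grid, plan.beams, mc_cfg, cfg.model)
            rec["mc_nonnorm_vrx_ptv"] = float(
                100.0 * (mc_dose.values[structures["PTV"]] >= rx).mean()
            )
            s_mc = normalize_to_coverage(mc_dose, structures["PTV"], rx,
                                         cfg.criteria.ptv_coverage)
            rec["mc_renorm_scale"] = s_mc
            mc_renorm = mc_dose.scaled(s_mc)
            rec["mc_planned_d99_ptv"] = _d99_pct(mc_renorm, structures["PTV"], rx)
            rec["mc_planned_d99_gtv"] = _d99_pct(mc_renorm, structures["GTV"], rx)
            rec["mc_uncertainty"] = mc_dose.meta["rel_uncertainty"]
            rec["mc_uncertainty_met"] = mc_dose.meta["uncertainty_met"]
            rec["mc_offset_d99_gtv"] = {}
            renorm_beams = plan.beams.with_mus(
                np.array([b.mu for b in plan.beams]) * s_mc
            )
            for off in offsets_mm:
                shifted = apply_systematic(renorm_beams, SystematicOffset.cc(off))
                mc_cfg_off = dataclasses.replace(cfg.mc, seed=seed + 1000 + int(off * 101))
                dose_off, _ = compute_mc_dose(grid, shifted, mc_cfg_off, cfg.model)
                rec["mc_offset_d99_gtv"][off] = _d99_pct(dose_off, structures["GTV"], rx)
        per_seed.append(rec)

    epl_diffs = [
        rec["epl_offset_d99_gtv"][o] - rec["epl_planned_d99_ptv"]
        for rec in per_seed for o in offsets_mm
    ]
    out = {
        "per_seed": per_seed,
        "offsets_mm": list(offsets_mm),
        "epl_diff_pp": float(np.mean(epl_diffs)),
        "epl_diff_sd_pp": float(np.std(epl_diffs)),
    }
    if include_mc:
        mc_diffs = [
            rec["mc_offset_d99_gtv"][o] - rec["mc_planned_d99_ptv"]
            for rec in per_seed for o in offsets_mm
        ]
        out["mc_diff_pp"] = float(np.mean(mc_diffs))
        out["mc_diff_sd_pp"] = float(np.std(mc_diffs))
    return out


def run_experiment(cfg: ExperimentConfig) -> ExperimentReport:
    """The full staged replication; see module docstring."""
    rx = cfg.criteria.rx
    outdir = Path(cfg.output_dir) if cfg.output_dir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
    per_seed: list[dict] = []
    for seed in cfg.replicate_seeds:
        spec = dataclasses.replace(cfg.phantom, seed=seed)
        grid, structures = build_phantom(spec)
        gtv_center = np.asarray(structures.spacing) * np.argwhere(structures["GTV"]).mean(axis=0)
        gtv_center = gtv_center + np.asarray(structures.origin)
        beams = generate_beamset(cfg.n_beams, gtv_center, cfg.diameters,
                                 sad=cfg.model.sad, seed=seed)
        plan = optimize_weights(grid, structures, beams, cfg.criteria, cfg.model)
        if not plan.feasible:
            raise RuntimeError(
                f"seed {seed}: EPL optimization infeasible: {plan.violations}"
            )
        mc_cfg = dataclasses.replace(cfg.mc, seed=seed)
        mc_dose, mc_unc = compute_mc_dose(grid, plan.beams, mc_cfg, cfg.model)
        s_mc = normalize_to_coverage(mc_dose, structures["PTV"], rx, cfg.criteria.ptv_coverage)
        mc_renorm = mc_dose.scaled(s_mc)

        rec: dict = {
            "seed": seed,
            "table2": {
                "EPL": metric_battery(plan.dose, structures, rx).round(6).to_dict(),
                "MC_nonnormalized": metric_battery(mc_dose, structures, rx).round(6).to_dict(),
                "MC_renormalized": metric_battery(mc_renorm, structures, rx).round(6).to_dict(),
            },
            "mc_renorm_scale": float(s_mc),
            "mc_uncertainty_met": bool(mc_dose.meta["uncertainty_met"]),
        }
        if outdir:
            write_grid(outdir / f"seed{seed}_density.nii.gz", grid)
            write_grid(outdir / f"seed{seed}_dose_epl.nii.gz", plan.dose)
            write_grid(outdir / f"seed{seed}_dose_mc.nii.gz", mc_dose)
            write_grid(outdir / f"seed{seed}_dose_mc_unc.nii.gz", mc_unc)
            plan.beams.to_json(outdir / f"seed{seed}_beams.json")

        # systematic sweep (CC axis)
        if cfg.systematic_sweep_mm:
            renorm_beams = plan.beams.with_mus(
                np.array([b.mu for b in plan.beams]) * s_mc
            )
            sweep: dict = {"offsets_mm": list(cfg.systematic_sweep_mm),
                           "epl_d99_gtv": [], "mc_d99_gtv": []}
            for off in cfg.systematic_sweep_mm:
                shifted_epl = apply_systematic(plan.beams, SystematicOffset.cc(off))
                sweep["epl_d99_gtv"].append(
                    _d99_pct(compute_epl_dose(grid, shifted_epl, cfg.model),
                             structures["GTV"], rx)
                )
                shifted_mc = apply_systematic(renorm_beams, SystematicOffset.cc(off))
                cfg_off = dataclasses.replace(cfg.mc, seed=seed + 1000 + int(off * 101))
                d_off, _ = compute_mc_dose(grid, shifted_mc, cfg_off, cfg.model)
                sweep["mc_d99_gtv"].append(_d99_pct(d_off, structures["GTV"], rx))
            rec["systematic_sweep"] = sweep
            if len(cfg.systematic_sweep_mm) >= 2:
                rec["acceptable_range_epl_mm"] = acceptable_offset_range(
                    cfg.systematic_sweep_mm, sweep["epl_d99_gtv"], 95.0
                )
                rec["acceptable_range_mc_mm"] = acceptable_offset_range(
                    cfg.systematic_sweep_mm, sweep["mc_d99_gtv"], 95.0
                )
            # offset-vs-planned differences at the +/- margin offsets, if scanned
            margin = cfg.phantom.ptv_margin_mm
            if margin in cfg.systematic_sweep_mm and -margin in cfg.systematic_sweep_mm:
                idx = [cfg.systematic_sweep_mm.index(o) for o in (-margin, margin)]
                rec["offset_vs_planned"] = {
                    "epl_pp": float(np.mean([sweep["epl_d99_gtv"][i] for i in idx])
                                    - _d99_pct(plan.dose, structures["PTV"], rx)),
                    "mc_pp": float(np.mean([sweep["mc_d99_gtv"][i] for i in idx])
                                   - _d99_pct(mc_renorm, structures["PTV"], rx)),
                }

        # random-error sweep
        if cfg.random_sigma_mm:
            rand: dict = {"sigma_mm": list(cfg.random_sigma_mm),
                          "epl_d99_gtv": [], "mc_d99_gtv": []}
            renorm_beams = plan.beams.with_mus(
                np.array([b.mu for b in plan.beams]) * s_mc
            )
            for sig in cfg.random_sigma_mm:
                errs = generate_random_errors(len(plan.beams), sig, seed=seed * 100 + int(sig))
                rand["epl_d99_gtv"].append(
                    _d99_pct(compute_epl_dose(grid, apply_random(plan.beams, errs), cfg.model),
                             structures["GTV"], rx)
                )
                cfg_r = dataclasses.replace(cfg.mc, seed=seed + 5000 + int(sig * 131))
                d_r, _ = compute_mc_dose(grid, apply_random(renorm_beams, errs), cfg_r, cfg.model)
                rand["mc_d99_gtv"].append(_d99_pct(d_r, structures["GTV"], rx))
            rec["random_sweep"] = rand
            if cfg.systematic_sweep_mm and len(set(np.abs(cfg.systematic_sweep_mm))) >= 2:
                try:
                    r_epl, per_e, exc_e = equivalence_ratio(
                        cfg.systematic_sweep_mm, rec["systematic_sweep"]["epl_d99_gtv"],
                        cfg.random_sigma_mm, rand["epl_d99_gtv"])
                    r_mc, per_m, exc_m = equivalence_ratio(
                        cfg.systematic_sweep_mm, rec["systematic_sweep"]["mc_d99_gtv"],
                        cfg.random_sigma_mm, rand["mc_d99_gtv"])
                    rec["equivalence_ratio"] = {
                        "epl": r_epl, "mc": r_mc,
                        "epl_excluded": exc_e, "mc_excluded": exc_m,
                    }
                except ValueError as err:
                    rec["equivalence_ratio"] = {"error": str(err)}
        per_seed.append(rec)

    summary: dict = {}
    for key in ("mc_renorm_scale",):
        vals = [r[key] for r in per_seed]
        summary[key] = {"mean": float(np.mean(vals)), "sd": float(np.std(vals))}
    if all("offset_vs_planned" in r for r in per_seed) and per_seed:
        for eng in ("epl_pp", "mc_pp"):
            vals = [r["offset_vs_planned"][eng] for r in per_seed]
            summary[f"offset_vs_planned_{eng}"] = {
                "mean": float(np.mean(vals)), "sd": float(np.std(vals))
            }
    report = ExperimentReport(per_seed=per_seed, summary=summary)
    if outdir:
        report.to_json(outdir / "report.json")
        rows = []
        for r in per_seed:
            for plan_name, metrics in r["table2"].items():
                row = {"seed": r["seed"], "plan": plan_name}
                row.update(metrics)
                rows.append(row)
        pd.DataFrame(rows).to_csv(outdir / "table2.csv", index=False)
    return report
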