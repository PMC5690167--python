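"""Heterogeneity-aware engine: water benchmarks, lung physics, smoothing,
statistical self-consistency and energy bookkeeping."""

import dataclasses
import math

import numpy as np
import pytest

from lungsbrt.beams import Beam, BeamSet
from lungsbrt.grids import DensityGrid, DoseGrid
from lungsbrt.mc import McConfig, compute_mc_dose, smooth_dose


def _beam(diam, mu=1.0, sad=800.0):
    return BeamSet([Beam(np.array([0.0, 0.0, sad]), np.zeros(3), diam, mu)], sad)


def _slab_grid(lung_from=-20.0, lung_to=30.0):
    shape = (40, 40, 48)
    spacing = (2.5, 2.5, 2.5)
    origin = tuple(-(np.asarray(shape) - 1) / 2.0 * np.asarray(spacing))
    vals = np.ones(shape, dtype=np.float32)
    z = origin[2] + spacing[2] * np.arange(shape[2])
    vals[:, :, (z >= lung_from) & (z <= lung_to)] = 0.3
    return DensityGrid(vals, spacing, origin)


def test_zero_mu_gives_zero_dose_and_uncertainty(water_grid, model, fast_mc):
    dose, unc = compute_mc_dose(water_grid, _beam(30.0, mu=0.0), fast_mc, model)
    assert not dose.values.any()
    assert not unc.values.any()
    assert dose.meta["uncertainty_met"]


def test_energy_bookkeeping_deposits_no_more_than_launched(water_grid, model, fast_mc):
    dose, _ = compute_mc_dose(water_grid, _beam(40.0), fast_mc, model)
    assert 0 < dose.meta["energy_deposited"] <= dose.meta["energy_launched"]


def test_dose_is_energy_per_voxel_mass(water_grid, model, fast_mc):
    """Unsmoothed, uncalibrated dose times voxel mass recovers the tallied
    deposited energy exactly: halving a voxel's mass doubles its dose."""
    cfg = dataclasses.replace(fast_mc, smoothing=0.0)
    dose, _ = compute_mc_dose(water_grid, _beam(30.0), cfg, model, calibrate=False)
    mass = np.asarray(water_grid.values, dtype=float) * water_grid.voxel_volume
    total = float((dose.values * mass).sum()) * dose.meta["batches"]
    assert total == pytest.approx(dose.meta["energy_deposited"], rel=1e-9)


def test_water_axis_attenuation_matches_closed_form(water_grid, model, fast_mc):
    """Axis dose ratio between 50 and 100 mm depth in water follows
    inverse-square x exp(-mu * 50) (build-up and kernels cancel)."""
    cfg = dataclasses.replace(fast_mc, initial_histories=600_000, histories_cap=600_000)
    dose, unc = compute_mc_dose(water_grid, _beam(40.0), cfg, model)
    c = 20
    z_top = water_grid.origin[2] + 47 * 2.5 + 1.25
    out = {}
    for depth in (50.0, 100.0):
        k = int(round((z_top - depth - water_grid.origin[2]) / 2.5))
        out[depth] = (
            dose.values[c - 1 : c + 2, c - 1 : c + 2, k - 1 : k + 2].mean(),
            unc.values[c - 1 : c + 2, c - 1 : c + 2, k - 1 : k + 2].mean(),
        )
    z50 = 800.0 - (z_top - 50.0)
    z100 = 800.0 - (z_top - 100.0)
    expected = (z50 / z100) ** 2 * math.exp(-model.mu_water * 50.0)
    got = out[100.0][0] / out[50.0][0]
    # 3 SD of the ROI statistics plus a small model term for step effects
    tol = 3.0 * math.sqrt(out[50.0][1] ** 2 + out[100.0][1] ** 2) + 0.02
    assert abs(got - expected) / expected < max(tol, 0.03)


def test_two_seeds_differ_consistently_with_reported_uncertainty(water_grid, model, fast_mc):
    """Per-voxel differences between independent seeds are on the scale the
    batch-method uncertainty reports (chi-square-like self-consistency)."""
    cfg1 = dataclasses.replace(fast_mc, seed=11)
    cfg2 = dataclasses.replace(fast_mc, seed=22)
    d1, u1 = compute_mc_dose(water_grid, _beam(40.0), cfg1, model)
    d2, u2 = compute_mc_dose(water_grid, _beam(40.0), cfg2, model)
    high = d1.values > 0.5 * d1.values.max()
    var = (u1.values * d1.values) ** 2 + (u2.values * d2.values) ** 2
    z2 = (d1.values[high] - d2.values[high]) ** 2 / var[high]
    # smoothed fields correlate neighbors; accept a generous consistency band
    assert 0.3 < z2.mean() < 3.0


def test_seed_determinism(water_grid, model, fast_mc):
    d1, _ = compute_mc_dose(water_grid, _beam(30.0), fast_mc, model)
    d2, _ = compute_mc_dose(water_grid, _beam(30.0), fast_mc, model)
    np.testing.assert_array_equal(d1.values, d2.values)


def test_lung_deficit_for_small_field(model, fast_mc):
    """10 mm field crossing rho=0.3 lung: the heterogeneity-aware dose at
    the distal lung interface is strictly below the EPL prediction."""
    from lungsbrt.epl import compute_epl_dose

    slab = _slab_grid()
    cfg = dataclasses.replace(fast_mc, initial_histories=400_000, histories_cap=400_000)
    beams = _beam(10.0)
    epl = compute_epl_dose(slab, beams, model)
    mcd, _ = compute_mc_dose(slab, beams, cfg, model)
    c = 20
    z = slab.origin[2] + 2.5 * np.arange(48)
    k = int(np.argmin(np.abs(z - (-22.5))))  # first voxel distal to the lung slab
    assert mcd.values[c, c, k] < epl.values[c, c, k]


def test_penumbra_broader_in_lung_than_in_water(model, fast_mc):
    """80-20% lateral falloff at mid-lung depth wider than in water."""
    from scipy.interpolate import interp1d

    cfg = dataclasses.replace(fast_mc, initial_histories=600_000, histories_cap=600_000)
    water = _slab_grid(lung_from=1.0, lung_to=0.0)  # empty slab -> all water
    lung = _slab_grid()
    widths = {}
    for name, grid in (("water", water), ("lung", lung)):
        dose, _ = compute_mc_dose(grid, _beam(25.0), cfg, model)
        z = grid.origin[2] + 2.5 * np.arange(48)
        k = int(np.argmin(np.abs(z - 5.0)))  # mid-lung depth
        prof = dose.values[:, 20, k]
        x = grid.origin[0] + 2.5 * np.arange(40)
        prof = prof / prof[17:24].max()
        right = slice(20, 40)
        f = interp1d(x[right], prof[right])
        xs = np.linspace(x[20], x[39], 4000)
        ys = f(xs)
        x80 = xs[np.argmin(np.abs(ys - 0.8))]
        x20 = xs[np.argmin(np.abs(ys - 0.2))]
        widths[name] = x20 - x80
    assert widths["lung"] > widths["water"]


class TestSmoothDose:
    def test_zero_width_is_identity(self):
        rng = np.random.default_rng(0)
        dose = DoseGrid(rng.random((10, 10, 10)), (1, 1, 1))
        out = smooth_dose(dose, 0.0)
        np.testing.assert_array_equal(out.values, dose.values)

    def test_delta_spike_spreads_to_gaussian_of_requested_width(self):
        vals = np.zeros((31, 31, 31))
        vals[15, 15, 15] = 1.0
        out = smooth_dose(DoseGrid(vals, (1, 1, 1)), 2.0)
        x = np.arange(31) - 15.0
        prof = out.values[:, 15, 15]
        # moment fit of the realized SD along one axis through the spike
        w = out.values.sum(axis=(1, 2))
        sd = math.sqrt((w * x**2).sum() / w.sum())
        assert sd == pytest.approx(2.0, rel=0.05)
        assert prof.argmax() == 15

    def test_uniform_field_unchanged_in_interior(self):
        dose = DoseGrid(np.full((20, 20, 20), 3.3), (1, 1, 1))
        out = smooth_dose(dose, 1.5)
        np.testing.assert_allclose(out.values[5:-5, 5:-5, 5:-5], 3.3, rtol=1e-12)

    def test_total_dose_conserved_in_interior(self):
        rng = np.random.default_rng(5)
        vals = np.zeros((24, 24, 24))
        vals[8:16, 8:16, 8:16] = rng.random((8, 8, 8))
        out = smooth_dose(DoseGrid(vals, (1, 1, 1)), 0.6)
        assert out.values.sum() == pytest.approx(vals.sum(), rel=1e-3)

    def test_negative_width_rejected(self):
        with pytest.raises(ValueError):
            smooth_dose(DoseGrid(np.zeros((3, 3, 3)), (1, 1, 1)), -0.5)


def test_config_validation():
    with pytest.raises(ValueError):
        McConfig(uncertainty_target=0.0)
    with pytest.raises(ValueError):
        McConfig(smoothing=-1.0)
    with pytest.raises(ValueError):
        McConfig(n_batches=1)
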