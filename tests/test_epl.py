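"""EPL engine: line integrals, depth dose, profiles, and its defining
path-length-only contract (shift covariance, lateral density blindness)."""

import math

import numpy as np
import pytest

from lungsbrt import compute_epl_dose, depth_dose, off_axis_ratio, radiological_depth
from lungsbrt.beams import Beam, BeamSet
from lungsbrt.epl import BeamDoseModel, output_factor
from lungsbrt.grids import DensityGrid


def _grid(values, spacing=(1.0, 1.0, 1.0)):
    values = np.asarray(values, dtype=np.float32)
    origin = (0.0, 0.0, 0.0)
    return DensityGrid(values, spacing, origin)


class TestRadiologicalDepth:
    def test_homogeneous_water_segment(self):
        g = _grid(np.ones((100, 10, 10)))
        # 80 mm fully inside unit-density medium
        assert radiological_depth(g, (5.0, 5.0, 5.0), (85.0, 5.0, 5.0)) == pytest.approx(80.0)

    def test_two_media_against_dense_sampling_oracle(self):
        vals = np.ones((100, 10, 10))
        vals[30:] = 0.3
        g = _grid(vals)
        a, b = np.array([-0.5, 5.0, 5.0]), np.array([79.5, 5.0, 5.0])
        got = radiological_depth(g, a, b)
        # independent oracle: dense midpoint sampling of the same integrand
        ts = (np.arange(800000) + 0.5) / 800000
        pts = a + ts[:, None] * (b - a)
        idx = np.clip(np.floor(pts - np.array([-0.5, -0.5, -0.5])).astype(int), 0, 99)
        oracle = vals[idx[:, 0].clip(0, 99), idx[:, 1].clip(0, 9), idx[:, 2].clip(0, 9)]
        oracle = oracle.mean() * np.linalg.norm(b - a)
        assert got == pytest.approx(45.0, abs=1e-4)
        assert got == pytest.approx(oracle, rel=1e-4)

    def test_vacuum_grid_gives_zero(self):
        g = _grid(np.zeros((10, 10, 10)))
        assert radiological_depth(g, (-5, 3, 3), (20, 3, 3)) == 0.0

    def test_degenerate_segment_gives_zero(self):
        g = _grid(np.ones((5, 5, 5)))
        assert radiological_depth(g, (2, 2, 2), (2, 2, 2)) == 0.0

    def test_additive_over_concatenated_segments(self):
        rng = np.random.default_rng(3)
        g = _grid(rng.uniform(0, 2, (20, 20, 20)))
        a = np.array([1.3, 2.1, 0.7])
        c = np.array([17.9, 16.2, 18.4])
        b = a + 0.37 * (c - a)
        whole = radiological_depth(g, a, c)
        split = radiological_depth(g, a, b) + radiological_depth(g, b, c)
        assert whole == pytest.approx(split, rel=1e-9)

    def test_oblique_ray_matches_dense_sampling(self):
        rng = np.random.default_rng(4)
        vals = rng.uniform(0, 1.5, (24, 24, 24))
        g = _grid(vals, spacing=(1.0, 1.5, 2.0))
        a = np.array([-3.0, 1.0, 2.0])
        b = np.array([25.0, 33.0, 40.0])
        got = radiological_depth(g, a, b)
        n = 2_000_000
        ts = (np.arange(n) + 0.5) / n
        pts = a + ts[:, None] * (b - a)
        ijk = np.floor((pts - np.array(g.origin)) / np.array(g.spacing) + 0.5).astype(int)
        inside = np.all((ijk >= 0) & (ijk < 24), axis=1)
        rho = np.zeros(n)
        rho[inside] = vals[ijk[inside, 0], ijk[inside, 1], ijk[inside, 2]]
        oracle = rho.mean() * np.linalg.norm(b - a)
        assert got == pytest.approx(oracle, rel=2e-3)


class TestDepthDose:
    def test_unity_at_depth_of_maximum(self, model):
        assert depth_dose(model.depth_of_maximum, model.ref_diameter, model) == pytest.approx(
            1.0, abs=1e-12
        )

    def test_monotone_beyond_buildup(self, model):
        assert depth_dose(100.0, model=model) < depth_dose(50.0, model=model)

    def test_log_slope_matches_attenuation_coefficient(self, model):
        """Finite-difference log slope beyond build-up ~ mu within 2%."""
        d1, d2 = 120.0, 121.0
        slope = -(math.log(depth_dose(d2, model=model)) - math.log(depth_dose(d1, model=model)))
        assert slope == pytest.approx(model.mu_water, rel=0.02)

    def test_negative_depth_rejected(self, model):
        with pytest.raises(ValueError):
            depth_dose(-1.0, model=model)

    def test_output_factor_mildly_decreases_for_small_fields(self, model):
        assert output_factor(60.0, model) == pytest.approx(1.0)
        assert 0.7 < output_factor(10.0, model) < 1.0


class TestOffAxisRatio:
    def test_center_is_unity(self, model):
        assert off_axis_ratio(0.0, 40.0, model=model) == pytest.approx(1.0, abs=1e-6)

    def test_half_value_at_projected_field_edge(self, model):
        d = model.depth_of_maximum  # projected radius equals nominal radius here
        assert off_axis_ratio(20.0, 40.0, d, model) == pytest.approx(0.5, abs=1e-12)

    def test_plane_integral_close_to_field_area(self, model):
        """2-D numeric integral of the profile ~ area of the field circle."""
        r = np.linspace(0, 60.0, 6000)
        d = model.depth_of_maximum
        prof = off_axis_ratio(r, 40.0, d, model)
        integral = np.trapezoid(2 * np.pi * r * prof, r)
        assert integral == pytest.approx(np.pi * 20.0**2, rel=0.05)


class TestComputeEplDose:
    def test_zero_mu_gives_zero_grid(self, water_grid, model):
        src = np.array([0.0, 0.0, 800.0])
        bs = BeamSet([Beam(src, np.zeros(3), 20.0, mu=0.0)], 800.0)
        dose = compute_epl_dose(water_grid, bs, model)
        assert not dose.values.any()

    def test_linearity_in_mu(self, water_grid, model):
        src = np.array([0.0, 0.0, 800.0])
        bs1 = BeamSet([Beam(src, np.zeros(3), 30.0, mu=1.0)], 800.0)
        bs2 = BeamSet([Beam(src, np.zeros(3), 30.0, mu=2.0)], 800.0)
        d1 = compute_epl_dose(water_grid, bs1, model)
        d2 = compute_epl_dose(water_grid, bs2, model)
        np.testing.assert_allclose(d2.values, 2.0 * d1.values, rtol=1e-12)

    def test_single_beam_axis_dose_matches_hand_formula(self, water_grid, model):
        """Independent scalar hand-calculation at a point on the beam axis."""
        src = np.array([0.0, 0.0, 800.0])
        tgt = np.zeros(3)
        diam = 30.0
        bs = BeamSet([Beam(src, tgt, diam, mu=1.0)], 800.0)
        dose = compute_epl_dose(water_grid, bs, model)
        # axis voxel at index (20, 20, 28): world (1.25, 1.25, 21.25)
        i, j, k = 20, 20, 28
        vx = np.array(water_grid.origin) + np.array([i, j, k]) * 2.5
        z = 800.0 - vx[2]
        surface_z = water_grid.origin[2] + 47 * 2.5 + 1.25
        # radiological depth along the slightly oblique ray inside the grid
        length = np.linalg.norm(vx - src)
        depth = (surface_z - vx[2]) * length / z
        beta, mu_w = model.buildup, model.mu_water
        dmax = math.log((beta + mu_w) / mu_w) / beta
        fmax = (1 - math.exp(-beta * dmax)) * math.exp(-mu_w * dmax)
        pdd = (1 - math.exp(-beta * depth)) * math.exp(-mu_w * depth) / fmax
        r = math.hypot(vx[0], vx[1])
        sig = model.penumbra / 1.683 * z / 800.0
        from scipy.special import erfc

        oar = 0.5 * erfc((r - 0.5 * diam * z / 800.0) / (math.sqrt(2) * sig))
        p, s = model.scatter_fraction, model.scatter_sigma
        cap = lambda dd: (1 - p) + p * (1 - math.exp(-((dd / 2) ** 2) / (2 * s**2)))
        hand = model.calibration * (800.0 / z) ** 2 * pdd * oar * cap(diam) / cap(60.0)
        assert dose.values[i, j, k] == pytest.approx(hand, rel=1e-9)

    def test_empty_beamset_gives_zero_grid(self, water_grid, model):
        dose = compute_epl_dose(water_grid, BeamSet([], 800.0), model)
        assert not dose.values.any()


def test_shift_covariance_in_uniform_medium(model):
    """Rigidly translating all beams shifts the EPL dose distribution."""
    shape = (48, 48, 48)
    spacing = (2.5, 2.5, 2.5)
    origin = tuple(-(np.asarray(shape) - 1) / 2.0 * np.asarray(spacing))
    water = DensityGrid(np.ones(shape, dtype=np.float32), spacing, origin)
    from lungsbrt import generate_beamset
    from lungsbrt.errors import SystematicOffset, apply_systematic

    beams = generate_beamset(40, np.zeros(3), (25.0,), seed=2)
    d0 = compute_epl_dose(water, beams, model).values
    shift_vox = 2  # 5 mm = 2 voxels, exact grid translation
    shifted = apply_systematic(beams, SystematicOffset(np.array([0.0, 0.0, 5.0])))
    d1 = compute_epl_dose(water, shifted, model).values
    a = d0[10:-10, 10:-10, 10 : -10 - shift_vox]
    b = d1[10:-10, 10:-10, 10 + shift_vox : -10]
    corr = np.corrcoef(a.ravel(), b.ravel())[0, 1]
    assert corr >= 0.99


def test_density_blindness_off_axis(model):
    """Perturbing densities lateral to the beam (off every primary ray)
    leaves the EPL dose bit-identical -- the path-length-only contract."""
    shape = (48, 48, 48)
    spacing = (2.5, 2.5, 2.5)
    origin = tuple(-(np.asarray(shape) - 1) / 2.0 * np.asarray(spacing))
    vals = np.ones(shape, dtype=np.float32)
    grid = DensityGrid(vals.copy(), spacing, origin)
    src = np.array([0.0, 0.0, 800.0])
    bs = BeamSet([Beam(src, np.zeros(3), 20.0, mu=1.0)], 800.0)
    d0 = compute_epl_dose(grid, bs, model).values
    # perturb a slab far off-axis: no source->voxel ray with nonzero profile
    vals2 = vals.copy()
    vals2[:8, :, :] = 0.05
    d1 = compute_epl_dose(DensityGrid(vals2, spacing, origin), bs, model).values
    np.testing.assert_array_equal(d0[8:, :, :], d1[8:, :, :])
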