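"""Geometric error injection: sigma_tot statistic, random error sets,
rigid systematic/random beam translations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lungsbrt import (
    SystematicOffset,
    apply_random,
    apply_systematic,
    generate_beamset,
    generate_random_errors,
    sigma_tot,
)
from lungsbrt.errors import RandomErrorSet

TARGET = np.array([10.0, -30.0, 0.0])


class TestSigmaTot:
    def test_single_axis_identity(self):
        assert sigma_tot(2.5, 0.0, 0.0) == pytest.approx(2.5)

    def test_unit_axes(self):
        assert sigma_tot(1.0, 1.0, 1.0) == pytest.approx(np.sqrt(3.0))

    def test_zero(self):
        assert sigma_tot(0.0, 0.0, 0.0) == 0.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            sigma_tot(-1.0, 0.0, 0.0)

    @settings(deadline=None, max_examples=50)
    @given(st.floats(0, 10), st.floats(0, 10), st.floats(0, 10),
           st.floats(0.01, 5))
    def test_positive_homogeneity(self, a, b, c, s):
        assert sigma_tot(s * a, s * b, s * c) == pytest.approx(s * sigma_tot(a, b, c))


class TestGenerateRandomErrors:
    def test_realized_sigma_tot_exact_at_study_size(self):
        """192 beams, 3 mm target: realized root-square sum is exact."""
        errs = generate_random_errors(192, 3.0, seed=5)
        sd = errs.offsets.std(axis=0, ddof=0)
        assert np.sqrt((sd**2).sum()) == pytest.approx(3.0, abs=1e-9)
        assert sd.max() / sd.min() <= 1.2  # near-equal axis weighting
        assert np.allclose(errs.offsets.mean(axis=0), 0.0, atol=1e-12)

    def test_zero_target_gives_all_zero_offsets(self):
        errs = generate_random_errors(50, 0.0, seed=1)
        assert not errs.offsets.any()

    def test_doubling_target_doubles_every_offset(self):
        e1 = generate_random_errors(100, 2.0, seed=3)
        e2 = generate_random_errors(100, 4.0, seed=3)
        np.testing.assert_allclose(e2.offsets, 2.0 * e1.offsets, rtol=1e-12)

    def test_too_few_beams_rejected(self):
        with pytest.raises(ValueError):
            generate_random_errors(1, 3.0)

    def test_negative_target_rejected(self):
        with pytest.raises(ValueError):
            generate_random_errors(10, -1.0)

    def test_seed_determinism(self):
        a = generate_random_errors(30, 5.0, seed=9)
        b = generate_random_errors(30, 5.0, seed=9)
        np.testing.assert_array_equal(a.offsets, b.offsets)

    def test_invariant_validation(self):
        with pytest.raises(ValueError, match="root-square sum"):
            RandomErrorSet(np.zeros((5, 3)), np.array([1.0, 1.0, 1.0]), 5.0, 0)

    def test_csv_round_trip(self, tmp_path):
        errs = generate_random_errors(20, 3.0, seed=2)
        errs.to_csv(tmp_path / "errs.csv")
        back = RandomErrorSet.from_csv(tmp_path / "errs.csv")
        np.testing.assert_allclose(back.offsets, errs.offsets)
        assert back.sigma_total == errs.sigma_total and back.seed == errs.seed


class TestApplySystematic:
    def test_zero_offset_is_identity(self):
        beams = generate_beamset(10, TARGET, (20.0,), seed=0)
        out = apply_systematic(beams, SystematicOffset(np.zeros(3)))
        for a, b in zip(beams, out):
            np.testing.assert_array_equal(a.source, b.source)
            np.testing.assert_array_equal(a.target, b.target)

    def test_offset_then_inverse_restores_coordinates(self):
        beams = generate_beamset(10, TARGET, (20.0,), seed=0)
        off = SystematicOffset(np.array([1.7, -2.3, 0.9]))
        back = apply_systematic(apply_systematic(beams, off),
                                SystematicOffset(-off.shift))
        for a, b in zip(beams, back):
            np.testing.assert_allclose(a.source, b.source, atol=1e-12)
            np.testing.assert_allclose(a.target, b.target, atol=1e-12)

    def test_cranial_shift_moves_only_cc_and_keeps_weights(self):
        beams = generate_beamset(12, TARGET, (20.0, 25.0), seed=1)
        out = apply_systematic(beams, SystematicOffset.cc(3.0))
        for a, b in zip(beams, out):
            assert b.target[2] - a.target[2] == pytest.approx(3.0)
            np.testing.assert_array_equal(a.target[:2], b.target[:2])
            assert a.diameter == b.diameter and a.mu == b.mu
            assert b.sad == pytest.approx(a.sad)  # rigid: direction preserved

    def test_original_set_unmodified(self):
        beams = generate_beamset(5, TARGET, (20.0,), seed=2)
        srcs = [b.source.copy() for b in beams]
        apply_systematic(beams, SystematicOffset.cc(5.0))
        for b, s in zip(beams, srcs):
            np.testing.assert_array_equal(b.source, s)


class TestApplyRandom:
    def test_zero_error_set_is_identity(self):
        beams = generate_beamset(8, TARGET, (20.0,), seed=0)
        errs = generate_random_errors(8, 0.0, seed=0)
        out = apply_random(beams, errs)
        for a, b in zip(beams, out):
            np.testing.assert_array_equal(a.target, b.target)

    def test_mean_applied_displacement_matches_error_set(self):
        beams = generate_beamset(40, TARGET, (20.0,), seed=1)
        errs = generate_random_errors(40, 4.0, seed=7)
        out = apply_random(beams, errs)
        disp = np.array([b.target - a.target for a, b in zip(beams, out)])
        np.testing.assert_allclose(disp.mean(axis=0), errs.offsets.mean(axis=0), atol=1e-12)

    def test_joint_permutation_equivariance(self):
        beams = generate_beamset(10, TARGET, (20.0,), seed=3)
        errs = generate_random_errors(10, 3.0, seed=4)
        perm = np.random.default_rng(0).permutation(10)
        out = apply_random(beams, errs)
        beams_p = type(beams)([beams[i] for i in perm], beams.sad)
        errs_p = RandomErrorSet(errs.offsets[perm], errs.sigma_axis,
                                errs.sigma_total, errs.seed)
        out_p = apply_random(beams_p, errs_p)
        got = sorted(tuple(b.target) for b in out)
        want = sorted(tuple(b.target) for b in out_p)
        np.testing.assert_allclose(got, want)

    def test_length_mismatch_rejected(self):
        beams = generate_beamset(5, TARGET, (20.0,), seed=0)
        errs = generate_random_errors(6, 2.0, seed=0)
        with pytest.raises(ValueError, match="rows"):
            apply_random(beams, errs)
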