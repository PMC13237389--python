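"""Tests for normalization, sigmoid inversion and the level offset."""

import math

import numpy as np
import pytest

import ecap_ipg as eig
from ecap_ipg.io_features import SigmoidFit
from ecap_ipg.offset import (
    invert_sigmoid,
    normalize_pair,
    offset_all_scales,
    stimulation_level_offset,
)
from ecap_ipg.scales import S1, S2, S3, cl_to_current, current_to_charge
from tests.conftest import make_io


def shifted_level_pair(level_grid, amplitudes, dcl, phase=50.0):
    """IPG-42 curve = same amplitudes at levels shifted down by ``dcl``."""
    io7 = make_io(level_grid, amplitudes, ipg=7.0, phase=phase)
    io42 = make_io(np.asarray(level_grid) - dcl, amplitudes, ipg=42.0, phase=phase)
    return io7, io42


class TestNormalizePair:
    def test_ipg7_maximum_maps_to_one(self, noise_free_pair):
        pair = normalize_pair(*noise_free_pair, S1)
        assert pair.io7.y.max() == pytest.approx(1.0, abs=1e-9)
        assert pair.normalizer == pytest.approx(noise_free_pair[0].amplitudes.max())

    def test_ipg42_may_exceed_one(self, level_grid):
        io7 = make_io(level_grid, np.linspace(10, 500, len(level_grid)), ipg=7.0)
        io42 = make_io(level_grid, np.linspace(20, 700, len(level_grid)), ipg=42.0)
        pair = normalize_pair(io7, io42, S1)
        assert pair.io42.y.max() > 1.0

    def test_zero_ipg7_maximum_rejected(self, level_grid):
        io7 = make_io(level_grid, np.zeros(len(level_grid)), ipg=7.0)
        io42 = make_io(level_grid, np.ones(len(level_grid)), ipg=42.0)
        with pytest.raises(ValueError):
            normalize_pair(io7, io42, S1)

    def test_offset_invariant_to_shared_amplitude_scale(self, noise_free_pair):
        # normalization touches only the output axis, so a shared gain on
        # both curves cannot move the level-axis offset
        io7, io42 = noise_free_pair
        r1 = stimulation_level_offset(normalize_pair(io7, io42, S1))
        k = 13.7
        io7k = make_io(io7.levels, k * io7.amplitudes, ipg=7.0)
        io42k = make_io(io42.levels, k * io42.amplitudes, ipg=42.0)
        r2 = stimulation_level_offset(normalize_pair(io7k, io42k, S1))
        assert r2.offset == pytest.approx(r1.offset, abs=1e-9)


class TestInvertSigmoid:
    def fit(self, y0=0.1, a=0.9, b=25.0, c=3.0):
        return SigmoidFit(y0=y0, a=a, b=b, c=c, converged=True)

    def test_midpoint_maps_to_b(self):
        f = self.fit()
        assert invert_sigmoid(f, f.y0 + f.a / 2) == pytest.approx(f.b, abs=1e-12)

    def test_three_quarters_maps_to_b_plus_c_ln3(self):
        f = self.fit()
        assert invert_sigmoid(f, f.y0 + 0.75 * f.a) == pytest.approx(
            f.b + f.c * math.log(3), abs=1e-12
        )

    def test_forward_inverse_round_trip(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            f = self.fit(y0=rng.uniform(-1, 1), a=rng.uniform(0.1, 10),
                         b=rng.uniform(0, 50), c=rng.uniform(0.5, 8))
            y = f.y0 + rng.uniform(0.05, 0.95) * f.a
            assert f(invert_sigmoid(f, y)) == pytest.approx(y, abs=1e-10)

    @pytest.mark.parametrize("frac", [-0.1, 0.0, 1.0, 1.5])
    def test_target_outside_open_range_rejected(self, frac):
        f = self.fit()
        with pytest.raises(ValueError):
            invert_sigmoid(f, f.y0 + frac * f.a)


class TestStimulationLevelOffset:
    def test_constructed_nc_shift_recovered(self, noise_free_pair):
        # IPG-42 ground truth midpoint sits 2.5 nC left of IPG-7's
        res = stimulation_level_offset(normalize_pair(*noise_free_pair, S1))
        assert res.offset == pytest.approx(2.5, abs=1e-6)
        assert res.label == "nC"

    def test_identical_functions_give_zero(self, level_grid, charge_grid):
        amps = eig.SigmoidParams(0, 300, 24, 3)(charge_grid)
        io7 = make_io(level_grid, amps, ipg=7.0)
        io42 = make_io(level_grid, amps, ipg=42.0)
        res = stimulation_level_offset(normalize_pair(io7, io42, S1))
        assert res.offset == pytest.approx(0.0, abs=1e-9)

    def test_sign_positive_when_long_ipg_more_efficient(self, noise_free_pair):
        # the 42-µs curve reaches equal amplitude at lower level ⇒ positive
        res = stimulation_level_offset(normalize_pair(*noise_free_pair, S1))
        assert res.offset > 0

    def test_multiplicative_current_ratio_recovered_in_db(
        self, level_grid, charge_grid, sigmoid_truth
    ):
        k = 1.3
        dcl = 255 * math.log10(k) / 2  # level shift dividing current by k
        io7, io42 = shifted_level_pair(level_grid, sigmoid_truth(charge_grid), dcl)
        for spec in (S2, S3):
            res = stimulation_level_offset(normalize_pair(io7, io42, spec))
            assert res.offset == pytest.approx(20 * math.log10(k), abs=1e-6)

    def test_antisymmetric_under_swap(self, level_grid, charge_grid, sigmoid_truth):
        # identical amplitude vectors at shifted levels share the same
        # normalizer, so swapping the roles exactly negates the offset
        io7, io42 = shifted_level_pair(level_grid, sigmoid_truth(charge_grid), 5.0)
        fwd = stimulation_level_offset(normalize_pair(io7, io42, S1))
        rev = stimulation_level_offset(normalize_pair(io42, io7, S1))
        assert rev.offset == pytest.approx(-fwd.offset, abs=1e-9)

    def test_translation_equivariance_on_input_axis(self, noise_free_pair):
        pair = normalize_pair(*noise_free_pair, S1)
        base = stimulation_level_offset(pair)
        delta = 1.75
        pair.io42.x = pair.io42.x + delta
        moved = stimulation_level_offset(pair)
        assert moved.offset == pytest.approx(base.offset - delta, abs=1e-9)

    def test_quantile_self_consistency(self, noise_free_pair):
        res = stimulation_level_offset(normalize_pair(*noise_free_pair, S1))
        for y, diff in zip(res.target_amplitudes, res.level_differences):
            assert diff == pytest.approx(
                invert_sigmoid(res.fit7, y) - invert_sigmoid(res.fit42, y), abs=0
            )
        assert res.offset == pytest.approx(np.mean(res.level_differences))
        lo, hi = res.overlap
        assert all(lo <= y <= hi for y in res.target_amplitudes)

    def test_empty_overlap_is_missing_with_reason(self, level_grid, charge_grid):
        lowered = eig.SigmoidParams(0.001, 0.5, 24, 3)(charge_grid)
        raised = 2.0 + eig.SigmoidParams(0.001, 0.5, 24, 3)(charge_grid)
        io7 = make_io(level_grid, lowered, ipg=7.0)
        io42 = make_io(level_grid, raised, ipg=42.0)
        res = stimulation_level_offset(normalize_pair(io7, io42, S1))
        assert res.missing and "overlap" in res.reason


class TestOffsetAllScales:
    def test_additive_shift_constant_on_nc(self, noise_free_pair):
        out = offset_all_scales(*noise_free_pair)
        assert set(out) == {"nC", "dB_linear/log", "dB_log/log"}
        assert out["nC"].offset == pytest.approx(2.5, abs=1e-6)

    def test_multiplicative_shift_constant_on_db(
        self, level_grid, charge_grid, sigmoid_truth
    ):
        k = 1.25
        dcl = 255 * math.log10(k) / 2
        io7, io42 = shifted_level_pair(level_grid, sigmoid_truth(charge_grid), dcl)
        out = offset_all_scales(io7, io42)
        assert out["dB_linear/log"].offset == pytest.approx(
            20 * math.log10(k), abs=1e-6
        )
        assert out["dB_log/log"].offset == pytest.approx(
            20 * math.log10(k), abs=1e-6
        )

    def test_all_missing_exits_cleanly(self, level_grid):
        flat = np.full(len(level_grid), 10.0)
        io7 = make_io(level_grid, flat, ipg=7.0)
        io42 = make_io(level_grid, flat, ipg=42.0)
        out = offset_all_scales(io7, io42)
        assert all(res.missing and res.offset is None for res in out.values())


class TestBrochierInvariance:
    def test_db_offsets_independent_of_r_n_s(self):
        # the shared factors cancel in the normalization, so every
        # downstream dB-scale offset is identical across factor choices
        k = 1.4
        rng = np.random.default_rng(9)
        reference = {}
        for trial in range(10):
            r, n, s = (1.0, 1.0, 1.0) if trial == 0 else rng.uniform(0.01, 100, 3)
            b7 = eig.BrochierConfig(r=r, n=n, s=s, g=1.0)
            b42 = eig.BrochierConfig(r=r, n=n, s=s, g=k)
            io7, io42 = eig.brochier_io_pair(b7, b42)
            for spec, name in ((S2, "S2"), (S3, "S3")):
                res = stimulation_level_offset(normalize_pair(io7, io42, spec))
                assert res.offset is not None
                if name in reference:
                    assert abs(res.offset - reference[name]) < 1e-9
                else:
                    reference[name] = res.offset

    def test_db_offset_equals_gain_ratio_in_db(self):
        # at equal voltage, I7/I42 = g42/g7, i.e. 20·log10(k) dB on the
        # log-input axis; the sigmoid approximation of the quadratic
        # curve recovers it to within its documented misfit
        k = 1.4
        io7, io42 = eig.brochier_io_pair(
            eig.BrochierConfig(g=1.0), eig.BrochierConfig(g=k)
        )
        for spec in (S2, S3):
            res = stimulation_level_offset(normalize_pair(io7, io42, spec))
            assert res.offset == pytest.approx(20 * math.log10(k), abs=1e-2)
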