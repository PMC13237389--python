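"""Tests for the STFT → phase-locking-value → aggregate chain."""

import numpy as np
import pytest

import ecap_ipg as eig
from ecap_ipg.plv import (
    DEFAULT_FREQUENCIES,
    PLVConfig,
    PLVGrid,
    aggregate_plv,
    phase_locking_value,
    plv_from_sweeps,
    stft_spectra,
)


def direct_dft_frame(frame, taper, nfft, bin_idx):
    """Brute-force DFT-by-summation oracle for one tapered, padded frame."""
    padded = np.zeros(nfft)
    padded[: len(frame)] = frame * taper
    return sum(
        padded[n] * np.exp(-2j * np.pi * bin_idx * n / nfft)
        for n in range(nfft)
    )


class TestSTFT:
    def test_matches_direct_dft_summation(self):
        # oracle equivalence on a known random 26-sample frame content
        rng = np.random.default_rng(0)
        data = rng.normal(0, 50, size=(3, 128))
        sweeps = eig.SweepSet(data=data, sampling_rate=20492.0)
        cfg = PLVConfig()
        spectra = stft_spectra(sweeps, cfg)
        taper = cfg.taper()
        bins = cfg.bins(20492.0)
        for k in (0, 2):
            for t in (0, 5):
                frame = data[k, t * cfg.hop : t * cfg.hop + cfg.frame_size]
                for j, b in enumerate(bins):
                    expect = direct_dft_frame(frame, taper, cfg.nfft, b)
                    assert spectra[k, t, j] == pytest.approx(expect, abs=1e-10)

    def test_aligned_cosine_has_zero_phase_at_its_bin(self):
        cfg = PLVConfig()
        fs = 20492.0
        bins = cfg.bins(fs)
        f = bins[0] * fs / cfg.nfft  # exact bin frequency
        t = np.arange(128) / fs
        data = np.tile(np.cos(2 * np.pi * f * t), (2, 1))
        spectra = stft_spectra(eig.SweepSet(data=data, sampling_rate=fs), cfg)
        # first frame starts at sample 0, so the cosine is phase-aligned
        assert abs(np.angle(spectra[0, 0, 0])) < 1e-9

    def test_all_zero_sweep_yields_zero_spectra_then_flagged(self):
        sweeps = eig.SweepSet(data=np.zeros((2, 128)), sampling_rate=20492.0)
        spectra = stft_spectra(sweeps)
        assert np.all(spectra == 0)
        with pytest.raises(ValueError, match="trial 0"):
            phase_locking_value(spectra)

    def test_frame_past_record_end_names_offending_frame(self):
        sweeps = eig.SweepSet(data=np.ones((2, 50)), sampling_rate=20492.0)
        with pytest.raises(ValueError, match="frame 5"):
            stft_spectra(sweeps, PLVConfig())

    def test_nominal_frequencies_map_to_even_bins(self):
        cfg = PLVConfig()
        assert list(cfg.bins(20492.0)) == [2, 4, 6, 8, 10, 12]
        realized = cfg.realized_frequencies(20492.0)
        assert np.allclose(realized, np.asarray(DEFAULT_FREQUENCIES), atol=0.5)


class TestPhaseLockingValue:
    def test_identical_nonzero_sweeps_give_unity_everywhere(self, noise_free_sweeps):
        grid = plv_from_sweeps(noise_free_sweeps)
        assert np.allclose(grid.values, 1.0, atol=1e-12)
        assert grid.aggregate == pytest.approx(1.0, abs=1e-12)

    def test_uniform_random_phases_match_rayleigh_expectation(self):
        # E|mean of N unit phasors| = sqrt(pi/(4N)) for independent uniform
        # phases; Monte-Carlo mean over 200 replicates at N = 400.
        rng = np.random.default_rng(12345)
        n_trials, reps = 400, 200
        expectation = np.sqrt(np.pi / (4 * n_trials))
        cells = []
        for _ in range(reps):
            phases = rng.uniform(0, 2 * np.pi, size=(n_trials, 1, 1))
            grid = phase_locking_value(np.exp(1j * phases))
            cells.append(grid.values[0, 0])
        cells = np.asarray(cells)
        se = cells.std(ddof=1) / np.sqrt(reps)
        assert abs(cells.mean() - expectation) < 3 * se

    def test_common_rotation_leaves_grid_invariant(self):
        # a common time shift rotates every trial's phasor identically per
        # cell; the modulus of the mean phasor cannot see that rotation
        rng = np.random.default_rng(3)
        data = rng.normal(0, 30, size=(50, 128))
        spectra = stft_spectra(eig.SweepSet(data=data, sampling_rate=20492.0))
        rotation = np.exp(1j * rng.uniform(0, 2 * np.pi, size=spectra.shape[1:]))
        g1 = phase_locking_value(spectra)
        g2 = phase_locking_value(spectra * rotation)
        assert np.allclose(g1.values, g2.values, atol=1e-9)

    def test_common_time_shift_of_identical_sweeps_keeps_unity(self):
        # time-domain counterpart on identical sweeps: shifting the whole
        # set by one latency leaves perfect coherence untouched
        base = eig.SweepSimConfig(latency_jitter_sd=0.0, amplitude_jitter_cv=0.0,
                                  noise_sd=0.0, n_sweeps=20, seed=3)
        shifted = eig.SweepSimConfig(**{**base.__dict__,
                                        "n1_latency": base.n1_latency + 97.0,
                                        "p2_latency": base.p2_latency + 97.0})
        g1 = plv_from_sweeps(eig.simulate_sweeps(base))
        g2 = plv_from_sweeps(eig.simulate_sweeps(shifted))
        assert g1.aggregate == pytest.approx(1.0, abs=1e-9)
        assert g2.aggregate == pytest.approx(1.0, abs=1e-9)

    def test_invariant_under_positive_per_sweep_scaling(self):
        rng = np.random.default_rng(7)
        data = rng.normal(0, 30, size=(40, 128))
        sweeps = eig.SweepSet(data=data, sampling_rate=20492.0)
        scaled = eig.SweepSet(
            data=data * rng.uniform(0.1, 10.0, size=(40, 1)),
            sampling_rate=20492.0,
        )
        g1, g2 = plv_from_sweeps(sweeps), plv_from_sweeps(scaled)
        assert np.allclose(g1.values, g2.values, atol=1e-12)

    def test_cells_bounded_for_random_sweeps(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            data = rng.normal(0, 20, size=(20, 128))
            grid = plv_from_sweeps(eig.SweepSet(data=data, sampling_rate=20492.0))
            assert np.all(grid.values >= 0) and np.all(grid.values <= 1)

    def test_three_trial_toy_matches_hand_computed_oracle(self):
        # independent complex-arithmetic oracle: explicit per-trial DFT sums
        # and unit-phasor averaging on a 3-trial, 2-frame, 2-frequency toy
        cfg = PLVConfig(frame_size=4, n_frames=2, hop=2, pad_ratio=2,
                        frequencies=(2561.5, 5123.0))
        rng = np.random.default_rng(2)
        data = rng.normal(0, 1, size=(3, 8))
        fs = 20492.0
        taper = 0.5 - 0.5 * np.cos(2 * np.pi * np.arange(4) / 4)
        bins = [round(f * 8 / fs) for f in cfg.frequencies]
        expected = np.empty((2, 2))
        for t in range(2):
            for j, b in enumerate(bins):
                phasors = []
                for k in range(3):
                    frame = data[k, t * 2 : t * 2 + 4] * taper
                    coef = 0j
                    for n in range(4):
                        coef += frame[n] * np.exp(-2j * np.pi * b * n / 8)
                    phasors.append(coef / abs(coef))
                expected[t, j] = abs(sum(phasors) / 3)
        sweeps = eig.SweepSet(data=data, sampling_rate=fs)
        grid = phase_locking_value(stft_spectra(sweeps, cfg), cfg, fs)
        assert np.allclose(grid.values, expected, atol=1e-10)


class TestAggregate:
    def test_constant_grid(self):
        grid = PLVGrid(values=np.full((6, 6), 0.5),
                       frame_center_times_us=np.zeros(6),
                       frequencies=np.zeros(6), realized_frequencies=np.zeros(6))
        assert aggregate_plv(grid) == pytest.approx(0.5)

    def test_default_config_averages_36_cells(self, noise_free_sweeps):
        grid = plv_from_sweeps(noise_free_sweeps)
        assert grid.values.shape == (6, 6)
        assert grid.values.size == 36

    def test_one_hot_grid(self):
        values = np.zeros((6, 6))
        values[2, 3] = 1.0
        grid = PLVGrid(values=values, frame_center_times_us=np.zeros(6),
                       frequencies=np.zeros(6), realized_frequencies=np.zeros(6))
        assert aggregate_plv(grid) == pytest.approx(1 / 36)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            PLVGrid(values=np.empty((0, 0)), frame_center_times_us=np.zeros(0),
                    frequencies=np.zeros(0), realized_frequencies=np.zeros(0))
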