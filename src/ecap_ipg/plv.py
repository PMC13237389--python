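"""Phase locking value (PLV) — trial-to-trial phase coherence of eCAP sweeps.

For each sweep k, short-time Fourier spectra F_k(f, t) are computed on
Hanning-tapered frames of 26 samples, zero-padded by a pad-ratio of 2, at
six analysis frequencies spaced by the spectral resolution of the frame
(nominally 788.2 Hz up to 4729.2 Hz at the 20,492-Hz device sampling
rate).  The PLV at each time-frequency cell is the modulus of the mean
unit phasor across trials,

    PLV(f, t) = | (1/N) Σ_k F_k(f, t) / |F_k(f, t)| |,

a unitless quantity in [0, 1]; 1 means perfectly reproducible phase.  A
single synchrony index is the arithmetic mean over all cells (six
frequencies × six partially overlapped frames by default).

Frame placement: consecutive frames advance by ``hop`` samples (default 13,
i.e. 50% overlap), so six frames span 91 samples ≈ 4.4 ms, covering the
window where the eCAP is expected.  The analysis frequencies are read at
the nearest FFT bin; both the nominal and the realized bin frequencies are
recorded on the output grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .synthetic import SweepSet

__all__ = [
    "PLVConfig",
    "PLVGrid",
    "DEFAULT_FREQUENCIES",
    "stft_spectra",
    "phase_locking_value",
    "aggregate_plv",
    "plv_from_sweeps",
]

DEFAULT_FREQUENCIES = (788.2, 1576.4, 2364.6, 3152.8, 3941.0, 4729.2)


@dataclass
class PLVConfig:
    frame_size: int = 26
    n_frames: int = 6
    hop: int = 13
    pad_ratio: int = 2
    window: str = "hanning"
    frequencies: Sequence[float] = DEFAULT_FREQUENCIES
    analysis_start: int = 0

    def validate(self, n_samples: int, sampling_rate: float) -> None:
        if self.frame_size < 2:
            raise ValueError("frame size must be ≥ 2 samples")
        if self.pad_ratio < 1:
            raise ValueError("pad ratio must be ≥ 1")
        if self.n_frames < 1 or self.hop < 1:
            raise ValueError("need at least one frame and a positive hop")
        if self.analysis_start < 0:
            raise ValueError("analysis start must be non-negative")
        for f in self.frequencies:
            if not 0 < f < sampling_rate / 2:
                raise ValueError(f"frequency {f} Hz outside (0, Nyquist)")
        last_end = self.analysis_start + (self.n_frames - 1) * self.hop + self.frame_size
        if last_end > n_samples:
            raise ValueError(
                f"frame {self.n_frames - 1} ends at sample {last_end}, "
                f"past the {n_samples}-sample record"
            )

    @property
    def nfft(self) -> int:
        return self.pad_ratio * self.frame_size

    def taper(self) -> np.ndarray:
        if self.window != "hanning":
            raise ValueError(f"unsupported taper {self.window!r}")
        # periodic Hann, matching FFT analysis convention
        n = np.arange(self.frame_size)
        return 0.5 - 0.5 * np.cos(2 * np.pi * n / self.frame_size)

    def bins(self, sampling_rate: float) -> np.ndarray:
        """Nearest FFT bin index for each nominal analysis frequency."""
        return np.array(
            [round(f * self.nfft / sampling_rate) for f in self.frequencies], dtype=int
        )

    def realized_frequencies(self, sampling_rate: float) -> np.ndarray:
        return self.bins(sampling_rate) * sampling_rate / self.nfft


@dataclass
class PLVGrid:
    """PLV(f, t) over frames × frequencies, with the aggregate index."""

    values: np.ndarray
    frame_center_times_us: np.ndarray
    frequencies: np.ndarray            # nominal, Hz
    realized_frequencies: np.ndarray   # actual FFT-bin frequencies, Hz
    aggregate: float = field(init=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size == 0:
            raise ValueError("empty PLV grid")
        if np.any(self.values < 0) or np.any(self.values > 1 + 1e-12):
            raise ValueError("PLV cells must lie in [0, 1]")
        self.aggregate = float(np.mean(self.values))


def stft_spectra(sweeps: SweepSet, config: PLVConfig | None = None) -> np.ndarray:
    """Per-trial complex spectral estimates F_k(f, t).

    Returns an (n_sweeps, n_frames, n_freqs) complex array: each frame is
    Hanning-tapered, zero-padded to ``pad_ratio × frame_size``, discrete-
    Fourier-transformed, and read at the bin nearest each analysis
    frequency.
    """
    config = config or PLVConfig()
    config.validate(sweeps.n_samples, sweeps.sampling_rate)
    taper = config.taper()
    bins = config.bins(sweeps.sampling_rate)
    starts = config.analysis_start + config.hop * np.arange(config.n_frames)
    # frames: (n_sweeps, n_frames, frame_size)
    frames = np.stack(
        [sweeps.data[:, s : s + config.frame_size] for s in starts], axis=1
    )
    spectra = np.fft.fft(frames * taper, n=config.nfft, axis=-1)
    return spectra[:, :, bins]


def phase_locking_value(spectra: np.ndarray, config: PLVConfig | None = None,
                        sampling_rate: float = 20492.0,
                        frame_center_times_us: np.ndarray | None = None) -> PLVGrid:
    """PLV grid from per-trial spectra: modulus of the mean unit phasor.

    A zero-magnitude coefficient has no phase; silently excluding it would
    bias the mean, so it raises with the offending (trial, frame,
    frequency) index instead.
    """
    config = config or PLVConfig()
    spectra = np.asarray(spectra, dtype=complex)
    if spectra.ndim != 3 or spectra.shape[0] < 2:
        raise ValueError("spectra must be (n_trials ≥ 2, n_frames, n_freqs)")
    if not np.all(np.isfinite(spectra)):
        raise ValueError("spectra contain non-finite values")
    mag = np.abs(spectra)
    if np.any(mag == 0):
        k, t, f = np.argwhere(mag == 0)[0]
        raise ValueError(
            f"zero-magnitude spectral coefficient (degenerate phase) at "
            f"trial {k}, frame {t}, frequency index {f}"
        )
    values = np.abs(np.mean(spectra / mag, axis=0))
    if frame_center_times_us is None:
        starts = config.analysis_start + config.hop * np.arange(spectra.shape[1])
        frame_center_times_us = (starts + (config.frame_size - 1) / 2) / sampling_rate * 1e6
    return PLVGrid(
        values=values,
        frame_center_times_us=np.asarray(frame_center_times_us, dtype=float),
        frequencies=np.asarray(config.frequencies, dtype=float)[: spectra.shape[2]],
        realized_frequencies=config.realized_frequencies(sampling_rate)[: spectra.shape[2]],
    )


def aggregate_plv(grid: PLVGrid) -> float:
    """Arithmetic mean of all time-frequency PLV cells (default 6×6 = 36)."""
    return float(np.mean(grid.values))


def plv_from_sweeps(sweeps: SweepSet, config: PLVConfig | None = None) -> PLVGrid:
    """Full chain: sweeps → STFT spectra → PLV grid (with aggregate)."""
    config = config or PLVConfig()
    spectra = stft_spectra(sweeps, config)
    starts = config.analysis_start + config.hop * np.arange(config.n_frames)
    centers = sweeps.t0_offset_us + (starts + (config.frame_size - 1) / 2) \
        / sweeps.sampling_rate * 1e6
    return phase_locking_value(
        spectra, config, sweeps.sampling_rate, frame_center_times_us=centers
    )
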