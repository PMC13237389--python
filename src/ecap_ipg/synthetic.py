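"""Synthetic eCAP data with the statistical structure the analysis assumes.

Three generators are provided:

* :func:`simulate_sweeps` — repeated single-trial eCAP recordings (a smooth
  biphasic N1/P2 deflection) with per-sweep latency jitter, multiplicative
  amplitude jitter, and an additive white noise floor.  Latency jitter is
  what degrades trial-to-trial phase coherence, so these sweep sets give
  the phase-locking-value chain a controllable ground truth.
* :func:`simulate_io_pair` — paired amplitude-growth (I/O) functions at
  interphase gaps of 7 and 42 µs, drawn from sigmoidal ground truth on the
  charge (nC) axis, with scenario presets that mirror the qualitative
  group structure of interest (see ``SCENARIO_PRESETS``).
* :func:`brochier_forward` — the theoretical forward model V = r·n·(s·g·I)²
  relating eCAP voltage to current through recording-electrode,
  neuron-count, stimulating-electrode and stimulus-gain factors; used to
  exercise the log-scale offset's algebraic invariance to r, n and s.

Every generator is a pure function of (config, seed): identical inputs give
bit-identical outputs.  A single top-level seed expands to per-component
substreams via ``numpy.random.SeedSequence.spawn`` (sweeps first, then the
IPG-7 and IPG-42 noise streams, in that order).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .scales import DEFAULT_LAW, DeviceLaw, cl_to_current, current_to_charge

__all__ = [
    "SweepSimConfig",
    "IOSimConfig",
    "BrochierConfig",
    "SweepSet",
    "IOFunction",
    "SigmoidParams",
    "SCENARIO_PRESETS",
    "simulate_sweeps",
    "simulate_io_pair",
    "brochier_forward",
    "brochier_io_pair",
    "scenario_config",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class SweepSet:
    """N×T matrix of repeated eCAP sweeps (µV) with sampling metadata."""

    data: np.ndarray
    sampling_rate: float
    t0_offset_us: float = 110.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] < 2:
            raise ValueError("sweep set must be an N×T matrix with N ≥ 2")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("sweep set contains non-finite values")
        if self.sampling_rate <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_sweeps(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def times_us(self) -> np.ndarray:
        """Sample times in µs relative to stimulus onset."""
        return self.t0_offset_us + np.arange(self.n_samples) / self.sampling_rate * 1e6


@dataclass
class IOFunction:
    """One measured eCAP amplitude-growth function.

    Levels are device current-level codes (integers for measured data;
    fractional levels are permitted for synthetic/theoretical curves),
    strictly increasing, bounded above by the maximum comfortable level.
    """

    levels: np.ndarray
    amplitudes: np.ndarray
    c_level: float
    phase_duration: float
    ipg: float
    subject: str = ""
    electrode: str = ""
    truth: Optional["SigmoidParams"] = None

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if len(self.levels) != len(self.amplitudes):
            raise ValueError("levels and amplitudes must have equal length")
        if len(self.levels) > 1 and not np.all(np.diff(self.levels) > 0):
            raise ValueError("levels must be strictly increasing")
        if np.any(self.amplitudes < 0):
            raise ValueError("amplitudes must be non-negative")
        if len(self.levels) and self.levels.max() > self.c_level:
            raise ValueError("levels may not exceed the C level")

    @property
    def label(self) -> str:
        return f"{self.subject}/{self.electrode}/ipg{self.ipg:g}"

    def __len__(self) -> int:
        return len(self.levels)


@dataclass(frozen=True)
class SigmoidParams:
    """Parameters of y = y0 + a / (1 + exp(−(x − b)/c)) on the nC axis."""

    y0: float
    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        if self.a <= 0 or self.c <= 0:
            raise ValueError("sigmoid truth requires a > 0 and c > 0")

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        out = self.y0 + self.a / (1.0 + np.exp(-(x - self.b) / self.c))
        return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# sweep simulation


@dataclass
class SweepSimConfig:
    """Single-trial eCAP simulation parameters.

    The waveform template is a smooth biphasic deflection: a negative
    Gaussian lobe (N1 trough) followed by a positive one (P2 peak).  The
    default noise floor of 5 µV sits at the top of the 2–5 µV range typical
    of newer recording hardware; older devices run nearer 20 µV.
    """

    n_sweeps: int = 400
    sampling_rate: float = 20492.0
    n_samples: int = 128
    n1_latency: float = 300.0       # µs after stimulus onset
    n1_amplitude: float = -200.0    # µV, trough (negative)
    n1_width: float = 120.0         # µs, Gaussian sigma
    p2_latency: float = 700.0
    p2_amplitude: float = 100.0
    p2_width: float = 250.0
    t0_offset_us: float = 110.0     # recording delay (device: 98–122 µs)
    latency_jitter_sd: float = 20.0  # µs per sweep
    amplitude_jitter_cv: float = 0.1
    noise_sd: float = 5.0           # µV additive white noise
    seed: int = 0

    def validate(self) -> None:
        if self.n_sweeps < 2:
            raise ValueError("need at least 2 sweeps")
        if self.n_samples <= 0 or self.sampling_rate <= 0:
            raise ValueError("n_samples and sampling_rate must be positive")
        if self.latency_jitter_sd < 0 or self.noise_sd < 0:
            raise ValueError("jitter and noise SDs must be non-negative")
        if self.amplitude_jitter_cv < 0:
            raise ValueError("amplitude jitter CV must be non-negative")


def _template(t_us: np.ndarray, cfg: SweepSimConfig) -> np.ndarray:
    """Noise-free biphasic template evaluated at continuous times (µs)."""
    n1 = cfg.n1_amplitude * np.exp(-0.5 * ((t_us - cfg.n1_latency) / cfg.n1_width) ** 2)
    p2 = cfg.p2_amplitude * np.exp(-0.5 * ((t_us - cfg.p2_latency) / cfg.p2_width) ** 2)
    return n1 + p2


def simulate_sweeps(config: SweepSimConfig) -> SweepSet:
    """Simulate an N×T sweep matrix.

    Each sweep is the continuous template shifted by a per-sweep latency
    drawn from Normal(0, latency_jitter_sd) — evaluated analytically, not
    by integer-sample shifting, to avoid quantization artifacts — scaled
    by a multiplicative amplitude factor Normal(1, cv) floored at 0, plus
    additive white noise.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    t = config.t0_offset_us + np.arange(config.n_samples) / config.sampling_rate * 1e6
    shifts = rng.normal(0.0, config.latency_jitter_sd, size=config.n_sweeps) \
        if config.latency_jitter_sd > 0 else np.zeros(config.n_sweeps)
    scales = rng.normal(1.0, config.amplitude_jitter_cv, size=config.n_sweeps) \
        if config.amplitude_jitter_cv > 0 else np.ones(config.n_sweeps)
    scales = np.maximum(scales, 0.0)
    data = np.empty((config.n_sweeps, config.n_samples))
    for k in range(config.n_sweeps):
        data[k] = scales[k] * _template(t - shifts[k], config)
    if config.noise_sd > 0:
        data += rng.normal(0.0, config.noise_sd, size=data.shape)
    return SweepSet(
        data=data,
        sampling_rate=config.sampling_rate,
        t0_offset_us=config.t0_offset_us,
        metadata={"config": config},
    )


# ---------------------------------------------------------------------------
# I/O-pair simulation


@dataclass
class IOSimConfig:
    level_grid: np.ndarray = field(default_factory=lambda: np.arange(150, 211, 4))
    c_level: float = 210.0
    phase_duration: float = 50.0          # µs/phase (25 or 50 in practice)
    ipg_pair: tuple = (7.0, 42.0)         # µs
    sigmoid_truth_per_ipg: dict = field(default_factory=dict)
    noise_sd: float = 2.0                 # µV
    scenario: str = "custom"
    electrode_position: str = "middle"
    subject: str = "sim"
    seed: int = 0
    law: DeviceLaw = DEFAULT_LAW

    def validate(self) -> None:
        grid = np.asarray(self.level_grid, dtype=float)
        if len(grid) < 2 or not np.all(np.diff(grid) > 0):
            raise ValueError("level grid must be strictly increasing with ≥ 2 levels")
        if grid.max() > self.c_level:
            raise ValueError("level grid must not exceed the C level")
        for ipg in self.ipg_pair:
            if ipg not in self.sigmoid_truth_per_ipg:
                raise ValueError(f"missing sigmoid truth for IPG {ipg} µs")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be non-negative")


def _charge_axis(cfg: IOSimConfig) -> np.ndarray:
    current = np.array([cl_to_current(cl, cfg.law) for cl in cfg.level_grid])
    return current_to_charge(current, cfg.phase_duration)


def simulate_io_pair(config: IOSimConfig):
    """Simulate (IOFunction at IPG-7, IOFunction at IPG-42) on a shared grid.

    Amplitudes are the ground-truth sigmoid evaluated on the charge axis
    plus Gaussian noise, floored at 0 µV (negative eCAP amplitudes are not
    meaningful).  Ground truth is carried in each function's ``truth``
    field for recovery tests.  The IPG-7 noise substream is spawned before
    the IPG-42 one.
    """
    config.validate()
    charge = _charge_axis(config)
    streams = np.random.SeedSequence(config.seed).spawn(len(config.ipg_pair))
    out = []
    for ipg, stream in zip(config.ipg_pair, streams):
        truth = config.sigmoid_truth_per_ipg[ipg]
        y = truth(charge)
        if config.noise_sd > 0:
            y = y + np.random.default_rng(stream).normal(0, config.noise_sd, len(y))
        out.append(
            IOFunction(
                levels=np.asarray(config.level_grid, dtype=float),
                amplitudes=np.maximum(y, 0.0),
                c_level=config.c_level,
                phase_duration=config.phase_duration,
                ipg=ipg,
                subject=config.subject,
                electrode=config.electrode_position,
                truth=truth,
            )
        )
    return tuple(out)


# Illustrative preset table (version 1) — NOT fitted to patient data.
# Encodes the qualitative structure the analyses should resolve:
#   * CND-like: low maximum amplitude, shallow growth, large leftward
#     IPG-42 level shift that increases toward the apex;
#   * NSCN-like / GJB2-like: high amplitude, steep growth, small shift
#     with no position gradient (GJB2 slightly smaller than NSCN).
# Amplitude ceilings sit inside realistic averaged-eCAP ranges
# (tens of µV to ~1 mV).  Shifts are on the charge (nC) axis.
SCENARIO_PRESETS = {
    "CND": {
        "y0": 0.0, "a": 150.0, "b7": 24.0, "c": 3.0, "a42_gain": 1.05,
        "shift_nc": {"basal": 2.0, "middle": 3.0, "apical": 4.0},
    },
    "NSCN": {
        "y0": 0.0, "a": 400.0, "b7": 21.0, "c": 2.0, "a42_gain": 1.05,
        "shift_nc": {"basal": 0.9, "middle": 0.9, "apical": 0.9},
    },
    "GJB2": {
        "y0": 0.0, "a": 550.0, "b7": 20.0, "c": 1.8, "a42_gain": 1.05,
        "shift_nc": {"basal": 0.8, "middle": 0.8, "apical": 0.8},
    },
}
SCENARIO_PRESETS_VERSION = 1


def scenario_config(
    scenario: str,
    electrode_position: str = "middle",
    seed: int = 0,
    noise_sd: float = 2.0,
    phase_duration: float = 50.0,
    subject: str = "sim",
) -> IOSimConfig:
    """Build an :class:`IOSimConfig` from the preset table."""
    if scenario not in SCENARIO_PRESETS:
        raise ValueError(f"unknown scenario {scenario!r}; options: {sorted(SCENARIO_PRESETS)}")
    p = SCENARIO_PRESETS[scenario]
    if electrode_position not in p["shift_nc"]:
        raise ValueError(f"unknown electrode position {electrode_position!r}")
    shift = p["shift_nc"][electrode_position]
    truth = {
        7.0: SigmoidParams(p["y0"], p["a"], p["b7"], p["c"]),
        42.0: SigmoidParams(p["y0"], p["a"] * p["a42_gain"], p["b7"] - shift, p["c"]),
    }
    return IOSimConfig(
        sigmoid_truth_per_ipg=truth,
        noise_sd=noise_sd,
        scenario=scenario,
        electrode_position=electrode_position,
        phase_duration=phase_duration,
        subject=subject,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# theoretical forward model


@dataclass(frozen=True)
class BrochierConfig:
    """Factors of the forward model V = r·n·(s·g·I)².

    r: recording-electrode factor; n: number of neurons near the
    stimulating electrode; s: stimulating-electrode factor; g: stimulus-
    dependent gain (differs between IPG conditions); current_grid in µA.
    """

    r: float = 1.0
    n: float = 1.0
    s: float = 1.0
    g: float = 1.0
    current_grid: tuple = tuple(np.linspace(100.0, 800.0, 15))

    def __post_init__(self) -> None:
        if min(self.r, self.n, self.s, self.g) <= 0:
            raise ValueError("all forward-model factors must be positive")
        if np.any(np.asarray(self.current_grid) <= 0):
            raise ValueError("all currents must be positive")


def brochier_forward(config: BrochierConfig) -> np.ndarray:
    """Noise-free voltage V = r·n·(s·g·I)² at each current of the grid."""
    current = np.asarray(config.current_grid, dtype=float)
    return config.r * config.n * (config.s * config.g * current) ** 2


def brochier_io_pair(
    config7: BrochierConfig,
    config42: BrochierConfig,
    phase_duration: float = 50.0,
    law: DeviceLaw = DEFAULT_LAW,
):
    """Express a pair of forward-model curves as IOFunctions on the CL axis.

    The shared current grid is mapped back through the device law to
    (fractional) current levels so the theoretical curves flow through the
    same scale transforms and offset machinery as measured data.
    """
    if tuple(config7.current_grid) != tuple(config42.current_grid):
        raise ValueError("both conditions must share one current grid")
    from .scales import current_to_cl

    levels = np.array([current_to_cl(i, law) for i in config7.current_grid])
    out = []
    for ipg, cfg in ((7.0, config7), (42.0, config42)):
        out.append(
            IOFunction(
                levels=levels,
                amplitudes=brochier_forward(cfg),
                c_level=levels.max(),
                phase_duration=phase_duration,
                ipg=ipg,
                subject="brochier",
                electrode="model",
            )
        )
    return tuple(out)
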