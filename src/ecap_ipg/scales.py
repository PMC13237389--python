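"""Stimulus-level and amplitude scale conversions.

Cochlear-implant stimulation levels are programmed in device current-level
units (CL, an integer code that maps exponentially onto current in µA).
Analyses of eCAP input/output functions are carried out on three
input/output scale combinations:

* S1 — charge in nC (linear input) vs. amplitude in µV (linear output)
* S2 — charge in dB re 1 nC (log input) vs. amplitude in µV (linear output)
* S3 — charge in dB re 1 nC (log input) vs. amplitude in dB re 1 µV (log output)

The fourth combination (linear charge input, logarithmic amplitude output)
has no physiological justification and is rejected at construction time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "DeviceLaw",
    "ScaleSpec",
    "ScaledIO",
    "S1",
    "S2",
    "S3",
    "ALL_SCALES",
    "OFFSET_LABELS",
    "cl_to_current",
    "current_to_charge",
    "to_db",
    "from_db",
    "transform_io",
]

INPUT_SCALES = ("nC", "dB re 1 nC")
OUTPUT_SCALES = ("uV", "dB re 1 uV")


@dataclass(frozen=True)
class DeviceLaw:
    """Exponential CL→current map, I(µA) = coeff · base^(cl / cl_max).

    The default (17.5 µA at CL 0, ×100 over the full 0–255 range) follows
    the manufacturer convention for the implant family the pipeline
    targets; it is overridable because devices differ.
    """

    coeff: float = 17.5
    base: float = 100.0
    cl_max: int = 255


DEFAULT_LAW = DeviceLaw()


def cl_to_current(cl: float, law: DeviceLaw = DEFAULT_LAW) -> float:
    """Convert a device current level to current in µA.

    Fractional levels are accepted (synthetic or theoretical curves may
    live between programmable steps); the level must lie in [0, cl_max].
    """
    if not 0 <= cl <= law.cl_max:
        raise ValueError(f"current level {cl} outside device range [0, {law.cl_max}]")
    return law.coeff * law.base ** (cl / law.cl_max)


def current_to_cl(current_ua: float, law: DeviceLaw = DEFAULT_LAW) -> float:
    """Inverse of :func:`cl_to_current` (fractional CL)."""
    if current_ua <= 0:
        raise ValueError("current must be positive")
    return law.cl_max * math.log(current_ua / law.coeff) / math.log(law.base)


def current_to_charge(current_ua: float, phase_us: float) -> float:
    """Charge per phase in nC: µA × µs / 1000."""
    if phase_us <= 0:
        raise ValueError("phase duration must be positive")
    if np.any(np.asarray(current_ua) < 0):
        raise ValueError("current must be non-negative")
    return current_ua * phase_us / 1000.0


def to_db(value, reference: float = 1.0):
    """Amplitude-like dB: 20·log10(value / reference).

    Both voltage (µV) and charge (nC) are amplitude-like quantities here,
    so the 20·log10 convention applies to both.
    """
    value = np.asarray(value, dtype=float)
    if reference <= 0:
        raise ValueError("reference must be positive")
    if np.any(value <= 0):
        raise ValueError("dB transform requires strictly positive values")
    out = 20.0 * np.log10(value / reference)
    return float(out) if out.ndim == 0 else out


def from_db(db, reference: float = 1.0):
    db = np.asarray(db, dtype=float)
    out = reference * 10.0 ** (db / 20.0)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ScaleSpec:
    input_scale: str
    output_scale: str

    def __post_init__(self) -> None:
        if self.input_scale not in INPUT_SCALES:
            raise ValueError(f"unknown input scale {self.input_scale!r}")
        if self.output_scale not in OUTPUT_SCALES:
            raise ValueError(f"unknown output scale {self.output_scale!r}")
        if self.input_scale == "nC" and self.output_scale == "dB re 1 uV":
            raise ValueError(
                "the (linear input, logarithmic output) scale is not supported"
            )

    @property
    def log_input(self) -> bool:
        return self.input_scale == "dB re 1 nC"

    @property
    def log_output(self) -> bool:
        return self.output_scale == "dB re 1 uV"

    @property
    def slope_units(self) -> str:
        return f"{self.output_scale}/{self.input_scale}"


S1 = ScaleSpec("nC", "uV")
S2 = ScaleSpec("dB re 1 nC", "uV")
S3 = ScaleSpec("dB re 1 nC", "dB re 1 uV")
ALL_SCALES = {"S1": S1, "S2": S2, "S3": S3}

# Offset-variant labels: the nC offset comes from the linear/linear function,
# "dB_linear/log" and "dB_log/log" from the log-input functions with linear
# and logarithmic outputs respectively.  The axis convention behind each
# label is carried alongside it in every output.
OFFSET_LABELS = {"S1": "nC", "S2": "dB_linear/log", "S3": "dB_log/log"}


@dataclass
class ScaledIO:
    """An I/O function re-expressed on an analysis scale.

    ``levels`` keeps the original device levels of the retained points so
    level-window selections (threshold → C level) remain possible after
    the transform.  Points excluded by a dB output transform (zero or
    negative amplitude) are reported in ``dropped``, never removed
    silently.
    """

    x: np.ndarray
    y: np.ndarray
    spec: ScaleSpec
    levels: np.ndarray
    provenance: str = ""
    dropped: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.levels = np.asarray(self.levels, dtype=float)
        if len(self.x) != len(self.y):
            raise ValueError("x and y must have equal length")
        if len(self.x) > 1 and not np.all(np.diff(self.x) > 0):
            raise ValueError("x must be strictly increasing")

    def __len__(self) -> int:
        return len(self.x)


def level_to_input(
    levels: Sequence[float],
    spec: ScaleSpec,
    phase_us: float,
    law: DeviceLaw = DEFAULT_LAW,
) -> np.ndarray:
    """Map device levels to the input coordinate of ``spec`` (nC or dB re 1 nC)."""
    levels = np.asarray(levels, dtype=float)
    current = np.array([cl_to_current(cl, law) for cl in levels])
    charge = current_to_charge(current, phase_us)
    return to_db(charge) if spec.log_input else charge


def transform_io(io, spec: ScaleSpec, law: DeviceLaw = DEFAULT_LAW) -> ScaledIO:
    """Re-express an :class:`~ecap_ipg.synthetic.IOFunction` on ``spec``.

    Under a dB output scale, points with non-positive amplitude cannot be
    represented and are excluded with an explicit report in ``dropped``.
    """
    x = level_to_input(io.levels, spec, io.phase_duration, law)
    y = np.asarray(io.amplitudes, dtype=float)
    levels = np.asarray(io.levels, dtype=float)
    dropped: list = []
    if spec.log_output:
        keep = y > 0
        dropped = [
            {"level_cl": float(l), "amplitude_uv": float(a)}
            for l, a in zip(levels[~keep], y[~keep])
        ]
        x, y, levels = x[keep], y[keep], levels[keep]
        y = to_db(y)
    return ScaledIO(
        x=x, y=y, spec=spec, levels=levels, provenance=getattr(io, "label", ""),
        dropped=dropped,
    )
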