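"""Stimulation level offset between IPG-7 and IPG-42 growth functions.

The offset asks: how much lower a stimulation level does the long-IPG
(42 µs) pulse need to reach the same eCAP amplitude as the short-IPG
(7 µs) pulse?  Both functions are first normalized to the maximum measured
amplitude of the IPG-7 function, re-expressed on the requested analysis
scale, and fitted with the four-parameter sigmoid.  The overlapping
amplitude interval is the intersection of the two fitted amplitude ranges
realized over each function's measured level span; target amplitudes are
placed at 25%, 50% and 75% of that interval, each fit is inverted in
closed form, and the offset is the mean of the three level differences

    offset = mean_q [ level_IPG7(y_q) − level_IPG42(y_q) ],

positive when the 42-µs pulse reaches equal amplitude at a lower level
(the long IPG is more efficient).  On the dB output scale the quantiles
are taken after the output-log transform, i.e. in dB space; the label and
axis convention of each variant are carried in the result.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .io_features import SigmoidFit, fit_sigmoid
from .scales import (
    ALL_SCALES,
    OFFSET_LABELS,
    ScaledIO,
    ScaleSpec,
    transform_io,
)
from .synthetic import IOFunction

__all__ = [
    "NormalizedPair",
    "OffsetResult",
    "QUANTILES",
    "normalize_pair",
    "invert_sigmoid",
    "stimulation_level_offset",
    "offset_all_scales",
]

QUANTILES = (0.25, 0.50, 0.75)


@dataclass
class NormalizedPair:
    """IPG-7/IPG-42 functions on one scale, amplitudes shared-normalized.

    ``normalizer`` is the maximum measured amplitude of the function
    passed as IPG-7, applied to both amplitude vectors *before* any
    output-scale log transform; the input (level) axis is untouched.
    """

    io7: ScaledIO
    io42: ScaledIO
    normalizer: float
    spec: ScaleSpec


def _round_sig(values: np.ndarray, digits: int = 9) -> np.ndarray:
    """Round to ``digits`` significant figures (elementwise; zeros kept).

    Normalized amplitudes are canonicalized this way: nine significant
    figures sit far below any measurement meaning (eCAP amplitudes carry
    a few µV-level digits), and the rounding makes normalization exactly
    idempotent with respect to floating-point roundoff of scale factors
    shared by both curves — mathematically identical normalized pairs map
    to bit-identical downstream results.
    """
    values = np.asarray(values, dtype=float)
    out = np.zeros_like(values)
    nz = values != 0
    quantum = 10.0 ** (np.floor(np.log10(np.abs(values[nz]))) - (digits - 1))
    out[nz] = np.round(values[nz] / quantum) * quantum
    return out


def normalize_pair(
    io7: IOFunction, io42: IOFunction, spec: ScaleSpec
) -> NormalizedPair:
    if len(io7) == 0 or len(io42) == 0:
        raise ValueError("both I/O functions must be non-empty")
    normalizer = float(np.max(io7.amplitudes))
    if normalizer <= 0:
        raise ValueError("IPG-7 maximum amplitude must be positive to normalize")

    def scaled(io: IOFunction) -> ScaledIO:
        norm = IOFunction(
            levels=io.levels,
            amplitudes=_round_sig(io.amplitudes / normalizer),
            c_level=io.c_level,
            phase_duration=io.phase_duration,
            ipg=io.ipg,
            subject=io.subject,
            electrode=io.electrode,
        )
        return transform_io(norm, spec)

    return NormalizedPair(
        io7=scaled(io7), io42=scaled(io42), normalizer=normalizer, spec=spec
    )


def invert_sigmoid(fit: SigmoidFit, y_target: float) -> float:
    """Closed-form inverse x = b − c·ln(a/(y − y0) − 1).

    Defined only for targets strictly inside the open amplitude range
    (y0, y0 + a).
    """
    if not fit.converged:
        raise ValueError("cannot invert a non-converged fit")
    if not fit.y0 < y_target < fit.y0 + fit.a:
        raise ValueError(
            f"target {y_target} outside the open range "
            f"({fit.y0}, {fit.y0 + fit.a}) of the fitted sigmoid"
        )
    return float(fit.b - fit.c * math.log(fit.a / (y_target - fit.y0) - 1.0))


@dataclass
class OffsetResult:
    label: str                       # nC | dB_linear/log | dB_log/log
    spec: Optional[ScaleSpec] = None
    offset: Optional[float] = None   # mean of the per-quantile differences
    quantiles: tuple = QUANTILES
    target_amplitudes: tuple = ()    # normalized-amplitude targets (output scale)
    level_differences: tuple = ()    # level_7 − level_42 at each target
    overlap: tuple = ()              # (low, high) of the overlapping range
    fit7: Optional[SigmoidFit] = None
    fit42: Optional[SigmoidFit] = None
    missing: bool = False
    reason: Optional[str] = None


def _realized_range(fit: SigmoidFit, sio: ScaledIO) -> tuple:
    """Fitted amplitude range over the measured level span (monotone fit)."""
    lo, hi = fit(sio.x[0]), fit(sio.x[-1])
    return (lo, hi) if lo <= hi else (hi, lo)


def stimulation_level_offset(
    pair: NormalizedPair, label: Optional[str] = None
) -> OffsetResult:
    """Offset from a normalized pair via per-quantile sigmoid inversion."""
    if label is None:
        label = next(
            (v for k, v in OFFSET_LABELS.items() if ALL_SCALES[k] == pair.spec),
            pair.spec.slope_units,
        )
    fit7 = fit_sigmoid(pair.io7)
    fit42 = fit_sigmoid(pair.io42)
    base = OffsetResult(label=label, spec=pair.spec, fit7=fit7, fit42=fit42)
    for name, fit in (("IPG-7", fit7), ("IPG-42", fit42)):
        if not fit.converged:
            base.missing, base.reason = True, f"{name} sigmoid fit: {fit.reason}"
            return base
    lo7, hi7 = _realized_range(fit7, pair.io7)
    lo42, hi42 = _realized_range(fit42, pair.io42)
    lo, hi = max(lo7, lo42), min(hi7, hi42)
    base.overlap = (lo, hi)
    if not lo < hi:
        base.missing, base.reason = True, "empty overlapping amplitude range"
        return base
    targets, diffs = [], []
    for q in QUANTILES:
        y = lo + q * (hi - lo)
        try:
            x7 = invert_sigmoid(fit7, y)
            x42 = invert_sigmoid(fit42, y)
        except ValueError as exc:
            base.missing, base.reason = True, f"inversion failed at q={q}: {exc}"
            return base
        targets.append(y)
        diffs.append(x7 - x42)
    base.target_amplitudes = tuple(targets)
    base.level_differences = tuple(diffs)
    base.offset = float(np.mean(diffs))
    return base


def offset_all_scales(io7: IOFunction, io42: IOFunction) -> dict:
    """One OffsetResult per allowed scale, keyed by its variant label.

    Per-scale failures (non-convergence, empty overlap, dB exclusions
    emptying a function) stay independent: each scale reports its own
    missingness.
    """
    out = {}
    for key, spec in ALL_SCALES.items():
        label = OFFSET_LABELS[key]
        try:
            pair = normalize_pair(io7, io42, spec)
            out[label] = stimulation_level_offset(pair, label=label)
        except ValueError as exc:
            out[label] = OffsetResult(
                label=label, spec=spec, missing=True, reason=str(exc)
            )
    return out
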