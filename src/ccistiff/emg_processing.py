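"""Raw EMG → per-cycle 101-point envelopes in four variants.

Processing chain for the *basic* envelope: 4th-order Butterworth high-pass at
40 Hz applied forward–backward (zero phase), demean, full-wave rectify, then a
4th-order zero-phase Butterworth low-pass whose cutoff adapts to the gait
cycle (3.5 / cycle period, e.g. 2.5 Hz for a 1.4 s cycle).  Small negative
ripple left by the low-pass is clamped to zero — envelopes are physically
non-negative and the per-cycle offset step would otherwise shift whole cycles
by ripple magnitude.

The continuous envelope is then segmented heel strike to heel strike, each
cycle linearly resampled to 101 points (0–100% in 1% steps), offset so its
minimum is exactly 0, and the whole set normalized so the maximum over all
analyzed cycles is exactly 1.

Variants:

- ``basic``      — the chain above on the undelayed record;
- ``delayed``    — same chain on the record shifted by the leg's
  electromechanical delay (shift applied to the continuous record, before
  segmentation);
- ``scaled``     — basic × muscle-specific scale factor (pointwise);
- ``calibrated`` — delayed × scale factor, i.e. delayed = calibrated / scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

__all__ = [
    "EmgCycleSet",
    "VARIANTS",
    "envelope",
    "lowpass_cutoff",
    "delay_shift",
    "segment_cycles",
    "segment_normalize",
    "make_variants",
]

log = logging.getLogger(__name__)

VARIANTS = ("basic", "scaled", "delayed", "calibrated")
N_GRID = 101
PERCENT_GRID = np.arange(N_GRID)  # 0–100 % gait cycle


@dataclass(frozen=True)
class EmgCycleSet:
    """Per-muscle, per-cycle 101-point envelopes of one variant."""

    muscle: str
    variant: str
    cycles: np.ndarray  # shape (n_cycles, 101)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        c = np.asarray(self.cycles, dtype=float)
        if c.ndim != 2 or c.shape[1] != N_GRID:
            raise ValueError("cycles must be (n_cycles, 101)")
        if np.any(c < 0):
            raise ValueError("envelope values must be non-negative")
        object.__setattr__(self, "cycles", c)

    @property
    def n_cycles(self) -> int:
        return self.cycles.shape[0]


def _zero_phase(x: np.ndarray, cutoff_hz: float, rate: float, btype: str, order: int) -> np.ndarray:
    nyq = rate / 2.0
    if cutoff_hz >= nyq:
        raise ValueError(f"cutoff {cutoff_hz} Hz >= Nyquist {nyq} Hz")
    sos = signal.butter(order, cutoff_hz / nyq, btype=btype, output="sos")
    # settling length ~ one period of the corner frequency; reflective padding
    # of 3x that keeps edge transients out of the analyzed record
    settle = int(np.ceil(rate / min(cutoff_hz, nyq - 1e-9) if btype != "highpass"
                         else rate / cutoff_hz))
    padlen = 3 * settle
    if x.shape[-1] <= padlen:
        raise ValueError(
            f"series of {x.shape[-1]} samples shorter than 3x filter settling "
            f"length ({settle} samples)"
        )
    return signal.sosfiltfilt(sos, x, padtype="even", padlen=padlen)


def envelope(
    raw: np.ndarray, rate: float, cycle_period: float, order: int = 4
) -> np.ndarray:
    """Linear envelope of a raw EMG record (continuous, same length).

    High-pass 40 Hz → demean → rectify → low-pass 3.5/cycle_period Hz, every
    filter a zero-phase (forward–backward) Butterworth of the given design
    order.  Negative low-pass ripple is clamped at 0.
    """
    if cycle_period <= 0:
        raise ValueError("cycle_period must be positive")
    if rate <= 2 * 40.0:
        raise ValueError("sampling rate must exceed twice the 40 Hz high-pass cutoff")
    x = np.asarray(raw, dtype=float)
    x = _zero_phase(x, 40.0, rate, "highpass", order)
    x = x - np.mean(x)
    x = np.abs(x)
    x = _zero_phase(x, 3.5 / cycle_period, rate, "lowpass", order)
    return np.maximum(x, 0.0)


def lowpass_cutoff(cycle_period: float) -> float:
    """Cycle-adaptive low-pass cutoff in Hz (3.5 / period)."""
    if cycle_period <= 0:
        raise ValueError("cycle_period must be positive")
    return 3.5 / cycle_period


def delay_shift(series: np.ndarray, rate: float, delay_ms: float) -> np.ndarray:
    """Shift a continuous record later by the electromechanical delay.

    Output sample at time t equals the input at t − delay; the leading gap is
    held at the first value (no signal is fabricated — analyzed cycles should
    begin after at least one delay length of lead-in).  Length is preserved.
    """
    if delay_ms < 0:
        raise ValueError("delay must be >= 0")
    x = np.asarray(series, dtype=float)
    d = int(round(delay_ms * rate / 1000.0))
    if d >= x.shape[-1]:
        raise ValueError("delay longer than the record")
    if d == 0:
        return x.copy()
    out = np.empty_like(x)
    out[..., :d] = x[..., :1]
    out[..., d:] = x[..., :-d]
    return out


def segment_cycles(
    series: np.ndarray, rate: float, heel_strikes: np.ndarray, t0: float = 0.0
) -> np.ndarray:
    """Resample each heel-strike-to-heel-strike interval to 101 points.

    No normalization or offsetting — plain per-cycle linear resampling onto
    the 0–100% grid.  ``t0`` is the time of the first sample of ``series``.
    Used for kinematics and activations as well as envelopes.
    """
    hs = np.asarray(heel_strikes, dtype=float)
    if hs.size < 2:
        raise ValueError("need at least two heel strikes (one full cycle)")
    if np.any(np.diff(hs) <= 0):
        raise ValueError("heel strikes must be strictly increasing")
    x = np.asarray(series, dtype=float)
    t = t0 + np.arange(x.shape[-1]) / rate
    if hs[0] < t[0] - 1e-9 or hs[-1] > t[-1] + 1e-9:
        raise ValueError("series does not cover the heel-strike interval")
    out = np.empty((hs.size - 1, N_GRID))
    for i in range(hs.size - 1):
        grid = hs[i] + (hs[i + 1] - hs[i]) * PERCENT_GRID / 100.0
        out[i] = np.interp(grid, t, x)
    return out


def segment_normalize(
    env: np.ndarray, rate: float, heel_strikes: np.ndarray, t0: float = 0.0
) -> np.ndarray:
    """Segment an envelope into normalized 101-point cycles.

    Each cycle is resampled to 101 points, offset by its minimum (per-cycle
    min exactly 0), and the whole set divided by its maximum over all analyzed
    cycles (global max exactly 1).  An all-zero envelope is returned as
    all-zero cycles with a logged warning instead of dividing by zero.
    """
    cyc = segment_cycles(env, rate, heel_strikes, t0=t0)
    cyc = cyc - cyc.min(axis=1, keepdims=True)
    peak = cyc.max()
    if peak == 0:
        log.warning("all-zero envelope: skipping max normalization")
        return cyc
    return cyc / peak


def make_variants(
    raw: np.ndarray,
    rate: float,
    cycle_period: float,
    heel_strikes: np.ndarray,
    scale: float,
    delay_ms: float,
    muscle: str = "",
    t0: float = 0.0,
    order: int = 4,
) -> dict[str, EmgCycleSet]:
    """Compute all four envelope variants for one muscle's raw record."""
    if not 0 < scale <= 1:
        raise ValueError("scale must lie in (0, 1]")
    prov = {
        "rate_hz": rate,
        "highpass_hz": 40.0,
        "lowpass_hz": lowpass_cutoff(cycle_period),
        "filter_order": order,
        "delay_ms": delay_ms,
        "scale": scale,
    }
    env = envelope(raw, rate, cycle_period, order=order)
    basic = segment_normalize(env, rate, heel_strikes, t0=t0)
    delayed = segment_normalize(
        delay_shift(env, rate, delay_ms), rate, heel_strikes, t0=t0
    )
    out = {
        "basic": basic,
        "scaled": basic * scale,
        "delayed": delayed,
        "calibrated": delayed * scale,
    }
    return {
        v: EmgCycleSet(muscle=muscle, variant=v, cycles=c, provenance=dict(prov))
        for v, c in out.items()
    }
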