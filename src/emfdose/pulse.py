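"""Characterization of monophasic magnetizing pulses.

A BCU magnetizes or demagnetizes an anti-theft strip with one strong
monophasic magnetic pulse.  Because the pulse is monophasic, its waveform is
fully characterized by three numbers: the temporal peak of B, the full width
at half maximum (FWHM) and the peak absolute time derivative |dB/dt|.  By
Faraday's law the induced electric field in tissue tracks dB/dt, so the peak
induced field of a device whose field map was never measured can be roughly
estimated as (mean device proportionality constant) x |dB/dt|peak, where the
constants Ein_peak / |dB/dt|peak come from the devices that were fully
characterized by numerical dosimetry.

Traces are stored internally in SI units (seconds, tesla); microtesla input
is converted at the I/O boundary (:meth:`PulseTrace.from_microtesla`,
:func:`read_pulse_trace`).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "PulseTrace",
    "InvalidTraceError",
    "pulse_peak",
    "pulse_fwhm",
    "dbdt_peak",
    "proportionality_constant",
    "estimate_internal_peak",
    "read_pulse_trace",
]

#: tolerated max/min sampling-step ratio before a trace is rejected
_UNIFORMITY_TOL = 1.01


class InvalidTraceError(ValueError):
    """Raised for traces that violate the sampling contract."""


@dataclass(frozen=True)
class PulseTrace:
    """A sampled pulse: strictly increasing times (s) and fields (T).

    Requires at least three samples, finite values and near-uniform sampling
    (max/min step ratio below 1.01) so that finite differences are
    well-conditioned.
    """

    times_s: np.ndarray
    fields_t: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=float)
        b = np.asarray(self.fields_t, dtype=float)
        object.__setattr__(self, "times_s", t)
        object.__setattr__(self, "fields_t", b)
        if t.ndim != 1 or b.ndim != 1 or t.shape != b.shape:
            raise InvalidTraceError("times and fields must be 1-D arrays of equal length")
        if t.size < 3:
            raise InvalidTraceError("a trace needs at least 3 samples")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(b))):
            raise InvalidTraceError("trace contains non-finite values")
        steps = np.diff(t)
        if np.any(steps <= 0):
            raise InvalidTraceError("times must be strictly increasing")
        if steps.max() / steps.min() >= _UNIFORMITY_TOL:
            raise InvalidTraceError("sampling must be uniform to within 1%")

    @classmethod
    def from_microtesla(cls, times_s: Sequence[float], fields_ut: Sequence[float]) -> "PulseTrace":
        return cls(np.asarray(times_s, float), np.asarray(fields_ut, float) * 1e-6)


def pulse_peak(trace: PulseTrace) -> float:
    """Temporal peak of |B| over the trace, in tesla."""
    return float(np.max(np.abs(trace.fields_t)))


def pulse_fwhm(trace: PulseTrace) -> float:
    """Full width at half maximum of a monophasic pulse, in seconds.

    The half-maximum level is half the peak of |B| (after orienting the
    trace so its extremum is positive).  Crossings are located by linear
    interpolation between bracketing samples; a valid monophasic pulse must
    yield exactly two crossings, otherwise the trace is rejected.
    """
    b = trace.fields_t
    # orient so the dominant lobe is positive; FWHM is sign-invariant
    if abs(b.min()) > abs(b.max()):
        b = -b
    peak = b.max()
    if peak <= 0:
        raise InvalidTraceError("pulse has no positive peak")
    half = 0.5 * peak
    s = b - half
    crossings: list[float] = []
    for i in range(len(s) - 1):
        if s[i] == 0.0:
            crossings.append(float(trace.times_s[i]))
        elif s[i] * s[i + 1] < 0.0:
            frac = s[i] / (s[i] - s[i + 1])
            crossings.append(float(trace.times_s[i] + frac * (trace.times_s[i + 1] - trace.times_s[i])))
    if s[-1] == 0.0:
        crossings.append(float(trace.times_s[-1]))
    if len(crossings) != 2:
        raise InvalidTraceError(
            f"expected exactly 2 half-maximum crossings, found {len(crossings)} "
            "(trace is not a clean monophasic pulse)"
        )
    return crossings[1] - crossings[0]


def dbdt_peak(trace: PulseTrace) -> float:
    """Peak |dB/dt| over the trace, in T/s.

    Central differences in the interior, one-sided at the endpoints.
    """
    deriv = np.gradient(trace.fields_t, trace.times_s)
    return float(np.max(np.abs(deriv)))


def proportionality_constant(ein_peak_vm: float, dbdt_peak_ts: float) -> float:
    """Device constant k = Ein_peak / |dB/dt|peak, in V·s/(T·m)."""
    if ein_peak_vm <= 0 or dbdt_peak_ts <= 0:
        raise ValueError("ein_peak and dbdt_peak must both be positive")
    return ein_peak_vm / dbdt_peak_ts


def estimate_internal_peak(dbdt_peak_ts: float, constants: Sequence[float]) -> float:
    """Rough peak induced field for an uncharacterized device, in V/m.

    The unweighted mean of the supplied device constants times the device's
    measured |dB/dt|peak.
    """
    if dbdt_peak_ts <= 0:
        raise ValueError("dbdt_peak must be positive")
    k = np.asarray(constants, dtype=float)
    if k.size == 0:
        raise ValueError("need at least one proportionality constant")
    if np.any(k <= 0):
        raise ValueError("proportionality constants must be positive")
    return float(k.mean() * dbdt_peak_ts)


def read_pulse_trace(path: str | Path) -> PulseTrace:
    """Read a two-column delimited waveform file.

    The header names the units: first column ``time_s``, second column
    ``field_T`` or ``field_uT``.  Comma, tab or whitespace delimited.
    """
    import pandas as pd

    df = pd.read_csv(path, sep=None, engine="python")
    cols = {c.strip().lower(): c for c in df.columns}
    if "time_s" not in cols:
        raise InvalidTraceError(f"{path}: missing 'time_s' column (found {list(df.columns)})")
    t = df[cols["time_s"]].to_numpy(float)
    if "field_t" in cols:
        return PulseTrace(t, df[cols["field_t"]].to_numpy(float))
    if "field_ut" in cols:
        return PulseTrace.from_microtesla(t, df[cols["field_ut"]].to_numpy(float))
    raise InvalidTraceError(f"{path}: need a 'field_T' or 'field_uT' column")
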