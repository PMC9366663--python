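"""ICNIRP 2010 occupational limits for low- and intermediate-frequency fields.

Two quantities are exposed:

* the **reference level** (RL) — the externally measurable magnetic flux
  density limit, in microtesla;
* the **basic restriction** (BR) — the limit on the electric field induced
  inside tissue, in V/m rms.

Both are piecewise functions of frequency.  Only the occupational tier is
implemented, over the band this package actually needs (25 Hz – 10 MHz);
general-public limits and the electric-field reference levels are out of
scope.

For monophasic pulses the BR, which is stated for sinusoidal rms values, is
converted to a peak limit by multiplying with sqrt(2)
(:func:`br_peak_for_pulse`), so that a calculated peak induced field can be
compared against it directly.
"""

from __future__ import annotations

import math

__all__ = [
    "FREQ_MIN_HZ",
    "FREQ_MAX_HZ",
    "rl_occupational",
    "br_occupational",
    "br_peak_for_pulse",
]

FREQ_MIN_HZ = 25.0
FREQ_MAX_HZ = 10e6


def _check_frequency(frequency_hz: float) -> float:
    f = float(frequency_hz)
    if not math.isfinite(f):
        raise ValueError(f"frequency must be finite, got {frequency_hz!r}")
    if not (FREQ_MIN_HZ <= f <= FREQ_MAX_HZ):
        raise ValueError(
            f"frequency {f} Hz outside supported domain "
            f"[{FREQ_MIN_HZ:g} Hz, {FREQ_MAX_HZ:g} Hz]"
        )
    return f


def rl_occupational(frequency_hz: float) -> float:
    """Occupational magnetic-flux-density reference level, in microtesla.

    Piecewise over the supported domain: 1000 uT up to 300 Hz, then
    3e5 / f uT up to 3 kHz, then 100 uT up to 10 MHz.  The function is
    continuous at both band edges; band boundaries belong to the
    lower-frequency band.

    >>> rl_occupational(220)
    1000.0
    >>> round(rl_occupational(366), 1)
    819.7
    >>> rl_occupational(14e3)
    100.0
    """
    f = _check_frequency(frequency_hz)
    if f <= 300.0:
        return 1000.0
    if f <= 3000.0:
        return 3e5 / f
    return 100.0


def br_occupational(frequency_hz: float) -> float:
    """Occupational basic restriction on the induced electric field, V/m rms.

    0.8 V/m up to 3 kHz, then 2.7e-4 * f V/m; the 3 kHz boundary takes the
    lower-band value of 0.8 V/m (the sub-3 kHz sources handled here are all
    assessed against 0.8 V/m).

    >>> br_occupational(220)
    0.8
    >>> round(br_occupational(14e3), 2)
    3.78
    """
    f = _check_frequency(frequency_hz)
    if f <= 3000.0:
        return 0.8
    return 2.7e-4 * f


def br_peak_for_pulse(frequency_hz: float) -> float:
    """Peak-value basic restriction for a monophasic pulse, V/m peak.

    The BR is defined in rms terms for sinusoids; for a pulse the comparable
    limit on the *peak* induced field is the rms BR scaled by sqrt(2).
    """
    return br_occupational(frequency_hz) * math.sqrt(2.0)
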