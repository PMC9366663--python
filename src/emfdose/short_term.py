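"""Short-term exposure ratios E1–E3, as percent of ICNIRP 2010 occupational limits.

Three exposure situations are assessed:

* **E1** — whole-body exposure of a worker seated within 3 m of an EM-EAS
  gate.  The field at the seat is extrapolated from the gate's 45-point
  spatial average ``B_IEC`` with an empirical power-law distance decay,
  and compared against the magnetic-flux-density reference level (RL).
* **E2** — local exposure while passing through or beside the gate.  The
  induced internal electric field is scaled from the reference gate's
  dosimetry constant by operating frequency and ``B_IEC``, and compared
  against the basic restriction (BR).
* **E3** — local exposure of the hand while operating a BCU.  The
  99th-percentile peak induced field of the pulse is compared against the
  peak-converted BR (rms BR x sqrt 2) in the band of the pulse's spectral
  peak (~200 Hz, where the BR is flat).

Ratios for simultaneous sources are additive (:func:`combined_ratio`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .icnirp import br_occupational, br_peak_for_pulse, rl_occupational
from .registry import BCUModel, GateModel, ReferenceGateConstants

__all__ = [
    "DECAY_COEFFICIENT",
    "DECAY_EXPONENT",
    "MIN_DISTANCE_CM",
    "PULSE_SPECTRAL_PEAK_HZ",
    "ShortTermExposure",
    "field_at_distance",
    "e1_ratio",
    "internal_field_scaled",
    "e2_ratio",
    "e3_ratio",
    "combined_ratio",
]

#: empirical distance-decay law B(r)/B_IEC = coef * r^(-exp), r in cm
DECAY_COEFFICIENT = 7.84e4
DECAY_EXPONENT = 2.89
#: the decay law is only validated for r > 50 cm; closer seats are clamped
MIN_DISTANCE_CM = 50.0
#: spectral peak of the magnetizing pulse; picks the (flat) BR band for E3
PULSE_SPECTRAL_PEAK_HZ = 200.0


@dataclass(frozen=True)
class ShortTermExposure:
    """Per-respondent E1–E3 ratios.

    ``None`` encodes absence of the corresponding source (not zero
    exposure).  ``flags`` carries quality markers: ``distance_clamped``,
    ``substituted_device``, ``rough_estimate``.
    """

    e1_pct_rl: Optional[float] = None
    e2_pct_br: Optional[float] = None
    e3_pct_br: Optional[float] = None
    flags: frozenset[str] = field(default_factory=frozenset)


def field_at_distance(gate: GateModel, r_cm: float) -> float:
    """Magnetic flux density at distance ``r_cm`` from the gate, in microtesla.

    Power-law extrapolation from the gate's spatially averaged field:
    ``B(r) = B_IEC * 7.84e4 * r^-2.89``.
    """
    if not r_cm > 0:
        raise ValueError(f"distance must be positive, got {r_cm!r}")
    return gate.b_iec_ut * DECAY_COEFFICIENT * r_cm ** (-DECAY_EXPONENT)


def clamp_distance(r_cm: float) -> tuple[float, bool]:
    """Clamp a seat distance to the decay law's validity floor (50 cm).

    Returns the usable distance and whether clamping occurred.
    """
    if not r_cm > 0:
        raise ValueError(f"distance must be positive, got {r_cm!r}")
    return (MIN_DISTANCE_CM, True) if r_cm < MIN_DISTANCE_CM else (float(r_cm), False)


def e1_ratio(gate: GateModel, r_cm: float, *, clamp: bool = True) -> float:
    """E1: seated whole-body exposure as percent of the occupational RL."""
    r, _ = clamp_distance(r_cm) if clamp else (r_cm, False)
    return 100.0 * field_at_distance(gate, r) / rl_occupational(gate.frequency_hz)


def internal_field_scaled(gate: GateModel, ref: ReferenceGateConstants | None = None) -> float:
    """Induced internal electric field near the gate, in V/m.

    Scales the reference gate's numerically computed field linearly in
    operating frequency and spatially averaged flux density:
    ``E = E_ref * (f / f_ref) * (B_IEC / B_IEC_ref)``.
    """
    ref = ref or ReferenceGateConstants()
    if gate.frequency_hz <= 0 or gate.b_iec_ut <= 0:
        raise ValueError("gate parameters must be positive")
    return ref.e_ref_vm * (gate.frequency_hz / ref.f_ref_hz) * (gate.b_iec_ut / ref.b_iec_ref_ut)


def e2_ratio(gate: GateModel, ref: ReferenceGateConstants | None = None) -> float:
    """E2: transient gate-pass exposure as percent of the occupational BR."""
    return 100.0 * internal_field_scaled(gate, ref) / br_occupational(gate.frequency_hz)


def e3_ratio(bcu: BCUModel, spectral_peak_hz: float = PULSE_SPECTRAL_PEAK_HZ) -> float:
    """E3: BCU pulse exposure as percent of the peak-converted BR.

    The comparison band is set by the pulse's spectral peak (default
    200 Hz); the BR is flat below 3 kHz so the exact assignment is inert.
    """
    if bcu.ein_peak_vm is None:
        raise ValueError(f"BCU {bcu.bcu_id} has no resolved peak induced field")
    return 100.0 * bcu.ein_peak_vm / br_peak_for_pulse(spectral_peak_hz)


def combined_ratio(exposure: ShortTermExposure) -> float:
    """Sum of the present E1–E3 ratios (absent sources contribute nothing)."""
    return sum(v for v in (exposure.e1_pct_rl, exposure.e2_pct_br, exposure.e3_pct_br) if v is not None)
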