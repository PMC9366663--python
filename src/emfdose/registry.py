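"""Device registry: EAS gates and book check units (BCUs).

The registry is the canonical parameter store for the surveyed devices:
eight electromagnetic EAS gate types (I–VIII) and nine BCU types (I–IX).
Parameters live in two bundled tab-separated files (``data/gates.tsv``,
``data/bcus.tsv``) so that a future device survey can extend them without
touching code; the bundled version is pinned by the test suite.

Substitution rules for unmeasured or unidentified devices are part of the
registry contract and are always recorded in ``substituted_from``:

* gates III and VI carry the spatially averaged field of the representative
  model with matching frequency/coil geometry (gates I and IV);
* gate VIII ("other gates", i.e. unidentified EM gates) carries gate I's
  parameters, gate I being the most common model in the field;
* BCUs II, III, IV, VI, VII and IX carry BCU I's peak induced field.

Questionnaire answers are mapped onto registry entries by
:func:`resolve_gate` / :func:`resolve_bcu` with an explicit, case-insensitive
controlled vocabulary.  Answers naming a device that emits no relevant field
(RFID or flapper gates, RF or unidentified non-EM BCUs, "none") resolve to
``None``, the null-source marker: absence of a source, never zero exposure.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Optional

import pandas as pd

__all__ = [
    "GateModel",
    "BCUModel",
    "ReferenceGateConstants",
    "DeviceRegistry",
    "load_default_registry",
    "resolve_gate",
    "resolve_bcu",
    "gate_family",
    "bcu_family",
    "GATE_FAMILIES",
    "BCU_FAMILIES",
    "UnknownLabelError",
]

GATE_IDS = ("I", "II", "III", "IV", "V", "VI", "VII", "VIII")
BCU_IDS = ("I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX")

#: questionnaire gate-answer families (Table-level categories)
GATE_FAMILIES = ("eas_em", "rfid", "flapper_or_cardreader", "dont_remember_other", "none")
#: questionnaire BCU-answer families
BCU_FAMILIES = ("em", "rf", "other", "none")


class UnknownLabelError(ValueError):
    """A questionnaire label outside the controlled vocabulary."""


@dataclass(frozen=True)
class ReferenceGateConstants:
    """Constants of the reference gate (gate II) used by the internal-field
    scaling law: its numerically computed 99th-percentile induced field,
    operating frequency and spatially averaged flux density."""

    e_ref_vm: float = 0.88
    f_ref_hz: float = 14000.0
    b_iec_ref_ut: float = 111.0


@dataclass(frozen=True)
class GateModel:
    """One EM-EAS gate type.

    ``internal_field_vm`` is the 99th-percentile induced electric field for
    near-gate exposure; it is a dosimetry result for the reference gate and
    is derived for every other gate by frequency/field scaling against the
    reference constants.
    """

    gate_id: str
    vendor_code: str
    frequency_hz: float
    b_iec_ut: float
    internal_field_vm: float
    share_pct: float
    substituted_from: Optional[str] = None

    def __post_init__(self) -> None:
        if self.frequency_hz <= 0 or self.b_iec_ut <= 0 or self.internal_field_vm <= 0:
            raise ValueError(f"gate {self.gate_id}: physical parameters must be positive")


@dataclass(frozen=True)
class BCUModel:
    """One book-check-unit type (pulsed magnetic-field source).

    ``b_iec_pulse_ut`` stores the registry's printed pulse field column
    verbatim; it is carried for completeness but plays no role in the
    exposure-ratio computation, which uses ``ein_peak_vm`` only.
    """

    bcu_id: str
    vendor_code: str
    ein_peak_vm: float
    estimate_kind: str  # calculated | rough_estimate | substituted
    share_pct: float
    pulse_peak_b_ut: Optional[float] = None
    fwhm_ms: Optional[float] = None
    dbdt_peak_ts: Optional[float] = None
    b_iec_pulse_ut: Optional[float] = None
    substituted_from: Optional[str] = None

    def __post_init__(self) -> None:
        if self.ein_peak_vm <= 0:
            raise ValueError(f"BCU {self.bcu_id}: ein_peak must be positive")
        if self.estimate_kind not in ("calculated", "rough_estimate", "substituted"):
            raise ValueError(f"BCU {self.bcu_id}: bad estimate_kind {self.estimate_kind!r}")
        if self.estimate_kind == "substituted" and not self.substituted_from:
            raise ValueError(f"BCU {self.bcu_id}: substituted value without provenance")
        for name in ("pulse_peak_b_ut", "fwhm_ms", "dbdt_peak_ts", "b_iec_pulse_ut"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValueError(f"BCU {self.bcu_id}: {name} must be positive if present")


def _normalize(label: str) -> str:
    return str(label).strip().lower().replace("-", "_").replace(" ", "_").replace("/", "_")


# synonyms accepted on top of the canonical tokens
_GATE_NULL = {"rfid", "flapper", "cardreader", "flapper_or_cardreader",
              "other_cardreader_flapper", "none"}
_GATE_OTHER = {"other", "dont_remember", "don't_remember", "dont_remember_other", "eas_em"}
_BCU_NULL = {"rf", "other", "none"}


@dataclass(frozen=True)
class DeviceRegistry:
    """Immutable collection of gate and BCU models keyed by id."""

    gates: dict[str, GateModel]
    bcus: dict[str, BCUModel]
    reference: ReferenceGateConstants = ReferenceGateConstants()

    def resolve_gate(self, label: str) -> Optional[GateModel]:
        """Map a questionnaire gate answer to a :class:`GateModel`.

        Unidentified EM gates ("other", "don't remember") map to gate VIII,
        which carries gate I's parameters.  Non-EM gates and "none" map to
        ``None`` (no IF-EMF source).  Anything else raises
        :class:`UnknownLabelError`.
        """
        token = _normalize(label)
        if token in _GATE_NULL:
            return None
        if token in _GATE_OTHER:
            return self.gates["VIII"]
        if token.startswith("gate_"):
            gate_id = token[5:].upper()
            if gate_id in self.gates:
                return self.gates[gate_id]
        raise UnknownLabelError(f"unrecognized gate label: {label!r}")

    def resolve_bcu(self, label: str) -> Optional[BCUModel]:
        """Map a questionnaire BCU answer to a :class:`BCUModel`.

        Unidentified EM BCUs ("em") map to BCU IX (BCU I's induced field,
        substituted).  RF, other and "none" answers map to ``None`` (no
        pulsed-field source).
        """
        token = _normalize(label)
        if token in _BCU_NULL:
            return None
        if token == "em":
            return self.bcus["IX"]
        if token.startswith("bcu_"):
            bcu_id = token[4:].upper()
            if bcu_id in self.bcus:
                return self.bcus[bcu_id]
        raise UnknownLabelError(f"unrecognized BCU label: {label!r}")


def gate_family(label: str) -> str:
    """Collapse a gate answer to its family: eas_em, rfid,
    flapper_or_cardreader, dont_remember_other or none."""
    token = _normalize(label)
    if token == "none":
        return "none"
    if token == "rfid":
        return "rfid"
    if token in {"flapper", "cardreader", "flapper_or_cardreader", "other_cardreader_flapper"}:
        return "flapper_or_cardreader"
    if token in _GATE_OTHER - {"eas_em"}:
        return "dont_remember_other"
    if token == "eas_em" or (token.startswith("gate_") and token[5:].upper() in GATE_IDS):
        return "eas_em"
    raise UnknownLabelError(f"unrecognized gate label: {label!r}")


def bcu_family(label: str) -> str:
    """Collapse a BCU answer to its family: em, rf, other or none."""
    token = _normalize(label)
    if token in _BCU_NULL or token == "none":
        return token
    if token == "em" or (token.startswith("bcu_") and token[4:].upper() in BCU_IDS):
        return "em"
    raise UnknownLabelError(f"unrecognized BCU label: {label!r}")


def _read_tsv(name: str) -> pd.DataFrame:
    with resources.files("emfdose.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh, sep="\t", dtype={"gate_id": str, "bcu_id": str})


def load_default_registry() -> DeviceRegistry:
    """Load the bundled device registry.

    Gate internal fields are resolved at load time: the reference gate keeps
    its dosimetry constant, every other gate is scaled by
    (f / f_ref) x (B_IEC / B_IEC_ref) from the reference value.
    """
    ref = ReferenceGateConstants()
    gates: dict[str, GateModel] = {}
    for row in _read_tsv("gates.tsv").itertuples(index=False):
        sub = None if pd.isna(row.substituted_from) else str(row.substituted_from)
        e_vm = ref.e_ref_vm * (row.frequency_hz / ref.f_ref_hz) * (row.b_iec_ut / ref.b_iec_ref_ut)
        gates[str(row.gate_id)] = GateModel(
            gate_id=str(row.gate_id),
            vendor_code=str(row.vendor_code),
            frequency_hz=float(row.frequency_hz),
            b_iec_ut=float(row.b_iec_ut),
            internal_field_vm=e_vm,
            share_pct=float(row.share_pct),
            substituted_from=sub,
        )
    bcus: dict[str, BCUModel] = {}
    for row in _read_tsv("bcus.tsv").itertuples(index=False):
        opt = lambda v: None if pd.isna(v) else float(v)  # noqa: E731
        sub = None if pd.isna(row.substituted_from) else str(row.substituted_from)
        bcus[str(row.bcu_id)] = BCUModel(
            bcu_id=str(row.bcu_id),
            vendor_code=str(row.vendor_code),
            ein_peak_vm=float(row.ein_peak_vm),
            estimate_kind=str(row.estimate_kind),
            share_pct=float(row.share_pct),
            pulse_peak_b_ut=opt(row.pulse_peak_b_ut),
            fwhm_ms=opt(row.fwhm_ms),
            dbdt_peak_ts=opt(row.dbdt_peak_ts),
            b_iec_pulse_ut=opt(row.b_iec_pulse_ut),
            substituted_from=sub,
        )
    if set(gates) != set(GATE_IDS) or set(bcus) != set(BCU_IDS):
        raise RuntimeError("bundled registry is incomplete")
    return DeviceRegistry(gates=gates, bcus=bcus, reference=ref)


def resolve_gate(label: str, registry: Optional[DeviceRegistry] = None) -> Optional[GateModel]:
    """Module-level convenience wrapper around :meth:`DeviceRegistry.resolve_gate`."""
    return (registry or load_default_registry()).resolve_gate(label)


def resolve_bcu(label: str, registry: Optional[DeviceRegistry] = None) -> Optional[BCUModel]:
    """Module-level convenience wrapper around :meth:`DeviceRegistry.resolve_bcu`."""
    return (registry or load_default_registry()).resolve_bcu(label)
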