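"""End-to-end run: read cohort, clean, impute, resolve devices, score, summarize.

The pipeline stages are: clean -> categorize weekly counts -> impute missing
gate-pass categories -> resolve devices -> E1–E3 -> D1–D3 -> classify ->
summarize.  Every source of randomness (imputation donor draws, tie breaks)
flows from the single configured seed, so a run is deterministic given its
inputs and configuration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import cohort as _cohort
from ._format import round_half_up, round_sig
from .cohort import CleanReport, RespondentRecord, classify_pattern
from .dose import ExposureProfile, d1, d2, d3, summarize_by_pattern
from .registry import DeviceRegistry, load_default_registry
from .short_term import clamp_distance, e1_ratio, e2_ratio, e3_ratio

__all__ = [
    "RunConfig",
    "PipelineResult",
    "read_cohort_csv",
    "write_cohort_csv",
    "profile_respondent",
    "run_pipeline",
    "profiles_frame",
]

log = logging.getLogger(__name__)

COHORT_COLUMNS = (
    "respondent_id", "sits_within_3m", "gate_label", "seat_distance_cm",
    "hours_in_seat", "gate_passes_per_week", "uses_bcu", "bcu_label",
    "bcu_ops_per_week",
)

_TRUE = {"yes", "y", "true", "1"}
_FALSE = {"no", "n", "false", "0"}


@dataclass(frozen=True)
class RunConfig:
    """Validated pipeline configuration."""

    registry: str = "default"
    outlier_ceiling_h: float = 80.0
    imputation_m: int = 5
    seed: int = 0
    weight_scheme: str = "ordinal"

    def __post_init__(self) -> None:
        if self.outlier_ceiling_h <= 0:
            raise ValueError("outlier_ceiling_h must be positive")
        if self.imputation_m < 1:
            raise ValueError("imputation_m must be >= 1")
        if self.weight_scheme not in ("ordinal", "midpoint"):
            raise ValueError(f"weight_scheme must be 'ordinal' or 'midpoint', got {self.weight_scheme!r}")
        if self.registry != "default" and not Path(self.registry).exists():
            raise ValueError(f"registry path does not exist: {self.registry}")

    def load_registry(self) -> DeviceRegistry:
        if self.registry == "default":
            return load_default_registry()
        raise NotImplementedError("custom registry files are not supported yet")


@dataclass(frozen=True)
class PipelineResult:
    profiles: tuple[ExposureProfile, ...]
    summary: pd.DataFrame
    clean_report: CleanReport
    imputation_provenance: dict[str, list[int]] = field(default_factory=dict)

    @property
    def pattern_counts(self) -> dict[int, int]:
        counts = {k: 0 for k in (1, 2, 3, 4)}
        for p in self.profiles:
            counts[p.pattern] += 1
        return counts


def _parse_bool(cell: str, row: int, col: str) -> Optional[bool]:
    token = cell.strip().lower()
    if token == "":
        return None
    if token in _TRUE:
        return True
    if token in _FALSE:
        return False
    raise ValueError(f"row {row}: column {col!r}: cannot parse yes/no value {cell!r}")


def _parse_float(cell: str, row: int, col: str) -> Optional[float]:
    token = cell.strip()
    if token == "":
        return None
    try:
        return float(token)
    except ValueError:
        raise ValueError(f"row {row}: column {col!r}: cannot parse number {cell!r}") from None


def read_cohort_csv(path: str | Path) -> list[RespondentRecord]:
    """Read a respondent cohort from the delimited-text schema.

    Header must contain exactly the documented columns; empty cells are
    missing values, never zeros.  All malformed rows are reported together.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(COHORT_COLUMNS) - set(df.columns)
    unknown = set(df.columns) - set(COHORT_COLUMNS)
    if missing or unknown:
        raise ValueError(
            f"{path}: cohort schema mismatch; missing columns {sorted(missing)}, "
            f"unknown columns {sorted(unknown)}"
        )
    records: list[RespondentRecord] = []
    errors: list[str] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        try:
            records.append(RespondentRecord(
                respondent_id=row.respondent_id.strip(),
                sits_within_3m=_parse_bool(row.sits_within_3m, i, "sits_within_3m"),
                gate_label=row.gate_label.strip() or "none",
                seat_distance_cm=_parse_float(row.seat_distance_cm, i, "seat_distance_cm"),
                hours_in_seat=_parse_float(row.hours_in_seat, i, "hours_in_seat"),
                gate_passes_per_week=_parse_float(row.gate_passes_per_week, i, "gate_passes_per_week"),
                uses_bcu=_parse_bool(row.uses_bcu, i, "uses_bcu"),
                bcu_label=row.bcu_label.strip() or "none",
                bcu_ops_per_week=_parse_float(row.bcu_ops_per_week, i, "bcu_ops_per_week"),
            ))
            records[-1].gate_family()  # label validation
            records[-1].bcu_family()
        except ValueError as exc:
            errors.append(str(exc) if str(exc).startswith("row") else f"row {i}: {exc}")
    if errors:
        raise ValueError(f"{path}: {len(errors)} malformed rows:\n" + "\n".join(errors))
    return records


def write_cohort_csv(records: Sequence[RespondentRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append({
            "respondent_id": r.respondent_id,
            "sits_within_3m": "" if r.sits_within_3m is None else ("yes" if r.sits_within_3m else "no"),
            "gate_label": r.gate_label,
            "seat_distance_cm": "" if r.seat_distance_cm is None else r.seat_distance_cm,
            "hours_in_seat": "" if r.hours_in_seat is None else r.hours_in_seat,
            "gate_passes_per_week": "" if r.gate_passes_per_week is None else r.gate_passes_per_week,
            "uses_bcu": "" if r.uses_bcu is None else ("yes" if r.uses_bcu else "no"),
            "bcu_label": r.bcu_label,
            "bcu_ops_per_week": "" if r.bcu_ops_per_week is None else r.bcu_ops_per_week,
        })
    pd.DataFrame(rows, columns=COHORT_COLUMNS).to_csv(path, index=False)


def profile_respondent(
    rec: RespondentRecord,
    registry: DeviceRegistry,
    weight_scheme: str = "ordinal",
) -> ExposureProfile:
    """Resolve devices and compute E1–E3 / D1–D3 for one cleaned record."""
    pattern = classify_pattern(rec)
    flags: set[str] = set()
    e1 = e2 = e3 = v1 = v2 = v3 = None

    if pattern in (1, 2):
        gate = registry.resolve_gate(rec.gate_label)
        assert gate is not None  # IF-exposed implies a resolvable EM gate
        if gate.substituted_from:
            flags.add("substituted_device")
        e2 = e2_ratio(gate, registry.reference)
        if rec.gate_pass_category is not None:
            v2 = d2(e2, rec.gate_pass_category, weight_scheme)
        if rec.seat_distance_cm is not None:
            r, clamped = clamp_distance(rec.seat_distance_cm)
            if clamped:
                flags.add("distance_clamped")
            e1 = e1_ratio(gate, r, clamp=False)
            if rec.hours_in_seat is not None:
                v1 = d1(e1, rec.hours_in_seat)

    if pattern in (1, 3):
        bcu = registry.resolve_bcu(rec.bcu_label)
        assert bcu is not None  # pulsed-exposed implies an EM check unit
        if bcu.estimate_kind == "substituted":
            flags.add("substituted_device")
        elif bcu.estimate_kind == "rough_estimate":
            flags.add("rough_estimate")
        e3 = e3_ratio(bcu)
        if rec.bcu_ops_category is not None:
            v3 = d3(e3, rec.bcu_ops_category, weight_scheme)

    return ExposureProfile(
        respondent_id=rec.respondent_id, pattern=pattern,
        e1_pct_rl=e1, e2_pct_br=e2, e3_pct_br=e3,
        d1=v1, d2=v2, d3=v3, flags=frozenset(flags),
    )


def run_pipeline(
    records: Sequence[RespondentRecord],
    config: RunConfig | None = None,
) -> PipelineResult:
    """Execute the full assessment on raw records.

    Deterministic given the configured seed; stage counts are logged.
    """
    cfg = config or RunConfig()
    registry = cfg.load_registry()

    cleaned, report = _cohort.clean_records(records, cfg.outlier_ceiling_h)
    log.info("clean: %d in, %d blank removed, %d outliers removed",
             report.n_input, report.n_blank_removed, report.n_outlier_removed)

    cleaned = _cohort.categorize_records(cleaned)
    rng = np.random.default_rng(cfg.seed)
    completed, provenance = _cohort.impute_gate_passes(cleaned, m=cfg.imputation_m, seed=rng)
    report = CleanReport(
        n_input=report.n_input, n_blank_removed=report.n_blank_removed,
        n_outlier_removed=report.n_outlier_removed, n_imputed=len(provenance),
    )
    log.info("impute: %d gate-pass categories filled (m=%d)", len(provenance), cfg.imputation_m)

    profiles = tuple(profile_respondent(r, registry, cfg.weight_scheme) for r in completed)
    summary = summarize_by_pattern(profiles)
    counts = {k: sum(p.pattern == k for p in profiles) for k in (1, 2, 3, 4)}
    log.info("classify: pattern counts %s", counts)
    return PipelineResult(profiles=profiles, summary=summary,
                          clean_report=report, imputation_provenance=provenance)


def profiles_frame(profiles: Sequence[ExposureProfile]) -> pd.DataFrame:
    """Per-respondent table: full-precision values plus printed-precision
    companions (percent ratios at 2 significant figures, dose indices as
    integers)."""
    df = pd.DataFrame([{
        "respondent_id": p.respondent_id,
        "pattern": p.pattern,
        "e1_pct_rl": p.e1_pct_rl, "e2_pct_br": p.e2_pct_br, "e3_pct_br": p.e3_pct_br,
        "d1": p.d1, "d2": p.d2, "d3": p.d3,
        "flags": ";".join(sorted(p.flags)),
    } for p in profiles])
    for col in ("e1_pct_rl", "e2_pct_br", "e3_pct_br"):
        df[col + "_printed"] = df[col].map(lambda v: None if pd.isna(v) else round_sig(v, 2))
    for col in ("d1", "d2", "d3"):
        df[col + "_printed"] = df[col].map(lambda v: None if pd.isna(v) else round_half_up(v, 0))
    return df
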