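"""Questionnaire cohort processing.

Cleans raw respondent records, bins the weekly-frequency answers into
ordinal categories, fills missing gate-pass categories by stratified
hot-deck multiple imputation, and classifies every respondent into one of
four exposure patterns:

1. combined IF-EMF and pulsed-EMF exposure,
2. IF-EMF only,
3. pulsed EMF only,
4. neither.

A respondent counts as IF-EMF exposed when they sit within 3 m of an EM-EAS
gate or of a gate they could not identify (unidentified gates are treated as
EM sources, the dominant type in the field), and as pulsed-EMF exposed when
they operate an EM-type BCU.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import numpy as np

from .registry import bcu_family, gate_family

__all__ = [
    "RespondentRecord",
    "CleanReport",
    "DEFAULT_OUTLIER_CEILING_H",
    "clean_records",
    "categorize_gate_passes",
    "categorize_bcu_ops",
    "impute_gate_passes",
    "classify_pattern",
]

log = logging.getLogger(__name__)

#: plausibility ceiling for hours/week spent in the seat.  Weekly seat time
#: above this is treated as a reporting error and the record dropped.
DEFAULT_OUTLIER_CEILING_H = 80.0

GATE_PASS_CATEGORIES = (0, 1, 2, 3, 4, 5)
BCU_OPS_CATEGORIES = (1, 2, 3, 4, 5)


@dataclass(frozen=True)
class RespondentRecord:
    """One questionnaire row.

    ``None`` always means "not answered / not applicable", never zero.
    The ordinal category fields are derived from the weekly counts during
    processing; a record may carry either or both.
    """

    respondent_id: str
    sits_within_3m: Optional[bool] = None
    gate_label: str = "none"
    seat_distance_cm: Optional[float] = None
    hours_in_seat: Optional[float] = None
    gate_passes_per_week: Optional[float] = None
    gate_pass_category: Optional[int] = None
    uses_bcu: Optional[bool] = None
    bcu_label: str = "none"
    bcu_ops_per_week: Optional[float] = None
    bcu_ops_category: Optional[int] = None
    imputed_gate_passes: bool = False

    def is_blank(self) -> bool:
        return self.sits_within_3m is None and self.uses_bcu is None

    def gate_family(self) -> str:
        return gate_family(self.gate_label)

    def bcu_family(self) -> str:
        return bcu_family(self.bcu_label)


@dataclass(frozen=True)
class CleanReport:
    n_input: int
    n_blank_removed: int = 0
    n_outlier_removed: int = 0
    n_imputed: int = 0

    @property
    def n_retained(self) -> int:
        return self.n_input - self.n_blank_removed - self.n_outlier_removed


def clean_records(
    records: Sequence[RespondentRecord],
    outlier_ceiling_h: float = DEFAULT_OUTLIER_CEILING_H,
) -> tuple[list[RespondentRecord], CleanReport]:
    """Drop blank responses and implausible seat-time records.

    A record is blank when neither yes/no screening question was answered.
    A record is an outlier when its weekly seat time exceeds
    ``outlier_ceiling_h`` (default 80 h/week).
    """
    kept: list[RespondentRecord] = []
    n_blank = n_outlier = 0
    for rec in records:
        if rec.is_blank():
            n_blank += 1
        elif rec.hours_in_seat is not None and rec.hours_in_seat > outlier_ceiling_h:
            n_outlier += 1
            log.info("dropping respondent %s: %s h/week in seat exceeds ceiling %s",
                     rec.respondent_id, rec.hours_in_seat, outlier_ceiling_h)
        else:
            kept.append(rec)
    report = CleanReport(n_input=len(records), n_blank_removed=n_blank, n_outlier_removed=n_outlier)
    return kept, report


def categorize_gate_passes(passes_per_week: float) -> int:
    """Bin weekly gate passes into the six ordinal categories 0–5.

    0 -> 0; 1–10 -> 1; 11–20 -> 2; 21–25 -> 3; 26–30 -> 4; >30 -> 5.
    """
    n = float(passes_per_week)
    if n < 0:
        raise ValueError(f"gate passes per week cannot be negative: {n}")
    if n == 0:
        return 0
    for cat, upper in ((1, 10), (2, 20), (3, 25), (4, 30)):
        if n <= upper:
            return cat
    return 5


def categorize_bcu_ops(books_per_week: float) -> int:
    """Bin weekly BCU operations into the five ordinal categories 1–5.

    0–20 -> 1; 21–50 -> 2; 51–100 -> 3; 101–299 -> 4; >=300 -> 5.
    """
    n = float(books_per_week)
    if n < 0:
        raise ValueError(f"BCU operations per week cannot be negative: {n}")
    for cat, upper in ((1, 20), (2, 50), (3, 100), (4, 299)):
        if n <= upper:
            return cat
    return 5


def _with_categories(rec: RespondentRecord) -> RespondentRecord:
    """Fill ordinal categories from raw weekly counts where absent."""
    updates = {}
    if rec.gate_pass_category is None and rec.gate_passes_per_week is not None:
        updates["gate_pass_category"] = categorize_gate_passes(rec.gate_passes_per_week)
    if rec.bcu_ops_category is None and rec.bcu_ops_per_week is not None:
        updates["bcu_ops_category"] = categorize_bcu_ops(rec.bcu_ops_per_week)
    return replace(rec, **updates) if updates else rec


def categorize_records(records: Iterable[RespondentRecord]) -> list[RespondentRecord]:
    return [_with_categories(r) for r in records]


def _imputation_stratum(rec: RespondentRecord) -> tuple:
    return (rec.sits_within_3m, rec.gate_family())


def impute_gate_passes(
    records: Sequence[RespondentRecord],
    m: int = 5,
    seed: int | np.random.Generator = 0,
) -> tuple[list[RespondentRecord], dict[str, list[int]]]:
    """Multiple imputation of missing gate-pass categories.

    Stratified hot-deck: for each record with a missing category, ``m``
    donors are drawn (with replacement) from the observed categories in the
    same stratum (sitting status x gate family); the assigned category is
    the modal draw, ties broken uniformly at random.  Strata without donors
    fall back to the overall observed distribution with a logged warning.
    Observed values are never altered.  Fully reproducible under a fixed
    seed.

    Only respondents who face a gate (gate family other than "none") are
    imputed; the question does not apply to the rest.

    Returns the completed records and, per imputed respondent id, the list
    of ``m`` drawn categories (imputation provenance).
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    donors_by_stratum: dict[tuple, list[int]] = {}
    all_donors: list[int] = []
    for rec in records:
        if rec.gate_pass_category is not None:
            donors_by_stratum.setdefault(_imputation_stratum(rec), []).append(rec.gate_pass_category)
            all_donors.append(rec.gate_pass_category)

    needs = [r for r in records
             if r.gate_pass_category is None and r.gate_family() != "none"]
    if needs and not all_donors:
        raise ValueError("no observed gate-pass categories to impute from")

    out: list[RespondentRecord] = []
    provenance: dict[str, list[int]] = {}
    for rec in records:
        if rec.gate_pass_category is not None or rec.gate_family() == "none":
            out.append(rec)
            continue
        pool = donors_by_stratum.get(_imputation_stratum(rec))
        if not pool:
            log.warning("no donors in stratum %s for respondent %s; using marginal pool",
                        _imputation_stratum(rec), rec.respondent_id)
            pool = all_donors
        draws = [int(v) for v in rng.choice(pool, size=m)]
        counts = Counter(draws)
        top = max(counts.values())
        modal = [c for c, k in counts.items() if k == top]
        category = int(rng.choice(modal)) if len(modal) > 1 else modal[0]
        provenance[rec.respondent_id] = draws
        out.append(replace(rec, gate_pass_category=category, imputed_gate_passes=True))
    return out, provenance


def classify_pattern(rec: RespondentRecord) -> int:
    """Assign the four-way exposure pattern.

    IF-EMF exposed: sits within 3 m of an EM-EAS or unidentified gate.
    Pulsed exposed: operates an EM-type BCU.
    1 = both, 2 = IF only, 3 = pulsed only, 4 = neither.
    """
    if_exposed = bool(rec.sits_within_3m) and rec.gate_family() in ("eas_em", "dont_remember_other")
    pulsed_exposed = rec.bcu_family() == "em"
    if if_exposed and pulsed_exposed:
        return 1
    if if_exposed:
        return 2
    if pulsed_exposed:
        return 3
    return 4
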