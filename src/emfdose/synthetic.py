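"""Synthetic questionnaire cohorts.

The survey behind this package published only categorical summaries of its
548 respondents: the share who sit within 3 m of a gate, gate-family and
gate-model shares, binned seat distances and weekly seat hours, gate-pass
and BCU-operation category shares, and a full cross-tabulation of sitting
status x gate family x BCU type.  This module turns those published
marginals into data:

* :func:`generate` draws stochastic cohorts whose marginals match the
  published ones.  Questionnaire dimensions are sampled independently,
  with two deliberate exceptions: BCU type is drawn conditionally on the
  (sitting status, gate family) cell of the published cross-tabulation
  (the survey shows strong association there — libraries with EM gates
  overwhelmingly use EM check units), and respondents at the
  high-frequency reference gate (gate II) are restricted to seats of at
  least ~1 m, without which independence would contradict the published
  cohort maximum for seated exposure.
* :func:`fixture_table3_cohort` reconstructs a deterministic 548-record
  cohort whose cross-tabulation reproduces the published table
  cell-for-cell; continuous fields are filled by stratified quantile
  positions so the fixture is byte-stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .cohort import RespondentRecord

__all__ = ["CohortMarginals", "default_marginals", "generate", "fixture_table3_cohort"]

_GATE_MODEL_LABELS = tuple(f"gate_{gid}" for gid in ("I", "II", "III", "IV", "V", "VI", "VII", "VIII"))
_BCU_MODEL_LABELS = tuple(f"bcu_{bid}" for bid in ("I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX"))
_FAMILIES = ("eas_em", "rfid", "flapper_or_cardreader", "dont_remember_other")


def _normalized(shares: Sequence[float]) -> tuple[float, ...]:
    v = np.asarray(shares, float)
    if np.any(v < 0) or v.sum() <= 0:
        raise ValueError("shares must be non-negative with positive total")
    return tuple(v / v.sum())


@dataclass(frozen=True)
class CohortMarginals:
    """The categorical distributions a synthetic cohort is sampled from.

    Defaults are the published survey shares (printed percentages are
    normalized so each distribution sums to one exactly).  ``bcu_type_by_cell``
    is the conditional distribution of BCU type given the (sitting status,
    gate family) cell, taken from the published cross-tabulation.
    ``gate_ii_min_distance_bin`` is the zero-based index of the closest
    seat-distance bin available to gate II respondents (default 2, i.e.
    101–150 cm).
    """

    p_sits_within_3m: float = 238 / 548
    gate_family_shares: tuple[float, ...] = (178 / 238, 22 / 238, 8 / 238, 30 / 238)
    gate_model_shares: tuple[float, ...] = (0.380, 0.115, 0.005, 0.159, 0.082, 0.019, 0.014, 0.226)
    seat_distance_edges_cm: tuple[float, ...] = (0, 50, 100, 150, 200, 250, 300)
    seat_distance_shares: tuple[float, ...] = (0.010, 0.106, 0.087, 0.337, 0.096, 0.365)
    hours_edges: tuple[float, ...] = (0, 10, 20, 30, 40, 50, 60)
    hours_shares: tuple[float, ...] = (0.611, 0.202, 0.058, 0.091, 0.034, 0.005)
    gate_pass_category_shares: tuple[float, ...] = (0.024, 0.169, 0.150, 0.256, 0.184, 0.217)
    bcu_model_shares: tuple[float, ...] = (0.416, 0.007, 0.017, 0.027, 0.270, 0.024, 0.003, 0.108, 0.128)
    bcu_ops_category_shares: tuple[float, ...] = (0.214, 0.214, 0.197, 0.186, 0.190)
    bcu_type_by_cell: dict[tuple[bool, str], dict[str, float]] = field(
        default_factory=lambda: {
            (True, "eas_em"): {"em": 153 / 178, "rf": 3 / 178, "other": 5 / 178, "none": 17 / 178},
            (True, "rfid"): {"em": 2 / 22, "rf": 13 / 22, "other": 2 / 22, "none": 5 / 22},
            (True, "flapper_or_cardreader"): {"em": 7 / 8, "rf": 0.0, "other": 0.0, "none": 1 / 8},
            (True, "dont_remember_other"): {"em": 12 / 30, "rf": 15 / 30, "other": 0.0, "none": 3 / 30},
            (False, "none"): {"em": 121 / 310, "rf": 22 / 310, "other": 18 / 310, "none": 149 / 310},
        }
    )
    missingness_rate: float = 0.10
    gate_ii_min_distance_bin: int = 2

    def __post_init__(self) -> None:
        if not 0 <= self.p_sits_within_3m <= 1:
            raise ValueError("p_sits_within_3m must be a probability")
        if not 0 <= self.missingness_rate <= 1:
            raise ValueError("missingness_rate must be a probability")
        for name in ("gate_family_shares", "gate_model_shares", "seat_distance_shares",
                     "hours_shares", "gate_pass_category_shares", "bcu_model_shares",
                     "bcu_ops_category_shares"):
            object.__setattr__(self, name, _normalized(getattr(self, name)))
        for cell, dist in self.bcu_type_by_cell.items():
            total = sum(dist.values())
            if any(p < 0 for p in dist.values()) or abs(total - 1.0) > 1e-9:
                raise ValueError(f"BCU distribution for cell {cell} must sum to 1")
        if len(self.seat_distance_shares) != len(self.seat_distance_edges_cm) - 1:
            raise ValueError("seat-distance shares/edges length mismatch")
        if len(self.hours_shares) != len(self.hours_edges) - 1:
            raise ValueError("hours shares/edges length mismatch")
        if not 0 <= self.gate_ii_min_distance_bin < len(self.seat_distance_shares):
            raise ValueError("gate_ii_min_distance_bin out of range")


def default_marginals() -> CohortMarginals:
    """The published survey marginals as a value object."""
    return CohortMarginals()


def _sample_bins(rng: np.random.Generator, n: int, shares: Sequence[float]) -> np.ndarray:
    return rng.choice(len(shares), size=n, p=np.asarray(shares))


def _within_bin(rng: np.random.Generator, bins: np.ndarray, edges: Sequence[float],
                midpoint: bool) -> np.ndarray:
    lo = np.asarray(edges)[bins]
    hi = np.asarray(edges)[bins + 1]
    if midpoint:
        return (lo + hi) / 2.0
    return lo + rng.random(bins.size) * (hi - lo)


_PASS_COUNT_RANGES = {0: (0, 0), 1: (1, 10), 2: (11, 20), 3: (21, 25), 4: (26, 30), 5: (31, 60)}
_OPS_COUNT_RANGES = {1: (0, 20), 2: (21, 50), 3: (51, 100), 4: (101, 299), 5: (300, 600)}


def generate(
    n: int,
    marginals: Optional[CohortMarginals] = None,
    seed: int | np.random.Generator = 0,
    bin_sampling: str = "uniform",
) -> list[RespondentRecord]:
    """Draw a synthetic cohort of ``n`` respondents.

    Within a respondent: gate fields exist only for sitters, BCU fields only
    for BCU users; BCU type follows the conditional cell distribution; gate
    II respondents' seat-distance bins are truncated at the configured
    minimum.  Continuous values are drawn uniformly within their sampled bin
    (``bin_sampling="midpoint"`` gives deterministic bin centers instead).
    Weekly gate-pass and BCU-operation counts consistent with the sampled
    category are synthesized so cohorts round-trip through the CSV schema.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if bin_sampling not in ("uniform", "midpoint"):
        raise ValueError(f"unknown bin_sampling {bin_sampling!r}")
    m = marginals or default_marginals()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    midpoint = bin_sampling == "midpoint"

    sits = rng.random(n) < m.p_sits_within_3m
    gate_labels = np.array(["none"] * n, dtype=object)
    families = np.array(["none"] * n, dtype=object)
    sit_idx = np.flatnonzero(sits)
    fam_draw = rng.choice(len(_FAMILIES), size=sit_idx.size, p=np.asarray(m.gate_family_shares))
    for k, fam in enumerate(_FAMILIES):
        families[sit_idx[fam_draw == k]] = fam
    gate_labels[sits] = families[sits]
    em_idx = np.flatnonzero(families == "eas_em")
    model_draw = rng.choice(len(_GATE_MODEL_LABELS), size=em_idx.size, p=np.asarray(m.gate_model_shares))
    gate_labels[em_idx] = np.asarray(_GATE_MODEL_LABELS, dtype=object)[model_draw]

    # seat distance: gate II respondents cannot sit closer than the configured bin
    distance = np.full(n, np.nan)
    dist_bins = np.full(n, -1)
    dist_bins[sit_idx] = _sample_bins(rng, sit_idx.size, m.seat_distance_shares)
    gate_ii = gate_labels == "gate_II"
    if np.any(gate_ii):
        k0 = m.gate_ii_min_distance_bin
        trunc = np.asarray(m.seat_distance_shares[k0:])
        dist_bins[gate_ii] = k0 + rng.choice(trunc.size, size=int(gate_ii.sum()), p=trunc / trunc.sum())
    distance[sits] = _within_bin(rng, dist_bins[sits], m.seat_distance_edges_cm, midpoint)

    hours = np.full(n, np.nan)
    hour_bins = _sample_bins(rng, sit_idx.size, m.hours_shares)
    hours[sit_idx] = _within_bin(rng, hour_bins, m.hours_edges, midpoint)

    pass_cat = np.full(n, -1)
    pass_cat[sit_idx] = _sample_bins(rng, sit_idx.size, m.gate_pass_category_shares)
    missing = np.zeros(n, bool)
    missing[sit_idx] = rng.random(sit_idx.size) < m.missingness_rate
    pass_cat[missing] = -1

    bcu_types = np.array(["none"] * n, dtype=object)
    for (cell_sits, cell_family), dist in m.bcu_type_by_cell.items():
        rows = np.flatnonzero((sits == cell_sits) & (families == cell_family))
        if rows.size == 0:
            continue
        types = list(dist)
        probs = np.asarray([dist[t] for t in types])
        bcu_types[rows] = np.asarray(types, dtype=object)[rng.choice(len(types), size=rows.size, p=probs)]
    bcu_labels = bcu_types.copy()
    em_bcu = np.flatnonzero(bcu_types == "em")
    bcu_model_draw = rng.choice(len(_BCU_MODEL_LABELS), size=em_bcu.size, p=np.asarray(m.bcu_model_shares))
    bcu_labels[em_bcu] = np.asarray(_BCU_MODEL_LABELS, dtype=object)[bcu_model_draw]
    uses_bcu = bcu_types != "none"

    ops_cat = np.full(n, -1)
    user_idx = np.flatnonzero(uses_bcu)
    ops_cat[user_idx] = 1 + _sample_bins(rng, user_idx.size, m.bcu_ops_category_shares)

    records: list[RespondentRecord] = []
    width = max(5, len(str(n)))
    for i in range(n):
        pc = int(pass_cat[i]) if pass_cat[i] >= 0 else None
        oc = int(ops_cat[i]) if ops_cat[i] >= 0 else None
        passes = None
        if pc is not None:
            lo, hi = _PASS_COUNT_RANGES[pc]
            passes = float(lo if lo == hi else rng.integers(lo, hi + 1))
        ops = None
        if oc is not None:
            lo, hi = _OPS_COUNT_RANGES[oc]
            ops = float(rng.integers(lo, hi + 1))
        records.append(RespondentRecord(
            respondent_id=f"S{i:0{width}d}",
            sits_within_3m=bool(sits[i]),
            gate_label=str(gate_labels[i]),
            seat_distance_cm=float(distance[i]) if sits[i] else None,
            hours_in_seat=float(hours[i]) if sits[i] else None,
            gate_passes_per_week=passes,
            gate_pass_category=pc,
            uses_bcu=bool(uses_bcu[i]),
            bcu_label=str(bcu_labels[i]),
            bcu_ops_per_week=ops,
            bcu_ops_category=oc,
        ))
    return records


def _mixture_invcdf(q: float, edges: Sequence[float], shares: Sequence[float],
                    min_bin: int = 0) -> float:
    """Inverse CDF of a piecewise-uniform mixture, optionally truncated below."""
    shares = np.asarray(shares[min_bin:], float)
    shares = shares / shares.sum()
    edges = np.asarray(edges[min_bin:], float)
    cum = np.concatenate([[0.0], np.cumsum(shares)])
    j = int(np.searchsorted(cum, q, side="right") - 1)
    j = min(j, len(shares) - 1)
    frac = (q - cum[j]) / shares[j] if shares[j] > 0 else 0.0
    return float(edges[j] + frac * (edges[j + 1] - edges[j]))


def _categorical_invcdf(q: float, shares: Sequence[float]) -> int:
    cum = np.cumsum(np.asarray(shares, float))
    return int(np.searchsorted(cum / cum[-1], q, side="left"))


def _largest_remainder(total: int, shares: Sequence[float]) -> list[int]:
    raw = np.asarray(shares, float) * total / np.sum(shares)
    base = np.floor(raw).astype(int)
    rem = total - base.sum()
    order = np.argsort(-(raw - base))
    base[order[:rem]] += 1
    return base.tolist()


# published cross-tabulation: (sits, gate family, uses BCU, BCU type) -> count
_TABLE3_CELLS: tuple[tuple[bool, str, bool, str, int], ...] = (
    (True, "eas_em", True, "em", 153),
    (True, "eas_em", True, "rf", 3),
    (True, "eas_em", True, "other", 5),
    (True, "eas_em", False, "none", 17),
    (True, "rfid", True, "em", 2),
    (True, "rfid", True, "rf", 13),
    (True, "rfid", True, "other", 2),
    (True, "rfid", False, "none", 5),
    (True, "flapper_or_cardreader", True, "em", 7),
    (True, "flapper_or_cardreader", False, "none", 1),
    (True, "dont_remember_other", True, "em", 12),
    (True, "dont_remember_other", True, "rf", 15),
    (True, "dont_remember_other", False, "none", 3),
    (False, "none", True, "em", 121),
    (False, "none", True, "rf", 22),
    (False, "none", True, "other", 18),
    (False, "none", False, "none", 149),
)

_REP_PASS_COUNT = {0: 0.0, 1: 5.0, 2: 15.0, 3: 23.0, 4: 28.0, 5: 35.0}
_REP_OPS_COUNT = {1: 10.0, 2: 35.0, 3: 75.0, 4: 200.0, 5: 350.0}


def fixture_table3_cohort(marginals: Optional[CohortMarginals] = None) -> list[RespondentRecord]:
    """Deterministic 548-record cohort matching the published cross-tabulation.

    Categorical cells reproduce the published table exactly.  EM gate models
    are allocated to the EAS sitters by largest-remainder apportionment of
    the model shares; seat distances, hours and weekly counts are filled at
    stratified quantile positions of the marginal distributions, so repeated
    calls are byte-identical.
    """
    m = marginals or default_marginals()
    records: list[RespondentRecord] = []
    rid = 0
    for sits, family, uses, bcu_type, count in _TABLE3_CELLS:
        for _ in range(count):
            records.append(RespondentRecord(
                respondent_id=f"T{rid:03d}",
                sits_within_3m=sits,
                gate_label=family if sits else "none",
                uses_bcu=uses,
                bcu_label=bcu_type,
            ))
            rid += 1

    # specific EM gate models for the identified-EM sitters
    eas_rows = [i for i, r in enumerate(records) if r.gate_label == "eas_em"]
    alloc = _largest_remainder(len(eas_rows), m.gate_model_shares)
    labels = [lbl for lbl, k in zip(_GATE_MODEL_LABELS, alloc) for _ in range(k)]
    for i, lbl in zip(eas_rows, labels):
        records[i] = replace(records[i], gate_label=lbl)

    # specific models for the EM check-unit users
    em_rows = [i for i, r in enumerate(records) if r.bcu_label == "em"]
    bcu_alloc = _largest_remainder(len(em_rows), m.bcu_model_shares)
    bcu_labels = [lbl for lbl, k in zip(_BCU_MODEL_LABELS, bcu_alloc) for _ in range(k)]
    for i, lbl in zip(em_rows, bcu_labels):
        records[i] = replace(records[i], bcu_label=lbl)

    # quantile filling of continuous and ordinal fields
    sit_rows = [i for i, r in enumerate(records) if r.sits_within_3m]
    for rank, i in enumerate(sit_rows):
        q = (rank + 0.5) / len(sit_rows)
        min_bin = m.gate_ii_min_distance_bin if records[i].gate_label == "gate_II" else 0
        dist = _mixture_invcdf(q, m.seat_distance_edges_cm, m.seat_distance_shares, min_bin)
        hrs = _mixture_invcdf(q, m.hours_edges, m.hours_shares)
        cat = _categorical_invcdf(q, m.gate_pass_category_shares)
        records[i] = replace(records[i], seat_distance_cm=dist, hours_in_seat=hrs,
                             gate_pass_category=cat,
                             gate_passes_per_week=_REP_PASS_COUNT[cat])
    user_rows = [i for i, r in enumerate(records) if r.uses_bcu]
    for rank, i in enumerate(user_rows):
        q = (rank + 0.5) / len(user_rows)
        cat = 1 + _categorical_invcdf(q, m.bcu_ops_category_shares)
        records[i] = replace(records[i], bcu_ops_category=cat,
                             bcu_ops_per_week=_REP_OPS_COUNT[cat])
    return records
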