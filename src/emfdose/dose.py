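"""Weekly ("mid-term") exposure indices D1–D3 and cohort summaries.

Each index multiplies an unrounded short-term exposure ratio by a weekly
working-condition factor from the questionnaire:

* ``D1 = E1 x hours in seat per week``      (% RL x h/week)
* ``D2 = E2 x gate-pass category weight``   (% BR x gate pass)
* ``D3 = E3 x BCU-operation category weight`` (% BR x BCU operation)

The gate-pass and BCU-operation answers are ordinal categories; under the
default ``ordinal`` scheme the weight is the category index itself (0–5 for
gate passes, 1–5 for BCU operations).  This is a reconstruction — the
weekly factors are only published as categories — and an alternative
``midpoint`` scheme (representative counts per bin) is available.  Time per
gate pass / per BCU operation is deliberately ignored: the indices count
repetitions, not exposure-seconds.

Also provided: per-pattern summary statistics (median / mean / sample SD /
max / min), histogram binning for index distributions, the Mann-Whitney
U test used to compare patterns, and the discrete population distribution
of an index implied by published marginal shares under independence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .registry import DeviceRegistry
from .short_term import e2_ratio, e3_ratio

__all__ = [
    "ORDINAL_GATE_PASS_WEIGHTS",
    "ORDINAL_BCU_OPS_WEIGHTS",
    "MIDPOINT_GATE_PASS_WEIGHTS",
    "MIDPOINT_BCU_OPS_WEIGHTS",
    "ExposureProfile",
    "d1",
    "d2",
    "d3",
    "summarize_by_pattern",
    "histogram",
    "mann_whitney_u",
    "population_d2_distribution",
    "population_d3_distribution",
    "weighted_quantile",
]

#: default weights: the ordinal category index itself
ORDINAL_GATE_PASS_WEIGHTS = {0: 0.0, 1: 1.0, 2: 2.0, 3: 3.0, 4: 4.0, 5: 5.0}
ORDINAL_BCU_OPS_WEIGHTS = {1: 1.0, 2: 2.0, 3: 3.0, 4: 4.0, 5: 5.0}
#: alternative: representative weekly counts per bin (open top bins use a
#: nominal representative value)
MIDPOINT_GATE_PASS_WEIGHTS = {0: 0.0, 1: 5.5, 2: 15.5, 3: 23.0, 4: 28.0, 5: 35.0}
MIDPOINT_BCU_OPS_WEIGHTS = {1: 10.0, 2: 35.5, 3: 75.5, 4: 200.0, 5: 400.0}

_GATE_SCHEMES = {"ordinal": ORDINAL_GATE_PASS_WEIGHTS, "midpoint": MIDPOINT_GATE_PASS_WEIGHTS}
_BCU_SCHEMES = {"ordinal": ORDINAL_BCU_OPS_WEIGHTS, "midpoint": MIDPOINT_BCU_OPS_WEIGHTS}


@dataclass(frozen=True)
class ExposureProfile:
    """Resolved per-respondent exposures: pattern, E1–E3 and D1–D3.

    ``None`` marks an index that is undefined for the respondent (no such
    source), never a zero exposure.
    """

    respondent_id: str
    pattern: int
    e1_pct_rl: Optional[float] = None
    e2_pct_br: Optional[float] = None
    e3_pct_br: Optional[float] = None
    d1: Optional[float] = None
    d2: Optional[float] = None
    d3: Optional[float] = None
    flags: frozenset[str] = field(default_factory=frozenset)


def d1(e1_pct_rl: float, hours_in_seat: float) -> float:
    """Continuous-exposure index: unrounded E1 times weekly seat hours."""
    if e1_pct_rl < 0 or hours_in_seat < 0:
        raise ValueError("E1 and hours must be non-negative")
    return e1_pct_rl * hours_in_seat


def d2(e2_pct_br: float, gate_pass_category: int, scheme: str = "ordinal") -> float:
    """Gate-pass index: unrounded E2 times the category weight."""
    if e2_pct_br < 0:
        raise ValueError("E2 must be non-negative")
    weights = _GATE_SCHEMES[scheme]
    if gate_pass_category not in weights:
        raise ValueError(f"gate-pass category out of range: {gate_pass_category}")
    return e2_pct_br * weights[gate_pass_category]


def d3(e3_pct_br: float, bcu_ops_category: int, scheme: str = "ordinal") -> float:
    """BCU-operation index: unrounded E3 times the category weight."""
    if e3_pct_br < 0:
        raise ValueError("E3 must be non-negative")
    weights = _BCU_SCHEMES[scheme]
    if bcu_ops_category not in weights:
        raise ValueError(f"BCU-operation category out of range: {bcu_ops_category}")
    return e3_pct_br * weights[bcu_ops_category]


_STATS = ("n", "median", "average", "sd", "max", "min")
_INDEX_COLS = ("e1_pct_rl", "e2_pct_br", "e3_pct_br", "d1", "d2", "d3")


def _column_stats(values: pd.Series) -> dict[str, float]:
    v = values.dropna()
    if v.empty:
        return {s: np.nan for s in _STATS} | {"n": 0}
    return {
        "n": int(v.size),
        "median": float(v.median()),
        "average": float(v.mean()),
        "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0,
        "max": float(v.max()),
        "min": float(v.min()),
    }


def summarize_by_pattern(profiles: Iterable[ExposureProfile]) -> pd.DataFrame:
    """Per-pattern and total summary of E1–E3 and D1–D3.

    Returns a DataFrame indexed by (group, statistic) with one column per
    index; groups are ``pattern_1`` … ``pattern_4`` plus ``total``, the
    total pooling patterns 1–3 (pattern 4 carries no indices).  Statistics
    over a respondent set in which an index is entirely undefined are NaN,
    not zero.  SD is the sample standard deviation (n-1).
    """
    df = pd.DataFrame([vars(p) for p in profiles])
    if df.empty:
        raise ValueError("no profiles to summarize")
    groups: dict[str, pd.DataFrame] = {
        f"pattern_{k}": df[df["pattern"] == k] for k in (1, 2, 3, 4)
    }
    groups["total"] = df[df["pattern"].isin((1, 2, 3))]
    rows = {}
    for name, g in groups.items():
        for stat in _STATS:
            rows[(name, stat)] = {
                col: _column_stats(g[col])[stat] if not g.empty else np.nan
                for col in _INDEX_COLS
            }
    out = pd.DataFrame(rows).T
    out.index.names = ["group", "statistic"]
    return out


def histogram(values: Sequence[float], bin_edges: Sequence[float]) -> np.ndarray:
    """Counts per bin, left-closed right-open, final bin closed."""
    edges = np.asarray(bin_edges, float)
    if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be a strictly increasing 1-D sequence")
    v = np.asarray(values, float)
    if not np.all(np.isfinite(v)):
        raise ValueError("values must be finite")
    counts, _ = np.histogram(v, bins=edges)
    return counts


def mann_whitney_u(group_a: Sequence[float], group_b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test between two exposure groups.

    Returns (U statistic of group A, two-sided p value).  Uses the exact
    null distribution when the smaller group has at most 8 observations and
    there are no ties; otherwise the tie-corrected normal approximation
    with continuity correction.
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(a.size, b.size) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def weighted_quantile(values: Sequence[float], weights: Sequence[float], q: float) -> float:
    """Quantile of a discrete distribution given by (value, probability) pairs."""
    v = np.asarray(values, float)
    w = np.asarray(weights, float)
    if not 0 <= q <= 1:
        raise ValueError("q must lie in [0, 1]")
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be non-negative with positive total")
    order = np.argsort(v)
    v, w = v[order], w[order] / w.sum()
    cum = np.cumsum(w)
    return float(v[np.searchsorted(cum, q)])


def population_d2_distribution(
    registry: DeviceRegistry,
    gate_shares: Optional[dict[str, float]] = None,
    pass_category_shares: Optional[Sequence[float]] = None,
    scheme: str = "ordinal",
) -> tuple[np.ndarray, np.ndarray]:
    """Discrete population distribution of D2 implied by marginal shares.

    Forms the joint distribution of (gate model, gate-pass category) as the
    product of the two marginal share vectors (independence), and assigns
    each cell the D2 value of its unrounded E2 ratio times the category
    weight.  Defaults take both marginals from the registry / survey
    shares.  Returns (values, probabilities).
    """
    from .synthetic import default_marginals

    dm = default_marginals()
    if gate_shares is None:
        gate_shares = {gid: g.share_pct / 100.0 for gid, g in registry.gates.items()}
    if pass_category_shares is None:
        pass_category_shares = dm.gate_pass_category_shares
    weights = _GATE_SCHEMES[scheme]
    vals, probs = [], []
    for gid, p_gate in gate_shares.items():
        e2 = e2_ratio(registry.gates[gid], registry.reference)
        for cat, p_cat in zip(sorted(weights), pass_category_shares):
            vals.append(e2 * weights[cat])
            probs.append(p_gate * p_cat)
    return np.asarray(vals), np.asarray(probs)


def population_d3_distribution(
    registry: DeviceRegistry,
    bcu_shares: Optional[dict[str, float]] = None,
    ops_category_shares: Optional[Sequence[float]] = None,
    scheme: str = "ordinal",
) -> tuple[np.ndarray, np.ndarray]:
    """Discrete population distribution of D3 implied by marginal shares.

    Same construction as :func:`population_d2_distribution`, over
    (BCU model, BCU-operation category)."""
    from .synthetic import default_marginals

    dm = default_marginals()
    if bcu_shares is None:
        bcu_shares = {bid: b.share_pct / 100.0 for bid, b in registry.bcus.items()}
    if ops_category_shares is None:
        ops_category_shares = dm.bcu_ops_category_shares
    weights = _BCU_SCHEMES[scheme]
    vals, probs = [], []
    for bid, p_bcu in bcu_shares.items():
        e3 = e3_ratio(registry.bcus[bid])
        for cat, p_cat in zip(sorted(weights), ops_category_shares):
            vals.append(e3 * weights[cat])
            probs.append(p_bcu * p_cat)
    return np.asarray(vals), np.asarray(probs)
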