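"""Dose indices D1–D3, pattern summaries, histograms and the U test."""

import itertools
import math

import numpy as np
import pytest

from emfdose._format import round_half_up, round_sig
from emfdose.dose import (ExposureProfile, d1, d2, d3, histogram, mann_whitney_u,
                          summarize_by_pattern, weighted_quantile)
from emfdose.short_term import e2_ratio, e3_ratio


def test_d1_is_product_of_ratio_and_hours():
    assert d1(0.186, 8) == pytest.approx(1.488)
    assert d1(14.7, 0) == 0
    assert d1(14.7, 35) == pytest.approx(514.5)  # the cohort-maximum scale
    with pytest.raises(ValueError):
        d1(-0.1, 5)


def test_d2_ordinal_weights(registry):
    e2_gate_ii = e2_ratio(registry.gates["II"], registry.reference)
    e2_gate_i = e2_ratio(registry.gates["I"], registry.reference)
    assert round_half_up(d2(e2_gate_ii, 5)) == 116
    assert round_half_up(d2(e2_gate_i, 4), 1) == 5.4
    assert d2(e2_gate_ii, 0) == 0
    with pytest.raises(ValueError):
        d2(1.0, 6)
    with pytest.raises(ValueError):
        d2(1.0, -1)


def test_d3_ordinal_weights(registry):
    assert round_half_up(d3(e3_ratio(registry.bcus["V"]), 5)) == 24
    assert round_half_up(d3(e3_ratio(registry.bcus["VIII"]), 1)) == 1
    assert round_half_up(d3(e3_ratio(registry.bcus["I"]), 3)) == 10
    with pytest.raises(ValueError):
        d3(1.0, 0)


def test_midpoint_scheme_uses_representative_counts():
    assert d2(2.0, 1, scheme="midpoint") == pytest.approx(2.0 * 5.5)
    assert d3(3.0, 5, scheme="midpoint") == pytest.approx(3.0 * 400.0)


def test_indices_monotone_in_both_factors():
    for cat in range(6):
        assert d2(2.0, cat) <= d2(2.0, min(cat + 1, 5))
        assert d2(1.0, cat) <= d2(2.0, cat)


def make_profile(i, pattern, **kw):
    return ExposureProfile(respondent_id=str(i), pattern=pattern, **kw)


def test_summary_hand_computed_statistics():
    profiles = [make_profile(0, 1, d2=0.0), make_profile(1, 1, d2=10.0)]
    s = summarize_by_pattern(profiles)
    assert s.loc[("pattern_1", "median"), "d2"] == 5
    assert s.loc[("pattern_1", "sd"), "d2"] == pytest.approx(math.sqrt(50), abs=5e-3)
    assert s.loc[("pattern_1", "n"), "d2"] == 2


def test_summary_single_respondent_collapses():
    s = summarize_by_pattern([make_profile(0, 3, e3_pct_br=4.8, d3=9.6)])
    for stat in ("median", "average", "max", "min"):
        assert s.loc[("pattern_3", stat), "d3"] == pytest.approx(9.6)
    assert s.loc[("pattern_3", "sd"), "d3"] == 0.0


def test_summary_total_pools_patterns_1_to_3_only():
    profiles = [make_profile(0, 1, d3=1.0), make_profile(1, 3, d3=3.0),
                make_profile(2, 4), make_profile(3, 2, d2=7.0)]
    s = summarize_by_pattern(profiles)
    assert s.loc[("total", "n"), "d3"] == 2
    assert s.loc[("total", "median"), "d3"] == 2.0
    # pattern 4 carries no indices: absent, not zero
    assert np.isnan(s.loc[("pattern_4", "median"), "d1"])


def test_histogram_binning():
    assert histogram([0, 5, 10], [0, 10, 20]).tolist() == [2, 1]
    assert histogram([1, 2, 3], [0, 10]).tolist() == [3]
    assert histogram([20], [0, 10, 20]).tolist() == [0, 1]  # final bin closed
    with pytest.raises(ValueError):
        histogram([1], [0, 0, 1])


def test_histogram_uniform_multinomial_tolerance():
    rng = np.random.default_rng(5)
    counts = histogram(rng.random(10000), np.linspace(0, 1, 11))
    sigma = math.sqrt(10000 * 0.1 * 0.9)
    assert np.all(np.abs(counts - 1000) < 3 * sigma)


def test_weighted_quantile_discrete():
    assert weighted_quantile([1, 2, 3], [0.25, 0.25, 0.5], 0.5) == 2
    assert weighted_quantile([1, 2, 3], [0.25, 0.25, 0.5], 0.9) == 3


def exact_mwu_p(a, b):
    """Enumeration oracle: exact two-sided p over all group assignments."""
    pooled = sorted(a) + sorted(b)
    n_a, n = len(a), len(a) + len(b)
    ranks = {v: r for r, v in enumerate(sorted(pooled), start=1)}
    u_obs = sum(ranks[v] for v in a) - n_a * (n_a + 1) / 2
    n_b = n - n_a
    lo = min(u_obs, n_a * n_b - u_obs)
    hi = n_a * n_b - lo
    count = total = 0
    for subset in itertools.combinations(range(1, n + 1), n_a):
        u = sum(subset) - n_a * (n_a + 1) / 2
        total += 1
        if u <= lo or u >= hi:
            count += 1
    return count / total


def test_mann_whitney_separated_groups():
    u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
    assert u == 0
    assert p == pytest.approx(0.1)


def test_mann_whitney_identical_groups():
    u, p = mann_whitney_u([1, 2, 9, 10], [3, 4, 7, 8])
    assert u == pytest.approx(4 * 4 / 2)
    assert p > 0.9


def test_mann_whitney_power_on_shifted_normals():
    rng = np.random.default_rng(2)
    _, p = mann_whitney_u(rng.normal(0, 1, 200), rng.normal(1, 1, 200))
    assert p < 0.05


def test_mann_whitney_matches_enumeration_small_layouts():
    rng = np.random.default_rng(8)
    for n_a in range(1, 5):
        for n_b in range(n_a, 5):
            a = rng.permutation(100)[: n_a + n_b].astype(float)
            u, p = mann_whitney_u(a[:n_a], a[n_a:])
            assert p == pytest.approx(exact_mwu_p(a[:n_a].tolist(), a[n_a:].tolist()))


def test_mann_whitney_empty_group_rejected():
    with pytest.raises(ValueError):
        mann_whitney_u([], [1, 2])


def test_rounding_helpers():
    assert round_sig(23.28, 2) == 23
    assert round_sig(0.18630, 2) == 0.19
    assert round_sig(1.3549, 2) == 1.4
    assert round_half_up(0.5) == 1.0
    assert round_half_up(10.45, 1) == 10.5
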