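"""Rate arithmetic, coverage budgets and the statistical tests."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from conjview import (
    compare_groups,
    conjugation_frequency,
    coverage_budget,
    mannwhitney_exact,
    percent_change,
    significance_code,
    transfer_rate,
)


# ---------------------------------------------------------------------------
# rate arithmetic


@pytest.mark.parametrize(
    "length,duration,expected",
    [
        (108_000, 2.9, 620.0),  # F plasmid from the conjugative-focus lifespan
        (4_600_000, 100.0, 770.0),  # whole chromosome in 100 min
        (1000, 1 / 60, 1000.0),  # identity check
    ],
)
def test_transfer_rate_examples(length, duration, expected):
    assert transfer_rate(length, duration).rate_nt_s == expected


def test_transfer_rate_identity_before_rounding():
    r = transfer_rate(123_456, 3.21)
    assert r.rate_raw_nt_s * r.duration_s == pytest.approx(123_456, rel=1e-12)
    with pytest.raises(ValueError):
        transfer_rate(1000, 0)


def test_coverage_budget_insufficient_for_the_full_plasmid():
    b = coverage_budget(1320, 8, 170, 650, 108_000)
    assert b.capacity_nt == pytest.approx((1320 / 8) * 170)  # 28,050 nt
    assert not b.sufficient


def test_coverage_budget_boundary_and_zero():
    need = 108_000 + 650
    monomers = 8 * need // 170 + (0 if (8 * need) % 170 == 0 else 1)
    b = coverage_budget(int(np.ceil(need / 170 * 8)), 8, 170, 650, 108_000)
    assert b.sufficient
    z = coverage_budget(0, 8, 170, 650, 108_000)
    assert z.capacity_nt == 0 and not z.sufficient


@pytest.mark.parametrize(
    "before,after,expected",
    [(10.4, 16.4, 58.0), (10.1, 13.0, 29.0), (5.0, 5.0, 0.0)],
)
def test_percent_change_examples(before, after, expected):
    assert percent_change(before, after) == expected


def test_percent_change_rejects_zero_baseline():
    with pytest.raises(ValueError):
        percent_change(0.0, 5.0)


def test_conjugation_frequency_bounds():
    assert conjugation_frequency(0, 100) == 0.0
    assert conjugation_frequency(100, 0) == 1.0
    with pytest.raises(ValueError):
        conjugation_frequency(0, 0)


@settings(max_examples=50, deadline=None)
@given(st.integers(0, 10_000), st.integers(0, 10_000))
def test_conjugation_frequency_always_a_fraction(t, r):
    if t + r == 0:
        return
    assert 0.0 <= conjugation_frequency(t, r) <= 1.0


def test_plating_simulation_recovers_success_probability():
    """Bernoulli mating with per-pair success 0.9: plating frequency lands
    inside the binomial 95% CI of the configured probability."""
    rng = np.random.default_rng(11)
    n = 2000
    t = int(rng.binomial(n, 0.9))
    freq = conjugation_frequency(t, n - t)
    assert abs(freq - 0.9) < 2 * np.sqrt(0.9 * 0.1 / n)


# ---------------------------------------------------------------------------
# Mann-Whitney


def _mw_enumeration_oracle(x, y):
    """Exhaustive two-sided permutation p-value (independent oracle)."""
    x, y = list(x), list(y)
    n1 = len(x)
    pooled = np.array(x + y, dtype=float)
    ranks = sps.rankdata(pooled)
    mu = n1 * len(y) / 2.0
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    dev = abs(u_obs - mu)
    hits = total = 0
    for idx in combinations(range(len(pooled)), n1):
        u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2.0
        total += 1
        if abs(u - mu) >= dev - 1e-9:
            hits += 1
    return hits / total


def test_minimal_p_for_three_vs_three_separated():
    u, p = mannwhitney_exact([1, 2, 3], [101, 102, 103])
    assert p == pytest.approx(0.1, abs=1e-12)  # 2/20 assignments


def test_identical_groups_not_significant():
    res = compare_groups([1, 2, 3, 4], [1, 2, 3, 4], test="mannwhitney")
    assert res.p_value == pytest.approx(1.0)
    assert res.code == "ns"


def test_exact_mannwhitney_matches_enumeration_for_all_small_sizes():
    """Every group-size combination up to 6 vs 6, with ties present."""
    rng = np.random.default_rng(3)
    for n1 in range(1, 7):
        for n2 in range(1, 7):
            for _ in range(3):
                x = rng.integers(0, 5, n1).astype(float)  # heavy ties
                y = rng.integers(0, 5, n2).astype(float)
                if np.ptp(np.concatenate([x, y])) == 0:
                    continue
                _, p = mannwhitney_exact(x, y)
                assert p == pytest.approx(_mw_enumeration_oracle(x, y), abs=1e-12), (
                    x,
                    y,
                )


def test_exact_mannwhitney_agrees_with_scipy_when_no_ties():
    rng = np.random.default_rng(4)
    for _ in range(10):
        x = rng.normal(0, 1, 6)
        y = rng.normal(0.5, 1, 5)
        _, p = mannwhitney_exact(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert p == pytest.approx(ref.pvalue, abs=1e-12)


def test_lifespan_comparison_is_powered():
    """Donor (2.5 +- 1.1 min, n = 197) vs transconjugant (2.9 +- 1.1 min,
    n = 294) lifespans: the typical replicate reaches p < 1e-3 and nearly
    every replicate is significant at the 5% level."""
    ps = []
    for k in range(40):
        rng = np.random.default_rng(100 + k)
        donors = np.clip(rng.normal(2.5, 1.1, 197), 0.01, None)
        trans = np.clip(rng.normal(2.9, 1.1, 294), 0.01, None)
        ps.append(compare_groups(donors, trans, test="mannwhitney").p_value)
    ps = np.array(ps)
    assert np.median(ps) < 1e-3
    assert (ps < 0.05).mean() >= 0.9


def test_significance_codes():
    assert significance_code(0.2) == "ns"
    assert significance_code(0.03) == "*"
    assert significance_code(0.004) == "**"
    assert significance_code(0.0004) == "***"
    assert significance_code(0.00004) == "****"


def test_anova_dunnett_flags_the_shifted_group():
    rng = np.random.default_rng(5)
    control = rng.normal(10.4, 4.7, 60)
    same = rng.normal(10.4, 4.7, 60)
    shifted = rng.normal(16.4, 9.5, 60)
    res = compare_groups(None, None, test="anova_dunnett", groups=[control, same, shifted])
    p_same, p_shift = res.details["dunnett_p"]
    assert p_shift < 0.01
    assert p_same > 0.05
    with pytest.raises(ValueError):
        compare_groups([1.0], [2.0, 3.0], test="anova_dunnett", groups=[[1.0], [2.0, 3.0]])
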