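"""Nonparametric test wrappers, cross-checked against brute-force oracles."""

import itertools

import numpy as np
import pytest

import xenovocal as xv


# ---------------------------------------------------------------------------
# sign test
# ---------------------------------------------------------------------------

def test_sign_test_symmetric_pairs_give_p_one():
    x = [-2.0, 2.0, -1.0, 1.0, -0.5, 0.5]
    assert xv.sign_test_one_sample(x, 0.0).p == pytest.approx(1.0)


def test_sign_test_all_positive_closed_form():
    res = xv.sign_test_one_sample(np.arange(1, 11, dtype=float), 0.0)
    assert res.p == pytest.approx(2 * 0.5 ** 10)
    assert res.n == 10


def test_sign_test_all_ties_is_undefined():
    with pytest.raises(xv.ValidationError):
        xv.sign_test_one_sample([3.0, 3.0, 3.0], 3.0)


def test_sign_test_holds_level_for_synchronous_lags():
    rng = np.random.default_rng(6)
    ok = 0
    for _ in range(200):
        lags = rng.normal(0.0, 0.3, size=26)  # zero-mean jitter, n = 26
        ok += xv.sign_test_one_sample(lags).p > 0.05
    assert ok >= 180


# ---------------------------------------------------------------------------
# Wilcoxon signed rank
# ---------------------------------------------------------------------------

def _wilcoxon_exact_bruteforce(d):
    """Two-sided exact p by enumerating every sign assignment."""
    d = np.asarray(d, dtype=float)
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    w_obs = ranks[d > 0].sum()
    n = d.size
    ws = []
    for signs in itertools.product([0, 1], repeat=n):
        ws.append(sum(r for s, r in zip(signs, ranks) if s))
    ws = np.asarray(ws, dtype=float)
    p_lo = np.mean(ws <= w_obs)
    p_hi = np.mean(ws >= w_obs)
    return min(1.0, 2.0 * min(p_lo, p_hi))


def test_wilcoxon_exact_matches_bruteforce_enumeration():
    rng = np.random.default_rng(2)
    for _ in range(5):
        d = rng.normal(0.4, 1.0, size=9)
        d = d[d != 0]
        res = xv.wilcoxon_signed_rank(d)
        assert "p_exact" in res.extras
        assert res.extras["p_exact"] == pytest.approx(
            _wilcoxon_exact_bruteforce(d), abs=1e-12)


def test_wilcoxon_exact_and_normal_agree_at_moderate_n():
    rng = np.random.default_rng(8)
    for _ in range(10):
        d = rng.normal(0.3, 1.0, size=15)
        res = xv.wilcoxon_signed_rank(d)
        assert abs(res.extras["p_exact"] - res.extras["p_normal"]) <= 0.02


def test_wilcoxon_identical_pairs_is_degenerate():
    x = np.array([1.0, 2.0, 3.0])
    with pytest.warns(UserWarning):
        res = xv.wilcoxon_signed_rank(x, x)
    assert res.p == 1.0 and res.extras.get("degenerate")


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

def _mannwhitney_exact_bruteforce(x, y):
    """Two-sided exact p by enumerating group-label permutations."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    n1 = x.size

    def u_stat(idx):
        a = pooled[list(idx)]
        b = np.delete(pooled, list(idx))
        return sum((ai > b).sum() + 0.5 * (ai == b).sum() for ai in a)

    u_obs = u_stat(range(n1))
    us = [u_stat(c) for c in itertools.combinations(range(pooled.size), n1)]
    us = np.asarray(us, dtype=float)
    p_lo = np.mean(us <= u_obs)
    p_hi = np.mean(us >= u_obs)
    return min(1.0, 2.0 * min(p_lo, p_hi))


def test_mann_whitney_exact_matches_bruteforce_enumeration():
    rng = np.random.default_rng(3)
    x = rng.normal(0.0, 1.0, size=5)
    y = rng.normal(1.0, 1.0, size=5)
    res = xv.mann_whitney_u(x, y)
    assert res.extras["p_exact"] == pytest.approx(
        _mannwhitney_exact_bruteforce(x, y), abs=1e-12)


def test_mann_whitney_identical_groups():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    res = xv.mann_whitney_u(x, x)
    assert res.statistic == pytest.approx(x.size * x.size / 2.0)
    assert res.p > 0.9
    with pytest.raises(xv.ValidationError):
        xv.mann_whitney_u(x, [])


def test_mann_whitney_two_sided_symmetry():
    rng = np.random.default_rng(11)
    x = rng.normal(0, 1, size=8)
    y = rng.normal(1, 1, size=9)
    assert xv.mann_whitney_u(x, y).p == pytest.approx(
        xv.mann_whitney_u(y, x).p)


# ---------------------------------------------------------------------------
# ANOVA
# ---------------------------------------------------------------------------

def test_anova_identical_groups_give_zero_F():
    g = [1.0, 2.0, 3.0, 4.0]
    res = xv.anova_oneway([g, g, g])
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.df == (2, 9)


def test_anova_validation():
    with pytest.raises(xv.ValidationError):
        xv.anova_oneway([[1.0, 2.0]])
    with pytest.raises(xv.ValidationError):
        xv.anova_oneway([[1.0, 2.0], [3.0]])
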