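import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.multitest import multipletests

from akoselect import (
    bh_select,
    intermediate_pvalues,
    knockoff_statistic,
    quantile_aggregate,
)

# ------------------------------------------------- independent brute-force oracles


def brute_intermediate_pvalues(W):
    p = len(W)
    out = []
    for j in range(p):
        if W[j] > 0:
            count = sum(1 for k in range(p) if W[k] <= -W[j])
            out.append((1 + count) / p)
        else:
            out.append(1.0)
    return np.array(out)


def brute_quantile_aggregate(pi_b, gamma):
    B, p = pi_b.shape
    rank = max(int(np.ceil(gamma * B)), 1)
    out = []
    for j in range(p):
        q = sorted(pi_b[:, j])[rank - 1]
        out.append(min(1.0, q / gamma))
    return np.array(out)


def brute_bh_select(pvals, alpha):
    m = len(pvals)
    order = sorted(pvals)
    k_star = 0
    for k in range(1, m + 1):
        if order[k - 1] <= k * alpha / m:
            k_star = k
    if k_star == 0:
        return np.zeros(m, dtype=bool), 0.0
    thr = order[k_star - 1]
    return np.array([pv <= thr for pv in pvals]), thr


# ---------------------------------------------------------------- W statistic


def test_knockoff_statistic_examples():
    np.testing.assert_allclose(
        knockoff_statistic([0.30, 0.1], [0.10, 0.1]), [0.20, 0.0]
    )
    z = np.array([0.2, 0.05, 0.6])
    np.testing.assert_allclose(knockoff_statistic(z, z), 0.0)


def test_knockoff_statistic_errors():
    with pytest.raises(ValueError, match="length"):
        knockoff_statistic([1.0], [1.0, 2.0])
    with pytest.raises(ValueError, match="finite"):
        knockoff_statistic([np.inf], [0.0])


# ---------------------------------------------------------- intermediate p-values


def test_intermediate_pvalue_hand_examples():
    np.testing.assert_allclose(
        intermediate_pvalues(np.array([3.0, -1.0, 2.0])), [1 / 3, 1.0, 1 / 3]
    )
    np.testing.assert_allclose(
        intermediate_pvalues(np.array([-0.1, -2.0, 0.0])), 1.0
    )
    # boundary tie W_k = -W_j is counted by the closed inequality
    np.testing.assert_allclose(intermediate_pvalues(np.array([5.0, -5.0])), [1.0, 1.0])


def test_intermediate_pvalue_empty_errors():
    with pytest.raises(ValueError, match="non-empty"):
        intermediate_pvalues(np.array([]))


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    st.lists(
        st.floats(-10, 10, allow_nan=False, width=32), min_size=1, max_size=12
    )
)
def test_intermediate_pvalue_matches_brute_force(w):
    W = np.array(w, dtype=float)
    np.testing.assert_allclose(
        intermediate_pvalues(W), brute_intermediate_pvalues(W), atol=1e-12
    )


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.data())
def test_intermediate_pvalue_monotone(data):
    W = np.array(
        data.draw(st.lists(st.floats(-5, 5, allow_nan=False), min_size=2, max_size=10))
    )
    pi = intermediate_pvalues(W)
    pos = np.nonzero(W > 0)[0]
    for a in pos:
        for b in pos:
            if W[a] > W[b]:
                assert pi[a] <= pi[b]


# ------------------------------------------------------------- aggregation


def test_quantile_aggregate_examples():
    np.testing.assert_allclose(
        quantile_aggregate(np.array([[0.1, 0.4, 1.0]]), gamma=0.5),
        [0.2, 0.8, 1.0],
    )  # B = 1 doubles and caps
    np.testing.assert_allclose(
        quantile_aggregate(np.array([[0.1], [0.2], [0.3]]), gamma=0.5), [0.4]
    )
    np.testing.assert_allclose(quantile_aggregate(np.ones((4, 3)), gamma=0.5), 1.0)


def test_quantile_aggregate_invalid_gamma():
    for g in (0.0, 1.0, -0.2):
        with pytest.raises(ValueError, match="gamma"):
            quantile_aggregate(np.ones((2, 2)), gamma=g)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    seed=st.integers(0, 2**20),
    B=st.integers(1, 5),
    p=st.integers(1, 10),
    gamma=st.floats(0.05, 0.95),
)
def test_quantile_aggregate_matches_brute_force(seed, B, p, gamma):
    pi_b = np.random.default_rng(seed).uniform(1e-6, 1.0, size=(B, p))
    np.testing.assert_allclose(
        quantile_aggregate(pi_b, gamma), brute_quantile_aggregate(pi_b, gamma),
        atol=1e-12,
    )


@settings(max_examples=50, deadline=None, derandomize=True)
@given(seed=st.integers(0, 2**20), gamma=st.floats(0.1, 0.9))
def test_quantile_aggregate_monotone_per_coordinate(seed, gamma):
    rng = np.random.default_rng(seed)
    pi = rng.uniform(size=(4, 6))
    bumped = np.minimum(pi + rng.uniform(0, 0.3, size=pi.shape), 1.0)
    assert (quantile_aggregate(bumped, gamma) >= quantile_aggregate(pi, gamma)).all()


# ---------------------------------------------------------------- BH step-up


def test_bh_hand_example():
    mask, thr = bh_select(np.array([0.001, 0.02, 0.8]), alpha=0.05)
    np.testing.assert_array_equal(mask, [True, True, False])
    assert thr == 0.02


def test_bh_nothing_passes():
    mask, thr = bh_select(np.ones(5), alpha=0.05)
    assert not mask.any() and thr == 0.0


def test_bh_boundary_is_inclusive():
    mask, _ = bh_select(np.array([0.05 / 3, 0.9, 0.9]), alpha=0.05)
    assert mask[0]


def test_bh_invalid_inputs():
    with pytest.raises(ValueError, match="alpha"):
        bh_select(np.array([0.5]), alpha=1.5)
    with pytest.raises(ValueError, match="non-empty"):
        bh_select(np.array([]), alpha=0.05)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    seed=st.integers(0, 2**20),
    m=st.integers(1, 10),
    alpha=st.floats(0.01, 0.2),
)
def test_bh_matches_brute_force_and_statsmodels(seed, m, alpha):
    pvals = np.random.default_rng(seed).uniform(size=m)
    mask, thr = bh_select(pvals, alpha)
    brute_mask, brute_thr = brute_bh_select(pvals, alpha)
    np.testing.assert_array_equal(mask, brute_mask)
    assert thr == pytest.approx(brute_thr)
    sm_mask = multipletests(pvals, alpha=alpha, method="fdr_bh")[0]
    np.testing.assert_array_equal(mask, sm_mask)
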