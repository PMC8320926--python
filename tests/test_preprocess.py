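import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from akoselect import (
    MissingnessThresholdFilter,
    SampleKNNImputer,
    UnitVarianceScaler,
    knn_impute,
    standardize,
    t_percent_filter,
)


def _table(values, columns=None):
    values = np.asarray(values, dtype=float)
    columns = columns or [f"m{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, columns=columns)


def _random_missing_table(rng, n=12, p=6, frac=0.3):
    vals = rng.normal(size=(n, p)) + 5
    mask = rng.random((n, p)) < frac
    vals[mask] = np.nan
    return _table(vals)


# ---------------------------------------------------------------- t% rule


def test_t0_is_a_no_op(rng):
    table = _random_missing_table(rng)
    out, report = t_percent_filter(table, 0)
    pd.testing.assert_frame_equal(out, table)
    assert report.dropped_metabolites == []


def test_t100_keeps_only_complete_columns():
    table = _table([[1, 1], [np.nan, 2], [3, 3]], columns=["A", "B"])
    out, report = t_percent_filter(table, 100)
    assert list(out.columns) == ["B"]
    assert report.dropped_metabolites == ["A"]


def test_threshold_counts_use_ceiling():
    """n=10: observed in 6 of 10 survives t=60, observed in 5 does not."""
    vals = np.ones((10, 2))
    vals[6:, 0] = np.nan  # 6 observed
    vals[5:, 1] = np.nan  # 5 observed
    out, _ = t_percent_filter(_table(vals, ["six", "five"]), 60)
    assert list(out.columns) == ["six"]


def test_zero_values_count_as_unobserved():
    vals = np.array([[0.0, 1.0], [2.0, 1.0], [3.0, 1.0]])
    out, _ = t_percent_filter(_table(vals, ["withzero", "full"]), 100)
    assert list(out.columns) == ["full"]


def test_filter_removing_everything_errors():
    table = _table([[np.nan], [np.nan], [1.0]])
    with pytest.raises(ValueError, match="every metabolite"):
        t_percent_filter(table, 100)


@pytest.mark.parametrize("t", (-1, 101))
def test_threshold_out_of_range(t):
    with pytest.raises(ValueError, match=r"\[0, 100\]"):
        t_percent_filter(_table([[1.0]]), t)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    seed=st.integers(0, 2**16),
    t_lo=st.integers(1, 99),
    t_delta=st.integers(1, 50),
)
def test_filter_is_monotone_in_t(seed, t_lo, t_delta):
    """The kept set shrinks (weakly) as t grows."""
    table = _random_missing_table(np.random.default_rng(seed))
    t_hi = min(t_lo + t_delta, 100)
    try:
        lo, _ = t_percent_filter(table, t_lo)
        hi, _ = t_percent_filter(table, t_hi)
    except ValueError:
        return  # filter removed everything; nothing to compare
    assert set(hi.columns) <= set(lo.columns)


# ------------------------------------------------------------ KNN imputation


def brute_force_knn_impute(values: np.ndarray, k: int) -> np.ndarray:
    """Independent re-derivation of sample-space KNN imputation.

    Distance between two samples is the Euclidean distance over co-observed
    coordinates rescaled to the full feature count; a missing entry takes the
    mean of the target metabolite among the k nearest donors that observed
    it, falling back to the metabolite's observed mean.
    """
    values = values.copy()
    n, p = values.shape
    obs = ~np.isnan(values)
    out = values.copy()
    for i in range(n):
        for j in range(p):
            if obs[i, j]:
                continue
            dists = np.full(n, np.inf)
            for r in range(n):
                if r == i:
                    continue
                shared = obs[i] & obs[r]
                if not shared.any():
                    continue
                sq = np.sum((values[i, shared] - values[r, shared]) ** 2)
                dists[r] = np.sqrt(sq * p / shared.sum())
            donors = [r for r in np.argsort(dists, kind="stable")
                      if np.isfinite(dists[r]) and obs[r, j]][:k]
            if donors:
                out[i, j] = values[donors, j].mean()
            else:
                out[i, j] = values[obs[:, j], j].mean()
    return out


def test_impute_is_a_no_op_on_complete_tables(rng):
    table = _table(rng.normal(size=(8, 3)))
    pd.testing.assert_frame_equal(knn_impute(table, k=3), table)


def test_identical_samples_impute_exactly():
    vals = np.array([[1.0, 7.0], [1.0, 7.0], [1.0, np.nan]])
    out = knn_impute(_table(vals), k=2)
    assert out.iloc[2, 1] == 7.0


@pytest.mark.parametrize("seed", range(5))
def test_impute_matches_brute_force_oracle(seed):
    rng = np.random.default_rng(seed)
    vals = rng.normal(size=(6, 4)) * 2 + 10
    miss = rng.choice(24, size=2, replace=False)
    vals.ravel()[miss] = np.nan
    expected = brute_force_knn_impute(vals, k=2)
    out = knn_impute(_table(vals), k=2)
    np.testing.assert_allclose(out.to_numpy(), expected, atol=1e-12)


def test_impute_larger_random_tables_match_oracle(rng):
    vals = rng.normal(size=(15, 6)) + 3
    mask = rng.random((15, 6)) < 0.2
    vals[mask] = np.nan
    expected = brute_force_knn_impute(vals, k=4)
    out = knn_impute(_table(vals), k=4)
    np.testing.assert_allclose(out.to_numpy(), expected, atol=1e-12)


def test_impute_never_alters_observed_entries(rng):
    table = _random_missing_table(rng)
    out = knn_impute(table, k=3)
    obs = table.notna()
    assert (out.to_numpy()[obs] == table.to_numpy()[obs]).all()
    assert not out.isna().to_numpy().any()


@pytest.mark.parametrize("k", (0, 12, 50))
def test_impute_invalid_k_errors(k, rng):
    with pytest.raises(ValueError, match="k must"):
        SampleKNNImputer(k=k).fit(_random_missing_table(rng, n=12))


def test_impute_all_missing_column_errors():
    vals = np.array([[np.nan, 1.0], [np.nan, 2.0], [np.nan, 3.0]])
    with pytest.raises(ValueError, match="no observed values"):
        SampleKNNImputer(k=1).fit(_table(vals))


# ------------------------------------------------------------ standardization


def test_standardize_zero_mean_unit_sd(rng):
    table = _table(rng.normal(loc=4, scale=3, size=(30, 5)))
    out, (means, sds) = standardize(table)
    np.testing.assert_allclose(out.mean(axis=0), 0, atol=1e-12)
    np.testing.assert_allclose(out.std(axis=0, ddof=1), 1, atol=1e-12)
    np.testing.assert_allclose(means, table.mean(axis=0))
    np.testing.assert_allclose(sds, table.std(axis=0, ddof=1))


def test_standardize_drops_constant_columns(rng, caplog):
    vals = rng.normal(size=(10, 3))
    vals[:, 1] = 2.5
    table = _table(vals, ["a", "const", "b"])
    with caplog.at_level("WARNING"):
        out, _ = standardize(table)
    assert list(out.columns) == ["a", "b"]
    assert "constant" in caplog.text


def test_standardize_is_idempotent(rng):
    table = _table(rng.normal(size=(20, 4)))
    once, _ = standardize(table)
    twice, _ = standardize(once)
    np.testing.assert_allclose(once.to_numpy(), twice.to_numpy(), atol=1e-12)


def test_standardize_rejects_missing_values(rng):
    with pytest.raises(ValueError, match="impute first"):
        standardize(_random_missing_table(rng))


def test_full_chain_on_complete_data_equals_filter_then_standardize(rng):
    """On complete tables imputation is a no-op inside the chain."""
    table = _table(rng.normal(size=(20, 6)) + 8)
    filtered, _ = t_percent_filter(table, 70)
    with_impute, _ = standardize(knn_impute(filtered, k=5))
    without, _ = standardize(filtered)
    pd.testing.assert_frame_equal(with_impute, without)


def test_transformers_compose_in_sklearn_pipeline(rng):
    from sklearn.pipeline import Pipeline

    table = _random_missing_table(rng, n=20, p=8, frac=0.1)
    pipe = Pipeline(
        [
            ("filter", MissingnessThresholdFilter(t=60)),
            ("impute", SampleKNNImputer(k=4)),
            ("scale", UnitVarianceScaler()),
        ]
    )
    out = pipe.fit_transform(table)
    assert not np.isnan(np.asarray(out)).any()
    np.testing.assert_allclose(np.asarray(out).mean(axis=0), 0, atol=1e-10)
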