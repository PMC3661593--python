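"""Contingency, similarity and permutation statistics, checked against
hand computations and independent enumeration oracles."""

import itertools
import math

import numpy as np
import pytest

from pollinet.errors import (
    AlignmentError,
    DegenerateTableError,
    InsufficientReplicationError,
    UndefinedMetricError,
)
from pollinet.stats import (
    ContingencyTable,
    DistanceMatrix,
    bray_curtis_similarity,
    mantel_test,
    pearson_chi_squared,
    permutation_context_compare,
)


def _table(counts):
    counts = np.asarray(counts)
    return ContingencyTable(
        row_labels=tuple(f"r{i}" for i in range(counts.shape[0])),
        col_labels=tuple(f"c{j}" for j in range(counts.shape[1])),
        counts=counts,
    )


def _dist(values, labels=None):
    values = np.asarray(values, dtype=float)
    labels = labels or tuple(f"s{i}" for i in range(values.shape[0]))
    return DistanceMatrix(labels=tuple(labels), values=values)


def _random_dist(rng, n):
    coords = rng.random((n, 2)) * 100
    d = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
    return _dist(d)


# ---- chi-squared

def test_perfect_homogeneity_gives_zero_statistic():
    res = pearson_chi_squared(_table([[10, 10], [10, 10]]))
    assert res.statistic == pytest.approx(0.0)
    assert res.df == 1
    assert res.p_value == pytest.approx(1.0)


def test_diagonal_table_hand_computation():
    # E = 5 everywhere, sum (O-E)^2/E = 4 * 25/5 = 20
    res = pearson_chi_squared(_table([[10, 0], [0, 10]]))
    assert res.statistic == pytest.approx(20.0)
    assert res.df == 1


def test_five_by_four_table_has_df_12(rng):
    counts = rng.integers(1, 50, size=(5, 4))
    assert pearson_chi_squared(_table(counts)).df == 12


def test_zero_marginal_is_degenerate():
    with pytest.raises(DegenerateTableError):
        pearson_chi_squared(_table([[10, 0], [10, 0]]))


def test_chi_squared_type_one_error_calibrated(rng):
    """Under a true null with large expected counts, rejection at alpha=0.05
    occurs in about 5% of replicates."""
    probs = np.array([0.3, 0.25, 0.2, 0.15, 0.1])
    reps = 500
    rejections = 0
    for _ in range(reps):
        cols = [rng.multinomial(400, probs) for _ in range(4)]
        table = _table(np.stack(cols, axis=1))
        if pearson_chi_squared(table).p_value < 0.05:
            rejections += 1
    assert rejections / reps == pytest.approx(0.05, abs=0.03)


# ---- Bray-Curtis

@pytest.mark.parametrize(
    "u, v, expected",
    [
        ((3, 1, 2), (3, 1, 2), 1.0),
        ((5, 0, 0), (0, 2, 3), 0.0),
        ((1, 2), (2, 2), 6 / 7),
    ],
)
def test_bray_curtis_examples(u, v, expected):
    assert bray_curtis_similarity(u, v) == pytest.approx(expected)


def test_bray_curtis_symmetric_and_permutation_invariant(rng):
    u = rng.integers(0, 20, size=6)
    v = rng.integers(0, 20, size=6)
    v[0] += 1  # avoid the all-zero corner case
    s = bray_curtis_similarity(u, v)
    assert bray_curtis_similarity(v, u) == pytest.approx(s)
    perm = rng.permutation(6)
    assert bray_curtis_similarity(u[perm], v[perm]) == pytest.approx(s)


def test_bray_curtis_all_zero_pair_undefined():
    with pytest.raises(UndefinedMetricError):
        bray_curtis_similarity((0, 0), (0, 0))


# ---- Mantel

def test_identical_matrices_give_r_one_and_minimum_p(rng):
    d = _random_dist(rng, 6)
    res = mantel_test(d, d, n_perm=99, seed=11)
    assert res.statistic == pytest.approx(1.0)
    assert res.p_value == pytest.approx(1 / 100)


def test_mantel_exhaustive_matches_independent_enumeration(rng):
    """Oracle: plain-loop enumeration of all 4! joint relabellings using
    np.corrcoef, written independently of the implementation."""
    d1 = _random_dist(rng, 4)
    d2 = _random_dist(rng, 4)
    res = mantel_test(d1, d2, exhaustive=True)

    iu = np.triu_indices(4, k=1)
    x = d1.values[iu]
    r_obs = np.corrcoef(x, d2.values[iu])[0, 1]
    count = 0
    for perm in itertools.permutations(range(4)):
        permuted = d2.values[np.ix_(perm, perm)]
        r = np.corrcoef(x, permuted[iu])[0, 1]
        if abs(r) >= abs(r_obs) - 1e-12:
            count += 1
    assert res.p_value == pytest.approx(count / math.factorial(4))
    assert res.statistic == pytest.approx(r_obs)


def test_mantel_reproducible_under_seed(rng):
    d1 = _random_dist(rng, 7)
    d2 = _random_dist(rng, 7)
    r1 = mantel_test(d1, d2, n_perm=199, seed=5)
    r2 = mantel_test(d1, d2, n_perm=199, seed=5)
    assert r1 == r2


def test_mantel_label_mismatch_raises():
    d1 = _dist(np.zeros((3, 3)), labels=("a", "b", "c"))
    d2 = _dist(np.zeros((3, 3)), labels=("a", "b", "x"))
    with pytest.raises(AlignmentError):
        mantel_test(d1, d2)


def test_mantel_constant_triangle_undefined():
    ones = np.ones((4, 4)) - np.eye(4)
    with pytest.raises(UndefinedMetricError):
        mantel_test(_dist(ones), _dist(ones))


def test_mantel_p_roughly_uniform_under_null(rng):
    """Independent random matrices: the permutation p-value should be close
    to uniform on its support (mean about 0.5)."""
    ps = []
    for _ in range(300):
        d1 = _random_dist(rng, 5)
        d2 = _random_dist(rng, 5)
        ps.append(mantel_test(d1, d2, n_perm=49, seed=int(rng.integers(2**31))).p_value)
    assert np.mean(ps) == pytest.approx(0.5, abs=0.07)
    assert (np.array(ps) < 0.1).mean() == pytest.approx(0.1, abs=0.06)


# ---- permutation context comparison

def test_constant_data_gives_p_one():
    values = {f"u{i}": 3.0 for i in range(8)}
    contexts = {f"u{i}": ("urban" if i % 2 else "rural") for i in range(8)}
    results = permutation_context_compare(values, contexts, n_perm=200, seed=1)
    assert all(r.p_value == pytest.approx(1.0) for r in results.values())


def test_separated_groups_reach_exhaustive_minimum():
    """Non-overlapping 3+3 values: only the observed assignment and its
    mirror reach |obs|, so the exact two-sided p is 2 / C(6,3) = 0.1."""
    values = {"a1": 1.0, "a2": 2.0, "a3": 3.0, "b1": 10.0, "b2": 11.0, "b3": 12.0}
    contexts = {k: ("low" if k.startswith("a") else "high") for k in values}
    results = permutation_context_compare(values, contexts, exhaustive=True)
    res = results[("high", "low")]
    assert res.p_value == pytest.approx(2 / 20)
    assert res.n_permutations == 20


def test_insufficient_replication_raises():
    values = {"a": 1.0, "b": 2.0, "c": 3.0}
    contexts = {"a": "x", "b": "x", "c": "y"}
    with pytest.raises(InsufficientReplicationError):
        permutation_context_compare(values, contexts)


def test_built_in_urbanisation_effect_is_detected(default_study, default_webs):
    """Per-web total interactions, semi-natural vs urban: the generator's
    built-in rate contrast should be detected at p < 0.05."""
    values = {}
    contexts = {}
    for w in default_webs:
        ctx = w.provenance.landscape_context
        if ctx in ("semi-natural", "urban"):
            key = f"{w.provenance.site_id}:{w.provenance.spatial_config}"
            values[key] = float(w.total())
            contexts[key] = ctx
    results = permutation_context_compare(values, contexts, exhaustive=True)
    assert results[("semi-natural", "urban")].p_value < 0.05
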