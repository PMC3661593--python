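"""In-scope statistics: Pearson chi-squared homogeneity tests, Bray-Curtis
similarity, a Mantel permutation test for spatial autocorrelation, and a
permutation comparison of per-web metrics across landscape contexts.

Permutation conventions (documented because the field is sloppy about them):

- Mantel: Pearson correlation (Spearman available) of the upper triangles,
  two-sided on |r|, rows and columns of the second matrix permuted jointly;
  sampled p uses the add-one convention p = (1 + exceedances) / (1 + n_perm),
  exhaustive p enumerates all n! relabellings (identity included).
- Context comparison: two-sided permutation test on the difference of group
  means under random relabelling, same add-one convention when sampling and
  exact enumeration of the C(n, n1) assignments when exhaustive. It is a
  deliberately assumption-free surrogate for mixed-model contrasts and is
  labelled as such in every report.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.spatial.distance import braycurtis, pdist, squareform

from .errors import (
    AlignmentError,
    DegenerateTableError,
    InsufficientReplicationError,
    UndefinedMetricError,
    ValidationError,
)
from .records import SiteMetadata

_EPS = 1e-12  # tolerance when comparing permuted statistics to the observed one


@dataclass(frozen=True)
class TestResult:
    """Outcome of one statistical test."""

    statistic: float
    df: int | None
    p_value: float
    n_permutations: int | None = None
    seed: int | None = None


@dataclass(frozen=True)
class ContingencyTable:
    """Counts cross-classified by plant (rows) and landscape context
    (columns), for visit-distribution homogeneity tests."""

    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("counts shape does not match labels")
        if np.any(counts < 0):
            raise ValueError("contingency counts must be non-negative")
        object.__setattr__(self, "counts", counts)


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric non-negative matrix with zero diagonal over labelled sites."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if values.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(values, values.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(values), 0.0):
            raise ValueError("distance matrix must have zero diagonal")
        if np.any(values < 0):
            raise ValueError("distances must be non-negative")
        object.__setattr__(self, "values", values)

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(len(self.labels), k=1)
        return self.values[iu]


def pearson_chi_squared(table: ContingencyTable) -> TestResult:
    """Pearson chi-squared test of homogeneity on a contingency table.

    Expected counts come from the marginal products over the grand total;
    df = (rows - 1)(cols - 1); the p-value is the asymptotic chi-squared
    upper tail with no continuity correction.
    """
    counts = table.counts
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        raise DegenerateTableError("contingency table has a zero marginal")
    statistic, p, dof, _ = sps.chi2_contingency(counts, correction=False)
    return TestResult(statistic=float(statistic), df=int(dof), p_value=max(float(p), np.finfo(float).tiny))


def bray_curtis_similarity(u: Sequence[float], v: Sequence[float]) -> float:
    """Bray-Curtis similarity 1 - sum|u-v| / sum(u+v) on raw count vectors."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValidationError("vectors must have equal length")
    if np.any(u < 0) or np.any(v < 0):
        raise ValidationError("counts must be non-negative")
    if u.sum() + v.sum() == 0:
        raise UndefinedMetricError("Bray-Curtis undefined for two all-zero vectors")
    return float(1.0 - braycurtis(u, v))


def geographic_distances(sites: Sequence[SiteMetadata]) -> DistanceMatrix:
    """Pairwise Euclidean distances (metres) between site coordinates."""
    coords = np.array([[s.x, s.y] for s in sites], dtype=float)
    return DistanceMatrix(
        labels=tuple(s.site_id for s in sites),
        values=squareform(pdist(coords, metric="euclidean")),
    )


def bray_curtis_distances(count_table: pd.DataFrame) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity (1 - similarity) between the rows
    of a site x morphotype count table."""
    values = squareform(pdist(count_table.to_numpy(dtype=float), metric="braycurtis"))
    return DistanceMatrix(labels=tuple(str(i) for i in count_table.index), values=values)


def _triangle_correlation(x: np.ndarray, y: np.ndarray, method: str) -> float:
    if method == "pearson":
        return float(sps.pearsonr(x, y).statistic)
    if method == "spearman":
        return float(sps.spearmanr(x, y).statistic)
    raise ValueError(f"unknown correlation method {method!r}")


def mantel_test(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_perm: int = 999,
    seed: int | None = None,
    method: str = "pearson",
    exhaustive: bool = False,
) -> TestResult:
    """Mantel permutation test of association between two distance matrices.

    The statistic is the correlation of the upper triangles; significance is
    assessed two-sided on |r| by jointly permuting the rows and columns of
    ``d2``. With ``exhaustive=True`` all n! relabellings are enumerated
    (feasible for a handful of sites) and the p-value is exact; otherwise
    ``n_perm`` random permutations are drawn with the add-one convention.
    """
    if set(d1.labels) != set(d2.labels):
        raise AlignmentError("distance matrices have different site labels")
    # align d2 to d1's label order
    order = [d2.labels.index(lab) for lab in d1.labels]
    m2 = d2.values[np.ix_(order, order)]
    n = len(d1.labels)
    iu = np.triu_indices(n, k=1)
    x = d1.values[iu]
    y = m2[iu]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedMetricError("constant upper triangle; correlation undefined")
    r_obs = _triangle_correlation(x, y, method)

    if exhaustive:
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            yp = m2[np.ix_(perm, perm)][iu]
            if np.ptp(yp) == 0:
                continue
            total += 1
            if abs(_triangle_correlation(x, yp, method)) >= abs(r_obs) - _EPS:
                count += 1
        return TestResult(
            statistic=r_obs, df=None, p_value=count / total,
            n_permutations=total, seed=None,
        )

    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        yp = m2[np.ix_(perm, perm)][iu]
        if np.ptp(yp) == 0:
            continue
        if abs(_triangle_correlation(x, yp, method)) >= abs(r_obs) - _EPS:
            count += 1
    return TestResult(
        statistic=r_obs,
        df=None,
        p_value=(1 + count) / (1 + n_perm),
        n_permutations=n_perm,
        seed=seed,
    )


def permutation_context_compare(
    values: Mapping[str, float],
    contexts: Mapping[str, str],
    n_perm: int = 9999,
    seed: int | None = None,
    exhaustive: bool = False,
) -> dict[tuple[str, str], TestResult]:
    """Pairwise two-sided permutation tests on context mean differences.

    For each unordered pair of landscape contexts, tests whether the mean of
    ``values`` differs between the two groups by permuting group labels.
    A permutation surrogate for model-based contrasts — not a mixed-model
    p-value.

    Raises InsufficientReplicationError if any context has < 2 values, and
    ValidationError with fewer than two contexts.
    """
    by_ctx: dict[str, list[float]] = {}
    for unit, value in values.items():
        try:
            ctx = contexts[unit]
        except KeyError:
            raise AlignmentError(f"no context label for unit {unit!r}") from None
        by_ctx.setdefault(ctx, []).append(float(value))
    if len(by_ctx) < 2:
        raise ValidationError("need at least two contexts to compare")
    for ctx, vals in by_ctx.items():
        if len(vals) < 2:
            raise InsufficientReplicationError(
                f"context {ctx!r} has {len(vals)} value(s); need >= 2"
            )

    rng = np.random.default_rng(seed)
    results: dict[tuple[str, str], TestResult] = {}
    for c1, c2 in itertools.combinations(sorted(by_ctx), 2):
        a = np.array(by_ctx[c1])
        b = np.array(by_ctx[c2])
        pooled = np.concatenate([a, b])
        n1 = len(a)
        obs = a.mean() - b.mean()
        if exhaustive:
            total = math.comb(len(pooled), n1)
            count = 0
            idx_all = set(range(len(pooled)))
            for idx in itertools.combinations(range(len(pooled)), n1):
                sel = np.array(idx)
                rest = np.array(sorted(idx_all - set(idx)))
                diff = pooled[sel].mean() - pooled[rest].mean()
                if abs(diff) >= abs(obs) - _EPS:
                    count += 1
            p = count / total
            n_used = total
        else:
            count = 0
            for _ in range(n_perm):
                perm = rng.permutation(pooled)
                diff = perm[:n1].mean() - perm[n1:].mean()
                if abs(diff) >= abs(obs) - _EPS:
                    count += 1
            p = (1 + count) / (1 + n_perm)
            n_used = n_perm
        results[(c1, c2)] = TestResult(
            statistic=float(obs), df=None, p_value=float(p),
            n_permutations=n_used, seed=seed,
        )
    return results
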