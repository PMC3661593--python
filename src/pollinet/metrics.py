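"""Network- and morphotype-level indices on a quantitative web.

All Shannon quantities use the natural logarithm. Zero cells never enter a
Shannon sum (the 0*ln 0 := 0 convention falls out of restricting sums to
realised links), which is exactly how interaction evenness is defined here:
the Shannon diversity of edge weights over realised links only, normalised
by ln(link count) so a perfectly uniform web scores 1.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import UndefinedMetricError
from .matrices import InteractionMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NetworkSummary:
    """Whole-web descriptors."""

    total_interactions: int
    link_count: int
    interaction_evenness: float | None


@dataclass(frozen=True)
class VisitProfile:
    """A morphotype's visit-count vector over plants and its normalisation.

    ``P`` is the empirical probability that one visit of this morphotype
    lands on each plant (counts / V); undefined (None) when V = 0.
    """

    morphotype: str
    plants: tuple[str, ...]
    counts_by_plant: np.ndarray
    V: int
    P: np.ndarray | None


@dataclass(frozen=True)
class GeneralismProfile:
    """Qualitative degree and weighted (Shannon, nats) generalism."""

    morphotype: str
    degree: int
    weighted: float


def total_interactions(matrix: InteractionMatrix) -> int:
    """Grand total of the web: sum of all cell counts."""
    return matrix.total()


def link_count(matrix: InteractionMatrix) -> int:
    """Number of realised links (cells with at least one visit)."""
    return int(np.count_nonzero(matrix.counts))


def interaction_evenness(matrix: InteractionMatrix) -> float:
    """Shannon evenness of edge weights over realised links.

    With p_ij = A_ij / total over the L nonzero cells, returns
    H / ln(L) where H = -sum p_ij ln p_ij. Equals 1 iff all realised links
    carry the same weight.

    Raises
    ------
    UndefinedMetricError
        If the web has fewer than two realised links (ln L normaliser is 0).
    """
    L = link_count(matrix)
    if L < 2:
        raise UndefinedMetricError(
            f"interaction evenness undefined for {L} realised link(s)"
        )
    weights = matrix.counts[matrix.counts > 0].astype(float)
    p = weights / weights.sum()
    H = float(-(p * np.log(p)).sum())
    return H / math.log(L)


def visit_distribution(matrix: InteractionMatrix, morphotype: str) -> VisitProfile:
    """The morphotype's visit counts over plants and the normalised P vector.

    A morphotype with zero visits yields a flagged profile (V = 0, P = None)
    rather than an error, so sparse webs remain summarisable.
    """
    counts = matrix.column(morphotype)
    V = int(counts.sum())
    P = counts / V if V > 0 else None
    return VisitProfile(
        morphotype=morphotype,
        plants=tuple(matrix.plant_labels),
        counts_by_plant=counts.copy(),
        V=V,
        P=P,
    )


def qualitative_generalism(matrix: InteractionMatrix, morphotype: str) -> int:
    """Degree: the number of plant species the morphotype visits at all."""
    counts = matrix.column(morphotype)
    if counts.sum() == 0:
        raise UndefinedMetricError(
            f"generalism undefined for unobserved morphotype {morphotype!r}"
        )
    return int(np.count_nonzero(counts))


def weighted_generalism(matrix: InteractionMatrix, morphotype: str) -> float:
    """Shannon index (nats) of the morphotype's visit distribution over
    plants: 0 for a perfect specialist, ln k for k equally-visited plants."""
    profile = visit_distribution(matrix, morphotype)
    if profile.P is None:
        raise UndefinedMetricError(
            f"generalism undefined for unobserved morphotype {morphotype!r}"
        )
    p = profile.P[profile.P > 0]
    return float(-(p * np.log(p)).sum())


def network_summary(matrix: InteractionMatrix) -> NetworkSummary:
    """Totals, link count and evenness; evenness is None when undefined."""
    L = link_count(matrix)
    evenness = interaction_evenness(matrix) if L >= 2 else None
    return NetworkSummary(
        total_interactions=total_interactions(matrix),
        link_count=L,
        interaction_evenness=evenness,
    )


def generalism_profiles(matrix: InteractionMatrix) -> list[GeneralismProfile]:
    """Per-morphotype generalism for every observed morphotype; unobserved
    morphotypes are excluded and logged."""
    profiles: list[GeneralismProfile] = []
    for m in matrix.morphotype_labels:
        if matrix.column(m).sum() == 0:
            logger.warning(
                "morphotype %r has zero visits in web %s/%s; excluded from generalism",
                m,
                matrix.provenance.site_id,
                matrix.provenance.spatial_config,
            )
            continue
        profiles.append(
            GeneralismProfile(
                morphotype=m,
                degree=qualitative_generalism(matrix, m),
                weighted=weighted_generalism(matrix, m),
            )
        )
    return profiles


def metrics_table(webs: list[InteractionMatrix]) -> pd.DataFrame:
    """Long-format per-web metric report: one row per (web, metric)."""
    rows = []
    for w in webs:
        prov = w.provenance
        base = {
            "site_id": prov.site_id,
            "spatial_config": prov.spatial_config,
            "landscape_context": prov.landscape_context,
        }
        summary = network_summary(w)
        rows.append(
            base | {"metric": "total_interactions", "subject": "network",
                    "value": float(summary.total_interactions)}
        )
        rows.append(
            base | {"metric": "link_count", "subject": "network",
                    "value": float(summary.link_count)}
        )
        if summary.interaction_evenness is not None:
            rows.append(
                base | {"metric": "interaction_evenness", "subject": "network",
                        "value": summary.interaction_evenness}
            )
        for g in generalism_profiles(w):
            rows.append(
                base | {"metric": "degree", "subject": g.morphotype,
                        "value": float(g.degree)}
            )
            rows.append(
                base | {"metric": "weighted_generalism", "subject": g.morphotype,
                        "value": g.weighted}
            )
    return pd.DataFrame(
        rows,
        columns=["site_id", "spatial_config", "landscape_context",
                 "metric", "subject", "value"],
    )
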