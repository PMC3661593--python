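"""Quantitative bipartite interaction matrices.

A web is an n-plants x m-morphotypes matrix A whose entry A[i, j] counts the
visits of morphotype j on plant i, cumulated over all observation rounds and
over the two plots sharing one spatial configuration within a site. A full
study of 12 sites x 2 configurations therefore yields 24 webs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import EmptySelectionError
from .records import (
    MORPHOTYPES,
    PLANTS,
    SPATIAL_CONFIGS,
    SiteMetadata,
    VisitationRecord,
    canonical_order,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Provenance:
    """Where a web came from: site, plot configuration, rounds cumulated."""

    site_id: str
    spatial_config: str
    rounds: tuple[int, ...] = ()
    landscape_context: str | None = None


@dataclass
class InteractionMatrix:
    """A labelled non-negative integer count matrix with provenance."""

    plant_labels: list[str]
    morphotype_labels: list[str]
    counts: np.ndarray
    provenance: Provenance = field(
        default_factory=lambda: Provenance(site_id="", spatial_config="systematic")
    )

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.plant_labels), len(self.morphotype_labels)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match labels "
                f"({len(self.plant_labels)} plants, {len(self.morphotype_labels)} morphotypes)"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                raise ValueError("counts must be integral")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        self.counts = self.counts.astype(np.int64)

    def total(self) -> int:
        return int(self.counts.sum())

    def plant_index(self, plant: str) -> int:
        try:
            return self.plant_labels.index(plant)
        except ValueError:
            raise KeyError(f"plant {plant!r} not in matrix") from None

    def morphotype_index(self, morphotype: str) -> int:
        try:
            return self.morphotype_labels.index(morphotype)
        except ValueError:
            raise KeyError(f"morphotype {morphotype!r} not in matrix") from None

    def column(self, morphotype: str) -> np.ndarray:
        return self.counts[:, self.morphotype_index(morphotype)]

    def row(self, plant: str) -> np.ndarray:
        return self.counts[self.plant_index(plant), :]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, InteractionMatrix):
            return NotImplemented
        return (
            self.plant_labels == other.plant_labels
            and self.morphotype_labels == other.morphotype_labels
            and np.array_equal(self.counts, other.counts)
            and self.provenance == other.provenance
        )


def build_interaction_matrix(
    records: Iterable[VisitationRecord],
    site_id: str,
    spatial_config: str,
) -> InteractionMatrix:
    """Cumulate the records of one (site, spatial configuration) into a web.

    Counts are summed over all observation rounds and over both plots of the
    configuration, so the matrix total equals the sum of the selected visit
    counts (conservation under cumulation).

    Raises
    ------
    EmptySelectionError
        If no record matches the selector. An all-zero selection (records
        present but every count zero) is a valid web, not an error.
    """
    selected = [
        r
        for r in records
        if r.site_id == site_id and r.spatial_config == spatial_config
    ]
    if not selected:
        raise EmptySelectionError(
            f"no visitation records for site {site_id!r}, configuration {spatial_config!r}"
        )
    plants = canonical_order((r.plant_species for r in selected), PLANTS)
    morphs = canonical_order((r.insect_morphotype for r in selected), MORPHOTYPES)
    p_idx = {p: i for i, p in enumerate(plants)}
    m_idx = {m: j for j, m in enumerate(morphs)}
    counts = np.zeros((len(plants), len(morphs)), dtype=np.int64)
    rounds: set[int] = set()
    contexts: set[str] = set()
    for r in selected:
        counts[p_idx[r.plant_species], m_idx[r.insect_morphotype]] += r.visit_count
        rounds.add(r.round_index)
        contexts.add(r.landscape_context)
    context = contexts.pop() if len(contexts) == 1 else None
    return InteractionMatrix(
        plant_labels=plants,
        morphotype_labels=morphs,
        counts=counts,
        provenance=Provenance(
            site_id=site_id,
            spatial_config=spatial_config,
            rounds=tuple(sorted(rounds)),
            landscape_context=context,
        ),
    )


def build_all_networks(
    records: Sequence[VisitationRecord],
    sites: Sequence[SiteMetadata] | None = None,
) -> list[InteractionMatrix]:
    """Build one cumulated web per (site, spatial configuration) pair present
    in the records — 24 webs for the full 12-site, two-configuration design.

    Pair order is deterministic: sites in metadata order when given (sorted
    by site id otherwise), configurations in canonical order. Site/config
    combinations absent from the records yield no matrix and are logged.
    """
    present = {(r.site_id, r.spatial_config) for r in records}
    if sites is not None:
        site_order = [s.site_id for s in sites]
        extra = sorted({sid for sid, _ in present} - set(site_order))
        site_order += extra
    else:
        site_order = sorted({sid for sid, _ in present})
    webs: list[InteractionMatrix] = []
    for sid in site_order:
        for config in SPATIAL_CONFIGS:
            if (sid, config) in present:
                webs.append(build_interaction_matrix(records, sid, config))
            else:
                logger.info("no records for site %r, configuration %r", sid, config)
    return webs
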