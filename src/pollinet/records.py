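"""Domain types and canonical label sets for visitation data.

The study system is an experimental plant community of five species exposed
to flower-visiting insects binned into nine morphological functional groups
("morphotypes"), observed at twelve sites spanning a four-level urbanisation
gradient. A visitation record is the aggregated visit count for one
(site, round, plot, plant, morphotype) cell of the observation design — the
granularity at which every downstream formula operates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

logger = logging.getLogger(__name__)

#: Four-level urbanisation gradient, from least to most urbanised.
LANDSCAPE_CONTEXTS: tuple[str, ...] = (
    "semi-natural",
    "agricultural",
    "suburban",
    "urban",
)

#: The two within-site plot layouts of the experimental design.
SPATIAL_CONFIGS: tuple[str, ...] = ("systematic", "random")

#: Canonical plant order: the three tubular-flowered species first, then the
#: two open-flowered species.
PLANTS: tuple[str, ...] = (
    "Medicago sativa",
    "Consolida regalis",
    "Lotus corniculatus",
    "Matricaria inodora",
    "Sinapis arvensis",
)

#: Canonical morphotype order.
MORPHOTYPES: tuple[str, ...] = (
    "solitary bees",
    "Apis mellifera",
    "bumblebees",
    "Coleoptera",
    "Lepidoptera",
    "Syrphidae",
    "other flies",
    "bugs",
    "other Hymenoptera",
)

#: Floral functional groups: tubular corollas conceal nectar from
#: short-mouthpart visitors; open corollas are accessible to all.
TUBULAR_PLANTS: frozenset[str] = frozenset(
    {"Medicago sativa", "Consolida regalis", "Lotus corniculatus"}
)
OPEN_PLANTS: frozenset[str] = frozenset({"Matricaria inodora", "Sinapis arvensis"})

FUNCTIONAL_GROUPS: tuple[str, ...] = ("open", "tubular")


@dataclass(frozen=True)
class VisitationRecord:
    """One cell of the observation design: who visited what, where, when,
    how often.

    ``visit_count`` is the number of visits observed in one 10-minute
    session, aggregated per plant species and morphotype.
    ``flowering_quality`` is an optional 0-6 indicator of how many plants of
    the species were in flower; it is carried through but never enters any
    computation.
    """

    site_id: str
    landscape_context: str
    round_index: int
    plot_id: str
    spatial_config: str
    plant_species: str
    insect_morphotype: str
    visit_count: int
    flowering_quality: int | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.visit_count, (int,)) or isinstance(self.visit_count, bool):
            raise ValueError(f"visit_count must be an integer, got {self.visit_count!r}")
        if self.visit_count < 0:
            raise ValueError(f"visit_count must be non-negative, got {self.visit_count}")
        if self.round_index < 1:
            raise ValueError(f"round_index must be >= 1, got {self.round_index}")
        if self.spatial_config not in SPATIAL_CONFIGS:
            raise ValueError(
                f"spatial_config must be one of {SPATIAL_CONFIGS}, got {self.spatial_config!r}"
            )
        if self.flowering_quality is not None and not (0 <= self.flowering_quality <= 6):
            raise ValueError(
                f"flowering_quality must be in [0, 6], got {self.flowering_quality}"
            )


@dataclass(frozen=True)
class SiteMetadata:
    """An observation site: its urbanisation context and planar coordinates
    in metres (used for pairwise geographic distances)."""

    site_id: str
    landscape_context: str
    x: float
    y: float


class FunctionalGroupMap:
    """Mapping of plant species to floral functional group (open / tubular)."""

    def __init__(self, mapping: Mapping[str, str]):
        for plant, group in mapping.items():
            if group not in FUNCTIONAL_GROUPS:
                raise ValueError(f"unknown functional group {group!r} for {plant!r}")
        self._mapping = dict(mapping)

    def group_of(self, plant: str) -> str:
        from .errors import ConfigurationError

        try:
            return self._mapping[plant]
        except KeyError:
            raise ConfigurationError(f"plant {plant!r} has no functional group") from None

    def members(self, group: str) -> tuple[str, ...]:
        return tuple(p for p, g in self._mapping.items() if g == group)

    def __contains__(self, plant: str) -> bool:
        return plant in self._mapping

    def items(self):
        return self._mapping.items()


#: The experimental community's assignment.
DEFAULT_FUNCTIONAL_GROUPS = FunctionalGroupMap(
    {p: ("tubular" if p in TUBULAR_PLANTS else "open") for p in PLANTS}
)


def warn_unknown_labels(records: Iterable[VisitationRecord]) -> None:
    """Log (once per label) any plant, morphotype or context label outside the
    canonical sets. Unknown labels are legal — the pipeline is not a taxonomy
    validator — but worth surfacing."""
    seen_plants: set[str] = set()
    seen_morphs: set[str] = set()
    seen_ctx: set[str] = set()
    for r in records:
        if r.plant_species not in PLANTS and r.plant_species not in seen_plants:
            seen_plants.add(r.plant_species)
            logger.warning("unknown plant species label: %r", r.plant_species)
        if r.insect_morphotype not in MORPHOTYPES and r.insect_morphotype not in seen_morphs:
            seen_morphs.add(r.insect_morphotype)
            logger.warning("unknown insect morphotype label: %r", r.insect_morphotype)
        if r.landscape_context not in LANDSCAPE_CONTEXTS and r.landscape_context not in seen_ctx:
            seen_ctx.add(r.landscape_context)
            logger.warning("unknown landscape context label: %r", r.landscape_context)


def canonical_order(labels: Iterable[str], canon: tuple[str, ...]) -> list[str]:
    """Order ``labels``: canonical entries first in canonical order, then any
    remaining labels in first-appearance order. Makes matrix layout and all
    report output deterministic."""
    labels = list(labels)
    present = set(labels)
    ordered = [lab for lab in canon if lab in present]
    for lab in labels:
        if lab not in canon and lab not in ordered:
            ordered.append(lab)
    return ordered
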