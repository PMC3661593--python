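"""Flower-constancy reproductive-success index.

Pollination requires conspecific pollen, so only consecutive visits to the
same plant species are assumed to count as potential reproductive events.
If a visitor group makes i.i.d. plant choices with probabilities P (its
empirical visit distribution), the chance that two successive visits both
land on plant f is P_f^2; scaling by the group's observed visit total V
gives its expected contribution of same-species visit pairs. The per-plant
index is therefore

    R_f = sum over visitor groups p with V_p > 0 of  (P_{p,f})^2 * V_p
        = sum_p A_{f,p}^2 / V_p

and a floral functional group's index is the sum over its member plants.
A specialist group (all V visits on one plant) contributes exactly V to that
plant; spreading the same visits over more plants contributes less — the
index rewards flower constancy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .matrices import InteractionMatrix, Provenance
from .records import FUNCTIONAL_GROUPS, FunctionalGroupMap


@dataclass(frozen=True)
class RSReport:
    """Per-plant and per-functional-group reproductive-success index values
    for one web. ``n_p`` is the number of visitor morphotypes with at least
    one visit (the groups actually contributing)."""

    per_plant: dict[str, float]
    per_group: dict[str, float]
    n_p: int
    provenance: Provenance


def plant_rs_index(matrix: InteractionMatrix, plant: str) -> float:
    """Reproductive-success index of one plant: sum_p A[f,p]^2 / V_p over
    morphotypes with V_p > 0 (zero-visit columns contribute 0).

    Raises KeyError for a plant not in the web.
    """
    row = matrix.row(plant).astype(float)
    V = matrix.counts.sum(axis=0).astype(float)
    active = V > 0
    if not active.any():
        return 0.0
    return float((row[active] ** 2 / V[active]).sum())


def group_rs_index(
    matrix: InteractionMatrix, groups: FunctionalGroupMap, group: str
) -> float:
    """Functional-group index: sum of member plants' R_f.

    Every plant in the web must be mapped (ConfigurationError otherwise);
    mapped plants absent from this web contribute nothing.
    """
    for plant in matrix.plant_labels:
        groups.group_of(plant)  # raises ConfigurationError if unmapped
    members = [p for p in matrix.plant_labels if groups.group_of(p) == group]
    return float(sum(plant_rs_index(matrix, p) for p in members))


def rs_report(matrix: InteractionMatrix, groups: FunctionalGroupMap) -> RSReport:
    """Full report for one web: R_f per plant and per functional group."""
    per_plant = {p: plant_rs_index(matrix, p) for p in matrix.plant_labels}
    per_group = {g: group_rs_index(matrix, groups, g) for g in FUNCTIONAL_GROUPS}
    n_p = int(np.count_nonzero(matrix.counts.sum(axis=0)))
    return RSReport(
        per_plant=per_plant, per_group=per_group, n_p=n_p, provenance=matrix.provenance
    )


def rs_table(webs: list[InteractionMatrix], groups: FunctionalGroupMap) -> pd.DataFrame:
    """Long-format report over webs: one row per (web, plant-or-group)."""
    rows = []
    for w in webs:
        rep = rs_report(w, groups)
        base = {
            "site_id": rep.provenance.site_id,
            "spatial_config": rep.provenance.spatial_config,
            "landscape_context": rep.provenance.landscape_context,
        }
        for plant, value in rep.per_plant.items():
            rows.append(base | {"plant_or_group": plant, "rs_index": value})
        for group, value in rep.per_group.items():
            rows.append(base | {"plant_or_group": group, "rs_index": value})
    return pd.DataFrame(
        rows,
        columns=["site_id", "spatial_config", "landscape_context",
                 "plant_or_group", "rs_index"],
    )
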