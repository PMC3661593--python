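"""Packaged reference counts: the study-wide per-morphotype visitation totals.

These nine numbers are the pooled interaction counts over all twelve sites
and all rounds of the field experiment, kept as a tiny packaged CSV so the
whole pipeline can be exercised on real published totals without any
external download. The pooled rows use the pseudo-labels ``community`` (all
five plants) and ``pooled`` (all four landscape contexts).
"""

from __future__ import annotations

from importlib import resources

from .io import read_visitation_table
from .matrices import InteractionMatrix, build_interaction_matrix
from .records import VisitationRecord


def overall_totals_records() -> list[VisitationRecord]:
    """The nine pooled per-morphotype totals as visitation records."""
    with resources.as_file(
        resources.files("pollinet.data").joinpath("overall_totals.csv")
    ) as path:
        return read_visitation_table(path)


def overall_totals_matrix() -> InteractionMatrix:
    """The pooled totals as a 1-plant x 9-morphotype web (total 17 857)."""
    return build_interaction_matrix(overall_totals_records(), "ALL", "systematic")
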