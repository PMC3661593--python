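"""Delimited-text input/output for visitation records, site metadata and webs.

Dialect: UTF-8, header row mandatory, comma-separated by default with a
delimiter argument for tab. Webs are written as TSV with '#'-prefixed
provenance comments, morphotype labels in the first row and plant labels in
the first column — lossless and byte-stable under a fixed label order.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError
from .matrices import InteractionMatrix, Provenance
from .records import SiteMetadata, VisitationRecord, warn_unknown_labels

logger = logging.getLogger(__name__)

VISITATION_COLUMNS = (
    "site_id",
    "landscape_context",
    "round",
    "plot_id",
    "spatial_config",
    "plant_species",
    "insect_morphotype",
    "visit_count",
)
SITE_COLUMNS = ("site_id", "landscape_context", "x", "y")


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")


def _int_field(value, row: int, name: str) -> int:
    """Parse a value that must be a non-negative integer; name the offending
    row (1-based, excluding header) on failure."""
    try:
        f = float(value)
    except (TypeError, ValueError):
        raise ValidationError(f"row {row}: {name} {value!r} is not a number") from None
    if not np.isfinite(f) or f != int(f):
        raise ValidationError(f"row {row}: {name} {value!r} is not an integer")
    i = int(f)
    if i < 0:
        raise ValidationError(f"row {row}: {name} {i} is negative")
    return i


def read_visitation_table(path, delimiter: str = ",") -> list[VisitationRecord]:
    """Read a visitation CSV into validated records.

    Unknown plant/morphotype/context labels are accepted and logged;
    malformed rows (negative or non-integer counts, out-of-range flowering
    quality) raise :class:`ValidationError` naming the row.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed file structure
        raise FormatError(f"{path}: could not parse ({exc})") from exc
    _require_columns(df, VISITATION_COLUMNS, path)
    has_fq = "flowering_quality" in df.columns
    records: list[VisitationRecord] = []
    for pos, row in enumerate(df.itertuples(index=False), start=1):
        d = row._asdict()
        fq = None
        if has_fq and str(d["flowering_quality"]).strip() != "":
            fq = _int_field(d["flowering_quality"], pos, "flowering_quality")
            if fq > 6:
                raise ValidationError(f"row {pos}: flowering_quality {fq} exceeds 6")
        try:
            records.append(
                VisitationRecord(
                    site_id=str(d["site_id"]),
                    landscape_context=str(d["landscape_context"]),
                    round_index=_int_field(d["round"], pos, "round"),
                    plot_id=str(d["plot_id"]),
                    spatial_config=str(d["spatial_config"]),
                    plant_species=str(d["plant_species"]),
                    insect_morphotype=str(d["insect_morphotype"]),
                    visit_count=_int_field(d["visit_count"], pos, "visit_count"),
                    flowering_quality=fq,
                )
            )
        except ValueError as exc:
            raise ValidationError(f"row {pos}: {exc}") from exc
    warn_unknown_labels(records)
    logger.info("read %d visitation records from %s", len(records), path)
    return records


def write_visitation_table(
    records: Sequence[VisitationRecord], path, delimiter: str = ","
) -> None:
    df = records_to_frame(records)
    df.to_csv(path, sep=delimiter, index=False)


def records_to_frame(records: Sequence[VisitationRecord]) -> pd.DataFrame:
    """Long-format DataFrame view of the records (column names match the
    on-disk dialect)."""
    return pd.DataFrame(
        {
            "site_id": [r.site_id for r in records],
            "landscape_context": [r.landscape_context for r in records],
            "round": [r.round_index for r in records],
            "plot_id": [r.plot_id for r in records],
            "spatial_config": [r.spatial_config for r in records],
            "plant_species": [r.plant_species for r in records],
            "insect_morphotype": [r.insect_morphotype for r in records],
            "visit_count": [r.visit_count for r in records],
            "flowering_quality": [
                "" if r.flowering_quality is None else r.flowering_quality
                for r in records
            ],
        }
    )


def read_sites_table(path, delimiter: str = ",") -> list[SiteMetadata]:
    path = Path(path)
    df = pd.read_csv(path, sep=delimiter)
    _require_columns(df, SITE_COLUMNS, path)
    sites = [
        SiteMetadata(
            site_id=str(r.site_id),
            landscape_context=str(r.landscape_context),
            x=float(r.x),
            y=float(r.y),
        )
        for r in df.itertuples(index=False)
    ]
    ids = [s.site_id for s in sites]
    if len(set(ids)) != len(ids):
        raise ValidationError(f"{path}: duplicate site_id values")
    return sites


def write_sites_table(sites: Sequence[SiteMetadata], path, delimiter: str = ",") -> None:
    pd.DataFrame(
        {
            "site_id": [s.site_id for s in sites],
            "landscape_context": [s.landscape_context for s in sites],
            "x": [s.x for s in sites],
            "y": [s.y for s in sites],
        }
    ).to_csv(path, sep=delimiter, index=False)


def write_matrix(matrix: InteractionMatrix, path) -> None:
    """Serialise a web to TSV with provenance header comments."""
    prov = matrix.provenance
    lines = [
        f"# site_id: {prov.site_id}",
        f"# spatial_config: {prov.spatial_config}",
        f"# rounds: {','.join(str(r) for r in prov.rounds)}",
        f"# landscape_context: {prov.landscape_context or ''}",
        "plant\t" + "\t".join(matrix.morphotype_labels),
    ]
    for i, plant in enumerate(matrix.plant_labels):
        lines.append(plant + "\t" + "\t".join(str(c) for c in matrix.counts[i]))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_matrix(path) -> InteractionMatrix:
    """Parse a web written by :func:`write_matrix` (lossless round-trip)."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    header: dict[str, str] = {}
    body: list[str] = []
    for line in text.splitlines():
        if line.startswith("#"):
            key, _, value = line[1:].partition(":")
            header[key.strip()] = value.strip()
        elif line.strip():
            body.append(line)
    if not body:
        raise FormatError(f"{path}: no matrix body")
    head = body[0].split("\t")
    if head[0] != "plant":
        raise FormatError(f"{path}: first body row must start with 'plant'")
    morphs = head[1:]
    plants: list[str] = []
    rows: list[list[int]] = []
    for line in body[1:]:
        parts = line.split("\t")
        if len(parts) != len(morphs) + 1:
            raise FormatError(
                f"{path}: row {parts[0]!r} has {len(parts) - 1} cells, expected {len(morphs)}"
            )
        plants.append(parts[0])
        try:
            rows.append([int(v) for v in parts[1:]])
        except ValueError as exc:
            raise FormatError(f"{path}: non-integer count in row {parts[0]!r}") from exc
    rounds = tuple(
        int(r) for r in header.get("rounds", "").split(",") if r.strip()
    )
    prov = Provenance(
        site_id=header.get("site_id", ""),
        spatial_config=header.get("spatial_config", "systematic"),
        rounds=rounds,
        landscape_context=header.get("landscape_context") or None,
    )
    return InteractionMatrix(
        plant_labels=plants,
        morphotype_labels=morphs,
        counts=np.array(rows, dtype=np.int64).reshape(len(plants), len(morphs)),
        provenance=prov,
    )
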