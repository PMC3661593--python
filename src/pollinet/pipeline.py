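"""End-to-end orchestration: data in (read or generated), reports out.

Stages: load/generate visitation records -> cumulate one web per
(site, spatial configuration) -> per-web network summaries and generalism
profiles -> reproductive-success report -> homogeneity chi-squared tables ->
Mantel spatial-autocorrelation check -> permutation comparisons of per-web
metrics across landscape contexts. All outputs are plain delimited text plus
a JSON run manifest; identical config and seed give byte-identical files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import ConfigurationError, DegenerateTableError, UndefinedMetricError
from .io import (
    read_sites_table,
    read_visitation_table,
    records_to_frame,
    write_sites_table,
    write_visitation_table,
)
from .matrices import InteractionMatrix, build_all_networks
from .metrics import generalism_profiles, network_summary
from .records import (
    DEFAULT_FUNCTIONAL_GROUPS,
    FUNCTIONAL_GROUPS,
    LANDSCAPE_CONTEXTS,
    MORPHOTYPES,
    FunctionalGroupMap,
    SiteMetadata,
    VisitationRecord,
)
from .reproduction import rs_table
from .simulate import GeneratorConfig, generate_study
from .stats import (
    ContingencyTable,
    bray_curtis_distances,
    geographic_distances,
    mantel_test,
    pearson_chi_squared,
    permutation_context_compare,
)

logger = logging.getLogger(__name__)

_FLOAT_FORMAT = "%.10g"


@dataclass
class PipelineConfig:
    """One analysis run: either CSV inputs or a generator config (exactly
    one), a functional-group map, permutation settings and an output dir."""

    output_dir: Path
    records_path: Path | None = None
    sites_path: Path | None = None
    generator: GeneratorConfig | None = None
    functional_groups: FunctionalGroupMap = field(
        default_factory=lambda: DEFAULT_FUNCTIONAL_GROUPS
    )
    mantel_permutations: int = 999
    comparison_permutations: int = 999
    stats_seed: int = 0
    delimiter: str = ","

    def __post_init__(self) -> None:
        has_files = self.records_path is not None or self.sites_path is not None
        if has_files and self.generator is not None:
            raise ConfigurationError(
                "config error at records_path/generator: give input paths OR "
                "generator settings, not both"
            )
        if not has_files and self.generator is None:
            raise ConfigurationError(
                "config error at records_path/generator: need input paths or "
                "generator settings"
            )
        if has_files and (self.records_path is None or self.sites_path is None):
            raise ConfigurationError(
                "config error at records_path/sites_path: both paths are required"
            )


def summarize_by_context(per_web: pd.DataFrame, value_column: str) -> pd.DataFrame:
    """Per-context mean, SD (ddof=1) and n of one per-web metric column.

    Contexts with no finite values are excluded with a warning.
    """
    rows = []
    for ctx, grp in per_web.groupby("landscape_context", sort=False):
        vals = grp[value_column].dropna().to_numpy(dtype=float)
        if vals.size == 0:
            logger.warning("context %r has no values for %s; excluded", ctx, value_column)
            continue
        rows.append(
            {
                "landscape_context": ctx,
                "metric": value_column,
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if vals.size > 1 else float("nan"),
                "n": int(vals.size),
            }
        )
    order = {c: i for i, c in enumerate(LANDSCAPE_CONTEXTS)}
    rows.sort(key=lambda r: order.get(r["landscape_context"], len(order)))
    return pd.DataFrame(rows, columns=["landscape_context", "metric", "mean", "sd", "n"])


def network_summary_table(webs: list[InteractionMatrix]) -> pd.DataFrame:
    rows = []
    for w in webs:
        s = network_summary(w)
        rows.append(
            {
                "site_id": w.provenance.site_id,
                "spatial_config": w.provenance.spatial_config,
                "landscape_context": w.provenance.landscape_context,
                "total_interactions": s.total_interactions,
                "link_count": s.link_count,
                "interaction_evenness": s.interaction_evenness,
            }
        )
    return pd.DataFrame(rows)


def generalism_table(webs: list[InteractionMatrix]) -> pd.DataFrame:
    rows = []
    for w in webs:
        for g in generalism_profiles(w):
            rows.append(
                {
                    "site_id": w.provenance.site_id,
                    "spatial_config": w.provenance.spatial_config,
                    "landscape_context": w.provenance.landscape_context,
                    "morphotype": g.morphotype,
                    "degree": g.degree,
                    "weighted_generalism": g.weighted,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["site_id", "spatial_config", "landscape_context", "morphotype",
                 "degree", "weighted_generalism"],
    )


def visit_context_tables(
    records: list[VisitationRecord],
) -> dict[str, ContingencyTable]:
    """Per-morphotype plant x landscape-context visit-count tables (pooled
    over sites, rounds and plots) for homogeneity testing."""
    df = records_to_frame(records)
    tables: dict[str, ContingencyTable] = {}
    for m in MORPHOTYPES:
        sub = df[df["insect_morphotype"] == m]
        if sub.empty:
            continue
        pivot = (
            sub.pivot_table(
                index="plant_species",
                columns="landscape_context",
                values="visit_count",
                aggfunc="sum",
                fill_value=0,
            )
        )
        tables[m] = ContingencyTable(
            row_labels=tuple(pivot.index),
            col_labels=tuple(pivot.columns),
            counts=pivot.to_numpy(dtype=np.int64),
        )
    return tables


def site_morphotype_totals(records: list[VisitationRecord]) -> pd.DataFrame:
    """Site x morphotype visit totals (the community vectors used for
    Bray-Curtis distances between sites)."""
    df = records_to_frame(records)
    pivot = df.pivot_table(
        index="site_id",
        columns="insect_morphotype",
        values="visit_count",
        aggfunc="sum",
        fill_value=0,
    )
    cols = [m for m in MORPHOTYPES if m in pivot.columns] + [
        c for c in pivot.columns if c not in MORPHOTYPES
    ]
    return pivot.loc[sorted(pivot.index), cols]


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run the full analysis; returns a name -> path map of written files."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    def _write(name: str, df: pd.DataFrame) -> None:
        path = out / name
        df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FORMAT)
        written[name] = path

    # --- stage 1: inputs
    if config.generator is not None:
        logger.info("stage generate: seed %d", config.generator.seed)
        records, sites = generate_study(config.generator)
        write_visitation_table(records, out / "records.csv")
        write_sites_table(sites, out / "sites.csv")
        written["records.csv"] = out / "records.csv"
        written["sites.csv"] = out / "sites.csv"
    else:
        records = read_visitation_table(config.records_path, config.delimiter)
        sites = read_sites_table(config.sites_path, config.delimiter)
    logger.info("stage load: %d records, %d sites", len(records), len(sites))

    # --- stage 2: webs
    webs = build_all_networks(records, sites)
    logger.info("stage webs: %d cumulated networks", len(webs))

    # --- stage 3: per-web metrics
    summary = network_summary_table(webs)
    _write("network_summary.tsv", summary)
    _write("generalism.tsv", generalism_table(webs))

    # --- stage 4: reproductive success
    rs = rs_table(webs, config.functional_groups)
    _write("rs_index.tsv", rs)

    # --- stage 5: chi-squared homogeneity per morphotype
    chi_rows = []
    for m, table in visit_context_tables(records).items():
        try:
            res = pearson_chi_squared(table)
        except DegenerateTableError:
            logger.warning("morphotype %r: degenerate visit table; chi-squared skipped", m)
            continue
        chi_rows.append(
            {"morphotype": m, "statistic": res.statistic, "df": res.df,
             "p_value": res.p_value}
        )
    _write("chi_squared.tsv",
           pd.DataFrame(chi_rows, columns=["morphotype", "statistic", "df", "p_value"]))

    # --- stage 6: Mantel spatial autocorrelation
    mantel_rows = []
    if len(sites) >= 3:
        geo = geographic_distances(sites)
        bc = bray_curtis_distances(site_morphotype_totals(records))
        try:
            res = mantel_test(
                geo, bc, n_perm=config.mantel_permutations, seed=config.stats_seed
            )
            mantel_rows.append(
                {"test": "mantel_geo_vs_braycurtis", "statistic": res.statistic,
                 "p_value": res.p_value, "n_permutations": res.n_permutations,
                 "seed": res.seed}
            )
        except UndefinedMetricError as exc:
            logger.warning("stage mantel skipped: %s", exc)
    _write("mantel.tsv",
           pd.DataFrame(mantel_rows,
                        columns=["test", "statistic", "p_value", "n_permutations", "seed"]))

    # --- stage 7: permutation context comparisons (per-web metrics)
    cmp_rows = []
    web_key = summary["site_id"] + ":" + summary["spatial_config"]
    contexts_by_web = dict(zip(web_key, summary["landscape_context"]))
    metric_values: dict[str, dict[str, float]] = {
        "total_interactions": dict(zip(web_key, summary["total_interactions"].astype(float))),
        "interaction_evenness": {
            k: float(v)
            for k, v in zip(web_key, summary["interaction_evenness"])
            if pd.notna(v)
        },
    }
    for group in FUNCTIONAL_GROUPS:
        sub = rs[rs["plant_or_group"] == group]
        keys = sub["site_id"] + ":" + sub["spatial_config"]
        metric_values[f"rs_index_{group}"] = dict(
            zip(keys, sub["rs_index"].astype(float))
        )
    n_contexts = len({c for c in contexts_by_web.values() if c is not None})
    for metric, values in metric_values.items():
        if n_contexts < 2 or len(values) < 4:
            continue
        ctxs = {k: contexts_by_web[k] for k in values}
        try:
            results = permutation_context_compare(
                values, ctxs,
                n_perm=config.comparison_permutations, seed=config.stats_seed,
            )
        except Exception as exc:  # noqa: BLE001 - comparisons are best-effort
            logger.warning("stage compare (%s) skipped: %s", metric, exc)
            continue
        for (c1, c2), res in sorted(results.items()):
            cmp_rows.append(
                {"metric": metric, "context_1": c1, "context_2": c2,
                 "mean_difference": res.statistic, "p_value": res.p_value,
                 "n_permutations": res.n_permutations,
                 "method": "permutation surrogate"}
            )
    _write("context_comparisons.tsv",
           pd.DataFrame(cmp_rows,
                        columns=["metric", "context_1", "context_2", "mean_difference",
                                 "p_value", "n_permutations", "method"]))

    # --- stage 8: context-level summaries
    summaries = pd.concat(
        [
            summarize_by_context(summary, "total_interactions"),
            summarize_by_context(summary, "interaction_evenness"),
            summarize_by_context(summary, "link_count"),
        ],
        ignore_index=True,
    )
    _write("context_summary.tsv", summaries)

    # --- manifest
    manifest = {
        "pollinet_version": __version__,
        "generator_seed": config.generator.seed if config.generator else None,
        "stats_seed": config.stats_seed,
        "mantel_permutations": config.mantel_permutations,
        "comparison_permutations": config.comparison_permutations,
        "n_records": len(records),
        "n_sites": len(sites),
        "n_webs": len(webs),
        "table_rows": {name: _count_rows(path) for name, path in written.items()},
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    written["manifest.json"] = manifest_path
    return written


def _count_rows(path: Path) -> int:
    with open(path, encoding="utf-8") as fh:
        return max(sum(1 for _ in fh) - 1, 0)  # minus header


def run_fixture(output_dir) -> dict[str, Path]:
    """Single-web report on the packaged pooled study totals."""
    from .metrics import interaction_evenness, link_count, total_interactions
    from .reference import overall_totals_matrix

    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    m = overall_totals_matrix()
    total = total_interactions(m)
    rows = [
        {"quantity": "total_interactions", "subject": "network", "value": float(total)},
        {"quantity": "link_count", "subject": "network", "value": float(link_count(m))},
        {"quantity": "interaction_evenness", "subject": "network",
         "value": interaction_evenness(m)},
    ]
    for j, morph in enumerate(m.morphotype_labels):
        rows.append(
            {"quantity": "share_percent", "subject": morph,
             "value": 100.0 * float(m.counts[:, j].sum()) / total}
        )
    path = out / "fixture_summary.tsv"
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format=_FLOAT_FORMAT)
    return {"fixture_summary.tsv": path}
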