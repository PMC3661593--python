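"""Synthetic visitation-study generator.

Emulates the field protocol: twelve sites over a four-level urbanisation
gradient, four observation rounds, four plots per site (two per spatial
configuration), 10-minute sessions. Per-session visit totals are Poisson
with context-specific rates matching the study's mean visits per minute
(16.10 semi-natural, 12.73 agricultural, 4.08 suburban, 4.23 urban); each
visit is assigned a morphotype from a context mix and then a plant from the
morphotype's site-level floral preference.

Preference model
----------------
Each morphotype has a baseline preference row over the five plants encoding
mouthpart/corolla matching (bumblebees and Lepidoptera concentrate on
tubular flowers; Syrphidae, solitary bees, other flies, Coleoptera and bugs
on open flowers). A context's preference sharpness kappa shrinks the mean
realised preference toward that baseline:

    m = (kappa * base + uniform) / (kappa + 1)

and each site draws its realised preference from Dirichlet(c0 * m) with a
fixed site-noise concentration c0. Large kappa therefore reproduces the
baseline (sharp, specialised foraging); small kappa flattens preferences
toward uniform (generalised foraging), so weighted generalism decreases
monotonically in kappa. Sharpness drops toward the urban end for the five
short-mouthpart groups and stays fixed for the others, mirroring the
urbanisation-driven generalism shift the analysis is meant to detect.

Visit totals are Poisson and plant choices i.i.d. multinomial: the weakest
assumptions consistent with a count-based analysis. No within-sequence
flower-constancy autocorrelation is simulated — the reproductive-success
index models constancy as independent draws from P, and a generator that
baked in sequence correlation would make that recovery test circular.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError
from .records import MORPHOTYPES, PLANTS, SPATIAL_CONFIGS, SiteMetadata, VisitationRecord

#: Mean visits per minute by landscape context (field-study calibration).
CONTEXT_VISIT_RATES: dict[str, float] = {
    "semi-natural": 16.10,
    "agricultural": 12.73,
    "suburban": 4.08,
    "urban": 4.23,
}

#: Preference sharpness kappa by context, applied to short-mouthpart groups.
CONTEXT_CONCENTRATIONS: dict[str, float] = {
    "semi-natural": 50.0,
    "agricultural": 40.0,
    "suburban": 8.0,
    "urban": 3.0,
}

#: Morphotypes whose foraging generalises along the urbanisation gradient.
SHORT_MOUTHPART: frozenset[str] = frozenset(
    {"solitary bees", "Coleoptera", "Syrphidae", "other flies", "bugs"}
)

#: Sharpness for morphotypes whose preferences do not vary with context
#: (bumblebees, Apis mellifera, Lepidoptera, other Hymenoptera).
FIXED_CONCENTRATION: float = 50.0

#: Morphotypes whose absolute visitation does not respond to urbanisation;
#: their expected visits per minute are held constant across contexts, so
#: their share of the (shrinking) urban visit pool grows.
CONSTANT_VISITORS: frozenset[str] = frozenset({"bumblebees", "Apis mellifera"})

#: Study-wide share of interactions per morphotype (pooled field totals).
OVERALL_SHARES: dict[str, float] = {
    "solitary bees": 5038 / 17857,
    "Apis mellifera": 36 / 17857,
    "bumblebees": 5567 / 17857,
    "Coleoptera": 565 / 17857,
    "Lepidoptera": 118 / 17857,
    "Syrphidae": 4789 / 17857,
    "other flies": 1686 / 17857,
    "bugs": 32 / 17857,
    "other Hymenoptera": 26 / 17857,
}

#: Baseline plant preferences, rows in canonical morphotype order, columns
#: in canonical plant order (three tubular species then two open species).
#: Long-mouthpart rows put >= 0.7 mass on tubular plants, short-mouthpart
#: rows >= 0.7 on open plants.
DEFAULT_PREFERENCE_BASE: np.ndarray = np.array(
    [
        # M.sativa C.regalis L.cornic  M.inodora S.arvensis
        [0.08, 0.07, 0.05, 0.42, 0.38],  # solitary bees (open)
        [0.22, 0.20, 0.18, 0.20, 0.20],  # Apis mellifera (generalist)
        [0.32, 0.30, 0.23, 0.08, 0.07],  # bumblebees (tubular)
        [0.06, 0.06, 0.05, 0.45, 0.38],  # Coleoptera (open)
        [0.30, 0.28, 0.22, 0.11, 0.09],  # Lepidoptera (tubular)
        [0.07, 0.06, 0.05, 0.44, 0.38],  # Syrphidae (open)
        [0.08, 0.07, 0.06, 0.41, 0.38],  # other flies (open)
        [0.06, 0.05, 0.04, 0.44, 0.41],  # bugs (open)
        [0.15, 0.13, 0.12, 0.31, 0.29],  # other Hymenoptera (mild open)
    ]
)

_CONTEXT_CODES = {
    "semi-natural": "SN",
    "agricultural": "AG",
    "suburban": "SU",
    "urban": "UR",
}

#: Grid spacing (metres) used when laying out synthetic site coordinates.
SITE_GRID_SPACING: float = 1000.0


@dataclass(frozen=True)
class ContextPreset:
    """Generator settings for one landscape context."""

    context: str
    visit_rate: float  # visits per minute per session patch
    morphotype_mix: np.ndarray  # probability over the 9 morphotypes
    concentration: float  # preference sharpness kappa (short-mouthpart)
    n_sites: int = 3
    session_minutes: float = 10.0
    rounds: int = 4
    plots_per_config: int = 2

    def __post_init__(self) -> None:
        mix = np.asarray(self.morphotype_mix, dtype=float)
        if mix.shape != (len(MORPHOTYPES),):
            raise ConfigurationError("morphotype_mix must have one entry per morphotype")
        if np.any(mix < 0) or not np.isclose(mix.sum(), 1.0):
            raise ConfigurationError("morphotype_mix must be a probability vector")
        if self.visit_rate < 0:
            raise ConfigurationError("visit_rate must be >= 0")
        if self.concentration <= 0:
            raise ConfigurationError("concentration must be > 0")
        object.__setattr__(self, "morphotype_mix", mix)


@dataclass(frozen=True)
class GeneratorConfig:
    """Full study design: one preset per landscape context, a baseline
    preference matrix, a site-noise concentration and a root seed."""

    contexts: tuple[ContextPreset, ...]
    preference_base: np.ndarray = field(
        default_factory=lambda: DEFAULT_PREFERENCE_BASE.copy()
    )
    site_noise: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        base = np.asarray(self.preference_base, dtype=float)
        if base.shape != (len(MORPHOTYPES), len(PLANTS)):
            raise ConfigurationError(
                "preference_base must be morphotypes x plants "
                f"({len(MORPHOTYPES)} x {len(PLANTS)})"
            )
        if np.any(base < 0) or not np.allclose(base.sum(axis=1), 1.0):
            raise ConfigurationError("preference_base rows must be probability vectors")
        if self.site_noise <= 0:
            raise ConfigurationError("site_noise must be > 0")
        object.__setattr__(self, "preference_base", base)


def context_morphotype_mixes() -> dict[str, np.ndarray]:
    """Per-context morphotype mixes derived from the pooled study shares.

    Bumblebees and Apis mellifera keep a constant expected visit rate across
    contexts (share inversely proportional to the context visit rate); the
    remaining groups keep their relative proportions and absorb the rest.
    """
    mean_rate = float(np.mean(list(CONTEXT_VISIT_RATES.values())))
    mixes: dict[str, np.ndarray] = {}
    const_total_share = sum(OVERALL_SHARES[m] for m in CONSTANT_VISITORS)
    for ctx, rate in CONTEXT_VISIT_RATES.items():
        mix = np.empty(len(MORPHOTYPES))
        const_ctx = 0.0
        for j, m in enumerate(MORPHOTYPES):
            if m in CONSTANT_VISITORS:
                mix[j] = OVERALL_SHARES[m] * mean_rate / rate
                const_ctx += mix[j]
        if const_ctx >= 1.0:
            raise ConfigurationError(
                f"constant-visitor share {const_ctx:.3f} >= 1 in context {ctx!r}"
            )
        scale = (1.0 - const_ctx) / (1.0 - const_total_share)
        for j, m in enumerate(MORPHOTYPES):
            if m not in CONSTANT_VISITORS:
                mix[j] = OVERALL_SHARES[m] * scale
        mixes[ctx] = mix / mix.sum()
    return mixes


def default_presets(seed: int = 0) -> GeneratorConfig:
    """The default study design: 4 contexts x 3 sites, field-calibrated
    visit rates, context-dependent preference sharpness."""
    mixes = context_morphotype_mixes()
    presets = tuple(
        ContextPreset(
            context=ctx,
            visit_rate=CONTEXT_VISIT_RATES[ctx],
            morphotype_mix=mixes[ctx],
            concentration=CONTEXT_CONCENTRATIONS[ctx],
        )
        for ctx in CONTEXT_VISIT_RATES
    )
    return GeneratorConfig(contexts=presets, seed=seed)


def mean_site_preferences(
    preset: ContextPreset, config: GeneratorConfig
) -> np.ndarray:
    """Expected (pre-noise) preference matrix for a site of this context:
    each row shrunk from uniform toward the baseline by its sharpness."""
    uniform = np.full(len(PLANTS), 1.0 / len(PLANTS))
    rows = []
    for j, m in enumerate(MORPHOTYPES):
        kappa = (
            preset.concentration if m in SHORT_MOUTHPART else FIXED_CONCENTRATION
        )
        base = config.preference_base[j]
        rows.append((kappa * base + uniform) / (kappa + 1.0))
    return np.array(rows)


def draw_site_preferences(
    preset: ContextPreset, config: GeneratorConfig, rng: np.random.Generator
) -> np.ndarray:
    """Realised per-site preference matrix: one Dirichlet draw per
    morphotype around its shrunk mean, with concentration ``site_noise``."""
    means = mean_site_preferences(preset, config)
    return np.array([rng.dirichlet(config.site_noise * row) for row in means])


def generate_session(
    preset: ContextPreset,
    site_id: str,
    round_index: int,
    plot_id: str,
    spatial_config: str,
    preferences: np.ndarray,
    rng: np.random.Generator,
    flowering_quality: dict[str, int] | None = None,
) -> list[VisitationRecord]:
    """One 10-minute observation session, aggregated to visit counts.

    The session total is Poisson(visit_rate * session_minutes); each visit
    gets a morphotype from the context mix and a plant from the morphotype's
    site-level preference row. Only nonzero (plant, morphotype) cells emit a
    record.
    """
    n_visits = int(rng.poisson(preset.visit_rate * preset.session_minutes))
    records: list[VisitationRecord] = []
    if n_visits == 0:
        return records
    per_morph = rng.multinomial(n_visits, preset.morphotype_mix)
    for j, m in enumerate(MORPHOTYPES):
        if per_morph[j] == 0:
            continue
        per_plant = rng.multinomial(per_morph[j], preferences[j])
        for i, plant in enumerate(PLANTS):
            if per_plant[i] == 0:
                continue
            fq = flowering_quality.get(plant) if flowering_quality else None
            records.append(
                VisitationRecord(
                    site_id=site_id,
                    landscape_context=preset.context,
                    round_index=round_index,
                    plot_id=plot_id,
                    spatial_config=spatial_config,
                    plant_species=plant,
                    insect_morphotype=m,
                    visit_count=int(per_plant[i]),
                    flowering_quality=fq,
                )
            )
    return records


def _site_layout(
    presets: tuple[ContextPreset, ...], rng: np.random.Generator
) -> list[SiteMetadata]:
    """Lay sites on a shuffled grid so landscape context is not spatially
    clustered (the spatial-autocorrelation null should hold by design)."""
    site_specs: list[tuple[str, str]] = []
    for preset in presets:
        code = _CONTEXT_CODES.get(preset.context, preset.context[:2].upper())
        for i in range(1, preset.n_sites + 1):
            site_specs.append((f"{code}{i}", preset.context))
    n = len(site_specs)
    ncols = int(np.ceil(np.sqrt(n)))
    cells = [(r, c) for r in range(int(np.ceil(n / ncols))) for c in range(ncols)][:n]
    order = rng.permutation(n)
    sites = []
    for (site_id, ctx), k in zip(site_specs, order):
        r, c = cells[k]
        sites.append(
            SiteMetadata(
                site_id=site_id,
                landscape_context=ctx,
                x=c * SITE_GRID_SPACING,
                y=r * SITE_GRID_SPACING,
            )
        )
    return sites


def generate_study(
    config: GeneratorConfig,
) -> tuple[list[VisitationRecord], list[SiteMetadata]]:
    """Generate a full study: every site x round x configuration x plot
    session, plus site metadata with grid coordinates.

    Randomness is governed solely by ``config.seed``: the root SeedSequence
    spawns one child stream for the site layout and one per site (in preset
    order), so any one site's data can be regenerated independently.
    """
    root = np.random.SeedSequence(config.seed)
    n_sites = sum(p.n_sites for p in config.contexts)
    children = root.spawn(n_sites + 1)
    layout_rng = np.random.default_rng(children[0])
    sites = _site_layout(config.contexts, layout_rng)

    records: list[VisitationRecord] = []
    child_iter = iter(children[1:])
    for preset in config.contexts:
        code = _CONTEXT_CODES.get(preset.context, preset.context[:2].upper())
        for i in range(1, preset.n_sites + 1):
            site_id = f"{code}{i}"
            rng = np.random.default_rng(next(child_iter))
            prefs = draw_site_preferences(preset, config, rng)
            for round_index in range(1, preset.rounds + 1):
                # one 0-6 flowering indicator per plant per round
                fq = {
                    plant: int(rng.integers(3, 7)) for plant in PLANTS
                }
                for spatial_config in SPATIAL_CONFIGS:
                    for plot in range(1, preset.plots_per_config + 1):
                        plot_id = f"{site_id}-{spatial_config[:3]}-{plot}"
                        records.extend(
                            generate_session(
                                preset,
                                site_id,
                                round_index,
                                plot_id,
                                spatial_config,
                                prefs,
                                rng,
                                flowering_quality=fq,
                            )
                        )
    return records, sites


def with_concentration(config: GeneratorConfig, kappa: float) -> GeneratorConfig:
    """A copy of ``config`` with every context's preference sharpness set to
    ``kappa`` (used for parameter-recovery sweeps)."""
    return replace(
        config,
        contexts=tuple(replace(p, concentration=kappa) for p in config.contexts),
    )
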