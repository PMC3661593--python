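"""Synthetic-study generator: presets, determinism, calibration and
parameter recovery."""

import numpy as np
import pytest

from pollinet.matrices import build_all_networks
from pollinet.metrics import weighted_generalism
from pollinet.records import MORPHOTYPES, PLANTS, TUBULAR_PLANTS
from pollinet.simulate import (
    DEFAULT_PREFERENCE_BASE,
    SHORT_MOUTHPART,
    ContextPreset,
    default_presets,
    generate_session,
    generate_study,
    mean_site_preferences,
    with_concentration,
)

LONG_MOUTHPART = ("bumblebees", "Lepidoptera")
TUBULAR_IDX = [i for i, p in enumerate(PLANTS) if p in TUBULAR_PLANTS]
OPEN_IDX = [i for i, p in enumerate(PLANTS) if p not in TUBULAR_PLANTS]


def test_default_presets_cover_twelve_sites():
    config = default_presets()
    assert sum(p.n_sites for p in config.contexts) == 12
    assert len(config.contexts) == 4


def test_visit_rates_follow_the_urbanisation_ordering():
    rates = {p.context: p.visit_rate for p in default_presets().contexts}
    assert rates["urban"] < rates["semi-natural"]
    assert rates["suburban"] < rates["agricultural"]


def test_morphotype_mixes_are_probability_vectors():
    for preset in default_presets().contexts:
        assert preset.morphotype_mix.shape == (9,)
        assert np.all(preset.morphotype_mix >= 0)
        assert preset.morphotype_mix.sum() == pytest.approx(1.0)


def test_baseline_preferences_encode_mouthpart_matching():
    for i, morph in enumerate(MORPHOTYPES):
        row = DEFAULT_PREFERENCE_BASE[i]
        assert row.sum() == pytest.approx(1.0)
        if morph in LONG_MOUTHPART:
            assert row[TUBULAR_IDX].sum() >= 0.7
        elif morph in SHORT_MOUTHPART:
            assert row[OPEN_IDX].sum() >= 0.7


def test_sharpness_decreases_toward_urban_for_short_mouthpart_groups():
    kappas = {p.context: p.concentration for p in default_presets().contexts}
    assert kappas["semi-natural"] >= kappas["agricultural"] > kappas["suburban"] > kappas["urban"]


def test_zero_visit_rate_gives_empty_session():
    config = default_presets()
    preset = ContextPreset(
        context="urban", visit_rate=0.0,
        morphotype_mix=config.contexts[0].morphotype_mix,
        concentration=5.0,
    )
    prefs = mean_site_preferences(preset, config)
    rng = np.random.default_rng(0)
    assert generate_session(preset, "S", 1, "P", "systematic", prefs, rng) == []


def test_fixed_seed_reproduces_the_study_exactly():
    a = generate_study(default_presets(seed=42))
    b = generate_study(default_presets(seed=42))
    assert a == b


def test_session_totals_are_poisson_calibrated():
    """Semi-natural sessions: mean total visits within 1% of rate*minutes
    (= 161.0) over 10^4 sessions."""
    config = default_presets(seed=9)
    preset = next(p for p in config.contexts if p.context == "semi-natural")
    rng = np.random.default_rng(9)
    prefs = mean_site_preferences(preset, config)
    totals = [
        sum(r.visit_count
            for r in generate_session(preset, "S", 1, "P", "systematic", prefs, rng))
        for _ in range(10_000)
    ]
    assert np.mean(totals) == pytest.approx(161.0, rel=0.01)


def test_site_totals_match_closed_form_expectation():
    """Per-site expected total = rate * 10 min * 4 rounds * 4 plots; the
    seed-averaged observed totals must sit within 3 SE of it."""
    n_seeds = 30
    sums: dict[str, list[int]] = {}
    expected: dict[str, float] = {}
    for seed in range(n_seeds):
        records, sites = generate_study(default_presets(seed=seed))
        by_site: dict[str, int] = {}
        for r in records:
            by_site[r.site_id] = by_site.get(r.site_id, 0) + r.visit_count
        ctx_rate = {s.site_id: s.landscape_context for s in sites}
        config = default_presets()
        rates = {p.context: p.visit_rate for p in config.contexts}
        for sid, tot in by_site.items():
            sums.setdefault(sid, []).append(tot)
            expected[sid] = rates[ctx_rate[sid]] * 10 * 4 * 4
    for sid, vals in sums.items():
        mean_total = np.mean(vals)
        # Poisson SE of the mean over n_seeds independent studies
        se = np.sqrt(expected[sid] / n_seeds)
        assert abs(mean_total - expected[sid]) <= 3 * se


def test_study_covers_all_rounds_plots_and_configs(default_study):
    records, sites = default_study
    assert len(sites) == 12
    assert {r.round_index for r in records} == {1, 2, 3, 4}
    assert {r.spatial_config for r in records} == {"systematic", "random"}
    plots_per_site_config = {
        (r.site_id, r.spatial_config, r.plot_id) for r in records
    }
    # two plots per (site, configuration)
    for sid in {s.site_id for s in sites}:
        for cfg in ("systematic", "random"):
            plots = {p for s, c, p in plots_per_site_config if s == sid and c == cfg}
            assert len(plots) == 2


def test_context_not_spatially_clustered(default_study):
    """Sites of the same context should not form one spatial block: the
    mean within-context pairwise distance should be comparable to (not much
    smaller than) the overall mean distance."""
    _, sites = default_study
    coords = {s.site_id: np.array([s.x, s.y]) for s in sites}
    ctx = {s.site_id: s.landscape_context for s in sites}
    ids = list(coords)
    within, overall = [], []
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            d = np.linalg.norm(coords[a] - coords[b])
            overall.append(d)
            if ctx[a] == ctx[b]:
                within.append(d)
    assert np.mean(within) > 0.5 * np.mean(overall)


def test_generalism_monotone_in_preference_sharpness():
    """Mean weighted generalism of short-mouthpart morphotypes is
    non-increasing in kappa."""
    means = []
    for kappa in (0.5, 2, 10, 50):
        vals = []
        for seed in range(10):
            config = with_concentration(default_presets(seed=seed), kappa)
            records, sites = generate_study(config)
            for w in build_all_networks(records, sites):
                for m in SHORT_MOUTHPART:
                    if m in w.morphotype_labels and w.column(m).sum() > 0:
                        vals.append(weighted_generalism(w, m))
        means.append(np.mean(vals))
    assert all(a >= b for a, b in zip(means, means[1:]))


def test_large_kappa_generalism_approaches_baseline_shannon():
    """kappa -> infinity pins site preferences to the baseline rows, so
    weighted generalism converges to the Shannon index of the baseline
    (up to residual site noise and finite-count bias)."""
    H_base = {
        m: float(-(row[row > 0] * np.log(row[row > 0])).sum())
        for m, row in zip(MORPHOTYPES, DEFAULT_PREFERENCE_BASE)
    }
    diffs = []
    for seed in range(5):
        config = with_concentration(default_presets(seed=seed), 1e7)
        records, sites = generate_study(config)
        for w in build_all_networks(records, sites):
            for m in SHORT_MOUTHPART:
                if m in w.morphotype_labels and w.column(m).sum() > 200:
                    diffs.append(weighted_generalism(w, m) - H_base[m])
    assert abs(np.mean(diffs)) < 0.08
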