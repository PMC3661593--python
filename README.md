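# pollinet

Quantitative plant–pollinator network analysis along an urbanisation
gradient.

`pollinet` is for ecologists analysing standardised visitation surveys: an
experimental community of five plant species (three tubular-flowered, two
open-flowered) observed at sites spanning semi-natural, agricultural,
suburban and urban landscape contexts, with flower visitors recorded as
nine morphological functional groups ("morphotypes"). From per-session
visit counts it builds cumulated bipartite webs — one per site and plot
spatial configuration, 24 for a full 12-site study — and computes:

- **Interaction evenness**: Shannon evenness of edge weights over realised
  links only, `H / ln L` with `H = −Σ p_ij ln p_ij` over the `L` nonzero
  cells of the web matrix `A`; 1 means uniformly distributed interactions.
- **Visitor generalism**: qualitative (degree — number of plant species
  visited) and weighted (Shannon index of the visit distribution, in nats).
- **Reproductive-success index**: per plant,
  `R_f = Σ_p P²_{p,f} · V_p = Σ_p A²_{f,p} / V_p`, crediting only
  consecutive same-species visits (flower constancy) as potential
  pollination events; summed per floral functional group (open/tubular).
- **Statistics**: Pearson chi-squared homogeneity tests of visit
  distributions, Bray–Curtis similarity, a seeded Mantel permutation test
  for spatial autocorrelation, and permutation comparisons of per-web
  metrics between landscape contexts (a labelled surrogate for mixed-model
  contrasts, which are out of scope).
- **A calibrated synthetic-study generator** reproducing the field design
  (Poisson session totals at context-specific visit rates,
  mouthpart-matched floral preferences, urbanisation-dependent generalism)
  so every stage is testable without field data.

## Worked example

Generate a synthetic study with the default presets and analyse it:

```sh
pollinet generate --seed 1 --out demo
```

`demo/context_summary.tsv` then contains (abridged):

```
landscape_context   metric               mean          sd            n
semi-natural        total_interactions   1275.166667   22.76327452   6
agricultural        total_interactions   1017.333333   45.65815006   6
suburban            total_interactions   328.5         13.1415372    6
urban               total_interactions   343.5         11.11305539   6
```

Each row summarises the six webs of one context. Semi-natural webs carry
roughly 1275 interactions against ~343 in urban webs — the generator's
built-in visit-rate gradient (16.10 vs 4.23 visits·min⁻¹), recovered by the
pipeline. `demo/context_comparisons.tsv` shows the corresponding
permutation tests (e.g. semi-natural vs urban total interactions:
mean difference 931.7, p = 0.002 at 999 permutations), and
`demo/mantel.tsv` reports the spatial-autocorrelation check
(r = −0.136, p = 0.161 — null retained, as designed: contexts are laid out
on a shuffled grid).

The packaged pooled study totals run without any input:

```sh
pollinet fixture --out fx
```

`fx/fixture_summary.tsv` reports 17 857 total interactions across the nine
morphotypes, interaction evenness 0.670, and per-morphotype shares
(solitary bees 28.2%, Syrphidae 26.8%, other flies 9.4%, …).

Existing data are analysed with
`pollinet analyze --records records.csv --sites sites.csv --out results`;
the input dialects are documented in `pollinet.io`.

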