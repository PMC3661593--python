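# Methods

## The system and the data model

`pollinet` analyses quantitative plant–pollinator visitation networks from a
standardised field design: an experimental community of five plant species —
three with tubular corollas (*Medicago sativa*, *Consolida regalis*, *Lotus
corniculatus*) and two with open corollas (*Matricaria inodora*, *Sinapis
arvensis*) — exposed at twelve sites spanning a four-level urbanisation
gradient (semi-natural, agricultural, suburban, urban; three sites each).
Flower visitors are binned into nine morphological functional groups
("morphotypes") because field identification below that level is unreliable.
Each site holds four plots, two per spatial configuration (systematic vs
random planting); observation consists of four rounds of 10-minute sessions
per plot.

The atomic datum is an aggregated visit count per
(site, round, plot, plant, morphotype) cell — not individual visit events —
because every downstream formula consumes counts. A 0–6 flowering-quality
indicator per plant and session is parsed and carried through for reporting
but never enters any computation here (its only analytical use is as a
covariate in model-based analyses that are outside this package's scope).

## Webs

A web is the matrix `A` (plants × morphotypes) of visit counts cumulated
over all rounds and over both plots of one spatial configuration at one
site; cumulation removes flowering asynchrony between rounds. A complete
study yields 12 × 2 = 24 webs. Cumulation conserves totals (the matrix sum
equals the sum of selected record counts), and building all webs partitions
the record set — both are tested properties. An empty selection is an error
distinct from a legitimately all-zero web. Matrix row/column order follows
the canonical species lists (unknown labels, which are accepted with a
warning, append in first-appearance order), so serialised output is
byte-stable.

## Indices

All Shannon quantities use natural logarithms; zero cells are excluded from
every Shannon sum (equivalently 0·ln 0 := 0).

**Interaction evenness.** With `p_ij = A_ij / total` over the `L` realised
(nonzero) links only, evenness is `H / ln L` with `H = −Σ p_ij ln p_ij`. It
is 1 iff all realised links carry equal weight, and is invariant to scaling
all counts. For `L ≤ 1` the normaliser vanishes; evenness is then *undefined*
(an error), deliberately neither 0 nor 1 — there is no principled value.

**Generalism.** Qualitative generalism of a morphotype is its degree (number
of plant species visited). Weighted generalism is the Shannon index (nats)
of its visit distribution `P` across plants: 0 for a perfect specialist,
`ln k` for `k` equally visited plants, and always `≤ ln(degree)`. Raw
weighted generalism is base-dependent; the package reports nats and makes no
cross-study numerical comparison of this quantity. Morphotypes with zero
visits in a web are excluded from generalism summaries and logged.

**Reproductive-success (RS) index.** Pollination needs conspecific pollen,
so only same-species consecutive visits (flower constancy) are credited.
Modelling a visitor group's choices as i.i.d. draws from its empirical visit
distribution `P`, the probability that two successive visits hit plant `f`
is `P_f²`; scaling by the group's visit total `V` (a proxy for the number of
foraging individuals/opportunities) and summing over groups gives

    R_f = Σ_p P_{p,f}² · V_p = Σ_p A_{f,p}² / V_p .

A specialist group contributes exactly `V`; by Cauchy–Schwarz no group can
contribute more than its `V`. A functional group's index is the sum over its
member plants, so open + tubular equals the total over plants. Zero-visit
columns contribute zero rather than erroring, keeping sparse urban webs
computable. The index is computed per web (site × configuration) and then
compared across contexts; computing it on context-pooled webs instead would
be a different, coarser choice — per-web matches the replication level of
every other per-web metric here. For a sequence of `N` i.i.d. choices the
expected number of immediate same-plant repeats is `(N−1)·ΣP²` while the
index uses `N·ΣP²`; the relative difference vanishes as `N` grows, which a
Monte-Carlo test verifies. No within-sequence autocorrelation is modelled:
the index *is* the i.i.d. approximation.

## Statistics

- **Pearson chi-squared** homogeneity tests (plants × contexts per
  morphotype): expected counts from marginal products, no continuity
  correction, asymptotic upper-tail p (delegated to
  `scipy.stats.chi2_contingency`). A zero marginal is a degenerate-table
  error. A 5-plant × 4-context table has df = 12.
- **Bray–Curtis similarity** `1 − Σ|u−v| / Σ(u+v)` on raw count vectors
  (not proportions); undefined for two all-zero vectors. The pipeline's
  site-dissimilarity matrix uses per-site morphotype totals (nine-element
  community vectors); the plant × morphotype cell vector is available by
  calling the function on flattened webs instead.
- **Mantel test** between geographic and community-dissimilarity distance
  matrices: Pearson correlation of upper triangles (Spearman available),
  two-sided on |r|, joint row/column permutation of the second matrix.
  Sampled p uses the add-one convention `(1 + exceedances) / (1 + n_perm)`
  (999 permutations by default), so p is never 0; an exhaustive mode
  enumerates all n! relabellings for exact small-n p-values. Tie comparison
  uses an absolute tolerance of 1e-12.
- **Permutation context comparison**: for each context pair, a two-sided
  permutation test on the difference of means of a per-web metric under
  random relabelling (exact enumeration of the C(n, n1) assignments on
  request). This is a deliberately assumption-free *surrogate* for
  mixed-model contrasts (GLMM/LMM with Tukey post-hocs are out of scope) and
  every output row is labelled "permutation surrogate" so it cannot be
  mistaken for a model-based p-value.

## Synthetic-study generator

The generator exists so the whole pipeline is testable without field data.
What it emulates, with defaults frozen to the study conditions:

- **Visit intensity**: session totals are Poisson(rate × 10 min) with
  context rates 16.10, 12.73, 4.08 and 4.23 visits·min⁻¹ (semi-natural,
  agricultural, suburban, urban) — the field calibration.
- **Community composition**: each visit draws a morphotype from a context
  mix derived from the pooled study shares (31.2% bumblebees, 28.2% solitary
  bees, 26.8% Syrphidae, …). Bumblebees and *Apis mellifera* keep a constant
  expected absolute visit rate across contexts — their visitation did not
  respond to urbanisation — so their *share* grows as the urban visit pool
  shrinks; the other seven groups scale with the context rate. No
  per-context count table exists to calibrate against, so these mixes are
  illustrative beyond the pooled shares.
- **Floral preference**: each morphotype has a baseline preference row over
  the five plants encoding mouthpart/corolla matching (bumblebees and
  Lepidoptera ≥ 0.7 mass on tubular plants; solitary bees, Syrphidae, other
  flies, Coleoptera and bugs ≥ 0.7 on open plants). A context's preference
  sharpness κ shrinks the mean realised preference toward the baseline,
  `m = (κ·base + uniform)/(κ + 1)`, and each site draws its realised row
  from Dirichlet(c₀·m) with fixed site-noise concentration c₀ = 100. This
  parameterisation was chosen over a plain Dirichlet(κ·base) because it
  gives κ the two properties the recovery tests need: weighted generalism is
  monotonically non-increasing in κ (small κ flattens preferences toward
  uniform), and as κ → ∞ generalism converges to the Shannon index of the
  baseline row (a plain Dirichlet concentration conflates sharpness with
  site noise and makes low-κ samples spiky, i.e. *more* specialised).
  Defaults: κ = 50/40/8/3 from semi-natural to urban for the five
  short-mouthpart groups, κ = 50 fixed for the rest — urbanisation
  flattens the diet of short-mouthpart visitors only.
- **Spatial layout**: sites sit on a 1 km grid with contexts assigned to
  cells by a seeded shuffle, so context is not spatially clustered and the
  Mantel no-autocorrelation null holds by construction.
- **Reproducibility**: one root seed; `numpy.random.SeedSequence.spawn`
  derives one child stream for the layout and one per site (preset order),
  so any site regenerates independently and a fixed seed reproduces the
  study byte-for-byte through the pipeline.

What it does **not** emulate: temporal flower-constancy autocorrelation
within foraging sequences (deliberately — the RS index approximates
constancy from marginal counts, and baking sequence correlation into the
generator would make that recovery test circular), weather and flowering
covariates, agent-based foraging, and reward dynamics. Passing recovery
tests therefore show that the pipeline detects the rate/preference structure
it assumes, not that real urban foraging obeys Poisson-multinomial sampling.

## Numerical and design choices

- Permutation p-values: add-one convention when sampling; exact enumeration
  counts the identity, so exhaustive p ≥ 1/n!.
- Statistic ties in permutation tests use a 1e-12 absolute tolerance.
- Evenness/generalism of undefined cases raise typed errors rather than
  returning sentinels; pipeline tables simply omit those rows with a
  warning.
- Chi-squared p-values are floored at the smallest positive float so the
  reported p is always in (0, 1].
- Context summaries use the sample SD (ddof = 1); a single-web context
  reports SD as NaN.
- Equal observation effort across the two plots of a configuration is
  assumed (the design gives no reason to weight them).
- Test problem sizes (e.g. 100 seeded studies for the effect-direction
  check, 500 replicates for the chi-squared calibration, 20 seeds per κ for
  the monotonicity sweep) were chosen so that simulation standard errors are
  several times smaller than the margins being asserted.

## Known limitations

- The RS index is a potential-reproduction proxy; it is not validated here
  against fruit or seed set.
- Raw weighted generalism values are not comparable across studies that use
  a different logarithm base.
- The generator's per-context morphotype mixes and preference baselines are
  qualitative calibrations; only visit rates and pooled shares are anchored
  to published numbers.
- GIS land-cover work, insect taxonomy and model-based (GLMM/LMM) inference
  are out of scope.
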