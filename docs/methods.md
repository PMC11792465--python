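# Methods

`foodtrace` implements a workflow for deciding which compounds in an
ingested extract reach host plasma and how their plasma abundances relate to
the gut microbiome. The workflow has three layers: targeted LC-MS compound
tracking, phylogenetic diversity computation, and a battery of
compound-level statistical screens designed around a small, pseudoreplicated
animal design (replicate mice per donor microbiome). This note records the
models, the tunable parameters, the numerical choices, and what the
synthetic data generator does and does not establish.

## Compound tracking

Tracking operates on vendor-export feature lists (compound id, neutral mass,
retention time, fraction, M1/M2 peak areas), not raw spectra; spectral
deconvolution and database annotation are upstream concerns.

1. **Extract list.** A feature belongs to the extract compound list iff it is
   matched (mass within the ppm window and RT within the RT window) in 100%
   of extract replicate injections, elutes before `extract_rt_max`, and is
   matched in no preparatory blank. The representative mass/RT/isotope areas
   are arithmetic means over the per-replicate matches — with four or fewer
   replicates the mean is as stable a consensus as any.
2. **Plasma matching.** For each extract compound and plasma sample, the best
   candidate within 10 ppm and ±0.2 min is taken; candidates further than
   0.3 min from the extract consensus RT are rejected outright (the outlier
   rule dominates any widened window). When both records carry an M2 peak,
   the observed M2/M1 ratio must sit within 20% (relative) of the extract's
   own observed ratio; a plasma record with no M2 peak is not penalized.
   A recorded second charge carrier is checked as a qualifier (equality
   within the ppm window) but never quantified. Ties break by smallest
   |Δppm|, then |ΔRT|, then compound id, so output is deterministic.
3. **Detection filter.** A compound is kept if at least `min_samples` (3)
   plasma samples show an area at or above the fraction floor — 20,000
   counts (aqueous) / 55,000 counts (lipid); the boundary is inclusive.
   Sub-threshold areas of surviving compounds are preserved untouched.
4. **Baseline subtraction.** Any compound matched (same mass+RT rule) in any
   plasma sample from animals never given the extract is removed. The
   `TrackingReport` asserts the conservation identity
   `retained = detected − baseline_removed` per fraction and in total.

Per-fraction RT ceilings (10.4 min lipid, 13 min aqueous) are applied to
plasma records at load time; the extract ceiling (10 min) when the extract
list is defined. All windows and floors live in `MatchParams` and are
configurable.

## Diversity

Faith's PD and unweighted UniFrac share one spanning convention: a community
spans every branch whose subtree contains at least one present tip,
*including* the stem(s) up to the root. PD is the summed length of the
spanned set; UniFrac(i, j) is (length spanned by exactly one of i, j) /
(length spanned by either). Implementations differ on root handling, so the
convention is fixed here explicitly; using the same rule in both keeps the
two metrics mutually consistent. The implementation builds a branch × tip
membership matrix in one postorder pass; the test suite checks it against a
brute-force enumerator that walks the tree API independently.

Rarefaction subsamples each sample without replacement (multivariate
hypergeometric) to a fixed depth — default 40,625 reads, a depth the
synthetic generator guarantees never excludes a sample — processing samples
in label order under a single seeded generator. UniFrac and PD are computed
on the rarefied table; Bray-Curtis on raw compound areas (only the
microbiome side is rarefied, since read depth is a sequencing artifact while
peak areas are the quantity of interest).

## Centroid collapsing and PERMANOVA

With two replicate mice per donor, mice are pseudoreplicates. Before any
permutation-based test, samples are collapsed to one centroid per treatment
unit (donor for humanized mice, experimental cohort for low-complexity
controls; 29 mice → 13 units). Between-centroid distances use the
distance-only identity

    d²(C_A, C_B) = mean d²(a, b) − ½ mean d²(a, a′) − ½ mean d²(b, b′)

which reproduces coordinate-mean centroids exactly for Euclidean-embeddable
matrices. Unweighted UniFrac need not be Euclidean-embeddable; a negative
squared centroid distance is clipped to 0 with a logged warning.
Abundances and diversity values are collapsed by arithmetic means.

PERMANOVA uses the McArdle–Anderson trace partition of the Gower-centered
matrix G = −½ J D² J. For a single continuous covariate the explained trace
reduces to x̃ᵀGx̃ / x̃ᵀx̃ with the predictor centered (q = 1); categorical
predictors are dummy-coded. The permutation scheme shuffles predictor rows
without restriction — valid precisely because the test runs on collapsed
centroids, which was the point of collapsing. P-values carry the
add-one correction (b + 1)/(m + 1).

## Procrustes randomization test

PCoA eigendecomposes G; axes with negative eigenvalues are dropped and their
total magnitude reported (`proportion_explained` is normalized by positive
plus |negative| mass so it never exceeds 1). Procrustes centers both
configurations, scales each to unit sum of squares, zero-pads to a common
column count, and finds the orthogonal map (reflections allowed) minimizing
the residual; the minimized residual m² = 1 − (Σσ)² lies in [0, 1]. The
randomization test permutes the target's row order (which rows pair with
which is the null being broken), counts permuted m² ≤ observed m², and uses
the add-one correction — at 10⁴ permutations the difference from the raw
proportion is ≤ 10⁻⁴. All retained PCoA axes enter; no axis cut is imposed.

## Regression screens

**Diversity screen.** Per compound: z-scored abundance regressed on Faith's
PD across all mice, with CR1 cluster-robust standard errors (clusters =
treatment units; small-sample factor G/(G−1) × (n−1)/(n−k); t reference
with G−1 df). The regression direction means the effect is SDs of compound
per PD unit. A regression containing any point with |DFFITS| > 1
(externally studentized) is excluded before BH adjustment. On a bimodal
diversity distribution (a low-diversity control cluster far from the
humanized cluster) the low-diversity points carry high leverage, so this
rule occasionally removes even a genuinely associated compound; that is the
rule operating as specified, not a failure mode.

**Taxon screen.** Per (compound, taxon) pair:

    z(compound) ~ β · arcsinh(100 · rel_abund) + (1 | treatment unit) + ε

fit by REML. The variance ratio λ = σ²ᵤ/σ²ₑ is profiled out of the REML
criterion (per-group sufficient statistics make each evaluation O(n)),
optimized on a log grid refined by bounded scalar minimization, with the
λ = 0 boundary always a candidate. At the boundary the fit is exactly OLS
and inference uses the residual df. Otherwise the Wald t for β uses
Satterthwaite's approximation: df = 2C²/(gᵀ A g) with C = Var(β̂) as a
function of θ = (σ²ᵤ, σ²ₑ), g its numerical gradient, and A the inverse
observed REML information of θ (central finite differences). On numerical
failure the df falls back to G − 1 and the row is flagged. The fit matches
lme4/lmerTest to ~1e−9 on β and SE and ~1e−4 on df on a frozen reference
dataset (see `tests/test_regression.py`).

Influence exclusion refits the model with each observation deleted and
standardizes the change in β̂ by se(β̂); a pair whose maximum influence
reaches 4 is dropped. Exact refitting is feasible at this scale and avoids
committing to one closed-form approximation of the mixed-model delta family.

## Balance selection

A balance over disjoint taxon sets (p in the numerator, q in the
denominator) is √(pq/(p+q)) · (mean ln xᵢ − mean ln xⱼ) on relative
abundances with a pseudocount of half the smallest nonzero relative
abundance (logged and configurable). The search is greedy: all singleton
pairs scored by regression R², orientation chosen so the slope is positive,
ties broken lexicographically; then single-taxon forward additions to either
side until no improvement or `max_size`. Cross-validation repeats the whole
selection inside each training fold (honest CV); below 2 × folds samples
the folds degenerate to leave-one-out, which is how a nominally 10-fold
protocol behaves at 13 units. Negative CV R² for noise responses is
expected and is the overfitting signal the CV exists to expose.

## Synthetic data generator

The generator emulates the study conditions: 10 donor microbiomes × 2
replicate mice + 9 low-complexity mice in 3 cohorts; sequencing depths
uniform on [40,625, 80,000] so the standard rarefaction depth excludes no
sample; a random bifurcating phylogeny with exponential branch lengths;
per-donor Dirichlet base compositions (subset inclusion 0.4, concentration
0.6 — chosen once to give replicate pairs visibly closer than different
donors under unweighted UniFrac); and a low-complexity community in which
six phylogenetically clustered ASVs carry 93% of the mass. Compound effects
are injected on a z-score latent scale — matching the screens'
parameterization — and mapped affinely to positive peak areas (base 5×10⁵,
scale 8×10⁴ counts, comfortably above the detection floors). LC-MS feature
lists displace true plasma features by ≤ 5 ppm and ≤ 0.1 min and decoys by
> 15 ppm or > 0.5 min; blank contaminants appear in all extracts and
blanks; designated baseline compounds also appear in baseline plasma.
Everything planted is recorded in a `GroundTruth` ledger, and identical
config + seed reproduces byte-identical worlds.

What passing tests show: the arithmetic and algorithms are correct (oracle
equivalence), the permutation tests hold their size, planted effects of
realistic magnitude are recovered, and the filters accept no decoys. What
they do not show: robustness to compositional artifacts beyond the planted
structure, chimeras/contamination in reads, realistic isotope envelopes,
annotation ambiguity, or batch effects — none of which the generator
emulates.

## Problem sizes and determinism

Default analysis sizes (29 samples, 120 ASVs, 40 compounds, 15 screen taxa,
10⁴ permutations) keep a full run in the low minutes on one core; the
validation benchmarks use 50 oracle instances, 200 calibration replicates at
999 permutations, and 500/100 recovery replicates. Every stochastic step
takes an explicit seed; derived seeds are drawn below 2³¹ from a single
parent generator per run.

## Known limitations

- The LMM supports exactly one random intercept and one fixed slope — the
  screen's model — not general mixed designs.
- PERMANOVA is single-predictor (no interactions, no strata-restricted
  permutations); PERMDISP-style dispersion tests are not provided.
- The balance search is greedy, not exhaustive, so it inherits selbal-style
  local-optimum behavior when taxa are collinear.
- Matching works on feature lists; nothing is re-extracted from spectra, so
  a feature missed upstream is invisible here.
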