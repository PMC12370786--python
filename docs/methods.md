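# Methods

`hoppertraits` implements a trait-based analysis of how generalist insect
herbivores (grasshoppers, Acrididae) assemble into communities and partition
feeding niches, together with a synthetic-data generator that produces inputs
with the statistical structure the analysis assumes. This note documents the
models, the parameter choices, and the design decisions taken where more than
one reasonable option existed.

## Trait equations

Three functional traits are derived per specimen:

* **Body volume** `V = (π/4)·L·D²` (mm³), with `L` the head-to-abdomen length
  and `D` the arithmetic mean of four body diameters (head, thorax, abdomen
  base, abdomen tip). The mean is taken *before* squaring; this is the natural
  reading of "mean diameter" and is fixed as the convention here.
* **Incisor strength** `F_in·L_in / (L_out·R_i)`, a mandible lever index of
  bite force with head volume standing in for the adductor-muscle force
  `F_in`, `L_in`/`L_out` the in- and out-lever arm lengths and `R_i` the
  length of the incisive region. Units cancel only partially, so the value is
  treated as a relative (unitless) index throughout.
* **C:N ratio** `%C / %N`, a mass ratio (elemental analyzers report mass
  percent; no molar conversion is applied).

Traits are averaged across individuals (sexes pooled) to a species trait
table. For correlation, ordination and distance computations, body volume and
incisor strength are natural-log transformed (right-skewed across species);
C:N enters raw. PCA is computed as the eigendecomposition of the
**correlation** matrix — the traits carry incommensurate units — with the
sign convention that each component's largest-magnitude loading is positive.
Near-zero eigenvalues of rank-deficient inputs are dropped.

## Functional dispersion and the trait-shuffle null

Community trait dispersion is measured by Rao's quadratic entropy
`Q = Σ_i Σ_j p_i p_j d_ij`, the expected trait distance between two random
individuals of a community row, with `p` the within-row relative abundances
(abundance-weighted by default; presence-based weighting is available via
`presence_only=True`).

Distances are **Gower**: each numeric trait is range-normalised to [0, 1]
and contributes an absolute difference; the categorical subfamily contributes
0/1; multi-trait sets average contributions with equal weight. Gower was
chosen because it treats the mixed numeric/categorical trait sets uniformly
and is the convention of the functional-dispersion literature; the analysis
is run for "all" (the three numeric traits), each single trait, and subfamily
as a coarse phylogenetic proxy. Whether "all" should also include subfamily
is genuinely ambiguous; the default excludes it (subfamily is analysed
separately), and `include_subfamily_in_all=True` exposes the other reading.
A constant trait has zero range and contributes zero distance (with a
warning) rather than failing.

The null model shuffles the species labels of the trait table — equivalently
permutes rows/columns of the distance matrix — keeping abundances and
richness fixed within every row. With 999 replicates, each row's standardized
effect size is `SES = (Q_obs − mean Q_null)/sd Q_null`; negative values
indicate trait clustering (under-dispersion, the filtering signature),
positive values over-dispersion (limiting similarity). One permutation per
replicate is shared across all rows, so a replicate is one coherent simulated
community set; `per_row_shuffle=True` draws independent permutations per row.
Because the global design shares nulls across rows, row SES values are
positively correlated and the dispersion of the *mean* SES across repeated
experiments is somewhat wider than the naive SE suggests; the calibration
tests therefore use seeded designs. Rows with null SD = 0 (e.g.
single-species rows) get an undefined SES and are excluded from summaries,
never coerced to 0.

SES values are summarised per trait set (optionally per sampling period)
with mean, SE and a one-sample two-sided t-test against zero. A mixed-model
treatment of the site structure is deliberately out of scope; the grouped
t-tests are the supported summary.

## Feeding niches and trait matching

From the cafeteria (mesocosm) consumption matrix, each individual's diet is
summarised by consumption-weighted means `CWM = Σ_i p_i·trait_i` over the
plants it ate, with `p_i` the proportion of its total consumed leaf area —
the only normalisation that makes CWM a weighted mean, hence bounded by the
consumed plants' trait range. Plant traits (LDMC mg g⁻¹, SLA mm² mg⁻¹, C:N)
enter untransformed. Individuals that ate nothing have undefined weights and
are excluded with a warning.

Diet differentiation among species or subfamilies is tested per plant trait
with a one-way F statistic whose p-value comes from `n_perm` random label
permutations: `p = (b+1)/(n_perm+1)` with `b` the number of null statistics
at or above the observed, so the attainable minimum is `1/(n_perm+1)`.

Trait matching regresses individual CWMs on the species-mean herbivore trait
(logged for body volume and incisor strength) for the three hypothesised
linkages — incisor strength↔LDMC, grasshopper C:N↔plant C:N, body
volume↔plant C:N — with **subfamily fixed intercepts**. A random-intercept
model is weakly identified with only four subfamilies; fixed intercepts keep
the estimate interpretable and the stack dependency-light. A subfamily
contributing a single species cannot separate its intercept from its trait
value and is merged into the reference level with a warning.

## Synthetic-data generator

The generator emulates the study conditions: 14 grasshopper species spanning
4 subfamilies with ~20 measured individuals each, 30 sites × 2 sampling
periods, 16 plant species, ~12 cafeteria replicates per species, and areas
quantised to the 0.05-cm² recording grid.

**Species pool.** Species-mean (log body volume, log incisor strength, C:N)
vectors are multivariate normal with correlation targets (+0.78, −0.69,
−0.74) — the trait-syndrome structure of the study system used as generator
parameters — marginal SDs (0.9, 0.7, 0.8) and means (6.0, 1.5, 4.5), i.e.
body volumes of a few hundred mm³ and C:N around 4.5. Subfamilies are
assigned at random by default (no trait signal, the right null for the
dispersion analyses) or blocked along the incisor-strength axis
(`by_trait`), emulating the real guild structure, for feeding-niche
demonstrations. Within-species deviations use the same correlation matrix
with SDs (0.20, 0.20, 0.35); zero SDs are permitted as a degenerate case.

**Back-solve.** Raw morphometrics are constructed so the trait equations
invert exactly: all diameters 1 mm with `L = 4V/π`; unit lever arms with
head volume equal to the incisor-strength value; `%N = 10` with
`%C = 10·C:N`. The trait equations applied to generated specimens therefore
reproduce the latent draws to round-off, making the full
specimens→species-means path exactly testable.

**Community assembly.** Each row draws a richness uniformly from 2–8 (the
field abundance/richness distributions are not published; these defaults
were chosen once to give realistic sweep-net-like communities), selects
species by the configured rule, and assigns geometric (log-series-like)
abundances. Filtering draws a per-row optimum uniformly over the
standardised trait range and weights species by
`exp(−s²·‖z−z_site‖²/2)`. Competition assembles greedily, rejecting
candidates whose minimum standardised trait distance to residents is below
`s` and choosing among admissible candidates with softmax weight
`exp(2·s·d_min)`. The softmax preference is part of the design because a
pure hard-threshold rule saturates: thresholds strong enough to produce a
reliably detectable over-dispersion signal at richness 8/14 are infeasible
(no species set satisfies them), while feasible thresholds leave the signal
too weak for consistent directional detection at the 60-row design.
`s = 0` reduces both rules exactly to neutral. Infeasible rows are retried
50 times, then fail with a diagnostic.

**Calibrated strengths.** `CALIBRATED_STRENGTH = {filtering: 2.0,
competition: 0.7}` were fixed by a pilot grid (20 seeds × 60-row design):
both give a significantly signed mean SES in 20/20 replicates, sit below the
saturation/feasibility limits, and leave mean SES monotone in strength over
the grids used in the tests.

**Plants and feeding.** LDMC and SLA are drawn through a Gaussian copula
with correlation −0.7 mapped onto (150–450 mg g⁻¹, 5–30 mm² mg⁻¹) — the
leaf-economics association in which tough leaves have low SLA — and plant
C:N is uniform on 10–60. Consumption follows a log-linear preference kernel
on standardised traits, `exp(β_IS·z_IS·z_LDMC + β_CN·z_CN·z_pCN +
β_BV·z_BV·z_pCN + ε)`, with lognormal noise (`noise_sd = 0.5`), scaled to 8
cm² per 48-h trial and quantised to 0.05 cm². Defaults `β = (0.8, −0.5,
+0.4)` reproduce the signs of the reported linkages at realistic (modest)
effect sizes. A row that quantises to all zeros is regenerated once, then
flagged `no_feeding`.

**What the generator does not emulate:** fire history and plant regrowth,
phenology, nymph identification, observation error in the morphometrics,
spatial autocorrelation among sites, and within-individual feeding dynamics.
Passing tests therefore demonstrate that the statistical machinery recovers
known structure under the design's sampling noise — not that the biological
conclusions would survive those unmodelled features.

## Numerical choices

* RNG: `numpy.random.default_rng`; every generator takes an explicit seed and
  the pipeline derives per-stage substreams via `SeedSequence`, so fixed
  seed ⇒ byte-identical CSVs.
* The kernel-implied trait-matching slope has no convenient closed form
  (quantisation and lognormal noise intervene); the reference value is
  computed by a large-n Monte Carlo (3000 replicates per species) and the
  study-scale estimate is checked by CI coverage against it.
* Permutation p-values use the add-one convention; F statistics with zero
  within-group variance are reported as degenerate (p = 1 when between-group
  variance is also zero).
* Eigenvalues below `1e-10` of the total variance are treated as zero
  (rank-deficiency cut-off).
* Problem sizes in the test suite (null counts of 199–999, 20-replicate
  detection runs, 100-replicate coverage runs) were chosen as the smallest
  designs at which the checked properties are stable across seeds.

## Known limitations

* SES row correlation under the shared-permutation null design (see above)
  means grouped t-tests are slightly anti-conservative; the per-row option
  removes this at the cost of departing from the single-shuffled-table
  reading of the null.
* With 14 species the sampling noise of a Pearson correlation is large
  (SE ≈ 0.12–0.25); correlation-recovery checks are run at 120–200 species,
  where they have power.
* The trait-matching model treats species-mean herbivore traits as fixed
  (no measurement-error-in-x correction), matching the original analysis.
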