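# Methods

`paleocomm` implements the quantitative core of census-style community
ecology for mapped assemblages of sessile benthic organisms — the kind of
data produced by digitising Ediacaran (Avalon-type) bedding-plane
surfaces, where every specimen's position, part measurements and taxonomic
identity are recorded on a single fossilised seafloor.  This note
documents the models, the conventions adopted where the underlying
field practice leaves choices open, and what the synthetic-data tests do
and do not demonstrate.

## Data model and derived geometry

A surface is a rectangle of mapped seafloor (metres) carrying specimens
with optional disc, stem and frond measurements (millimetres).  Three
per-specimen quantities are derived:

* **Height.** Reclining forms (e.g. *Fractofusus*) rest on the substrate;
  their vertical reach is taken as one-third of the frond width (falling
  back to disc width).  All other forms reach
  `stem_length + frond_length`, with a missing part contributing zero.
  Bush- and comb-like forms (*Bradgatia*, *Pectinifrons*) are treated as
  erect with stem length zero unless a stem was measured.
* **Uptake interval.** The vertical band occupied by the branching
  (feeding/exchange) portion: `[0, height]` for recliners — their
  branches sit at substrate level — and `[stem_length, height]` for
  erect forms.
* **Areal coverage** (biomass proxy). Sum of the disc and frond ellipse
  areas `π/4 · length · width` plus the stem rectangle
  `stem_length · stem_width`.  Digitised outlines would be preferable
  but are not generally tabulated; the ellipse/rectangle proxy is
  reproducible from the standard measurement set.  Specimens with no
  measurable part get height and coverage zero and are flagged.

### Retrodeformation

Tectonically sheared surfaces are restored using holdfast-disc
ellipticity.  Discs with both axes measured and mean diameter > 10 mm
calibrate the strain: their axial-circular mean long-axis orientation
`θ` and mean axial ratio `R`.  The correction is the area-preserving
inverse pure shear `Rot(θ) · diag(1/√R, √R) · Rot(−θ)`, applied about the
map centre to coordinates and — via an exact 2×2 SVD — to the disc
ellipses themselves.  Stem and frond measurements carry no recorded
orientation and are left unchanged; because strain factors here are
modest (≲1.5) this biases lengths by at most ~√R on unfavourably
oriented parts, which affects neither counts nor ratios of like-oriented
comparisons and is noted as a limitation.  Fewer than `n_min = 10`
qualifying discs (configurable) makes the calibration unreliable; such
surfaces are returned unchanged and flagged.  The transform has unit
determinant, so total areal coverage is exactly invariant, and applying
it after a known forward shear restores inter-point distances and
near-unit disc ratios (verified to 1% / 5% in the tests).

## Spatial jackknife

Compositional variability within a surface is estimated by repeatedly
(default 1,000×) subsampling 66% of the mapped *area*: a square box grows
around a uniformly seeded centre point; a side that reaches the surface
edge freezes while the others continue; growth halts when the captured
area fraction reaches the target.  Because the captured area of the
clipped square is continuous and strictly monotone in the box half-size,
the halting box is computed directly as the root of
`area(t) − 0.66 · A` (Brent's method, relative tolerance 1e-12) rather
than by stepping a discrete increment — the two formulations agree in
the limit of small steps and the root form removes the step-size
parameter.  Boundary specimens are included (closed intervals).  Samples
are drawn independently and may overlap.  For a spatially uniform
pattern the expected included-specimen fraction equals the area fraction;
this Monte-Carlo identity is checked at n = 10,000 points.

## Composition analyses

Count tables are built per community (a full surface or one jackknife
replicate) at species, genus or morphogroup level; records unidentifiable
at the requested level keep their finest available label as their own
column.  Poorly preserved ("effaced") fronds are handled by four
treatments: dropped (standard); kept as one pseudo-taxon; randomly
relabelled in proportion to the community's identified composition
(count-conserving; the draw is per community); or mapped to a best-guess
identity with the remainder dropped.

* **Dissimilarity.** Bray–Curtis, `Σ|aᵢ−bᵢ| / Σ(aᵢ+bᵢ)`.
* **Ordination.** Non-metric MDS (Kruskal stress-1) on the Bray–Curtis
  matrix, 20 random restarts by default, 300 iterations, convergence
  1e-7, best restart kept, deterministic under a fixed seed.  Jackknife
  ordinations use counts; a per-surface cap on replicates entering the
  ordination (pipeline default 100) keeps the distance matrix tractable,
  mirroring how such ordinations are usually plotted.
* **Clustering.** Agglomerative UPGMA (average linkage) on Bray–Curtis
  distances of full-surface relative abundances; the linkage is exposed
  as configuration since textbook practice varies.  Dendrograms export
  to Newick.
* **Stage prediction.** A linear discriminant on replicate relative
  abundances, scored by holding out all replicates of three randomly
  chosen surfaces per repeat (100 repeats; folds missing a stage are
  redrawn) and reporting the median correct fraction.  A permutation
  null (fresh label shuffle per permutation, pooled repeats) provides
  the chance level, ~1/3 for three balanced stages.

## Succession: ABC curves and the W statistic

For each community, taxa are ranked twice — by count abundance and,
independently, by biomass (areal coverage) — and cumulative percentages
`A` and `B` accumulated along each ranking.  The summary statistic is

    W = Σᵢ (Aᵢ − Bᵢ) / (50 (S − 1)),   W ∈ [−1, 1],

oriented so that **abundance dominance gives W > 0** (many small
individuals: recently disturbed / earlier succession) and biomass
dominance W < 0 (later succession).  Parts of the ABC literature use the
mirrored sign; the orientation is a module constant.  Rank ties are
broken lexicographically by taxon label, which the cumulative curves
make W-neutral for exact ties.  Communities with fewer than two taxa are
undefined and skipped with a log entry.

Staging compares jackknife W distributions pairwise: replicate-wise
(index-paired) differences, percentile confidence interval at
alpha = 0.05, significant when the interval excludes zero.  A surface
whose significant comparisons are all positive is *earlier*, all
negative *later*, mixed *intermediate*.  Surfaces with no significant
comparison — and surfaces too small or too deformed to jackknife —
are placed with the resolved group whose mean-W range is nearest and
flagged `by_mean_w`; with no significant structure at all every surface
is flagged and rated intermediate.  Percentile rather than
normal-approximation intervals were chosen because the replicate
distributions are bounded and can be skewed.

Mean W is regressed (OLS) on surface covariates — specimen density,
total areal coverage, mean and maximum height — reporting F, p and
adjusted R²; residual degrees of freedom are n − 2.

## Tiering: DVS metrics

Distinct vertical stratification is scored per taxon within a community:

* **DVS^u** — the proportion of the taxon's uptake zone (the union of
  its specimens' uptake intervals, computed by exact interval merging,
  not the [min, max] hull) that overlaps no other taxon's zone.
* **DVS^h** — the proportion of the taxon's specimens whose height falls
  outside the closed [min, max] height envelope of every other taxon.
  The envelope rule was chosen over tolerance-band matching because it
  needs no bin-width parameter and is deterministic.

Community scores are means over taxa, unweighted or abundance-weighted
(weights `n_t / N` over the scored taxa); weighting lets rare taxa enter
without dominating.  Zero-measure uptake zones (e.g. entirely unmeasured
taxa) are excluded from DVS^u with a log entry.  Communities are classed
high (> 0.70), medium (0.40–0.70) or low (< 0.40).  A morphogroup-level
variant treats each gross morphology (recliners, *Bradgatia*-like,
*Pectinifrons*-like, upright fronds) as one taxon-unit and requires at
least three groups with more than 30 specimens.  Exactness of the
interval arithmetic is verified against a 0.01 mm occupancy-grid brute
force on random communities.

Cross-surface associations: OLS of each DVS metric on mean W, and
Spearman correlations of stem proportion (specimen-weighted share of
taxa with positive mean stem length) against weighted DVS^u and of
DVS^h against DVS^u.

## Synthetic data

The generator draws per-taxon counts multinomially from configured
weights; positions from a uniform Poisson or Thomas cluster process
(Poisson parents, Gaussian offspring, off-map offspring redrawn); part
sizes lognormally with a fixed width allometry; and marks frondose
specimens effaced with a configurable probability while retaining true
identities in a hidden column.  Defaults (lognormal sizes, Thomas
clustering) reflect that mapped benthic communities are typically
clustered and right-skewed in size.  A successional state couples
abundance and size: `early` sets frond-length medians ∝ weight^(−1/2)
(biomass spread evenly, abundance uneven, W > 0 expected, the rarest
taxon large), `late` mirrors it (biomass concentrated in the dominant,
W < 0).  A forward pure shear can be applied for retrodeformation tests.

`generate_study_fixture` emits 12 surfaces — four Community Types
(*F. misrai*-, *F. andersoni*-, *Bradgatia*- and frond-dominated), each
in three successional states — with 250–1,500 specimens and effaced
fractions 0–0.35.  `generate_planted_w_surface` builds two-taxon
communities whose full-surface W is planted analytically (with two taxa
only the first rank separates the curves, so `W = (A₁ − B₁)/50`), used
for staging-recovery checks.

What the synthetic data do **not** emulate: taphonomic gradients,
current alignment of fronds, growth/size cohorts, real taxonomic
richness (dozens of taxa), or irregular (non-rectangular) mapped
outlines.  Passing the planted-recovery tests therefore demonstrates
the correctness of the computations and the detectability of strong
planted structure, not that real surfaces contain such structure.

## Problem sizes and numerical choices

The validation suite uses 1,000 jackknife replicates where resampling
behaviour itself is under test, 100 LDA repeats, 200 random communities
for the DVS oracle, and fixture surfaces of a few hundred to ~1,500
specimens — large enough that multinomial noise is well below the
planted effect sizes.  All randomness flows from named
`numpy.random.default_rng` seeds; pipeline stages derive per-stage
streams from one master seed via `SeedSequence.spawn`, so identical
configurations reproduce every output byte for byte.  Degenerate inputs
(zero-area extents, all-zero composition rows, constant covariates,
single-taxon communities) raise informative errors rather than silently
producing NaN.

## Known limitations

* The coverage proxy understates organisms whose outline is far from
  elliptical and ignores overlap between parts.
* Stem/frond measurements are not strain-corrected during
  retrodeformation (no recorded orientation).
* The `by_mean_w` placement depends on at least one resolved group;
  sparse datasets may leave all surfaces unresolved.
* LDA assumes shared within-class covariance of relative abundances;
  with many taxa and few replicates per surface the discriminant can
  overfit, which the surface-level hold-out is designed to expose.
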