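# Methods

`zotrad` re-implements, as a reusable and fully tested pipeline, a CT
radiomics analysis for discriminating renal oncocytoma (RO) from clear
cell renal cell carcinoma (ccRCC): peritumoral zone-of-transition (ZOT)
extraction, genetic-algorithm (GA) wrapper feature selection scored by a
decision-tree classifier, and a dual evaluation design that quantifies
how the placement of feature selection relative to the train/test split
changes the measured performance.  Patient imaging is not
redistributable, so the package ships a synthetic-data module that
reproduces the *statistical structure* of the problem; every claim the
test suite makes is therefore a claim about that structure, not about
any clinical cohort.

## Zone of transition

A tumor mask `M` (binary, 3D, with physical spacing) is dilated and
eroded `iterations = 2` times with a 3x3x3 structuring element; the ZOT
is `dilate²(M) \ erode²(M)`.  The "circular" 3x3x3 element is
interpreted as the face-connected 7-voxel cross — the discretization of
the Euclidean unit ball on a 3³ grid; the full 27-voxel cube is
available as a config option.  Two sequential passes with the radius-1
element equal one pass with the element's Minkowski self-sum (verified
by test).  Conventions:

* Out-of-grid space is background.  Dilation that would cross the grid
  boundary is clipped with a warning; erosion eats inward from the
  boundary.
* An erosion that empties the mask (thin or tiny lesions, e.g. T1a
  masses a few voxels thick at 2.5 mm slices) is not an error: the ZOT
  equals the dilated mask and a warning is logged.
* Morphology operates in voxel space and ignores anisotropic spacing,
  because the reference protocol includes no resampling step; callers
  who need isotropic behaviour can resample before calling.
* Masks and volumes must agree in shape, and in spacing/origin within
  1e-3 mm, else a `GeometryError` is raised.

A brute-force Minkowski-sum oracle (explicit shift-OR dilation and
shift-AND erosion) lives in the test suite and is checked voxel-wise
against the `scipy.ndimage` implementation on random masks.

## Radiomic features

Each region (tumor, ZOT) of the arterial-phase volume is summarized by
shape descriptors plus first-order intensity statistics computed on the
original image and on a filtered-image bank.  The shipped default
configuration is

* 3 shape features (voxel count, physical volume, face-connected
  surface-voxel count),
* 27 first-order statistics per image (moments, order statistics,
  dispersion and histogram measures; entropy/uniformity use a fixed
  bin width of 25 HU),
* an image bank of 1 original + 24 stationary-wavelet subbands
  (`coif1`, 3 levels, 8 lo/hi axis combinations per level, a-trous
  implementation so the grid is preserved) + 20 Laplacian-of-Gaussian
  responses (sigma 0.5 ... 10 mm in 0.5 mm steps),

giving `3 + 27 x 45 = 1218` features per region and 2436 per patient —
the catalogue size is the binding contract; its composition is a
package design choice, frozen by config hash.  Feature names render as
`W-<subband><level>-` / `L-<sigma>-` prefixes for wavelet / Laplacian
features and a trailing `(ZOT)` for ZOT-region features; rendering and
parsing round-trip exactly.

The extraction engine is pluggable.  The `external` engine slot is an
adapter for a full radiomics engine and raises an informative error
when none is importable; the `native` engine implemented here is the
default.  Re-implementing the grey-level co-occurrence texture families
is explicitly out of scope: the native catalogue exists so that the
selection and evaluation layers are fully testable.  The volume is
cropped to the mask bounding box plus `crop_pad = 2` voxels before
filtering (reflect boundary), so features depend only on intensities
inside that padded box; this bounds the spatial support of the filter
bank and makes region sensitivity a testable property.  No feature
normalization is applied — decision trees are scale-invariant.

Tables are cleaned by dropping columns containing non-finite values
(logged); constant columns are retained because the wrapper may still
select them and subset fitness is unaffected.

## GA wrapper selection

A genome is a binary inclusion vector over feature columns; its fitness
is the mean ROC AUC of a `DecisionTreeClassifier` (Gini, unlimited
depth, seeded) over a stratified 5-fold cross-validation restricted to
the selected columns.  AUC is computed from the tree's class-score
output via the Mann-Whitney rank statistic, so tied scores contribute
half per tied pair.  Defaults follow the reference protocol (150
genomes, 100 generations, 5 folds); the operators, unspecified there,
are tournament selection (size 3), uniform crossover (rate 0.9),
per-gene bit-flip mutation (rate 1/L) and single-genome elitism.
Numerical conventions:

* The fold partition is fixed per run and seeded identically to the
  public `genome_fitness` operation, so fitness is deterministic,
  cacheable by bit pattern, and reproducible outside the GA.
* An all-zero genome scores chance level (0.5) instead of raising;
  empty subsets are thereby penalized naturally and evolution stays
  total.  Fitness itself is AUC alone — there is no feature-count
  penalty term.
* Exact fitness ties are broken toward the sparser genome, then
  lexicographically by bit pattern.  This makes comparisons
  deterministic and, on saturated landscapes (many perfect separators),
  prevents the best genome from degenerating into an arbitrary
  half-dense bit pattern.

The selector is also exposed as a scikit-learn `SelectorMixin`
estimator (`GeneticFeatureSelector`) so it composes with pipelines and
model selection; `evolve` is the functional core.

## Evaluation design

Two variants differ only in where selection sits relative to the
stratified 80/20 split (per-class train counts are `round(n_c * 0.8)`,
round half up):

* **Procedure A** — GA on the whole dataset, then split, then a fresh
  decision tree fit on the training rows restricted to the selected
  features, ROC AUC on the test rows.
* **Procedure B** — split first; the GA sees the training rows only
  (a guard raises `LeakageGuardError` if the selection view contains
  any row outside the training set), test rows stay untouched until
  scoring.

Each variant is repeated (default 100 times) with per-repeat seeds
derived as `hash(master_seed, stage, repeat)`; A and B share the same
split sequence, so the placement of selection is the only difference.
The GA is re-run every repetition (it is stochastic, so repeated runs
on identical data still differ).  The final per-repeat classifier is
refit on the full training set; CV-fold models are not reused.  AUC on
small test sets is reported as-is, without smoothing — the spread of
the per-repeat AUC distribution partly reflects the 15-16-row test
sets.  Per-feature selection rates (percent of repetitions whose best
genome includes the feature) provide a stability-based importance
ranking; top-k ties break lexicographically by rendered name.

## Synthetic data

**Phantoms.**  A lesion is a sphere of radius 12 mm (default) on a
64³ 1-mm grid: uniform background parenchyma, uniform tumor, and — for
the ccRCC-like class only — a rim ("pseudocapsule") in the shell just
outside the tumor mask, plus iid Gaussian voxel noise.  The rim shell
is realized in the same face-connected voxel metric the ZOT morphology
uses (`round(thickness/spacing)` cross-dilation passes), so a rim up to
two voxels thick lies inside the two-pass ZOT by construction — which
is exactly what makes ZOT features, and only ZOT features, carry the
class signal at the voxel level.  Default intensities are plausibility
choices for arterial-phase renal CT in HU (parenchyma 180, tumor 110,
rim 50, noise sd 20); they are artifact parameters, not estimates of
any cohort.  Cohort generation adds per-patient variation: tumor
radius jittered uniformly by ±3 mm and each tissue intensity offset
independently by N(0, 40 HU), emulating size heterogeneity and
contrast-timing variability.  Without such variation every ZOT
intensity feature would be a perfect separator (averaging removes voxel
noise) and the selection problem would be degenerate.  What the
phantoms deliberately do *not* model: CT reconstruction texture and
noise correlation, lesion shape irregularity, partial-volume blur, and
multi-phase acquisition — so passing tests demonstrate that the
pipeline recovers a rim-borne signal of realistic contrast under
realistic inter-patient variability, not that it reproduces clinical
performance numbers.

**Feature tables.**  For testing the selection/evaluation machinery
directly, tables with the cohort's shape (defaults: n = 77, class
fractions 0.39/0.61 giving 30 RO / 47 ccRCC; p up to 2436 with catalogue
column names) are drawn iid standard normal; `k_informative` columns
are shifted by `effect_size` in the ccRCC class (`k_informative = 0` is
the null regime).  Exact class counts come from rounding; informative
column identities are recorded in table provenance.

**Seeding.**  All randomness derives from master seeds through a fixed
integer hash (`numpy.random.SeedSequence` over `(master, *tags)`, tags
CRC-32-folded), so per-item and per-repeat streams are reproducible
independently of generation order.

## Experiment scales in the shipped tests and acceptance script

Chosen once for statistical resolution against runtime on one CPU, and
documented here as the package's own defaults:

* Null-leakage experiment: table n = 40, p = 500, GA population 30 /
  20 generations, 20 repeats per procedure.
* Planted-feature recovery: table n = 120, p = 100, 5 planted columns
  at effect size 3, Procedure B with GA population 40 / 60 generations,
  10 repeats (8 in the acceptance script).
* Phantom cohort: 20 + 20 phantoms, screening extraction bank
  (original + LoG sigmas 1-3 mm, no wavelet; 111 features per region),
  Procedures A and B with GA population 50 / 100 generations, 16
  repeats (12 in the acceptance script).  The lean bank and the long GA
  run were chosen together: selection-rate rankings are only
  informative once the GA has converged enough that per-repeat best
  genomes are sparse, and at p = 222 that convergence is affordable.
* GA-vs-exhaustive: p = 6, exhaustive 64-subset oracle, population 16 /
  20 generations, 10 seeds.

## Findings the implementation forced us to document

**Selection-before-split optimism requires concentrated selection or
real signal.**  On *pure-null* tables (labels independent of all
features) the GA wrapper at the scales above selects roughly half of
all columns; a fresh decision tree restricted to such a dense,
individually-uninformative subset shows no optimism on held-out rows
(measured mean test AUC of Procedure A ~0.49 across GA budgets up to
population 50 / 150 generations).  The winner's curse the GA accrues
lives in the genome-by-fold interaction and does not transfer through a
refit tree.  By contrast, a *filter*-style selection (top-10 columns by
full-data per-feature AUC) on the same null table is measurably
optimistic, and on a signal-bearing cohort — where the converged GA is
concentrated on few features — selection-before-split (Procedure A)
scores above selection-after-split (Procedure B).  The acceptance
script therefore reports the null-table gap as measured, the
filter-selection reference on the same table and splits, and the A-vs-B
comparison on the phantom cohort.

**Redundant informative features split the selection rate.**  With
several interchangeable strong features, subset fitness saturates after
2-3 of them (measured: adding the 4th/5th planted column changes mean
CV AUC by less than the fold-resampling sd), so per-repeat best genomes
contain a subset of the planted columns and selection rates distribute
over them.  Rate-based importance rankings should be read at the level
of feature *groups*, a known property of wrapper selection on
correlated radiomic features.

## Known limitations

* The native feature catalogue shares only its first-order/shape core
  with full radiomics engines; texture families (GLCM, GLRLM, ...) are
  absent, so absolute feature values are not comparable to engine
  output even where names resemble each other.
* Phantoms are spherical and noise is white; morphological and texture
  realism is out of scope.
* ROC AUC on 8-16-row test sets is coarsely quantized; per-repeat
  scores should only be interpreted in distribution.
* The GA explores ~10³-10⁴ subsets per run at the shipped scales —
  adequate for the planted-signal experiments, but no claim of global
  optimality is made for p in the thousands.
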