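# Methods

This note documents the models, conventions and design choices behind
`flavoromics` — an integrated analysis of two molecular platforms
(non-volatile metabolites from LC-MS and volatile organic compounds, VOCs,
from GC×GC-TOF MS) across a small number of sample groups, here three
cattle breeds (GL, SN, XZ). It covers what each stage computes, the
tunable parameters and their defaults, what the synthetic-data generator
does and does not emulate, and the numerical conventions that make runs
byte-reproducible.

## Preprocessing and semi-quantification

Raw feature tables carry non-negative intensities with missing cells
(empty CSV cells, never 0 — zero is a legal intensity and the missingness
filter must count true absences). The chain runs in a fixed order:

1. **Peak QC** (VOC platform). A peak is retained iff its signal-to-noise
   ratio is ≥ 50 *and* its spectral library-match similarity is ≥ 700
   (0–999 scale); both thresholds are inclusive. When a calculated
   retention index is available, identity confirmation additionally
   requires |calculated RI − theoretical RI| *strictly* below 20.
2. **Internal-standard normalization.** Each sample's intensities are
   divided by that sample's internal-standard intensity, yielding
   *relative content*; the IS channel (identically 1 afterwards) is
   dropped. A missing or non-positive IS value is a hard error naming the
   sample — semi-quantification is meaningless without it.
3. **Missingness filter.** Features missing in strictly more than 50% of
   samples are removed; a feature missing in exactly half is kept. The
   boundary semantics are deliberate (QC inclusive, missingness strict,
   RI strict) and are asserted by dedicated tests.
4. **Half-minimum imputation.** Each remaining missing cell becomes half
   the feature's minimum observed value — the standard stand-in for
   values censored at the detection limit. The choice of imputation is a
   design decision (the field offers several); half-minimum is used
   because most missingness in these data is detection-limit-shaped.

Applying the chain to its own output is a no-op. Whether the LC table also
passes the missingness filter is a flag (`missing_filter_metabolites`,
default on).

**Retention indices** use the van den Dool–Kratz linear form for
temperature-programmed GC: with bracketing ladder alkanes of carbon
numbers $c_n < c_{n+1}$ at times $t_n < t_{n+1}$,

$$RI(t) = 100\,c_n + 100\,(c_{n+1}-c_n)\,\frac{t-t_n}{t_{n+1}-t_n}.$$

An alkane's own time maps exactly to $100 c$; times outside the ladder
span are an error (no extrapolation).

## Multivariate models

Both models operate on log₂ intensities of the imputed table, autoscaled
(mean-centered, unit variance). Autoscaling is the metabolomics default:
fold-changes matter more than absolute abundance, and without it a handful
of high-intensity features dominate every component. A constant feature
under autoscaling is an error naming the feature.

**PCA** is computed by singular value decomposition of the scaled matrix;
explained-variance fractions are ratios of squared singular values.

**OPLS-DA** follows the orthogonal-projection scheme for a single binary
response: repeatedly (for `n_ortho` components, default 1) the
y-orthogonal part of the X-loading is split off, its score removed from X;
then one predictive PLS component is fit on the filtered matrix. With
`n_ortho = 0` the model is exactly one-component PLS1 — the equivalence is
enforced to 1e-10 against an independent closed-form implementation in the
tests. Orthogonal scores have zero covariance with the response and with
the predictive score by construction. Models are fit pairwise per group
comparison (GL vs SN, GL vs XZ, SN vs XZ); the three-group overview is a
PCA.

*R²Y* is the fraction of (centered) class-indicator variance explained by
the fitted predictive component. *Q²* = 1 − PRESS/SSY with predictions
from models refit on each training fold; leave-one-out when n ≤ 12 (the
default design has 6 samples per pairwise model), otherwise seeded
stratified 7-fold. A Q² near or below 0 means the model predicts held-out
class membership no better than the mean — the expected outcome on null
data, which the test suite verifies on permuted labels.

**VIP** (variable importance in projection) over predictive components:

$$VIP_j = \sqrt{p \cdot \frac{\sum_a SSY_a\,(w_{ja}/\lVert w_a\rVert)^2}{\sum_a SSY_a}}$$

normalized so the mean of VIP² across the p features is exactly 1; the
conventional VIP > 1 cut flags features carrying more than an average
share of class-predictive variance. Only the predictive component enters
by default (marker selection should reflect class-predictive variation);
a total-VIP variant including orthogonal components weighted by captured
X-variance is exposed as an option.

**Sign convention.** Every score/loading pair (and the predictive weight)
is flipped so its largest-magnitude element is positive, making fits
byte-identical across BLAS implementations.

## Differential screening

Markers per pairwise comparison satisfy **VIP > 1 (strict) and p < 0.05**,
with the pairwise p from Welch's t-test on log intensities. The omnibus
one-way ANOVA across all groups and Benjamini–Hochberg adjusted p-values
are always computed alongside. The raw-p default and the BH alternative
reflect a genuine tension in practice: multivariate screening pipelines
conventionally pair VIP with raw p, while formal significance statements
require multiplicity control. Both are first-class here — `use_adjusted`
switches the rule — and the recovery experiment in the acceptance suite
uses the BH rule, because an evaluation that targets a false-discovery
bound belongs to the multiplicity-controlled selection (at 20 replicates
per group the raw-p rule admits ≈ 0.05 × #null false positives that the
VIP filter largely duplicates rather than removes).

ANOVA conventions: a feature with zero between-group *and* zero
within-group variance gets p = 1; zero within-group variance with a real
difference gets p = 0. Fold changes are computed on unlogged group means
of the normalized table and reported as log2; "up" means higher in the
first group of the comparison.

**Heatmap ordering** mirrors the figure convention: per-feature z-scores
across samples (constant features become all-zero rows, logged as a
convention), Euclidean distances, complete-linkage agglomeration. The
agglomeration is implemented here rather than delegated because the
contract fixes a deterministic tie-break — among pairs at minimal
distance, the pair whose clusters contain the lowest original indices
merges first — which library implementations do not guarantee; scipy's
linkage is the cross-check on tie-free data.

## Aroma-contribution scoring (OAV / ROAV)

For each compound with a known odor threshold in water $OT_i$ (same units
as relative content), the odor activity value is $OAV_i = C_i / OT_i$ and
the relative odor activity value $ROAV_i = 100 \cdot OAV_i / OAV_{max}$,
so the most aroma-active compound scores exactly 100 and all scores are
invariant to global rescaling of contents. $C_i$ is the group mean of
IS-normalized content (median available as an option; the aggregation of
replicates into one per-breed content is not uniquely determined by
convention). Each group is scored independently with its own $OAV_{max}$.
Compounds without a threshold are carried unscored and never define the
reference maximum. Contribution classes, read strictly: **key** iff
ROAV > 1, **moderate** iff 0.1 ≤ ROAV ≤ 1, **minor** below. The
normalization divides before multiplying by 100 so the maximum is exactly
100.0 in floating point, not 100 ± 1 ulp.

ROAV deliberately ignores perceptual interactions (masking, synergy);
it ranks single-compound contributions only.

## Presence/absence and networks

The three-group Venn partition assigns every detected feature (observed in
at least one sample of a group) to exactly one of 7 exclusive regions;
regions are pairwise disjoint and cover the union — a property test, since
off-by-one region logic is the classic failure mode.

The VOC–sensory network is bipartite: one edge per (differential VOC,
sensory descriptor). Attributes are ranked by degree with lexicographic
tie-break, and only the top 10 (configurable) attributes with their
incident edges are retained.

## Cross-platform association

**Spearman correlation** between differential metabolites and VOCs is
Pearson correlation of mid-ranks (average ranks on ties), with the
t-approximation p-value on n − 2 degrees of freedom; an exact permutation
p is available for n ≤ 10. It is computed blockwise from ranks rather
than through a library call because a single constant column must
invalidate only its own correlations (reported NaN with a warning), not
the whole matrix. Significance flags default to raw p < 0.05 — the
double-matrix heatmap convention — with BH-adjusted values reported
alongside.

**Pathway over-representation** is the upper-tail hypergeometric test:
with N universe features, K in the pathway, n selected and k overlapping,
p = P(X ≥ k); BH adjustment across pathways. The universe is an explicit
required input (all detected vs all annotated metabolites changes the
test materially, and no convention can decide it); pathway membership is
intersected with the universe before testing. Topology/impact scoring of
web-based pathway tools is out of scope.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes,
not the instruments. Per table (metabolites, VOCs):

- log-intensity = sample effect + latent group mean + N(0, σ), with
  σ² = ln(1 + cv²) so `cv_noise` is the multiplicative coefficient of
  variation. Baseline log-means are uniform over ln(10⁴)–ln(10⁷).
- A planted subset (`frac_differential`, default 0.1) receives ±ln(effect
  size) on exactly one affected group's latent mean — so planted log-fold
  differences are *exact* in the latent matrix, the acceptance surface for
  recovery tests.
- One internal-standard channel shares the per-sample effect (tight 5%
  measurement noise), is never planted and never censored; IS
  normalization therefore removes the sample effect by construction.
- Below-detection censoring (values under the pooled `lod_quantile`)
  precedes missing-at-random masking (`missing_rate`), mimicking
  detection-limit structure so the half-minimum imputation decision is
  exercised.
- The alkane ladder is affine in carbon number (C7–C30, 1.8 min/carbon)
  with jitter bounded by 1% of the spacing — monotone by construction and
  exactly linear at zero jitter.
- VOC annotations draw chemical classes from a closed taxonomy
  (hydrocarbons, alcohols, aldehydes, esters, ketones, others), log-normal
  odor thresholds (~8% of compounds lack one, exercising the unscored
  path), theoretical RIs consistent with the ladder ± a small
  perturbation, and 1–4 sensory descriptors from a packaged static
  vocabulary — a stand-in for an external flavor-descriptor database, so
  no network access is needed. Peak QC records give most peaks passing
  S/N and similarity with a realistic failing minority.
- The pathway database has 12 pathways of 8–24 members; two are
  deliberately loaded with planted metabolites and recorded as the
  enrichment ground truth.

Defaults are the study conditions: 3 groups × 3 replicates, 200
metabolites, 150 VOCs, 4-fold effects on 10% of features under 20% CV
noise, 10% missing-at-random plus 5% censoring. Power and recovery
experiments use 20 replicates per group, where a 4-fold effect against
σ ≈ 0.2 on the log scale is detected essentially always. Everything
derives from one seeded generator; identical configs give byte-identical
studies.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: chromatographic peak shape and co-elution,
between-batch drift and QC-sample structure, correlated feature blocks
(adducts, isotopes, in-source fragments), heavy-tailed or
intensity-dependent noise, structured (non-random) missingness beyond the
LOD mechanism, and any real biochemical relationship between metabolite
precursors and VOC products (correlations in synthetic data arise from
shared group structure, not chemistry).

## Pipeline and reproducibility

`run_all` executes simulate → preprocess → chemometrics → diff → roav →
network → correlate → enrich as a pure function of (inputs, config, seed).
Outputs are CSV/JSON with a schema-version line; the manifest records the
config echo, per-stage record counts and SHA-256 checksums. No timestamps
or absolute paths enter any output, so two runs with the same config are
byte-identical — asserted at file level in the acceptance suite. A stage
failure aborts with the stage name; partial outputs are preserved.

At the default scale the full pipeline completes in about a second on one
CPU; the heaviest acceptance experiments (50 null studies, 20 recovery
studies at 60 samples × 200 features) run in a few seconds each. These
problem sizes were chosen as the smallest at which the measured
sensitivities, false-discovery proportions and null rates are stable
across seeds.

## Known limitations

- One predictive component only (binary comparisons); no multi-class
  OPLS-DA.
- VIP is computed from the single predictive component; orthogonal
  inclusion is a reported variant, not the default.
- The exact permutation Spearman p enumerates n! permutations and is
  practical only for n ≤ 10.
- The hand-rolled complete-linkage agglomeration is O(n³) — fine for the
  tens-to-hundreds of items a heatmap displays, not for thousands.
- ROAV aggregation (mean vs median content) and the pathway universe are
  modelling choices exposed as parameters, not inferred from data.
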