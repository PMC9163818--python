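# Methods

This note documents the statistical procedures `cazlink` implements, the
choices made where the design was genuinely open, what the synthetic-data
generator does and does not emulate, and the package's known limitations.

## Data model

The pipeline consumes five tables: a bin table (id, GTDB-style taxonomy,
CheckM-style completeness/contamination), a bin-by-sample relative
abundance matrix in % of total DNA, a per-protein CAZyme annotation table
(protein, bin, CAZy family, optional CUPP group; one row per CAZyme
*domain*, so multi-domain proteins contribute once per domain), a
family/group → linkage-target mapping, and sample metadata (animal, diet
group, phenotype). Bins with completeness below 10% are excluded before
any analysis; the threshold is configurable (`completeness_min`).

### Linkage-target ontology

A linkage target is the triple *major polysaccharide :: branch ::
specific target* (the specific part may itself contain a linkage label
such as `β-1,4::Xyl`; parsing splits only the first two separators, and
whitespace around internal separators is canonicalised at construction so
format∘parse is the identity). The packaged mapping is a curation over
142 CAZy families and 86 distinct targets, covering the full set of
targets reported as significantly changed in the reference feeding trial
plus family-level fallbacks; it is a working default, not a reproduction
of any supplementary file, and users can substitute their own TSV. A
family mapping to *k* targets splits each domain equally (1/k) unless the
mapping provides explicit weights (validated to sum to 1 per key); a
(family, CUPP-group) rule shadows the family rule; unknown families map
to nothing rather than failing, since the CAZy family universe is
open-ended.

## Profiles and normalisation

For feature f (family or target) and sample s, the raw mass is
m(f, s) = Σ_b a(b, s) · w(b, f), where a is relative abundance and w the
(weighted) domain count. Each sample column is rescaled to sum to 100.
"Normalised per diet group" summaries are implemented as per-animal
normalisation followed by group mean ± SD — group dispersion requires
per-animal values, and the group mean of per-animal percentages is itself
a percentage. Weighting domain counts by bin abundance is the default
because phenotype correlation operates per animal; an unweighted
per-genome analysis can be had by passing a uniform abundance matrix.
Samples with zero CAZyme mass are kept as all-zero columns, flagged, and
excluded from correlation rather than dropped silently.

## Group contrasts

* **Test.** Equal-variance two-sample Student's t (df = n₁ + n₂ − 2),
  two-sided, on the per-animal values — the default behaviour of the
  standard scipy routine. Zero pooled variance is handled explicitly:
  equal means give (t = 0, p = 1); unequal means give p = 0 with a
  degeneracy flag.
* **Per-bin classification** labels each bin reference-dominant,
  contrast-dominant (mean comparison when p ≤ α, α = 0.05) or
  not-significant; the three classes partition the bin set. No
  fold-change rule applies at the bin level.
* **Dual feature filter.** A family or target is significantly changed
  iff p < α **and** the relative change |mean_con − mean_ref|/mean_ref
  is ≥ 20%. The baseline is always the reference (Standard) group; a zero
  baseline with nonzero contrast counts as infinite change (the feature
  appears/disappears), which passes the change rule. The 20% is relative
  change, not percentage points.
* **No multiplicity correction** is applied by default, matching the raw
  p ≤ 0.05 convention of the motivating analysis; a Benjamini–Hochberg
  option exists behind `bh_correct=True`.
* **Compact letters** come from all pairwise equal-variance t-tests via
  insert-and-absorb: groups share a letter iff their pairwise p > α.
  Whether the reference trial's letters came from pairwise t-tests or a
  mixed model with animal effects is not stated there; pairwise t is what
  this package implements. Intransitive significance patterns legally
  yield multiple letters per group.
* **Phenotype association** is Spearman rank correlation (average ranks
  for ties) of each feature against the per-animal phenotype, pooling all
  diet groups; constant features get an undefined (NaN) ρ.

## Ordination and separation score

Samples are embedded by classical (metric) MDS — double-centred squared
distances, eigendecomposition, top two axes — of the correlation distance
1 − ρ between sample profiles. Rank (Spearman) correlation is the
default, Pearson an option; classical MDS was chosen over non-metric
stress optimisation for determinism and exactness on Euclidean input
(reproduction to 1e-6 is part of the test suite). Negative eigenvalues of
non-Euclidean inputs are clipped for coordinates; the explained-inertia
diagnostic uses the positive spectrum only. Axis signs are fixed by
making each axis's largest-|coordinate| entry positive, so runs are
bit-reproducible.

The separation score divides the inter-centroid distance by the
accumulated member-to-centroid distances of the two clusters. Its
narrative description ("average distance") and its displayed definition
(sums) disagree in the source material; the sum form is the default
(`variant="sum"`) and the mean form is exposed as `variant="mean"`. The
score is invariant under rotation, translation and uniform scaling, zero
iff the centroids coincide, and undefined (error) when both clusters are
singletons. The reference trial's printed scores (1.56/2.15/2.11 for
bins/families/targets) depend on its raw data and are bundled as context,
not as quantities a synthetic study should reproduce.

## Presence/absence clustering

The observation matrix is binary (target present in bin iff its weighted
count > 0), optionally restricted to the significantly changed targets.
Distances are binary Jaccard (|XOR|/|OR|; two all-absent rows get
distance 0 by convention, so enzyme-poor bins cluster together) and the
tree is built with the Ward (minimum-variance, Lance–Williams) update
applied directly to those distances. Ward's variance interpretation
strictly assumes Euclidean geometry and Jaccard distances are not
Euclidean; the combination is kept deliberately for fidelity to the
motivating analysis, and average linkage can be obtained by clustering
the distance matrix with scipy directly. Agglomeration is deterministic
with ties broken toward the lowest pair index. Newick export writes
branch lengths as merge-height differences (leaves at height 0) and
quotes labels containing reserved characters; round-tripping topology and
heights to 1e-9 is tested against an independent Newick parser.

## Synthetic-data generator

The generator emulates the *structure* the analysis assumes, at the
reference trial's design size: 3 diet groups × 4 animals, 500 bins over
15 phyla with weights proportional to the trial's per-phylum bin counts,
completeness ~ U(10, 100) (an explicit `low_completeness_bins` spike-in
exercises the filter). Abundances are heavy-tailed: per-bin baselines are
lognormal (log-SD 1.5) and per-sample values add multiplicative lognormal
noise (`lognormal_sd`, default 0.5 ≈ 53% CV). In the contrast group, a
planted fraction of bins (10%) changes 4-fold — three quarters of them
downward, mirroring the trial's preponderance of reference-dominant
bins — and five starch-leaning "takeover" bins are amplified 25-fold,
reproducing the fewer-but-dominant-species character of the extreme-diet
community; columns are renormalised to 100 afterwards, so realised fold
changes are compositionally damped. CAZyme domain counts are Poisson per
bin with phylum-class rates (archaea ≈ 2 domains/bin, fibre degraders 45,
starch degraders 30, generalists 22) and families drawn from
hallmark-weighted class pools (GH13-heavy for starch degraders,
GH43/GH10/GH2/GH3-heavy for fibre degraders) — uniform pools would spread
domains so thinly that no target could carry a detectable group signal.
The phenotype sits on a CH₄-yield-like scale: baseline 25.3 minus
1.0 × (summed % abundance of the coupled starch-backbone targets) plus
N(0, 0.9) noise, which puts the linear coupling at R² ≈ 0.7 across the 12
animals; the ground-truth ledger records every planted bin, takeover bin
and coupled-target coefficient.

What the generator does **not** emulate: phylogenetic correlation between
repertoires beyond the class pools, co-occurrence structure among
targets, read-level or assembly noise, compositional zeros from shallow
sequencing, and animal-level random effects. Passing recovery tests on
these studies therefore demonstrates the statistical machinery under the
assumed model, not performance on real rumen data.

### Calibration and power under the default conditions

Two quantitative behaviours of the defaults are worth stating explicitly,
because both are measured by the test suite and the acceptance script:

* The equal-variance t-test is exactly sized on Gaussian features
  (null positive rate ≈ 5%); on lognormal features with log-SD 0.5 at
  4 + 4 samples it is *conservative* (≈ 4.3%). The dual filter always
  passes fewer features than the p-rule alone.
* With 4 + 4 samples and 53% CV multiplicative noise, a true 4-fold
  abundance change gives the t-test roughly 76% power (renormalisation
  after the planted and takeover mass shifts damps the realised up-fold
  to ≈ 3.2×, down-planted bins are correspondingly easier). End-to-end
  recovery of planted bins is therefore ≈ 79%, not near-complete;
  near-complete (> 99%) recovery of planted features is reached at
  log-SD 0.1, which the suite also checks. Recovery of the *sign* of the
  phenotype coupling and of planted presence/absence blocks under the
  Ward tree are both ≥ 95% under the defaults.

## Numerical conventions

Tolerances: profile columns sum to 100 within 1e-6; mapping weights sum
to 1 within 1e-9; MDS reproduces Euclidean-realizable distances within
1e-6; Newick round-trips heights within 1e-9. Ties: average ranks in
Spearman; lowest-pair-index tie-breaks in agglomeration. Degenerate
inputs (zero-variance tests, all-absent binary rows, zero-mass samples,
singleton clusters) follow the explicit conventions above rather than
propagating NaNs. All tabular I/O is UTF-8 TSV with `#` comments; the run
manifest records input SHA-256 checksums, parameters and library versions
so a run can be reproduced byte-for-byte.

## Limitations

* The packaged ontology is a pragmatic curation; substrate assignments of
  several families are genuinely ambiguous and should be overridden with
  a study-specific mapping when available.
* Pairwise t-tests ignore animal-level covariates (parity, period); the
  reference trial's emission table itself came from a mixed model.
* Ward-on-Jaccard is a faithful but geometrically improper combination
  (see above).
* Relative-abundance data are compositional; no log-ratio transformation
  is applied anywhere, again for fidelity to the motivating analysis.
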