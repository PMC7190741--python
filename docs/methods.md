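# Methods

## Scope

`matnet` analyzes microbial-mat community structure from an OTU table onward.
Upstream read processing (primer trimming, denoising, chimera removal,
taxonomic assignment) is out of scope: the pipeline's inputs are a samples ×
taxa count table, a QIIME-style taxonomy map, and — for the downstream
modules — isolate records with best-hit 16S identities, OD590 replicate
tables, and metabolite intensity time courses.  Identity computation against
reference databases, phylogenetic tree building, and figure styling are
likewise out of scope.

## Network estimation

Relative abundances are computed on the **full** table before genus filtering,
so a taxon's fraction always refers to the whole community; filtering
afterwards leaves row sums ≤ 1 by design.  All-zero samples are errors, not
silently dropped.

Correlation is Spearman's ρ, computed as the Pearson correlation of
midrank-transformed columns; two-sided p-values use the t approximation
`t = ρ√((n−2)/(1−ρ²))` with n−2 degrees of freedom.  Fewer than 4 samples is
an error (the approximation is meaningless there), and perfectly monotone
pairs get p = 0.  Constant taxa have no defined rank correlation and are
recorded as ρ = 0, p = 1 (never an edge) with a warning.  No multiple-testing
correction is applied by default: the thresholding convention this pipeline
reproduces uses raw p < 0.05, and a Benjamini–Hochberg switch would change
the method being studied.  Edges require |ρ| > 0.6 **and** p < 0.05, both
strict, so a pair at exactly 0.6 is excluded; negative correlations are edges
with `sign="negative"`.  Nodes are genus-annotated OTUs (no genus
aggregation), and taxa with no qualifying edge are dropped from the graph by
default — which is why classified node counts are smaller than the filtered
taxon count.

## Node classification

Centrality is raw degree; the (N−1) normalization cannot change the ranking,
so it is not computed.  With quota `ceil(0.2·N)` per extreme class, ties at a
class boundary are **absorbed** into the extreme class: the key class is the
smallest degree-downward-closed set of at least the quota, and symmetrically
for peripheral.  Absorption is the mechanism that lets the bottom class grow
far beyond 20% in real networks, where large numbers of degree-1 vertices tie
at the boundary; a `truncate` rule (exact quota, ties broken by node ID) is
available for comparison.  If one node qualifies for both classes (tiny
networks), key wins and a warning is emitted.

## Candidate selection

Culture-collection oxygen requirements and growth-temperature ranges are
declared metadata, applied as filters in a fixed order (presence →
availability → oxygen → temperature); each rejected key-node genus records
exactly the first filter it failed.  Ranking (max key-node degree, then
supporting OTU count, then name) is a deterministic reporting convention, not
a claim about wet-lab priority — in practice all surviving candidates would
be screened.

## Isolate novelty

Identity bands are lower-inclusive for the higher tier: ≥ 98.7% known
species, 95.3–98.7 novel species, 90.0–95.3 novel genus, < 90 novel higher
taxon; isolates under 95.3% are flagged for full-length cloning.  The species
threshold is configurable because the literature uses both 98.5 and 98.7.
SCM percentages round half-up to integers (239/319 → 75%); per-sample read
averages use floor (2,173,872/26 → 83,610).

## Assay and metabolome statistics

OD590 comparisons use a two-sided two-sample t test, pooled by default: with
equal replicate counts the pooled and Welch statistics coincide, and at
triplicate sample sizes the Welch degrees-of-freedom correction is markedly
conservative (measured true level ≈ 0.035 at nominal 0.05), while the pooled
test holds its level exactly; `equal_var=False` selects Welch.  Stars follow
the two-level convention `*` p < 0.05, `***` p < 0.001.  Zero-variance
degenerate groups use the convention p = 1 for equal means, p = 0 (logged)
otherwise.

Fold change is the ratio of replicate-mean intensities between two
timepoints; compounds with a zero reference mean are flagged undefined rather
than erroring.  The default reference is 0 h, with a named preset
`stationary_vs_exponential` = (12 h, 24 h).  Accumulation significance is a
per-compound one-way fixed-effects ANOVA across timepoints on raw replicate
intensities, uncorrected at α = 0.05; constant compounds get p = 1.

Heatmap ordering z-scores each compound's timepoint means, then clusters rows
and columns with Ward linkage (scipy), whose merge criterion is the
squared-Euclidean minimum-variance objective ("d²").  Constant rows are
scaled to zeros, warned about, and appended after the clustered rows; leaf
orders are deterministic.

## Synthetic data generators

The community generator emulates a 26-sample, 200-taxon compositional survey
with planted structure:

* **Hub groups.** Each of 5 hubs is a *deterministic monotone driver* of its
  own latent variable; its 20 partners load on that latent at
  `latent_loading = 0.85` with idiosyncratic Gaussian noise scaled by
  `noise_sd`.  Hub–partner pairs therefore have population correlation equal
  to the loading, partner–partner pairs its square — which is what gives hubs
  the highest degree once the 0.6 threshold is applied.  At `noise_sd = 0`
  and loading 1 the coupling is exactly monotone, so sample Spearman ρ is
  exactly ±1 (asserted on the closed relative-abundance output; multinomial
  count sampling necessarily perturbs ranks).
* **Latent draws** are random permutations of fixed standard-normal scores
  rather than iid normals.  This quantile matching leaves the rank structure
  (all that Spearman sees) untouched while removing the seed-to-seed lottery
  in the latent's empirical spread, which otherwise alternately saturates a
  whole group's correlations or starves its hub of edges.
* **Abundances.** Per-taxon log-normal baselines target mean fractions:
  hubs at half their ceiling (`hub_mean_rel_abund = 0.008`, so ~0.4%
  realized — the halving keeps every run under the ceiling despite sampling
  noise), partners at 0.3%, three abundant independent taxa at 10% each
  (labelled *Chloroflexus*, *Thermus*, *Roseiflexus*), and the background
  sharing the rest with a moderate log-normal spread.  Log-scale spreads are
  deliberately modest (`log_sd = 0.5`, abundant taxa 0.25): compositional
  closure couples every taxon through the shared denominator, and wide swings
  in any large group smear spurious correlations across the table.  The
  residual closure artifact is accepted and documented, not corrected — the
  planted loadings dominate it at n = 26.
* **Counts.** Fixed per-sample depth (83,610 reads, the survey's mean;
  per-sample depth variation is not modelled) via multinomial sampling;
  a `relative` output mode skips count sampling.
* **Taxonomy.** 30% of taxa carry an empty genus token (never the planted
  taxa), exercising the genus filter; hubs are labelled with the five
  culturable key-node genera.

Defaults were frozen after a one-time simulation study (4 disjoint 20-seed
blocks): planted-hub recovery by the full pipeline 96–100%, planted abundant
taxa never classified key, hub–partner mean sample |ρ| ≈ 0.785, and the
abundance contrast (hubs < 1%, abundant taxa > 5%) holding in every run.

The isolate generator plants exact per-phylum (4/5/3/6/69/142/13/77, total
319) and per-medium (239 SCM of 319) totals with randomized assignment, and
draws identities per novelty tier unless an explicit identity list is
supplied.  The assay generator plants OD590 mean shifts over a control
(defaults emulate a harvest-time experiment where only the 8/12/24 h
supernatants help; replicate noise sd 0.005).  The metabolome generator
plants 83 accumulating compounds among 412, with log-uniform folds in (2, 50),
a 0.5 weak fraction in (1.15, 2.0), one compound pinned at 78.9-fold
(deoxycytidine), accumulation concentrated late in growth (ramp 0, 0.05,
0.15, 0.40, 1.0 across 0/4/8/12/24 h), and log-normal replicate noise
(sd 0.15).  The effect-size mixture was calibrated once by Monte-Carlo so the
uncorrected ANOVA screen recovers ≈ 83 significant compounds (true positives
plus the expected ~16 false positives from 329 nulls at raw α = 0.05), then
frozen.

What the generators do **not** emulate: sequencing error and chimeras,
per-sample depth variation, overdispersion beyond log-normal × multinomial,
phylogenetic correlation among taxa, batch effects, or missing metabolite
values.  Passing recovery tests therefore demonstrates that the pipeline's
inference chain is correct under its own assumptions, not that the thresholds
are optimal for any particular real survey.

## Numerical conventions

Single integer seeds expand into per-generator substreams
(`SeedSequence([seed, tag])`), so module outputs are independent and each is
bit-reproducible for identical (spec, seed).  Problem sizes in the test suite
and acceptance script (20 pipeline seeds, 5 metabolome seeds, 1000-draw null
calibrations) were chosen to keep full runs in the seconds-to-minutes range
while leaving Monte-Carlo noise well inside the asserted bands.  Tolerances:
oracle equivalence at 1e-12 (rank correlation) and 1e-9 (Ward merge heights);
compositional closure at 1e-9.

## Known limitations

* Spearman-on-relative-abundance inherits compositional bias; SparCC-style
  corrected estimators are deliberately not offered because the point is to
  reproduce the plain-Spearman convention.
* The tie-absorption rule is one of several conventions consistent with
  "top/bottom 20% centrality" reporting; both supported rules are explicit
  parameters rather than a claim about any particular study's software.
* With 26 samples, a population |ρ| of 0.85 still leaves a ~0.6% chance per
  pair of falling under the 0.6 threshold; single-run hub recovery is
  therefore high but not guaranteed, which is why recovery is asserted as an
  average over seeds.
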