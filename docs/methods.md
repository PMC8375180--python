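# Methods

This note documents the models and procedures implemented in `xcnv`, the
conventions adopted where the underlying method leaves choices open, and
what the synthetic-data experiments do and do not demonstrate.

## Coordinates and domain types

All internal coordinates are 1-based inclusive (`length = end − start + 1`),
the convention of the large CNV archives. BED input (0-based half-open) is
converted on read and back on write; for structural-variant VCF records the
affected segment is POS+1..END (the anchor base at POS is excluded), with
SVTYPE DEL → loss and DUP → gain. Chromosome names are stored without a
`chr` prefix so calls from mixed sources compare. Only binary gain/loss
typing is supported — multi-allelic copy-number states are out of scope.
Population groups use nine codes (AFR, AMR, ASJ, EAS, FIN, NFE, SAS, OTH,
UKN); unrecognized or absent group values map to UKN rather than being
rejected, since "unknown" is itself a first-class group.

## CNV unification

Two calls on the same chromosome are indistinguishable when the Chebyshev
distance between their breakpoint pairs, `max(|ΔS|, |ΔE|)`, is strictly
below the genomic window GW (default 100 bp, the resolution below which
platforms cannot reliably distinguish breakpoints). Conventions adopted
where the method is underdetermined:

- **Boundary.** Distance exactly equal to GW counts as *not* similar (the
  defining cases are `<` and `>`; the boundary had to be assigned one way,
  and the strict reading keeps the window a true lower limit).
- **Types never merge.** A gain and a loss over the same segment are
  biologically distinct events, so similarity edges require equal type.
- **Clique extraction.** Each connected component of the similarity graph is
  reduced by repeatedly removing a maximum clique until empty. Ties among
  equal-size maximum cliques break by the lexicographically smallest sorted
  member-id tuple, making runs exactly reproducible. Clique enumeration uses
  networkx (`find_cliques`); the iterative removal loop and the tie rule are
  this package's.
- **Representative interval.** Per-coordinate median of member starts and
  ends, rounding half up — robust to a single outlier breakpoint. The
  representative is a summary, not a member.
- **Complexity.** Candidate pairs are limited to calls whose starts differ
  by less than GW (necessary for similarity), found by sorting per
  chromosome/type; the resulting graph is identical to the naive all-pairs
  construction (tested), avoiding the O(n²) blowup on large call sets.

Distinct carrier samples are counted once per unified CNV per group;
records without a sample id each count as one anonymous carrier.

## Population allele frequency

"Allele frequency" here is *carrier frequency*: the fraction of samples in
a group carrying the unified CNV (CNV archives report carrier samples, not
diploid genotypes). A query CNV takes the frequency of the best
reciprocal-overlap match (RO ≥ 0.7) among reference entries of the same
chromosome *and type*; ties on RO resolve to the higher frequency, and a
query with no qualifying match gets 0. The type restriction and the
deterministic tie rule are package conventions. The frequency enters the
feature matrix as two columns — gain-PAF and loss-PAF — with the query's
value in its own type's column and 0 in the other, so the booster can learn
type-specific frequency effects.

## Feature matrix (30 columns)

- **Universal (4):** length (bp); type encoded gain=1 / loss=0 (arbitrary
  but fixed); gain-PAF; loss-PAF.
- **Coding (13):** nine SNV-level deleteriousness aggregates (FATHMM, LR,
  LRT, MutationAssessor, MutationTaster, PolyPhen2, RadialSVM, SIFT, VEST3);
  three gene-level haploinsufficiency scores (pLI, Episcore, GHIS); and the
  count of overlapped protein-coding genes. The thirteenth slot is
  configurable — the gene count is a reasonable dosage-sensitivity proxy and
  keeps the schema at its declared width when only twelve scored sources are
  available.
- **Noncoding (8):** overlap with the six ENCODE cCRE classes (PLS, pELS,
  dELS, CTCF-bound, CTCF-only, DNase-H3K4me3) plus two CDTS columns.
- **Genome-wide (5):** CADD, GERP, phyloP 100-way, phyloP 46-way,
  SiPhy 29-way aggregates.

Aggregation conventions:

- **Positional scores** aggregate as sum / number of *scored* bases inside
  the CNV — i.e. the mean over covered positions. Dividing by total CNV
  length would conflate sparse annotation coverage with low deleteriousness;
  a `denominator="total"` switch preserves the alternative reading.
- **Gene scores** reduce over overlapping genes by `max` (the worst gene
  dominates pathogenicity), configurable to `mean`.
- **cCRE scores** default to covered-bp / CNV-length, bounded in [0, 1] and
  invariant to how region intervals are split. The inverted ratio
  (CNV length / total length of touched elements) is retained as
  `length_ratio` mode for comparability, but it is unbounded and treated as
  a formula inversion.
- **CDTS** features are the fraction of a CNV's scored bases below the
  genome-wide 1% and 5% CDTS percentile thresholds (low CDTS = constrained
  sequence). Thresholds are inputs carried by the annotation bundle, not
  recomputed from the query batch.
- **Missingness.** A CNV overlapping no scored base (or no gene) is missing
  for that feature; missing cells are imputed with the per-column minimum of
  the *training* matrix, at training and prediction time alike. Imputation
  is idempotent and a column entirely missing in training raises an error
  naming the feature.

## Classifier and MVP score

CNVs longer than 10 Mb are excluded before modelling (flagged "assumed
likely pathogenic" — at that size the class prior is overwhelming) and only
pathogenic/benign rows are used for training; the intermediate tiers are too
ambiguous to anchor a binary loss.

The hyperparameter search covers three boosters (gbtree, dart, gblinear) ×
four objectives (binary logistic, regression logistic, squared error,
squared-log error) by repeated stratified k-fold cross-validation (defaults
100 repeats × 10 folds; the synthetic studies use 5 × 5). Folds are
stratified by label to stabilize AUC at small n. Per repeat, fold AUCs
average into one value; the combination with the highest *median* across
repeats wins, ties resolving to the declared order (gbtree before dart
before gblinear; binary logistic first). Combinations that fail numerically
(squared-log error with a linear booster can leave the gradient's domain)
record NaN and cannot win. Tree depth (6), learning rate (0.3) and 50
boosting rounds are fixed library defaults with early stopping off — only
booster and objective are searched. Single-threaded training with a fixed
seed makes refits bit-reproducible.

The **MVP score** is the fitted booster's probabilistic output in [0, 1]
(higher = more pathogenic). Regression objectives can emit raw values
outside the unit interval; MVP clamps them with a warning — relevant only
during the search, since logistic objectives win on any realistic data.

**Five-tier cutoffs.** For each of the four ordered class boundaries
(benign | likely benign | uncertain | likely pathogenic | pathogenic),
classes above the boundary are positives and the cutoff is the observed
score value minimizing |sensitivity − specificity|; ties take the smaller
threshold (more sensitive boundary calls). The four cutoffs are derived
independently, so monotonicity is not guaranteed; violations are corrected
by a running maximum with a warning. Category assignment at cutoffs
(a, b, c, d): benign `s < a`; likely benign `a ≤ s < b`; uncertain
`b ≤ s < c`; likely pathogenic `c ≤ s ≤ d`; pathogenic `s > d` — the upper
boundary is inclusive on the likely-pathogenic side, matching the published
phrasing of the reference cutoffs (0.14 / 0.16 / 0.46 / 0.76), which ship
as `PUBLISHED_CUTOFFS`.

## Evaluation

The metric suite computes MCC, accuracy, F1, Fowlkes–Mallows index,
sensitivity and specificity directly from the confusion counts. MCC with a
zero denominator (an empty margin) is reported as 0 with a flag; ratios with
empty classes come back NaN with a flag rather than an arbitrary value. AUC
is the rank-based Mann–Whitney statistic with ties counted ½ —
threshold-free and invariant under monotone transforms of the scores.

The **leakage filter** drops every training CNV with ≥ 50% reciprocal
overlap to any validation CNV, ignoring type (a gain and a loss over the
same segment still share regional information — the conservative choice).
Stratified reports cover all CNVs, four length bins with boundaries at
10 kb / 100 kb / 1 Mb / 10 Mb (left-open, right-closed, so the bins tile
(0, 10 Mb] without overlap), and gain/loss. When external five-tier
predictions are dichotomized for comparison, pathogenic/likely-pathogenic
are positives, benign/likely-benign negatives, and uncertain rows are
excluded from binary metrics (that exclusion is this package's stated
choice). Relative improvement between metric values is (a − b)/|b| × 100.

## Synthetic data generator

`SimConfig` defaults define the standard study conditions: two 6 Mb
chromosomes; 200 samples (NFE 100, EAS 60, AFR 40 — a realistic skew toward
European-ancestry sampling); 500 true CNVs with lengths log-uniform between
1 kb and ~50 kb; 40% gains; Normal(0, 20 bp) breakpoint jitter with one or
two replicate calls per carrier. Each true CNV carries a latent liability
z ~ N(0, 1):

- **Rarity.** Carrier counts are 1 + Binomial(30, expit(−1.2 − 1.5 z)), so
  high-liability CNVs are rare — the purifying-selection pattern that makes
  PAF informative.
- **Annotations.** Track scores inside a CNV are Normal(w·effect_size·z, 1)
  at a sparse subset of bases (2% coverage, ≤ 40 positions, 10% per-track
  dropout so imputation paths are exercised; w = 0.8 for coding tracks, 0.6
  genome-wide, −0.8 for CDTS since constraint lowers it); background
  positions score N(0, 1), and the CDTS percentile thresholds are the
  standard-normal 1%/5% quantiles of that background. 70% of CNVs contain a
  gene whose pLI/Episcore/GHIS are liability-linked through a logistic
  transform; PLS and CTCF-bound elements are placed preferentially over
  high-liability CNVs, the other cCRE classes at a flat rate.
- **Labels.** latent = effect_size·z + N(0, 0.3), banded at its
  0.30/0.40/0.60/0.70 quantiles into the five tiers (30% benign, 30%
  pathogenic keeps binary training balanced). The band edges are recorded as
  ground truth for cutoff-recovery checks. `effect_size=0` severs every
  feature–label link and draws the latent as pure noise — the null
  condition.
- **Placement.** True CNVs sit on a per-chromosome slot grid guaranteeing
  same-chromosome start separation of ≥ 300 bp, so distinct events never
  fall within the 100 bp unification window even after jitter; the AF
  database is then built by the package's own unify-and-count pipeline on
  the jittered calls.

What the generator does *not* emulate: real length distributions spanning
into the Mb range, locus-specific mutation/recombination processes,
correlated annotation tracks, segmental-duplication hotspots, and
inter-database coordinate lift-over noise. Passing synthetic tests
demonstrates the pipeline's correctness and its ability to recover injected
signal under a known generative model — not real-data accuracy. The
headline real-data figures (training/validation AUC 0.96/0.94) require the
actual public CNV archives and annotation resources and are explicitly not
reproduced here.

## Validation studies and problem sizes

The acceptance studies run the full pipeline at 2000 true CNVs per dataset
over ten seeds — large enough for stable AUC estimates on a ~360-row
held-out split while keeping a complete run of tests plus acceptance in the
minutes range — with cross-validation reduced to 5 repeats × 5 folds for
the same reason. Under strong signal the held-out pathogenic-vs-benign AUC
exceeds 0.9 on every seed (observed ≈ 0.99); under the null it must fall in
the precomputed 95% Monte-Carlo band for the ten-seed mean, [0.4812,
0.5185], obtained by permutation simulation of the rank statistic.
Oracle suites check the clique partition against exhaustive enumeration on
200 random ≤ 12-node instances, jitter-closure on 100 replicated-CNV
instances, the metric formulas against independent arithmetic on the
exhaustive 0–20 confusion grid, and the AUC against the O(n²) pairwise
statistic.

## Known limitations

- The clique-removal loop is exponential in the worst case; it is fast on
  realistic similarity graphs (small, dense components) but adversarial
  components could stall it.
- AF lookup returns a single best match; overlapping reference entries are
  not frequency-merged.
- Gene-level features use interval overlap only — no transcript-aware
  consequence reasoning.
- Cutoff derivation needs all five classes present and at least a few
  observations per class to be meaningful.
- The booster's feature importances are gain-based and normalized; for the
  linear booster only weight magnitudes are available.
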