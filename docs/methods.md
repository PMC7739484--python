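# Methods

This note documents the statistical models behind `nichepart`, the
defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the places where the design was
genuinely open.

## Detection and presence

Detection (breadth of coverage) of genome *g* in sample *s* is the
fraction of *g*'s nucleotide positions covered by at least one read.
It is invariant under permutation of positions and monotone under
added coverage.  Presence is called when detection exceeds
`detection_presence_threshold` (default 0.5).  The comparator is
configurable because the two natural readings — strictly greater
vs. at-least — disagree exactly at the threshold; the default is
strict (`detection > 0.5`).  A second convention used by
coverage-classifier workflows derives the threshold from a tolerance
parameter α as 0.5 + α (0.6 at α = 0.1); this is exposed as
`ThresholdConfig.mcg_presence_threshold` rather than a separate mode.

With per-position depth c ~ Poisson(λ), expected detection is
1 − e^{−λ}: ≈ 1 at λ = 20, ≈ 0.5 at λ = 0.69.  Nonspecific read
recruitment to an absent genome covers a small random fraction of
positions, so absent genomes sit far below any sensible threshold —
this separation is what the 0.5 cutoff exploits.

## Non-outlier mean coverage and normalization

Depth is summarized robustly: positions whose coverage deviates from
the median by more than `outlier_mad_multiplier` (default 2.5) times
the median absolute deviation are excluded, and with
`zeros_are_outliers` (default on) zero-coverage positions are dropped
before the median and MAD are computed.  When MAD = 0 (heavily tied
data), only positions equal to the median qualify; when nothing
qualifies the mean is 0.  The MAD multiplier and the MAD = 0 fallback
are this package's choices — a standard robust rule — since upstream
tools do not publish their exact outlier criterion; both are
configurable.

To compare depths across samples of unequal sequencing effort, each
sample's read count is divided by the largest sample's count, giving a
factor in (0, 1], and non-outlier mean coverages are divided by that
factor.  Normalized coverage is invariant in expectation under uniform
downsampling of a sample's reads (tested at 50% downsampling,
tolerance 5% at ≥ 20× depth).

## Relative abundance

Reads recruited by each genome are divided by the sample's non-human
read count and by genome length; reads recruited by no genome form an
UNKNOWN bin whose length is unknowable (it aggregates many genomes)
and is set to a 2 Mbp surrogate.  The length-corrected values are
renormalized to proportions per sample so columns sum to 1 — the
renormalization is this package's convention and is documented because
upstream descriptions stop at "length-normalized abundance".

## Site specificity

A genome detected in ≥ 1 sample of exactly one site is a specialist
for that site; detection in ≥ 2 sites makes it cosmopolitan.
Subject-level prevalence counts a subject as positive at a site when
any of their samples from that site is positive (the any-sample rule
is our choice; an alternative majority rule would be stricter).  The
per-genome site-association test is Pearson's χ² on the 2 × 2
detected/not × site table without continuity correction (correction
available by flag); a zero margin — detected everywhere or nowhere —
yields χ² = 0, p = 1 by convention.

## Dereplication

Redundancy edges require ANI ≥ `ani_redundancy_threshold` (99.8%) and
alignment coverage of ≥ `ani_min_alignment_fraction_shorter` (0.5) of
the *shorter* genome; both comparisons are inclusive.  Groups are
connected components of the edge graph — the standard transitive
reading of "sets of genomes sharing the threshold"; a clique-based
reading is conceivable but changes nothing on data without
near-threshold chains.  Representatives maximize completion −
redundancy, then length, then take the lexicographically smallest id;
the final tie-break is ours, added so output is reproducible.  A
separate, looser alignment-fraction knob (0.25, on both genomes)
exists only for ANI *reporting* contexts and plays no role in
dereplication.

## Functional enrichment

Let y_g ∈ {0,1} be a function's occurrence in genome g (a function is
present iff any gene cluster annotated with it has count ≥ 1 — union
semantics; copy number is deliberately ignored).  The model is a
binomial GLM of y on the genome's group (clade) as a categorical
predictor.  The Rao score test of equal proportions evaluates the
score vector and expected information of the full design at the
intercept-only null fit, which is analytic (the pooled proportion p̄),
giving

    S = Σ_k n_k (p̂_k − p̄)² / (p̄ (1 − p̄)),   df = K − 1.

No iterative fitting is needed; the GLM-based numeric computation is
retained in the test suite as an independent oracle, alongside the
exact identity with Pearson's χ² of the 2 × K table and, for K = 2,
with the squared pooled two-proportion z statistic.  Degenerate
functions (present in all or no genomes) get S = 0, p = 1.

q-values use Storey's estimator by default: π̂₀ = min(1,
#{p > λ}/((1 − λ)m)) with λ = 0.5, then the step-up rule q_(i) =
min_{t ≥ p_(i)} π̂₀ m t / #{p ≤ t}; `fdr_method: bh` sets π̂₀ = 1
(Benjamini–Hochberg), the conservative fallback.  λ is fixed rather
than smoothed because the smoothing spline adds a tuning surface with
no benefit at the scale of a pangenome (hundreds to ~1000 functions);
when every p falls below λ, π̂₀ is floored at 1/m to keep q-values
positive.  Enrichment requires q strictly below
`enrichment_q_threshold` (0.05).  The functional core is defined by an
occurrence-fraction threshold (default 0.9) — "predominantly in all
genomes" is not an operational rule, so the fraction is exposed for
calibration.  A function's associated groups are those whose
occurrence proportion exceeds the pooled proportion.

Calibration, verified by the test suite on simulated data: type-I
error at p < 0.05 within [0.035, 0.065] under a Bernoulli null
(4 groups of 10, 2000 functions, 20 seeds); empirical FDR of the
q < 0.05 rule ≤ 0.10 on a 10%-alternatives mixture; power ≥ 90% for
planted enrichment at p_in = 0.9 / p_out = 0.1 with 20 genomes per
clade.

## SNV subpopulations

Only positions with coverage strictly above `snv_min_coverage` (20) in
*every* sample are assessed — missing (position, sample) records are an
error, not an implicit zero.  The minor-allele frequency is the
frequency of the second-most-frequent base (ties resolved by the fixed
order A < C < G < T); the "1 − dominant" shortcut is avoided because it
overstates the minor allele at triallelic sites.  A position is
variable in a group when the per-sample MAF reaches
`snv_maf_threshold` (0.10, inclusive) in at least one of the group's
samples; a group with zero variable positions is monoclonal, otherwise
mixed.

Detection vs. estimation: the per-sample maximum is the *detection*
rule — it flags a subpopulation present in any single sample — but as
an estimator of the subpopulation frequency it is biased upward by
roughly one order statistic of the binomial noise (≈ +0.05 at depth
100 over six samples).  Frequency *estimation* therefore uses the
pooled mode (`pooled=True`), which sums allele counts across the
group's samples before computing the MAF; pooling shrinks the standard
error by √(number of samples) and recovers planted frequencies of
0.2–0.4 within 0.05 at depth 100.

## Synthetic data

The generator emulates the tabular statistics of a two-habitat oral
cohort — not reads, sequences, or assemblies.  Defaults and rationale:

- **Cohort**: 7 subjects × 2 sites × 5 days = 70 samples, matching the
  scale of multi-day two-site sampling designs; read totals 15–30 M
  with 5–45% human contamination.
- **Occupancy**: 80% of genomes are single-site specialists (presence
  probability 0.9 per sample of their site), ~13% cosmopolitan, the
  rest absent — the regime where nearly all detected genomes are
  specialists.
- **Coverage**: Poisson depth (mean 20×) when present — the simplest
  model that exercises the detection threshold; overdispersion
  (negative binomial) would lower detection slightly but not change
  the present/absent separation.  Absent genomes get coverage 1 on a
  random 5% of positions (spurious recruitment).  Genome lengths are
  20–50 kb; detection and the robust mean are length-invariant in
  expectation, so the reduced scale changes only Monte-Carlo noise,
  not the quantities under test.
- **ANI**: 3 planted groups of 3 bins at ANI 99.85–99.98 with
  alignment fraction ≥ 0.5; all other pairs fail the rule, a tenth of
  them by high ANI with low alignment fraction (the case the coverage
  guard exists for).
- **Pangenome**: 4 clades × 10 genomes; 205 core clusters (all
  genomes), 60 accessory clusters per clade at p_in = 0.9 /
  p_out = 0.1, 500 singletons; annotation rates 0.90 (core), 0.55
  (accessory), 0.29 (singletons), mirroring the steep drop in
  annotation coverage from core to singleton gene clusters seen in
  real pangenomes.  Every tenth annotated core cluster shares its
  accession with the previous one so union semantics are exercised.
- **SNVs**: 2000 positions at depth ~100 for two groups of 6 samples;
  2% of positions carry a 0.40-frequency subpopulation in the mixed
  group only; sequencing error 1%.  This reproduces, at reduced scale,
  the signature of a cosmopolitan population that is monoclonal in one
  habitat and mixed in the other (≈ 2% variable positions, median
  minor-allele frequency ≈ 40%).

What passing tests on these simulations shows — and what it does not:
recovery results demonstrate that the estimators implement their
definitions correctly and are calibrated under the stated generative
models.  Real data add complications the generator omits: correlated
coverage along the genome, GC and mappability bias, overdispersed
depth, strain mixtures below the ANI threshold, mis-binned contigs,
and annotation errors.  Thresholds tuned here should be revisited
against such data rather than assumed transferable.

## Numerical and degenerate-input conventions

- Matrices are read/written as TSV with 10 significant digits;
  round-trips are exact to labels and ~1e−6 relative on values.
- Empty coverage vectors, zero-read samples, empty sample sets, and
  empty groups raise errors rather than returning sentinels.
- All generators and the pipeline driver are deterministic given the
  seed; independent RNG streams per stage keep one stage's draws from
  shifting another's.
- Positions are 0-based; 1-based exports must be shifted on ingest.

## Known limitations

- The enrichment test is asymptotic; with very small clades (n_k ≤ 3)
  the χ² reference is approximate and an exact test would be
  preferable.
- Storey's π̂₀ with fixed λ can be unstable for very few tests
  (m ≲ 50); use `fdr_method: bh` there.
- The dereplication graph uses connected components; a long chain of
  borderline pairs can merge genomes that are pairwise below the
  threshold.
- Subject-level prevalence assumes the any-sample rule; designs with
  very unequal samples per subject may prefer a fraction-based rule.
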