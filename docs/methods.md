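# Methods

## The question and the model

`pooldeg` evaluates a study-design question: when replicate RNA samples are
mixed in equal masses into one pooled library before sequencing, how well do
effect-size DEG criteria applied to that single library recover the genes
that replicate-based significance testing would have found? Everything in
the package serves that comparison: a generator with known truth, the
criteria themselves, and concordance statistics between called gene sets.

### Count generator

Each simulated experiment is a wild-type vs. mutant contrast over `n_genes`
genes. Baseline relative expression is log-normal,
`b_g ~ LogNormal(baseline_log_mean, baseline_log_sd)`; a fraction `frac_up`
of genes is planted as upregulated with true fold change `f_g` drawn
log-uniformly from `[fc_low, fc_high]`, and `frac_down` as downregulated
with `1/f_g` from the same law (symmetric on the log scale). Mutant means
are `b_g · f_g`. For each sample the gene-mean vector is rescaled to sum to
`library_size` and counts are drawn from a negative binomial with mean `m`
and variance `m + φ m²` (`dispersion` = φ; φ = 0 is the Poisson limit).
This is the standard bulk RNA-seq noise model; samples are plates of
hundreds to thousands of animals, so bulk (not single-animal) noise is the
right regime. Note that because profiles are renormalised per library,
planted fold changes are compositional: planting many strong up-genes
shrinks every observed CPM ratio by the total-mass factor, exactly as in
real sequencing.

### Pooling operator

Equal-mass pooling is modelled on relative abundances, not raw counts: each
replicate column is divided by its column sum (each replicate contributes
the same RNA mass regardless of its sequencing depth), and the pooled
profile is the unweighted mean of those proportion vectors. Two modes
separate the mixing arithmetic from sequencing noise: `expectation` returns
the profile scaled to `pooled_library_size` (linearity in the replicate
proportions is then exact and is asserted bit-for-bit in tests), and
`multinomial` returns one multinomial draw of that depth. Analysis matrices
therefore admit nonnegative reals; simulated and serialized count matrices
are strictly integer.

### Expression unit and group statistics

Counts are normalised to counts per million (CPM). No unit is canonical for
ratio-of-averages criteria; CPM is the minimal depth correction that makes
per-gene averages comparable across libraries, and gene length cancels in
every within-gene comparison, so no length correction is applied (no
TMM/median-of-ratios either — the criteria are deliberately simple). The
wild-type standard deviation uses the n−1 (sample) denominator over the
individually sequenced wild-type columns only; this is fixed, not
configurable, so results are reproducible from the config alone. Pooled
columns never enter `sd_wt` (a pooled library is a mixture, not a
replicate); `mean_mut` averages all mutant columns, so a lone pooled mutant
column passes through verbatim. A wild-type group consisting solely of
pooled samples is either an error or summarized by mean with `sd_wt = 0`,
per the `pooled_policy` flag.

### DEG criteria

A "T% increase" threshold is read as ratio > T/100 (500% → 5×, 150% → 1.5×):
the criterion compares the plain ratio of averages against the threshold.
The alternative reading (ratio − 1 > T/100) was considered and rejected —
with it the named thresholds would be 6×, 3× and 2.5×, which no longer match
the thresholds' own names. All comparisons are strict ("above the
threshold"), so a gene at exactly the boundary is not called. Conventions at
degenerate denominators are stated in the API docs and tested: a gene absent
in wild type but expressed in mutant has infinite ratio (called at any
threshold); a gene with zero `sd_wt` passes an SD criterion iff its mean
moved in the requested direction at all. Down-regulation mirrors
up-regulation by exchanging the roles of the two means. Combined criteria
are exact set intersections of their constituents, and all criteria are
monotone in their thresholds (property-tested).

The significance route is a per-gene Welch t-test on log₂(CPM+1) with
two-sided p-values and Benjamini–Hochberg adjustment across genes (rejection
at adjusted p ≤ α, sign must match the direction). It stands in for a full
DE pipeline by design: the package evaluates designs, so any transparent,
calibrated test suffices, and the chosen one is named in output metadata.
BH is delegated to `statsmodels` behind the `bh_adjust` surface; tests
verify it against a hand-executed step-up oracle. Genes with zero variance
in both groups get p = 1 (no evidence, rather than NaN propagation).

### Concordance statistics

Percent overlap divides the intersection by the smaller set
(`100·|A∩B|/min(|A|,|B|)`); identification is recall against a reference,
accuracy is precision of the candidate. Percentages are computed at full
precision and rounded half-up to integers only for display. Fold enrichment
requires an explicit background universe size N — there is no defensible
default, so none is guessed — and its hypergeometric upper-tail p-value is
computed by `scipy.stats.hypergeom`, with the natural-log tail reported
alongside because strong enrichments underflow double precision (a printed
"p = 0" is an underflow, not a probability). Tests compare the tail against
exact rational enumeration (`math.comb`/`Fraction`) for every
parameterization with N ≤ 25, and Venn partitions against per-element
enumeration. Identifier harmonization maps through a user-supplied
two-column table; ids absent from the table are dropped and reported
(retired identifiers no longer denote genes), and many-to-one mappings
deduplicate.

## Study orchestration and seeding

A study realizes one transcriptome as several arms. Gene-level biology
(baseline means and planted fold changes) is drawn once from the master
seed and shared by every arm — the arms are meant to be independent
sequencing experiments on the same biological contrast, and a single truth
set is what identification/accuracy are scored against. Per-arm count noise
uses seeds offset from the master seed by a fixed stride (7919·arm-index),
so arms are independent but the whole study is byte-reproducible. All
randomness flows through `numpy` `SeedSequence` children: one child for
gene-level draws, one for counts, a further offset for the pooled
multinomial draw.

Each arm is analyzed as its design dictates: individually sequenced arms use
all columns; pooled arms use the individually sequenced wild-type columns
plus the single pooled mutant column. The significance criterion is reported
as not-applicable for pooled arms instead of silently skipped. Two reference
sets are scored: the planted truth (available only in simulation) and the
intersection of the individually sequenced arms' FDR calls — the
replicate-anchored reference a real study would use. Percentages whose
denominator is empty are reported as `null`, never invented, and the report
validator recomputes every stored percentage from its stored counts.

## Defaults

| parameter | default | rationale |
|---|---|---|
| `n_genes` | 12 000 | order of detected genes in a worm bulk library |
| `replicates_wt/mut` | 6 | the replication level of the designs compared |
| `baseline_log_mean/sd` | 0.0 / 1.5 | several orders of magnitude of relative expression; location is irrelevant after renormalisation |
| `dispersion` | 0.05 | typical bulk dispersion for isogenic animals |
| `frac_up/frac_down` | 0.10 / 0 | a substantial upregulated programme |
| `fc_low/fc_high` | 2 / 8 | the effect range the ratio criteria target |
| `library_size` | 2 × 10⁶ | modest bulk depth; enough that counting noise is not limiting |
| `pooling_mode` | `multinomial` | realistic sequencing of the pooled library |

These are conventions chosen to emulate the study design, not estimates
fitted to any particular deposited dataset. The flat `key = value` config
dialect covers every generator field plus the design keys `arms`
(`name:reps_wt:reps_mut:pooled`, comma-separated), `criteria`,
`background_size` and `seed`.

## What the generator does and does not emulate

It emulates: two genotypes with biological replicates, smooth bulk noise,
library-size renormalisation (hence compositional fold-change distortion),
equal-mass pooling, and known truth. It does not emulate batch or
collection-day effects, gene length or GC bias, mapping ambiguity, isoform
structure, or any upstream read-level processing — counts are the atomic
unit. Consequently, passing tests show that the criteria and the pooling
arithmetic behave as specified under the stated noise model; they do not
show that a particular wet-lab pooled design will match an individually
sequenced one in the presence of batch structure the model excludes.

## Problem sizes

The test suite runs null-calibration at 20 × 2000 genes, power checks at
1000 genes, and the pooled-design recovery study at 12 000 genes with 6+6
replicates and 2M-read libraries; the acceptance script uses the same sizes.
Monte-Carlo moment checks use 1000 replicate samples (variance vs. mean
within 3 standard errors) and 500 replicates per genotype for fold-change
recovery (within 10%, after accounting for the compositional mass factor —
with 0.4% of genes planted at fold change 4, the expected observed ratio is
already ≈ 3.94, not 4).

## Known limitations

- The significance route is a two-sample Welch t per gene, not a
  negative-binomial test with dispersion shrinkage; with 3 replicates it is
  conservative (see the `indiv3` row of the README example).
- Fold enrichment is only as meaningful as the supplied background size.
- Multiway partitions are exact set algebra; no proportional-area Venn
  rendering is attempted.
- Pooled arms pool the mutant side only; pooling both sides would leave the
  SD criteria without any replicate spread and is not implemented.
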