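# Methods

## Model and procedure

`lncgba` annotates lncRNAs by guilt by association: a lncRNA inherits
candidate functions from the protein-coding genes whose expression
profiles track its own across a panel of conditions (typically
tissues).  The pipeline has two statistical stages.

### Co-expression stage

For each (lncRNA, coding) pair the sample Pearson correlation r is
computed over the n conditions and tested with the exact
bivariate-normal test, t = r·√(n−2)/√(1−r²) against t(n−2),
two-sided.  This requires n ≥ 3 and nonzero variance in both
profiles; constant profiles have no defined correlation, so such
pairs are dropped (and counted) rather than assigned r = 0.

All lncRNA × coding pairs form one multiple-testing family, adjusted
by Benjamini–Hochberg.  BH is the default because distinct gene pairs
are much closer to the independent-test regime BH assumes than the
nested term families of the enrichment stage; Benjamini–Yekutieli is
available behind the same interface for users who want control under
arbitrary dependence.  An edge requires |r| > 0.9 **and** adjusted
p < 0.05, both inequalities strict.  With 19 conditions, |r| = 0.9
corresponds to t ≈ 8.5 on 17 degrees of freedom (raw p ≈ 1.6×10⁻⁷),
so the |r| cutoff, not the p cutoff, usually binds at panel sizes in
the tens; the p threshold matters for larger condition panels.

The pairwise computation is blocked over lncRNA rows; block size
changes memory use only, never results, and output order is fixed
(lexicographic in lncRNA then coding id) so files are byte-stable.

Expression values are used as read.  A log2(x+1) transform and a
minimum-expression prefilter exist as opt-in flags but default to
off: correlation on the raw scale is the baseline behaviour, and any
transform belongs to the user's explicit choices, not hidden
defaults.

### Enrichment stage

A query of n coding genes is tested against each functional term with
the upper hypergeometric tail

p = Σ_{i=m}^{min(n,M)} C(M,i)·C(N−M,n−i) / C(N,n)

where N is the size of the protein-coding universe, M the term's
annotated genes within that universe, and m the query/term overlap.
The universe defaults to *all* protein-coding genes in the supplied
catalog (not only annotated ones); M is always counted after
intersecting the term's gene set with that universe so numerator and
denominator describe the same population.

GO annotation follows the true-path rule: a term's gene set is the
union of direct annotations over the term and all of its descendants
along `is_a` and `part_of` — the two relations for which ancestor
inheritance is semantically safe; other relationship types are
ignored for propagation.  Propagation is a single topological sweep
(children before parents) and is idempotent.  All three GO namespaces
are loaded; enrichment can be restricted to one namespace by flag.
GAF evidence codes are all accepted by default (an exclusion list is
available), and `NOT`-qualified rows are always skipped.

Two size filters guard the test where it is unreliable:

* terms with M < `min_term_size` (default 5) are not tested;
* queries with n < `min_coexp` (default 5) are "not annotatable" —
  an explicit outcome carrying a reason, distinct from an empty
  result list.

Each `enrich` call is one correction family: exactly the set of terms
tested in that call.  GO families use Benjamini–Yekutieli, since
ancestor/descendant terms share genes and their p-values are strongly
positively dependent; pathway collections are flat and use
Benjamini–Hochberg.  Significance is corrected p < 0.05 (strict).

### Set annotation

A set query is reduced to the union of coding genes co-expressed with
at least K of its members (support counts are reported but never
weight the test; n is the plain union size).  K = 1 is the default;
raising K shrinks the union monotonically.  Query lncRNAs absent from
the network contribute nothing but are listed in a skipped-ID report
rather than dropped silently.

## Numerical choices

* The hypergeometric tail is summed in log-space: each term's log-pmf
  comes from log-gamma, the tail is combined with log-sum-exp (the
  batch path uses a cumulative `logaddexp` from the largest i down).
  All terms are positive, so there is no cancellation and the
  relative error is dominated by log-gamma accuracy; against exact
  integer arithmetic over every instance with N ≤ 60 the worst
  relative error observed is ~10⁻¹³, and an extreme published
  contingency at p ≈ 10⁻¹⁰⁹ is reproduced on the log scale.  m = 0
  returns exactly 1, and `hypergeom_log_pvalue` is exposed for tails
  beyond double-precision underflow.
* BH/BY adjustments are delegated to
  `statsmodels.stats.multitest.multipletests` and pinned by tests to
  hand-stepped oracles; Pearson p-values use the regularised
  incomplete beta (vectorised) and are pinned to a
  numerical-integration oracle of the t density.
* r is clamped to [−1, 1] after the dot-product computation; |r| = 1
  maps to p = 0 exactly.
* Result ordering is fully deterministic (corrected p, then raw p,
  then term id), and output files use 17-significant-digit floats so
  a write/read cycle is bit-exact.

## Synthetic fixtures

`lncgba.synthetic` generates self-contained datasets with known
truth.  Each of `n_modules` modules draws one latent profile z over
the conditions; every member gene (coding and lncRNA) is
s·z + σ·ε with i.i.d. Gaussian noise, so two members correlate at
ρ = s²/(s²+σ²) and s is solved from the target ρ in closed form.
Background genes are pure noise.  Module coding genes are directly
annotated to a module-specific GO leaf (all leaves under one root)
and to a module-specific pathway.  Non-negativity is achieved by a
single constant shift of the whole matrix (correlation-invariant;
an exponentiation mode exists for users who want multiplicative
scale).

Defaults — 19 conditions, 5 modules of 20 coding + 3 lncRNA genes,
ρ = 0.95, σ = 1, 150 background coding + 50 background lncRNA genes —
describe a tissue-panel-sized problem in which a planted lncRNA's
sample correlation with its module (≈0.95 ± 0.02 at 19 conditions)
clears the 0.9 edge threshold with high probability, so end-to-end
recovery is expected but not trivially guaranteed.  What the fixture
does *not* emulate: heavy-tailed FPKM distributions, shared library
size or batch structure, correlated background genes, isoform-level
effects.  Passing the recovery tests therefore demonstrates the
pipeline's correctness under its own model assumptions, not
performance on real RNA-seq.

The null calibration check draws random queries independent of
random term gene sets and asks that the fraction of raw p-values
below 0.05 be close to 0.05.  Because the hypergeometric is discrete,
that fraction is biased low when the attainable p-values near 0.05
are sparse; the simulation therefore uses sizes chosen in advance to
make the distribution nearly continuous (universe 5,000; term sizes
500–2,000; query size 300), for which the largest attainable p below
0.05 is close to 0.05 and the bias is within the stated ±0.02 band.

Problem sizes in the test suite (fixture of 315 genes × 19
conditions, 20 replicate seeds, exhaustive oracle at N ≤ 60) were
chosen so the full suite completes in seconds while each check still
exercises the regime it is about: the exhaustive small-N sweep covers
every attainable contingency shape, and the replicate fixtures give
300 planted (lncRNA, term) decisions for the recovery rate.

## Design decisions and limitations

* The co-expression significance test (exact t-test) and its
  correction family (one global BH family over all pairs) are the
  package's own choices among defensible options; per-lncRNA families
  and rank-based correlations are deliberately out of scope.
* Corrected p-values depend on the family size, i.e. on exactly which
  terms enter a call; comparisons across runs are only meaningful
  with identical ontology, annotation, universe and filters.
* Biotype is load-bearing: genes absent from the catalog are dropped
  with a logged count, never guessed.
* Pathway files are treated as opaque gene-symbol sets; no identifier
  mapping is attempted.  Users must ensure expression, annotation and
  pathway files share one gene-identifier space.
* The estimator classes (`CoexpressionNetworkBuilder`,
  `FunctionalAnnotator`) follow scikit-learn conventions (parameters
  at construction, data in `fit`, fitted attributes with trailing
  underscores) so they compose with sklearn tooling; module-level
  functions remain as thin wrappers for script use.
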