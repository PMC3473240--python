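# Methods

## Corpus construction

A GAF 2.x file is read one annotation line at a time (1-based column 4
qualifier, 5 GO id, 7 evidence code, 9 aspect letter). Each surviving
line contributes **one token** to its corpus, so a gene–term pair
annotated under two evidence codes counts twice. This matches
"number of annotations" bookkeeping and keeps per-line evidence
filtering well defined; a `dedupe` switch collapses to one token per
(gene product, term) pair for users who prefer type counts. Lines with
fewer than 15 columns, malformed GO ids or unknown aspect letters are
skipped with a counted warning rather than aborting — real annotation
corpora are dirty and a hard failure on line 3 of 50,000 helps nobody.

NOT-qualified annotations are **excluded by default**: a statement that
a gene product does *not* have a function is not a use of the term in
the Zipfian sense. They can be kept with `exclude_negated=False`.

Evidence classes: HC = {IDA, IPI, IMP, TAS, EXP, IC, IEP, IGI},
LC = {IEA}, ALL = no filter, plus arbitrary CUSTOM sets. When an
ontology is supplied, alternate GO ids are resolved to primary ids
before counting; otherwise tokens are taken as written.

Frequency tables rank distinct terms by descending count with ties
broken lexicographically by term id, so every downstream quantity is
deterministic.

## Power-law fitting

Term frequencies are small positive integers, so the discrete
(Hurwitz-zeta) formulation is used throughout; the continuous MLE
appears only as a test oracle.

- **MLE.** ℓ(β) = −n·ln ζ(β, xmin) − β·Σ ln x_i over the tail
  x_i ≥ xmin, maximised by bounded scalar search on β ∈ (1, 10] with
  xatol = 1e−6. ζ is `scipy.special.zeta`. A tail with a single
  distinct value has a divergent MLE and is rejected.
- **Standard error.** From the Fisher information
  n · d²/dβ² ln ζ(β, xmin), with the second derivative by central
  differences (h = 1e−4); at these curvatures the finite-difference
  error is orders of magnitude below the statistical error.
- **KS distance.** max over distinct observed tail values of
  |empirical − model| tail CCDF, both conditioned on x ≥ xmin; the
  model tail CCDF is ζ(β, x)/ζ(β, xmin).
- **xmin selection.** Every distinct observed value whose tail holds at
  least `min_tail` points (default 10) and two distinct values is a
  candidate; smallest KS wins, ties to the smallest xmin (largest
  tail). The default minimum tail keeps the MLE from chasing
  ten-point tails while still letting small corpora fit.
- **Goodness of fit.** Semi-parametric bootstrap: each replicate of
  size n draws each point, with probability n_below/n, uniformly from
  the observed sub-xmin values, else from the fitted discrete power
  law; each replicate is refit from scratch (including xmin selection)
  and p is the fraction with refit KS ≥ observed. Default 1000
  replicates (the pipeline default is 200, chosen to keep a
  multi-corpus run interactive; p is then granular at 0.005).
  p > 0.1 sets the `plausible` flag. The p-value is deterministic given
  its seed. In the rare replicate where no xmin candidate exists the
  replicate is counted as fitting worse, biasing p conservatively
  upward.

Exponent algebra: β = 1 + 1/α, α = 1/k, β = 1 + k are enforced jointly
to 1e−9 by the `ZipfExponents` container; conversion from any one
exponent fills in the other two.

## Synthetic corpora

The generator draws per-term **target frequencies** from the discrete
power law at (β_true, xmin) — i.e. it samples the frequency
distribution the fitter assumes, the Pareto-of-frequencies form, not a
rank model — then emits `n_annotations` records by sampling terms with
probability proportional to their targets, with evidence codes i.i.d.
from a profile. Sampling is inverse-CDF on a tabulated CDF (cap 10⁶,
configurable); the rare draws beyond the table are inverted exactly
against the analytic Hurwitz-zeta CCDF, so no tail mass is lumped or
distorted. Synthetic ids use the reserved GO:9xxxxxx range.

Defaults emulate one sub-ontology of a mid-sized genome annotation
release: 50,000 annotations over 2,500 terms (the October-2009 GOA
corpora run ~23k–75k annotations over ~50–5,400 distinct terms per
sub-ontology), β_true = 2.0 (the value typical of both natural-language
corpora and GO annotation), and an evidence profile of 55% IEA, 34% HC
codes, 11% ISS — roughly the manual/electronic mix of the human and
mouse releases.

**What the rendering does and does not preserve.** The realised counts
are a multinomial rendering of power-law targets. The tail exponent is
preserved, but near the low-frequency end the count distribution is a
Poisson-type mixture rather than an exact zeta law, which adds variance
and a small upward bias (~+0.05 at 20k annotations / 2k terms) to the
fitted β beyond the MLE's Fisher-information standard error. Tests of
the corpus route therefore check the median error across seeds; the
sharp recovery property (median |β̂ − β_true| ≤ 0.05 with 3-SE coverage
≥ 95% at 20,000 tail points) holds on direct frequency samples, where
the MLE's sampling theory applies exactly. Real corpora differ from
the generator in further ways it does not attempt to model — curation
dynamics, term obsolescence, correlated annotation of related gene
products — so passing tests demonstrate correctness of the estimators,
not that any particular real corpus is power-law distributed.

The toy ontology is a balanced is_a tree per namespace (root depth 0);
optional cross-edges add a second parent one level up, which keeps the
graph a DAG and provably leaves shortest-path depths unchanged. With
`shallow_frequent_coupling`, the largest target frequencies are
assigned to the shallowest terms, giving the generic-terms-are-frequent
structure seen in real annotation.

## Term depth

Depth is the length of the **shortest** is_a path from a term to its
namespace root; part_of and other relations are ignored. This matches
the conventional reading of "levels down from the root" (e.g. protein
binding two levels below the molecular-function root); longest-path
depth would systematically inflate multi-parent terms. Quartiles are
over distinct terms (not tokens), floor(n/4) each, with boundary ties
resolved by the frequency table's deterministic order. Significance
across corpora is a paired t-test on (top, bottom) mean-depth pairs.

## Exponent comparisons

Per-sub-ontology means are plain arithmetic means of fitted β. The
high- vs low-confidence comparison is a paired t-test across
(species × sub-ontology) cells. Two-sided p-values are the default;
the one-sided value is exposed because the directional hypothesis
(experimentally supported annotation uses a richer vocabulary, hence a
steeper exponent) is the one of interest — on the published
October-2009 GOA pairs the one-sided p is 0.011 and the two-sided
0.021. Size association uses Spearman rank correlation of β with the
distinct-term count and with the total annotation count; a constant β
is defined to have correlation 0. No multiple-testing correction is
applied across this handful of comparisons.

## Numerical and degenerate-input choices

- ζ(β, q) in double precision via scipy; the MLE search interval is
  β ∈ (1 + 1e−6, 10].
- Empty corpora, empty tails, single-distinct-value tails, cyclic
  is_a graphs, obsolete/unknown terms and zero-variance paired
  differences all raise typed exceptions rather than returning NaN.
- Bootstrap and generator randomness flows exclusively through
  `numpy.random.default_rng` seeds; pipeline runs derive one seed per
  corpus from the run seed, and rerunning a config writes byte-identical
  JSON.

## Problem sizes used in the test and acceptance runs

Parameter recovery uses 20,000-point samples (3 exponents × 20 seeds);
GOF calibration uses 200 runs of 200-point samples at 250 bootstrap
replicates (a reduced but still calibrated setting — the fraction of
null runs with p < 0.1 stays near 0.1); the depth property uses 20
corpora of 8,000 annotations over 600 terms. The acceptance script
runs a trimmed version of the same computations (5 seeds per exponent,
60 calibration runs at 150 replicates, one 50,000-annotation pipeline
corpus).

## Known limitations

- No comparison against alternative heavy-tailed models (lognormal,
  stretched exponential) — a power law being *plausible* is not a power
  law being *the best* model.
- The true-path rule (propagating annotations to ancestors) is not
  applied; tokens are the terms as annotated.
- Only is_a edges enter depth; GO's part_of and regulates relations are
  ignored, and real GO depths depend on the ontology release used.
- Published exponents for the October-2009 GOA corpora are shipped as
  reference inputs for the comparison operations; refitting those
  corpora requires the original release files, which are not included.
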