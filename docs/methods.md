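# Methods

`hscnet` implements a cross-tissue gene-set association analysis — the kind
used to ask whether genes specifically expressed in hematopoietic stem cells
(HSCs) are over-represented in neurological-disease protein-interaction
networks or among mouse-knockout phenotype annotations — together with the
single-hit Poisson estimator of repopulating-cell frequency from
limiting-dilution transplantation. This note records the models, the defaults
and why they were chosen, the numerical choices, and what the synthetic-data
generator does and does not emulate.

## Overlap model

All comparisons are asymmetric: a *fixed set* of size `K` (e.g. a 319-gene
HSC expression fingerprint) is held fixed within a *universe* of `N` genes
(everything that could have been sampled on the platform), and a *comparator
set* of size `n` (e.g. a differential-expression list, an interactome's gene
complement, or a phenotype annotation set) is modeled as a random draw. Under
the null the observed overlap `a` is central hypergeometric with

- expected overlap `E = (K/N)·n` (fixed-set frequency times comparator size),
- SD, by default the finite-population (hypergeometric) form
  `sqrt(n·p·(1−p)·(N−n)/(N−1))` with `p = K/N`. The binomial form
  `sqrt(n·p·(1−p))` is available as an option and is recorded in the output
  metadata. The hypergeometric default was chosen because it is the SD of the
  same distribution whose mean the expected-overlap formula is; the two
  differ only by the `(N−n)/(N−1)` correction.

The enrichment Z-score is `(a − E)/SD`. When the SD is degenerate (zero), a
matching observation gives Z = 0 and a mismatch gives a signed infinity so
that the degeneracy is visible rather than a NaN.

### Cross-platform hygiene

Comparing lists from different platforms or species requires (i) a case
normalization (upper-case by default, since mouse `Gata2` and human `GATA2`
differ only in case; `asis` for same-species work), (ii) ortholog mapping
through homology groups built as connected components of (source, target)
pairs — by default a source contributes *all* of its group's targets, with a
stricter `drop_ambiguous` policy available — and (iii) restriction of the
comparator to the fixed set's universe before counting, so that genes that
could never have been sampled do not inflate the "neither" cell. Symbols lost
at each step are counted and logged; the pipeline surfaces them in its run
log because silent attrition is where such analyses usually go wrong.

## Fisher's exact test

`fisher_p` computes the exact hypergeometric tail (one-sided) or the
minimum-likelihood two-sided p (sum over all tables with the same margins
whose point probability does not exceed the observed one). For universes with
`N ≤ 500` the tails are summed in exact integer arithmetic
(`math.comb` + `Fraction`), so small-table p-values carry no floating-point
accumulation at all; above that the same sums are done in log space with
`gammaln` and `logsumexp`. On the log-space path, two-sided ties are detected
with a 1e−7 relative tolerance (the convention of the major statistical
environments). Both one-sided (greater) and two-sided values are always
reported; table outputs carry both columns so the caller chooses the
headline.

## Odds ratio

Two estimators are provided:

- `sample`: `(a·d)/(b·c)` with the Haldane–Anscombe +0.5 applied to every
  cell when any cell is zero, and a Wald 95% CI on the log odds ratio.
- `cmle` (default): the conditional maximum-likelihood estimate under the
  Fisher noncentral hypergeometric distribution with all margins fixed — the
  value of the odds parameter at which the conditional expectation of the
  overlap equals the observed count — with the CI obtained by inverting
  one-sided exact tests at 2.5% per side. This matches the estimator/CI style
  of standard exact-test software and is therefore the default for reported
  results. An overlap at its margin-feasible maximum (minimum) has no finite
  CMLE; the result is flagged with an open upper (lower) bound rather than
  raised as an error, and a zero margin yields a flagged degenerate result.

The CMLE and its CI are found by bracketed root finding on the log-odds scale
(brentq, 1e−12 tolerances, bracket expanded geometrically); the noncentral
pmf is normalized explicitly over the feasible overlap range with cached
log-binomial weights per margin triple, which makes repeated inference on
same-margin tables (the common case in simulation) cheap.

No multiple-testing correction is applied by default; Benjamini–Hochberg
adjustment (via statsmodels) can be switched on and adds a column rather than
replacing raw p-values.

## Phenotype annotations

MGI-style gene–phenotype data are held as a binary gene × phenotype incidence
matrix. Set-vs-phenotype enrichment treats each phenotype column as a
comparator set; the universe defaults to the genes present in the matrix —
the genes actually *tested* for phenotypes — because enrichment against all
genome symbols would confound phenotype association with testedness. The
phenotype–phenotype association measure is the phi coefficient (Pearson
correlation of the binary indicator columns, equivalently the normalized 2×2
determinant), chosen because it is the natural measure on a [−1, 1] heatmap
scale. Genes with all-zero rows are retained (co-absence is informative).
Constant columns make phi undefined; such pairs are flagged through an
explicit definedness mask instead of silently propagating NaN. Phenotype
labels are free strings; no phenotype-ontology traversal is attempted.

## Interactome projection

Interactomes are undirected simple graphs (self-loops dropped on read,
reversed duplicates collapsed; SIF relation labels kept as edge attributes
but ignored by the analysis). The projection retains exactly the edges with
at least one endpoint in expressed ∪ fingerprint and classes each retained
node with precedence fingerprint > expressed > partner. The union rule means
a fingerprint gene missing from the expressed list still retains its edges —
fingerprint genes are expressed by definition, so disagreement between the
two inputs is treated as an inconsistency to warn about, not to obey.
Consequently no retained edge connects two partner nodes. Degrees
("connectedness") are computed within the projection, not the parent graph.
GraphML export carries node class and degree and round-trips exactly.

## Limiting-dilution analysis

Each recipient is scored engrafted when its percent multilineage chimerism is
*strictly* greater than the threshold (default 0.1%); a reading exactly at
the threshold is negative. Under the single-hit Poisson model the probability
that a recipient of dose `d` fails to engraft is `exp(−f·d)`, giving the
binomial log-likelihood

    ℓ(f) = Σ_groups [ neg·(−f·d) + pos·log(1 − exp(−f·d)) ].

`ℓ` is strictly concave in `f` whenever the data contain at least one
positive and one negative animal, so the MLE is the unique root of the score
function, found by bracketed root finding (relative tolerance 1e−14; the
single-dose closed form `f = −ln(neg/tested)/d` agrees to better than 1e−8
relative, which is asserted by a property test). All-negative data yield
`f = 0` with a `zero` boundary flag; all-positive data have no finite MLE and
are flagged `infinite` — neither is an exception, because both occur in real
dilution series.

The default 95% CI is Wald on `log f` using the observed information
(`I_logf = −f̂²·ℓ''(f̂)`), the standard choice of limiting-dilution software; a
profile-likelihood CI is available for boundary-adjacent data. The
non-responder curve reports `(d, ln(fraction negative))` per dose group —
linear through the origin with slope `−f` under the model — with groups at
zero negatives flagged excluded (their log-fraction is undefined) while still
contributing to the likelihood.

## Synthetic data

The generator produces every input the analysis consumes, from one root seed
with a fixed stream offset per generator (adding a generator never perturbs
another's output). Defaults are the study-scale conditions the package is
aimed at: a 20,000-gene universe, a 319-gene fixed set, a 1,013-gene
comparator, an ortholog map covering 86% of symbols (so a 319-gene set maps
to ~274 targets), dilution experiments with true frequency 1e−4 at doses
2×10³/10⁴/5×10⁴ with 10 animals per dose.

- Overlap pairs: the overlap count is sampled from the Fisher noncentral
  hypergeometric at a planted odds parameter by explicit normalization of the
  likelihood over the feasible range (no rejection sampling); odds = 1
  reduces exactly to the central hypergeometric, odds 0/∞ to the
  minimal/maximal feasible overlap. Members are then placed uniformly.
- Annotations: phenotypes are split into blocks and each gene gets a latent
  block; annotation probability is `within_rate` (default 0.4) for own-block
  phenotypes and `between_rate` (default 0.05) otherwise, which plants
  positive within-block phi by construction. The defaults were chosen once as
  plausible annotation prevalences for knockout-phenotype data.
- Interactomes: Erdős–Rényi G(n, p) by default (n = 250, p = 0.02), with a
  preferential-attachment mode for heavy-tailed degree distributions.
- Dilution experiments: per-animal engraftment ~ Bernoulli(1 − exp(−f·d)).

What the generator does *not* emulate — and hence what passing tests do not
establish about real data: real phenotype-ontology structure and its
literature reporting bias, real interactome topology (degree mixing,
clustering), gene–gene correlation within sets, and microarray intensity
noise upstream of the input lists. The generator validates the statistics'
calibration and recovery, not the biology of any particular curated list.

## Problem sizes used in the checks

The bundled statistical checks run at: the full 2×2 grid to `N = 25` against
exact-rational enumeration (plus literal subset enumeration at `N ≤ 10`);
10,000 null overlap draws at `N = 5000, K = 300, n = 1000` for Z and test
calibration; 500 noncentral tables at odds 2 for CMLE recovery and CI
coverage; 1,000 simulated dilution experiments for frequency recovery; and
100 random-graph projections against a brute-force filter. These sizes give
sub-percent Monte-Carlo error on the checked summaries while keeping the
whole suite fast.

## Known limitations

- The CMLE CI inverts one-sided exact tests; like all exact 2×2 intervals it
  is conservative (coverage above nominal), which is the accepted trade-off.
- The Wald CI on `log f` degrades when the positive (or negative) count is
  very small; use the profile CI near boundaries.
- No GSEA-style rank statistics, permutation gene-set tests, multi-hit or
  heterogeneity dilution models, or graph layout/rendering — exports are
  data files for downstream viewers.
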