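# Methods

## Model

A protein family is represented by a profile hidden Markov model: a
chain of match states, each carrying an emission distribution over the
20 standard amino acids. The package treats these models as given
(read from HMMER3 ASCII files); it does not train them. A substitution
is scorable when three conditions hold:

1. a domain assignment aligns the protein to a model with e-value
   ≤ `e_max` (default 0.01);
2. the substituted residue maps onto a **match** state under the
   assignment's M/I/D alignment string (insert columns and positions
   outside the aligned span are unscorable);
3. the model is resolvable in the registry.

When several assignments cover the position, the model with the largest
information gain is used: the Kullback–Leibler divergence (in nats) of
the emission vector at the mapped match state from a background amino
acid composition. Positional KL is the default because the score itself
is positional; a whole-model mean-KL mode is available
(`select_model(..., positional_kl=False)`). Ties break on lower
e-value, then lexicographic model id, so selection is deterministic and
invariant to assignment order.

The magnitude-of-effect score is

    score = ln( P_m (W_p + δ) / ( P_w (W_c + δ) ) )

with P_w, P_m the wild-type/mutant emission probabilities at the match
state and W_c, W_p the model's pathogenicity weights. The score is
strictly increasing in P_m and W_p and strictly decreasing in P_w and
W_c, reduces to ln(P_m/P_w) when W_c = W_p, and is antisymmetric under
swapping wild-type and mutant at equal weights. Scores ≤ τ are labelled
CANCER. The boundary is inclusive by design: an exact-threshold score
is a positive call, never silently neutral.

## Pathogenicity weights

Weights are estimated from a labelled catalogue (CANCER /
NEUTRAL variants). Each variant is routed through model selection at
its own position; W_c for a model is its share of all mapped CANCER
variants, W_p its share of all mapped NEUTRAL variants ("relative"
mode, each class summing to 1 across models). A "raw" mode exposes the
unnormalised counts instead, since per-model counts are the other
defensible reading of relative frequency; the mode is recorded in the
weight-table file header. Duplicate catalogue records collapse to one;
a substitution carrying both labels is a validation error rather than
being arbitrated.

The pseudo-count δ (default 1.0) is applied at scoring time as
(W + δ), not folded into the stored table, so stored weights remain
interpretable as frequencies and a model absent from the table
degrades gracefully to the unweighted log-ratio (W_c = W_p = 0).

For models built ab initio from homologous-sequence alignments rather
than curated domain libraries, weights aggregate over the member
proteins that contributed sequences to the model
(`weights_for_ab_initio_model`), using the same dataset totals so the
two weighting routes are commensurable. The package starts from the
membership table such a homology search would produce; running the
search itself is out of scope.

## Evaluation protocol

Drivers are the positive class; "score ≤ τ" predicts positive.

*Normalized metrics.* Each class is first reduced to rates
(sensitivity s, specificity e, false-positive rate f, miss rate m) and
the six parameters are computed from the rates: accuracy = (s+e)/2,
precision = s/(s+f), NPV = e/(e+m), MCC = (se − fm)/√((s+f)(s+m)(e+f)(e+m)).
This makes the metrics insensitive to class imbalance; raw-count
formulas are available with `normalized=False` and agree exactly on
balanced classes. Undefined ratios (zero denominators) propagate as
`None`, never as silent zeros.

*Cumulative ROC.* Scores sweep from most to least damaging; tied
scores are processed as one block so the curve cannot depend on input
order. The trapezoidal area on the rate scale equals the Mann–Whitney
concordance (ties counted half), which the tests verify by brute
force. An optional cap truncates the curve at a false-positive
fraction (e.g. 1%) for the conservative regime.

*Threshold derivation.* Candidate thresholds run over
[min score, max score] in steps of `grid_step` (default 0.05); the
returned threshold maximises the sum over datasets of sensitivity +
specificity (summed Youden index — the standard scalarisation of
"both maximized"). Ties resolve to the candidate closest to the median
of the tied set, then the most negative. The shipped default τ = −0.75
is the documented operating point of the method on its original
mutation datasets; it is a configuration value here, not something the
synthetic studies re-derive.

*Cross-validation.* k-fold CV rebuilds the weight table from the fold
complement before scoring the held-out fold, removing the circularity
of scoring a variant with weights it contributed to. Folds are
label-stratified and seeded; variants are canonically sorted before
the seeded shuffle, so fold membership depends only on the variant set
and seed, not input order. k = n gives leave-one-out, implemented as
single-variant exclusion (the table rebuilt without exactly that
variant); excluding the variant's whole protein or model would be a
stricter scope and can be composed from `WeightTableBuilder.build(exclude=...)`.

*Odds ratios.* OR = (a·d)/(b·c) with the 95% Woolf interval
exp(ln OR ± 1.96·√(1/a+1/b+1/c+1/d)); any zero cell triggers the
Haldane–Anscombe +0.5 correction and is flagged in the result.

## Synthetic data

`generate_scenario` builds a complete study: profile HMMs with
Dirichlet-sampled emission columns (concentration 0.3 — conserved,
peaked columns typical of domain models), proteins tiled over the
models with one significant all-match assignment each, and a labelled
catalogue with planted structure. Half the models are designated
cancer-enriched; cancer variants land on them with odds multiplied by
`cancer_enrichment` (default 3.0, i.e. a 4:1 odds split). Driver
substitutions are planted at columns whose wild type is the column
mode (~0.6 emission) and whose mutant emission is near
`driver_emission_low` (0.02); neutral substitutions swap to a residue
near `neutral_emission_high` (0.30). Lognormal jitter on both targets
spreads each class's score distribution so the classes overlap near
τ = −0.75 — roughly 95–98% of drivers fall below the threshold and
84–89% of neutral variants above it at the defaults — rather than
separating perfectly; a generator whose classes never overlap would
make threshold behaviour, cross-validation stability and the
weighting-scheme contrast all vacuous.

Defaults: seed 7, 4 models × 300 match states (every one of the 1000
variants gets its own planted column), 20 proteins, 500 variants per
class. Randomness is split into independent child streams per artifact
type (profiles, assignments, variants) spawned from the master seed.
The truth table records every planted quantity, including the realized
per-model placement frequencies the weight estimator should recover.

What the synthetic studies demonstrate: the plumbing and estimators
are correct (position mapping, selection, weight recovery, exclusion
semantics, metric arithmetic), and the score separates planted classes
in the direction and rough magnitude the model predicts. What they do
not demonstrate: performance on real mutation catalogues — real
drivers are not guaranteed to sit at conserved columns of
cancer-enriched domains, catalogues are noisy and biased, proteins
carry overlapping domain assignments with correlated e-values, and
none of that heterogeneity is simulated.

## Numerical choices and degenerate inputs

- HMMER3 emissions are stored as −ln p; the fixture writer emits 10
  decimal places so probabilities round-trip well under 1e-9, and
  writes files that HMMER's own tooling (via pyhmmer) parses.
  The `*` token (probability zero) is accepted by the parser but
  rejected by the profile invariant, which requires strictly positive
  emissions summing to 1 within 1e-6.
- Nonstandard residues (B, Z, X, U, O, J) are rejected at every
  boundary, never redistributed.
- A declared wild-type residue that is not the model's modal residue
  at the match state is logged, not rejected: homolog alignments
  routinely differ from the query sequence.
- Batch prediction isolates per-row failures in an `error` column and
  never aborts; single-row and batch scoring are tested to agree
  exactly.
- Coordinates are 1-based closed intervals throughout (HMMER
  convention); insert columns consume sequence without a match state,
  delete columns the reverse.
- Scores are carried at full precision and rounded to 2 dp only in
  report files.

## Known limitations

- Eq-style weighting assumes the catalogue classes are sampled
  comparably across models; systematic ascertainment differences
  between cancer and neutral catalogues bias W_c/W_p.
- The default background composition is a built-in SwissProt-style
  frequency table; analyses sensitive to the null should supply their
  own (`--background`).
- The ab-initio weighting route is only as good as the membership
  table supplied to it.
- Model selection considers one position at a time; multi-residue
  variants and indels are out of scope.
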