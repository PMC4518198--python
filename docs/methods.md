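# Methods

## Model and procedure

A metabolic phenotype is a map from metabolite identifiers to
signal-intensity ratios (SIR = treatment/control, dimensionless, > 0).
Comparing a query to a reference:

1. **Identifier normalization.** Raw identifiers are trimmed; parenthesized
   or bracketed derivative tags and trailing standalone derivative tokens
   (TMS/MeOX/MX with optional multiplicity, e.g. `(3TMS)`) and trailing
   retention-index/library codes (`RI1310`, bare ≥ 3-digit codes) are
   stripped; whitespace and `_,;` collapse to single spaces; the result is
   lowercased and looked up in a synonym table. Resolved names are "known";
   unresolved normalized strings are kept as "unknown" metabolites and can
   be matched across phenotypes by exact string (the `unknowns keep|drop`
   policy decides whether they participate). Hyphens are not delimiters, so
   `glucose-6-phosphate` survives. The shipped table covers ~200 common
   primary-metabolite synonyms and can be extended or overridden by a user
   TSV; full chemical-identifier resolution is a service-scale resource and
   out of scope.
2. **Filter.** Metabolites absent from either phenotype or with
   |fold change| < `fc_threshold` (default 1.5, i.e. SIR strictly inside
   (1/1.5, 1.5)) in either are discarded. Boundary values are kept (≥ / ≤
   semantics — the filter's purpose is removing sub-threshold responses, so
   a response exactly at threshold counts).
3. **RV transform.** SIR → RV = SIR − 1 (SIR > 1), 1 − 1/SIR (SIR < 1),
   0 (SIR = 1). Antisymmetric under SIR inversion; linear in the
   fold-change, so strong responses keep their weight.
4. **Correlation.** Pearson R of the paired RV vectors. Degenerate pairs
   (n < 2, or a constant vector) define R = 0 rather than raising, so
   whole-library scans cannot crash on sparse overlaps.
5. **Directional overlap.** Counts a (up/up), b (down/down), c (up in query,
   down in reference), d (down/up) feed a two-tailed Fisher's Exact Test on
   the table [[a, c], [d, b]] (orientation frozen for reproducibility; the
   two-sided p is invariant to transposition). The p-value uses the
   standard "sum of all tables no more probable than the observed"
   definition and is clamped to ≥ 1e-300 so −log₁₀ stays finite. The empty
   table returns p = 1.
6. **Score.** ranking metric = R² · (−log₁₀ FET2p) ≥ 0;
   PM score = sgn(R) · ranking metric. Matching strength combines two
   complementary signals — quantitative co-variation (R²) and qualitative
   directional agreement (FET2p) — each of which alone misranks phenotypes
   the other resolves.

Biweight midcorrelation (Langfelder–Horvath: center by median, scale by
9×MAD, Tukey biweights (1 − u²)² inside |u| < 1, zero outside) is provided
as an alternative robust correlation for benchmark mode; zero-MAD vectors
fall back to Pearson with a warning.

## Search and significance

A search scores the query against every reference and ranks descending by
the configured statistic (`pm` by default; `r2`, `bicor` magnitude, or
−log₁₀ FET2p for benchmarking), with ties broken by smaller FET2p, then
larger R², then reference id. Comparisons with fewer than `min_overlap`
(default 3) post-filter shared metabolites are reported as "no hit"; the
value is a package choice — some gate is needed before calling a 1-2
metabolite coincidence a match.

Significance is permutation-based. The query's metabolite labels are
shuffled `permutations` times (default 30); each shuffle is searched
exactly like the real query (same filter, unknowns policy, and min-overlap
gate, sub-gate comparisons contributing score 0), pooling
permutations × library-size null scores — one null model per query, shared
by all its matches. The null pools |score| magnitudes by default:
significance asks whether a score is *exceeded in magnitude* by chance,
and a magnitude null also makes inverse (negative) matches testable. A
signed-null mode exists behind `signed_null` for comparison. The null is
modeled as a normal with the pooled sample mean and SD (ddof = 1);

    z = (|score| − mean) / SD,   p_non_bio = upper-tail normal P(Z > z)

floored at 1e-308 (the double limit). A hit requires
p_non_bio ≤ `alpha` (default 0.05); no multiple-testing correction is
applied across references by default (a Bonferroni option exists). The
empirical null distribution is right-skewed with a point mass near 0, so
the normal model is conservative in the far tail; the calibration test
therefore checks the *empirical* 95th-percentile of the pooled null scores
against fresh shuffled queries (5% ± 2% exceedance) and uses
300-permutation nulls to keep the quantile's Monte-Carlo error well inside
that band.

Because shuffles permute the query's own metabolite set against the same
references, the null inherits any platform/coverage bias (references
sharing more detected metabolites with the query can reach higher scores),
and p_non_bio is automatically adjusted for it; the synthetic
coverage-masking test verifies calibration survives 50% masking.

## Networks

All unordered pairs are scored once (the score is symmetric; the suite
asserts score(A,B) = score(B,A) to 1e-10). Edges keep
FET2p ≤ `max_fet2p` (default 0.007) and R² ≥ `min_r2` (default 0.09); an
edge is a *top hit* when it is the best-ranked match of at least one
endpoint, computed on pre-filter rankings, so a node's top hit can be
filtered out unless `keep_top_hits` retains it. Per-edge p_non_bio is
optional (off by default — the edge filters need only FET2p and R²); since
the permutation null is per-query and therefore directional, an undirected
edge stores the smaller of its two directional p-values. Layout is left to
downstream viewers; export formats are GraphML (primary), GML (booleans
encoded 0/1), and a flat edge TSV.

## Synthetic data

The generator emulates a mutant panel spanning the steps of a metabolic
pathway, with allelic pairs (independent mutations in one gene) as ground
truth. Defaults define the study conditions:

| parameter | default | meaning |
|---|---|---|
| n_metabolites | 100 | metabolome size |
| pathways | 4 (4/4/3/2 genes) | 13 genes total |
| responding_fraction | 0.30 | metabolites responding per pathway |
| base_sd | 1.0 | SD of pathway base log-signature (ln units) |
| gene_offset_sd | 0.5 | within-pathway gene divergence |
| severity_range | [0.7, 1.3] | per-allele severity multiplier |
| noise_sd (σ) | 0.1 | log-scale replicate noise |
| alleles_per_gene | 2 | 26 phenotypes total |

Each allele's SIR_m = exp(severity · signature_m + ε_m), ε_m ~ N(0, σ) —
log-normal by construction, so SIRs stay positive and many responses fall
below the 1.5-fold filter, as in real data. base_sd = 1.0 ln-units gives
typical ~e-fold responses with multi-ten-fold tails, the magnitude range
reported for strong metabolism mutants. An optional `coupled_genes` flag
sets two genes' signatures identical, recreating the hard case of
biochemically coupled enzymes whose mutants are near-indistinguishable
directionally. `inject_platform_bias` masks a random (1 − coverage)
fraction of each phenotype's metabolites to emulate platforms with
differing metabolome coverage.

What passing synthetic tests does *not* show about real data: the generator
draws independent log-normal noise per metabolite and ignores correlated
analytical drift, batch effects, missing-not-at-random detection, saturated
signals, and misidentified peaks. Twin-recovery rates on it bound behavior
under its assumptions only.

## Numerical choices and edge cases

* Fisher two-sided p via `scipy.stats.fisher_exact`; the test suite sweeps
  every 2×2 table with total ≤ 30 against an exact integer-arithmetic
  enumeration oracle (relative error < 1e-7, ties admitted at the same
  tolerance).
* Per-metabolite order is sorted-by-canonical-key everywhere, making
  floating-point sums and permutation draws reproducible run-to-run.
* One integer seed drives `numpy.random.default_rng`; search results are
  byte-identical for identical inputs + seed.
* Duplicate metabolite rows after normalization keep the row with the
  largest |RV| (preserves the strongest signal) and warn.
* SIR ≤ 0 or non-finite input rows are dropped with a warning; a `clamp`
  flag caps them at 10^±6 instead. Input scale (`ratio`, `log2`, `log10`,
  `ln`) must be declared — no autodetection, to avoid silent misreads.
* With `fc_threshold` = 1 an RV of exactly 0 can pass the filter; such
  zero responses are counted as "up" in the overlap table. Unreachable at
  any threshold > 1.
* FET2p floor 1e-300, p_non_bio floor 1e-308.

## Known limitations

* The normal null model is conservative in the far tail; reported
  p_non_bio values like 1e-308 are model extrapolations, not empirical
  frequencies.
* p_non_bio is computed per query; it is not symmetric in query and
  reference (unlike every other statistic).
* The shipped synonym table is deliberately small; unmatched identifiers
  degrade gracefully to exact-string "unknown" matching rather than
  chemical resolution.
* No FDR control across multi-query batches; `alpha` applies per match as
  in the original significance policy.
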