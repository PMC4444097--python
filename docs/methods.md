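# Methods

## The statistical model

Each tag's count in a library is treated as Poisson distributed: with a
library of millions of clean reads, any single tag occupies a tiny
fraction of it, so the binomial sampling of that tag's reads is in the
Poisson limit. For a tag with count `x` in library 1 (total clean reads
`N1`) and count `y` in library 2 (total `N2`), the hypothesis of equal
per-read rate gives `Y | x` the distribution

    p(Y = y | x) = (N2/N1)^y * (x+y)! / (x! y!) * (1 + N2/N1)^-(x+y+1)

This is the negative-binomial law `NB(x+1, N1/(N1+N2))` — the posterior
predictive of a second Poisson count given the first under a flat prior
on the rate. The library totals enter only through their ratio; counts
are never normalized before testing.

### Two-sidedness and the conditioning convention

The test statistic is a doubled tail probability, capped at 1. The
published values fix the convention precisely: the **larger** of the two
counts conditions, and the p-value is twice the smaller count's
inclusive lower tail,

    p = min(1, 2 * P(Y <= y_small | x_large)),

equivalently, in the `y > x` orientation, twice the *strict* upper tail
`2 * P(Y > y | x)`. This reproduces all nine explicitly printed
p-values of the reference comparison to printed precision (0.01846,
0.0175, 0.0078, 0.0001–0.0015). The plausible alternative — always
conditioning on library A and taking `2 * min` of the two inclusive
tails — reproduces only the rows whose larger count is already in
library A and disagrees on the others (e.g. it yields 0.0108 where
0.0078 is printed), so it was rejected. In the implementation the
general form is `2 * min(lower, upper)` of the tested count under the
larger-count conditioning, which reduces to the expression above
whenever the smaller count lies below the conditional mean (always the
case for near-equal library sizes). A tie in counts is conditioned on
the side with the larger library total, which keeps the p-value exactly
symmetric under swapping the two libraries.

### Numerical evaluation

All probability mass is computed in log space with log-gamma
factorials, so conditioning counts up to 10^7 neither overflow nor lose
the tails. Tail sums are accumulated from the nearer end of the
support with `logsumexp`; when the requested tail would exceed ~half
the mass, the complement is summed instead, so both tails carry bounded
relative error. Open-ended upper sums stop when a geometric bound on
the remaining mass (the term ratio `q(x+y+1)/(y+1)` decreases toward
`q = N2/(N1+N2) < 1`) falls below 1e-16 of the accumulated sum. The
test suite checks the pmf against 60-digit arbitrary-precision direct
factorial evaluation (1e-12 relative, all `x, y <= 30`) and the tails
against the independent closed-form negative-binomial CDF (1e-10).

### Confidence intervals

`[y_min, y_max]` at confidence `1 - 2*eps`: `y_min` is the largest `y`
whose inclusive lower tail is `<= eps` (absent when `y = 0` already
exceeds it), `y_max` the smallest `y` whose inclusive upper tail is
`<= eps`. Inclusive-boundary `<=` was chosen; the convention is
underdetermined by the source material, and the worked `x = 0`,
equal-libraries case (`y_max = 6` at `2*eps = 0.05`) pins the tests to
it. Both bounds are found by bisection on the monotone tails.

## Expression and fold change

TPM is `count / library_total * 1e6`, with the denominator the
whole-library clean-read total, not the table's column sum — the
published TPM entries confirm this (931 tags / 9,246,256 reads =
100.69 TPM). A side with count 0 receives a floor of **0.01 TPM**,
applied on the TPM scale rather than as a count pseudocount: only this
convention reproduces the printed fold changes for the zero-count rows
(7.02 = log2(1.2978/0.01), 8.99). Fold change is
`|log2(TPM_B / TPM_A)|` computed on unrounded TPMs; the printed value
8.32 for the 339-vs-1 row is only reachable unrounded (the rounded
table entries give 8.38). Reports store full-precision values;
rounding is for display.

## DE calls, FDR, uniqueness

A tag is differentially expressed when `p < alpha` (strict, default
0.05) **and** `|log2FC| >= 1` (non-strict, i.e. at least 2-fold).
Benjamini–Yekutieli q-values (step-up with harmonic-number inflation
`c(m)`, valid under arbitrary dependence) are computed across all tags
of a run and reported with a default 0.001 cap as a *separate* flag,
not conjoined into the DE rule: the two filters are stated side by side
in the source analysis and their composition is not defined, so the
pipeline reports both and leaves the conjunction to the caller. The BY
adjustment is delegated to `statsmodels.stats.multitest.multipletests`
(`fdr_by`); the test suite checks it against a direct evaluation of the
step-up formula. Library-unique classification is purely the zero
pattern of the counts (`only_in_a`: x > 0, y = 0, etc.).

## Target-consensus integration

A gene is a consensus target of a miRNA when **every** prediction
source lists it; a miRNA absent from a source contributes an empty set
there, making the strict consensus empty. Because "absent from one
predictor's output" and "not a target" are not distinguishable in list
form, a `min_sources = k` relaxation is provided. Coordinated genes
are consensus targets that also appear in the supplied DE gene list;
identifiers are trimmed and upper-cased before comparison since
prediction tools mix case conventions. Class summaries and the
sense/antisense comparison operate on pre-annotated tag records;
annotation itself (miRBase/Rfam lookup, genome mapping) is out of
scope. Genes observed in only one orientation are excluded from the
antisense-lower-than-sense fraction — the comparison requires a
corresponding sense count.

## Synthetic data and calibration

The generator emulates exactly the structure the test assumes: relative
abundances drawn log-normal and normalized, a `de_fraction` subset
multiplied by `2^(±effect_log2)` in library B (sign random), library B
renormalized, and counts drawn independently per tag as
`Poisson(total × abundance)`. Randomness comes from counter-based
Philox streams keyed by `(seed, draw-kind)`, so each draw vector is
independently reproducible and the full pipeline is byte-deterministic
given `(config, thresholds)`.

Defaults are the study conditions of the reference comparison: library
totals 9,246,256 and 8,714,768 (the two liver libraries), `de_fraction
0.1` (22 of ~200 detected miRNAs were DE), `effect_log2 2.0` (printed
effects span 1.0–9.0 with bulk near 1–2.5), and log-normal abundance
spread `sdlog 1.5`, giving the few dominant tags over a long low-count
tail typical of small-RNA libraries. `min_expected_count` optionally
lifts abundances to a floor (two lift-and-renormalize passes) for
calibration runs that need every tag in the comfortable Poisson regime.

**Composition shift.** Renormalizing library B after multiplicative
effects shifts every non-effect tag by `-log2(Z)`, `Z` the
renormalization constant — the classic composition bias of relative
abundance data, which this test family does not correct. The recorded
truth stores the composition-corrected effect (exactly 0 for null tags,
exactly `±effect_log2` for DE tags) alongside the exact
post-normalization abundances, so the shift is visible but does not
blur the null/DE labels. Calibration experiments are placed where the
shift is negligible: the type-I experiment uses `de_fraction 0` (no
shift at all), and the FDR experiment uses `effect_log2 1`, where
`log2(Z) ≈ 0.02` is far below the resolution of the counts used. At
very deep counts a large `de_fraction × effect` makes the shift
statistically visible on null tags — a real property of the method, not
of the generator.

**Calibration results** (recomputed by `analysis/02_calibration.py` and
asserted in the test suite): with 2,000 all-null tags at expected
counts ≥ 25, the p < 0.05 rejection rate is ≈ 0.05–0.057, within the
binomial band `0.05 + 3·SE ≈ 0.065` of an exact test; with 10% of tags
at `|log2FC| = 3` and expected counts ≥ ~120, the DE rule recovers
100% of true effects; over 200 replicates of a mixed truth (10% DE at
`|log2FC| = 1`, counts ~125), the mean empirical FDR of BY-filtered
calls is ≈ 0 against the 0.001 cap.

**What the generator does not emulate**: sequencing error, adaptor
artifacts, mapping ambiguity, overdispersion between biological
replicates (both conditions are single pooled libraries, per the
design), or tag-to-gene aggregation. Passing calibration therefore
shows the inference machinery is correct *under the model's own
assumptions*; it says nothing about robustness to replicate-level
biological variance, which this test family is known not to capture.

## Problem sizes

The calibration experiments use 400–5,000 tags and 50k–2M-read
libraries — sizes chosen so every experiment's sampling error is small
relative to the margins being asserted while the whole suite runs in
well under a minute of compute apiece. The published-table
computations run on the 22 packaged count pairs at the original
9.2M/8.7M-read totals.

## Known limitations

- No replicate-aware dispersion: a negative-binomial test with
  estimated dispersion (DESeq2/edgeR style) is the modern tool when
  replicates exist; this package implements the single-library-pair
  exact test faithfully, including its anti-conservatism under
  biological variability.
- The DE rule and the FDR cap are reported as parallel filters; their
  published composition is ambiguous (see above).
- Consensus integration reproduces set algebra only; actual predictor
  outputs are version-dependent and not reproducible from lists alone.
- The composition shift of relative-abundance data is surfaced but not
  corrected (no TMM-style factor), matching the method being
  implemented.
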