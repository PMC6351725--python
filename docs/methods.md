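# Methods

## Data model and conventions

An experiment is a non-negative abundance matrix with samples as rows and
features as columns, joined to two metadata tables indexed by sample and
feature identifiers in matrix order (heatmaps transpose at display time so
features are drawn as rows, the convention readers of microbiome heatmaps
expect). Operations never mutate their input: each returns a new experiment
and appends one JSON-serializable history record, which is what makes
`replay_history` exact — replaying the recorded `(op, params)` sequence on
the pristine input reproduces the final matrix bit for bit. Storage may be
dense or CSR sparse; the two are contractually equivalent (every operation
is tested to produce element-wise identical results under both), sparsity
being only a memory optimization. Indices are 0-based throughout the
library; the CLI speaks in identifiers, not positions.

Metadata columns read from disk stay strings unless *every* non-missing
value parses as a number, in which case the column is coerced to numeric;
empty cells become NaN (never the empty string). Table samples missing from
a metadata file are kept with missing-marker rows and a warning — dropping
them silently would change downstream statistics — while metadata rows
absent from the table are dropped with a logged count.

## Transforms

- **TSS** rescales each sample to a fixed total (default 10 000), the
  standard way to make per-sample read depths comparable. Samples with zero
  total raise unless explicitly dropped.
- **Outlier-excluding TSS**: per sample, features whose within-sample
  relative abundance exceeds `outlier_fraction` (default 0.1) are excluded
  from the scaling denominator, iterating with the fraction recomputed over
  the remaining features until the excluded set is stable (it can only
  grow, so the iteration terminates); the resulting factor is applied to
  *all* features, excluded ones included, and exclusions are logged. The
  method's name fixes what it must do — keep single dominant features from
  driving the scaling — but not this algorithm; the iterative-exclusion
  rule and the rescale-everything choice are this package's decisions.
- **CLR**: y = ln(x + c) − mean ln(x + c) per sample, with a pseudocount
  shift c (default 1) rather than zero-replacement imputation — the
  simplest documented zero handling. Natural log; rows sum to 0; the result
  is flagged non-count so downstream non-negativity checks stand down.
- **log**: y = log₂(max(x, cutoff)) with cutoff 1, so zero counts map to 0
  and ordering is preserved.
- **binarize**: presence is strictly `x > cutoff` with cutoff 0, so any
  positive abundance counts as present.
- **Unit scaling** (pre-clustering): per-feature centering and division by
  the population (n) standard deviation; zero-variance features map to
  zeros. Population vs sample sd is a coin-flip choice fixed once.

## Filtering and sorting

Threshold semantics are uniform: `>=` keeps. A feature whose total equals
the minimum survives (the low-abundance rule drops only strictly-less), and
a feature present in exactly the minimum fraction of samples survives the
prevalence filter. Filters never renormalize — re-normalization after, say,
contaminant removal is an explicit separate TSS call, so the analyst sees
both steps in the history.

Sorts are stable everywhere (ties keep current order), which makes outputs
deterministic and lets nested sorts compose: sorting by plate after sorting
by group yields plate-major blocks with group order preserved inside.
Metadata sorts compare numerically when a column is fully numeric-parsable.
Center-of-mass ordering uses 0-based positions *within* the chosen sample
subset (not global indices); features with zero total over the subset carry
no positional signal and are placed last with a warning.

Cluster ordering runs log transform → per-item standardization (per-feature
when ordering features, per-sample when ordering samples — the per-sample
variant mirrors the per-feature rule rather than being separately
prescribed) → Euclidean distances → agglomerative linkage (single by
default; average/complete available) → dendrogram leaf order as produced by
scipy's deterministic traversal. Only the ordering changes; values are
untouched.

## Permutation tests

Group selection takes two disjoint value sets over a sample-metadata field
(group 2 defaulting to the complement); the optional transform (mid-ranks
within each feature across the *selected* samples, or presence/absence) is
followed by the difference-of-group-means statistic. The null is built
either by Monte-Carlo label shuffles (seeded, default B = 1000) or by
exhaustive enumeration of all distinct assignments when requested and the
count is ≤ 20 000 (above that the library refuses and suggests random
mode).

p-values: Monte-Carlo mode uses the add-one rule
p = (1 + #{b : |s⁽ᵇ⁾| ≥ |s|}) / (1 + B), which keeps p > 0 and valid for
step-up procedures. Exhaustive mode enumerates the observed labeling among
the B assignments, so p = #{b : |s⁽ᵇ⁾| ≥ |s|} / B with the count always at
least 1 — a perfectly separating feature under a 4+4 design attains
p = 2/70 (the true split and its mirror). Two-sided by |s| is the default;
one-sided is a flag.

### dsFDR

The discrete FDR estimate at a candidate threshold t (candidates are the
observed |s| values) is

    FDR̂(t) = min(1, mean_b #{j : |s⁽ᵇ⁾_j| ≥ t} / max(1, #{j : |s_j| ≥ t}))

and the rejection threshold is the smallest candidate with FDR̂ ≤ α; the
per-feature q-value is the best FDR̂ over candidates at or below that
feature's |s|, hence monotone non-increasing in |s|. The min/max guards
define the degenerate cases (at α = 1 everything at or above the smallest
observed |s| is rejected). The implementation is O((F + FB) log) via sorted
searches and is verified in the tests against a brute-force scan over every
candidate threshold.

A structural note on power-benchmark expectations: with k true features at
level α, the cutoff at the largest null feature requires the mean
permutation exceedance count at that value to be ≤ α(k + 1). For any
continuous-valued statistic the rank distribution of the null maximum makes
that count's expectation ≈ 1 regardless of the data distribution, so with
k = 10 and α = 0.1 the procedure sits exactly at the boundary: roughly half
of simulated studies reject one or two borderline null features (the FDR,
an expectation, is still controlled — the calibration suite shows mean
realized FDP ≈ α). Heavily tied (sparse, discrete) statistics inflate the
exceedance count and push the procedure conservative; that is the regime
the discrete method was designed for.

### BH and filtered BH

BH is the standard step-up with monotone-adjusted q-values (cross-checked
against statsmodels). Filtered BH first removes from the testing family the
features whose minimal achievable p — the p-value rule evaluated at the
most extreme value of the feature's own permutation null — exceeds α (such
features, e.g. one present in a single sample under a binarized exhaustive
null, can never be significant and only dilute the correction); they are
reported with q = 1. Shrinking the family can only help, so filtered BH
never rejects fewer features than BH.

### Correlation

Spearman (mid-rank Pearson) or Pearson statistics of every feature against
a numeric covariate, permuting the covariate; exhaustive mode enumerates
all n! orderings when ≤ 20 000. Zero-variance features get statistic 0 and
p = 1 by decision. The underlying prevalence-vs-abundance ambiguity is
resolved by computing on abundance; binarize the experiment first for the
prevalence reading.

## Annotation store and enrichment

Annotations are flat records (id, feature set, type, terms, source
experiment) in JSON-lines or tab-delimited files; ontology parent relations
are *not* expanded — terms are compared exactly as given. Type weights are
+2 higher_in/high_freq, +1 common, −2 lower_in; contamination and other
contribute 0 to term scores but drive the contaminant flag
(contaminant ≻ annotated ≻ none). Features without any annotation stay in
the enrichment rank test with score 0, since the absence of a term is
itself information. `most_common_term` sums candidate-term scores and
breaks ties by candidate order, falling back to "other" at non-positive
totals — the display rule is a package decision, as only the display
itself is prescribed by the figures it mimics.

## Synthetic data

The count generator draws per-feature baseline relative abundances from a
log-normal (σ = 1), jitters per-sample depth uniformly ±20% around the
target (default 10 000), and draws counts from a negative binomial with
variance μ + 0.1·μ² — moderately overdispersed, fully dense data. The
two-group effect multiplies the expected group-1 counts of the first
`n_diff` features by `effect_fold` *without* renormalizing the composition,
so non-planted features are exactly null and the returned truth mask is
exact. Real amplicon data differ in ways that matter for transfer: heavy
sparsity (most features absent from most samples), compositional closure
(a blooming taxon depresses every other relative abundance), and
taxon-correlated noise. Passing tests on this generator therefore
demonstrate the correctness and calibration of the machinery under clean
exchangeable nulls, not robustness to closure artifacts — the correlation
example shows how quickly closure and library-size leakage produce real
(but uninteresting) associations once TSS enters the picture.

The annotation-store generator plants specified (term, feature-set, type)
annotations and adds decoy annotations whose term-feature associations are
exchangeable across any feature grouping (each decoy covers a Bernoulli(0.3)
random feature subset with a random non-contamination type).

## Problem sizes and numerical choices

The test and acceptance workloads use 2×10-sample, 100-feature studies
(50–100 replicates), B = 1000 permutations, a 70-assignment exhaustive
oracle at 4+4 samples, and 100×200 tables for transform/IO invariants —
sizes at which every quantity is stable to well under the asserted
tolerances while the whole suite runs in seconds. Tolerances: TSS row sums
1e-6, CLR row sums 1e-9, sparse/dense equivalence 1e-9, round-trips exact.
Comparisons inside the permutation machinery are exact (`>=`) — rank and
presence/absence statistics are sums of half-integers divided by fixed
group sizes, so equal values are equal floats and mirror assignments negate
exactly.

## Known limitations

- No paired/blocked designs or covariate-adjusted models; the tests are
  two-group or single-covariate.
- The annotation store is local and flat: no live database clients, no
  ontology expansion, no curation workflow.
- Heatmaps are static (PNG/SVG) or self-contained HTML with minimal
  hover interactivity; no dendrograms, no ordination plots.
- BIOM support is JSON (1.0) first-class; HDF5 (2.x) read-only behind the
  h5py capability flag.
- The machine-learning conveniences some exploration suites bundle are out
  of scope; the Experiment exposes plain numpy/pandas objects for use with
  scikit-learn directly.
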