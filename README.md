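# abundex

Exploratory analysis of microbiome and metabolomics feature tables: a
study-centric data model joining a samples × features abundance matrix with
sample and feature metadata, plus the operations an analyst chains on it —
compositional normalization and transforms, metadata- and data-driven
filtering, clustering-based ordering, permutation tests for differential
abundance and correlation under discrete FDR control, annotation-term
enrichment against a local annotation store, and static/HTML heatmaps.

It is written for microbial ecologists and metabolomics analysts working
with amplicon sOTU tables (exact sequence variants as feature identifiers),
classic tab-delimited feature tables, BIOM-JSON tables, or MS1 bucket
tables, who want every step of an exploratory session to be scripted,
recorded and replayable.

## The data model

An `Experiment` holds a non-negative matrix `X` (n samples × m features),
a sample-metadata table and a feature-metadata table, kept synchronized
along both axes. Every operation returns a **new** experiment and appends a
`(op_name, params, timestamp)` record to its history, so

```python
ax.replay_history(original, processed.history)
```

rebuilds any processed view bit-exactly from the pristine input.

## The statistics

**Differential abundance.** For two sample groups, each feature's values are
optionally transformed (mid-ranks within the feature, or presence/absence),
and the statistic is the difference of group means,
s_j = mean(x_j | group1) − mean(x_j | group2). The null distribution comes
from random relabelings of the samples (or exhaustive enumeration of all
C(n, n₁) assignments when requested and feasible), giving permutation
p-values p_j = (1 + #{b : |s⁽ᵇ⁾_j| ≥ |s_j|}) / (1 + B).

**Multiple testing.** Three controls at level α:

- **dsFDR** (discrete FDR) thresholds the statistic directly:
  FDR̂(t) = min(1, E_perm[#{j : |s⁽ᵇ⁾_j| ≥ t}] / max(1, #{j : |s_j| ≥ t})),
  rejecting at the smallest observed |s| with FDR̂ ≤ α. Working on the
  statistic scale avoids the power loss that coarse discrete p-value
  supports inflict on step-up procedures with sparse counts.
- **BH**: Benjamini–Hochberg step-up on the permutation p-values.
- **filtered BH**: features whose permutation-null support cannot reach α
  (minimal achievable p > α) are removed from the testing family before BH.

**Correlation.** A continuous sample covariate is correlated with every
feature (Spearman, Pearson, or user-supplied), permuting the covariate
vector for the null, with the same FDR machinery.

**Term enrichment.** A local annotation store maps feature identifiers to
ontology terms through typed observations scored +2 (higher_in, high_freq),
+1 (common), −2 (lower_in). Between two feature groups, each term's summed
scores are ranked across the pooled features and tested with the rank-mean
permutation test under dsFDR, permuting feature group labels.

## Worked example

`examples/differential_abundance.py` generates a synthetic study (two
groups of 10 samples, 100 features, ten with a genuine 4-fold effect,
~10 000 reads/sample) and runs the rank-mean test with dsFDR at 0.1:

```
11 of 100 features significant at dsFDR 0.1 (statistic threshold 6.80)
              feature_id  stat        p        q direction
ACTTCCCTGCAGACGAGTTATCCC  10.0 0.000999 0.000250    group1
ACCTGGGAGGACTTCCACCGCGAC  10.0 0.000999 0.000250    group1
...
AGCGGTACACTAGAGATAGAGATG   6.8 0.005994 0.080636    group1
planted features recovered: 10 of 10
```

`stat` is the mean-rank difference (10.0 = perfect group separation of the
20 ranks), `p` the permutation p-value at B = 1000 (floor 1/1001), `q` the
dsFDR estimate at that feature's statistic, and `direction` the group with
the larger mean. All ten planted features are recovered; the eleventh hit
is a null feature whose statistic crossed the estimated threshold — the
price of controlling the FDR at 0.1 rather than the family-wise error.

The other example scripts show table loading/normalization/clustering with
HTML heatmap export (`explore_feature_table.py`), term enrichment
(`term_enrichment.py`), and covariate correlation plus CLR
(`correlation_and_transforms.py`). The same functionality is scriptable
from the shell via the `abundex` command (`abundex --help`).

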