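"""Deterministic synthetic data: overdispersed count tables and annotation stores.

Count model
-----------
Per-feature baseline relative abundances are drawn log-normal (sigma = 1),
normalized to compositions; a two-group design multiplies the first
``n_diff`` features' expected group-1 counts by ``effect_fold``, leaving
the remaining features with identical expectations in both groups (no
compositional renormalization — closure effects are a property of real
sequencing this generator deliberately omits, so the truth mask is exact).
Per-sample library size is
``depth`` jittered uniformly by +/-20%, and counts are negative binomial
with variance ``mu + dispersion * mu**2`` — the standard sparse,
overdispersed approximation to amplicon sequencing counts.  Sample metadata
carries the group, a random two-level extraction plate, and a continuous
covariate correlated (rho = 0.8) with the first planted feature for
correlation tests.

Everything is a pure function of the seed; the generators never produce
negative counts or NaN, and metadata is complete.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .enrichment import Annotation, AnnotationStore
from .experiment import Experiment, ValidationError

_BASES = np.array(list("ACGT"))


def _amplicon_ids(rng: np.random.Generator, n: int, length: int = 24) -> list[str]:
    ids = set()
    out = []
    while len(out) < n:
        seq = "".join(rng.choice(_BASES, size=length))
        if seq not in ids:
            ids.add(seq)
            out.append(seq)
    return out


def make_count_experiment(
    n_per_group: tuple[int, int] = (10, 10),
    n_features: int = 100,
    n_diff: int = 10,
    effect_fold: float = 4.0,
    depth: float = 10_000,
    dispersion: float = 0.1,
    seed: int = 0,
    sparse: bool = False,
) -> tuple[Experiment, np.ndarray]:
    """Two-group count experiment with planted differential features.

    Returns ``(experiment, truth_mask)`` where the mask marks features with
    a genuine group effect (all False when ``effect_fold == 1``).
    """
    n1, n2 = n_per_group
    if n_diff > n_features:
        raise ValidationError("n_diff cannot exceed n_features")
    if effect_fold < 1:
        raise ValidationError("effect_fold must be >= 1")
    if n1 < 1 or n2 < 1 or depth <= 0 or dispersion < 0:
        raise ValidationError("invalid generator parameters")
    rng = np.random.default_rng(seed)
    n = n1 + n2

    baseline = rng.lognormal(mean=0.0, sigma=1.0, size=n_features)
    frac = baseline / baseline.sum()
    fold = np.ones(n_features)
    fold[:n_diff] = effect_fold

    depths = depth * rng.uniform(0.8, 1.2, size=n)
    counts = np.empty((n, n_features))
    for i in range(n):
        mu = frac * depths[i] * (fold if i < n1 else 1.0)
        mu = np.maximum(mu, 1e-9)
        if dispersion > 0:
            r = 1.0 / dispersion
            counts[i] = rng.negative_binomial(r, r / (r + mu))
        else:
            counts[i] = rng.poisson(mu)

    group = np.array(["group1"] * n1 + ["group2"] * n2)
    plate = rng.choice(["pa", "pb"], size=n)
    f0 = counts[:, 0]
    z = (f0 - f0.mean()) / (f0.std() if f0.std() > 0 else 1.0)
    covariate = 0.8 * z + np.sqrt(1 - 0.8**2) * rng.standard_normal(n)

    sample_ids = [f"S{i:03d}" for i in range(n)]
    smd = pd.DataFrame(
        {"group": group, "plate": plate, "covariate": np.round(covariate, 6)},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    feature_ids = _amplicon_ids(rng, n_features)
    fmd = pd.DataFrame(index=pd.Index(feature_ids, name="feature_id"))
    exp = Experiment(counts, smd, fmd, sparse=sparse, experiment_type="amplicon")
    truth = np.zeros(n_features, dtype=bool)
    if effect_fold > 1:
        truth[:n_diff] = True
    return exp, truth


def make_annotation_store(
    feature_ids,
    n_terms: int = 200,
    planted: tuple | list | None = None,
    n_decoy_annotations: int = 200,
    seed: int = 0,
) -> AnnotationStore:
    """Annotation store with optional planted term(s) plus random decoys.

    ``planted`` is one or a list of ``(term, feature_subset,
    annotation_type)`` triples.  Decoy annotations assign decoy terms to
    random feature subsets with random (non-contamination) types, so their
    term-feature associations are exchangeable across any feature grouping.
    """
    feature_ids = [str(f) for f in feature_ids]
    rng = np.random.default_rng(seed)
    store = AnnotationStore()
    if planted is not None:
        if isinstance(planted, tuple):
            planted = [planted]
        for k, (term, subset, ann_type) in enumerate(planted):
            subset = [str(f) for f in subset]
            if not set(subset) <= set(feature_ids):
                raise ValidationError("planted feature subset not within feature_ids")
            store.add(
                Annotation(
                    annotation_id=f"planted{k}",
                    feature_ids=frozenset(subset),
                    annotation_type=ann_type,
                    terms=[term],
                    experiment_id="planted",
                )
            )
    decoy_terms = [f"decoy_term_{t:04d}" for t in range(n_terms)]
    types = ["higher_in", "lower_in", "common", "high_freq"]
    for k in range(n_decoy_annotations):
        term = decoy_terms[k % n_terms] if n_terms else None
        mask = rng.random(len(feature_ids)) < 0.3
        if not mask.any():
            mask[rng.integers(len(feature_ids))] = True
        store.add(
            Annotation(
                annotation_id=f"decoy{k}",
                feature_ids=frozenset(np.array(feature_ids)[mask]),
                annotation_type=types[int(rng.integers(len(types)))],
                terms=[term],
                experiment_id="decoy",
            )
        )
    return store
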