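"""Local annotation store and ontology-term enrichment between feature groups.

Annotations are curated statements tying a set of feature identifiers
(e.g. amplicon sequence variants) to ontology terms, with a type describing
the kind of observation: differential presence (``higher_in`` /
``lower_in``), prevalence (``common``, ``high_freq``), candidate
``contamination``, or ``other``.  Term scores aggregate annotations per
(term, feature) pair with type weights +2 (higher_in, high_freq), +1
(common) and -2 (lower_in).

Term enrichment between two feature groups ranks each term's scores across
the pooled features and runs the two-group rank-mean permutation test with
dsFDR control — permuting *feature* group labels, since features are the
sampling units here.  Features without any annotation stay in the test with
score 0: absence of a term is information.

The store is a flat local file (JSON lines or tab-delimited); ontology
parent relations are NOT expanded — terms are compared as given.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field as dc_field

import numpy as np

from .experiment import Experiment, ValidationError
from .stats import (
    dsfdr_control,
    per_feature_transform,
    permutation_null,
    permutation_pvalues,
    _stat_over_labelings,
)

logger = logging.getLogger("abundex")

ANNOTATION_TYPES = ("higher_in", "lower_in", "common", "high_freq", "contamination", "other")

#: per-annotation term score contribution by annotation type
TYPE_SCORES = {
    "higher_in": 2.0,
    "high_freq": 2.0,
    "common": 1.0,
    "lower_in": -2.0,
    "contamination": 0.0,
    "other": 0.0,
}


@dataclass
class Annotation:
    annotation_id: str
    feature_ids: frozenset
    annotation_type: str
    terms: list
    experiment_id: str = ""

    def __post_init__(self):
        self.feature_ids = frozenset(str(f) for f in self.feature_ids)
        if self.annotation_type not in ANNOTATION_TYPES:
            raise ValidationError(
                f"unknown annotation type {self.annotation_type!r} "
                f"(annotation {self.annotation_id})"
            )
        if not self.terms and self.annotation_type != "contamination":
            raise ValidationError(
                f"annotation {self.annotation_id} has no terms "
                f"(only contamination annotations may be term-free)"
            )


class AnnotationStore:
    """In-memory collection of annotations with a feature-id index."""

    def __init__(self, annotations: list[Annotation] | None = None):
        self.annotations: list[Annotation] = []
        self._index: dict[str, list[int]] = {}
        self._ids: set[str] = set()
        for a in annotations or []:
            self.add(a)

    def add(self, annotation: Annotation) -> None:
        if annotation.annotation_id in self._ids:
            raise ValidationError(f"duplicate annotation_id {annotation.annotation_id!r}")
        pos = len(self.annotations)
        self.annotations.append(annotation)
        self._ids.add(annotation.annotation_id)
        for fid in annotation.feature_ids:
            self._index.setdefault(fid, []).append(pos)

    def __len__(self) -> int:
        return len(self.annotations)

    def feature_annotations(self, feature_id: str) -> list[Annotation]:
        """All annotations whose feature set contains the id."""
        return [self.annotations[i] for i in self._index.get(str(feature_id), [])]

    @property
    def all_terms(self) -> list[str]:
        seen = {}
        for a in self.annotations:
            for t in a.terms:
                seen.setdefault(t, None)
        return list(seen)


def load_store(path: str) -> AnnotationStore:
    """Load annotations from a JSON-lines or tab-delimited file."""
    store = AnnotationStore()
    with open(path) as fh:
        lines = [ln.rstrip("\r\n") for ln in fh]
    for num, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        try:
            if line.lstrip().startswith("{"):
                rec = json.loads(line)
                ann = Annotation(
                    annotation_id=str(rec["annotation_id"]),
                    feature_ids=frozenset(rec["features"]),
                    annotation_type=rec["type"],
                    terms=list(rec.get("terms", [])),
                    experiment_id=str(rec.get("experiment", "")),
                )
            else:
                parts = line.split("\t")
                if len(parts) < 4:
                    raise ValidationError("expected >= 4 tab-separated fields")
                ann = Annotation(
                    annotation_id=parts[0],
                    annotation_type=parts[1],
                    terms=[t for t in parts[2].split(";") if t],
                    feature_ids=frozenset(f for f in parts[3].split(";") if f),
                    experiment_id=parts[4] if len(parts) > 4 else "",
                )
        except (json.JSONDecodeError, KeyError, ValidationError) as e:
            raise ValidationError(f"{path}: malformed annotation record {num}: {e}")
        store.add(ann)
    return store


def save_store(store: AnnotationStore, path: str) -> None:
    """Write the store as JSON lines (round-trips with :func:`load_store`)."""
    with open(path, "w") as fh:
        for a in store.annotations:
            fh.write(
                json.dumps(
                    {
                        "annotation_id": a.annotation_id,
                        "type": a.annotation_type,
                        "terms": list(a.terms),
                        "experiment": a.experiment_id,
                        "features": sorted(a.feature_ids),
                    }
                )
                + "\n"
            )


def feature_annotations(store: AnnotationStore, feature_id: str) -> list[Annotation]:
    return store.feature_annotations(feature_id)


@dataclass
class TermScores:
    matrix: np.ndarray  # terms x features
    term_ids: list
    feature_ids: list


def term_score_matrix(store: AnnotationStore, feature_ids) -> TermScores:
    """Summed per-(term, feature) annotation scores over the given features."""
    feature_ids = [str(f) for f in feature_ids]
    terms = store.all_terms
    term_pos = {t: i for i, t in enumerate(terms)}
    mat = np.zeros((len(terms), len(feature_ids)))
    for j, fid in enumerate(feature_ids):
        for ann in store.feature_annotations(fid):
            w = TYPE_SCORES[ann.annotation_type]
            if w == 0:
                continue
            for t in ann.terms:
                mat[term_pos[t], j] += w
    return TermScores(mat, terms, feature_ids)


@dataclass
class EnrichmentResult:
    term: str
    stat: float
    p_value: float
    q_value: float
    rejected: bool
    enriched_group: str  # 'group1' | 'group2'
    group1_mean_score: float
    group2_mean_score: float


def enrich_terms(
    store: AnnotationStore,
    group1_ids,
    group2_ids,
    n_permutations: int = 1000,
    alpha: float = 0.1,
    seed: int = 0,
) -> list[EnrichmentResult]:
    """Rank-mean permutation test with dsFDR over all annotation terms.

    Results come back for every term (sorted by q then |stat| descending);
    significant ones carry ``rejected=True`` and the group they are
    enriched in.
    """
    g1 = [str(f) for f in group1_ids]
    g2 = [str(f) for f in group2_ids]
    if not g1 or not g2:
        raise ValidationError("both feature groups must be non-empty")
    if set(g1) & set(g2):
        raise ValidationError("feature groups overlap")
    scores = term_score_matrix(store, g1 + g2)
    if not scores.term_ids:
        return []
    labels = np.zeros(len(g1) + len(g2), dtype=bool)
    labels[: len(g1)] = True
    # features play the role of the test's sampling units
    x = per_feature_transform(scores.matrix.T, "rank")
    s_obs = _stat_over_labelings(x, labels[None, :], "meandiff")[0]
    S_perm = permutation_null(
        x, labels, n_permutations=n_permutations, seed=seed, exhaustive=False
    )
    p = permutation_pvalues(s_obs, S_perm, two_sided=True)
    rejected, threshold, q = dsfdr_control(s_obs, S_perm, alpha)
    g1_mean = scores.matrix[:, : len(g1)].mean(axis=1)
    g2_mean = scores.matrix[:, len(g1):].mean(axis=1)
    results = [
        EnrichmentResult(
            term=t,
            stat=float(s_obs[i]),
            p_value=float(p[i]),
            q_value=float(q[i]),
            rejected=bool(rejected[i]),
            enriched_group="group1" if s_obs[i] >= 0 else "group2",
            group1_mean_score=float(g1_mean[i]),
            group2_mean_score=float(g2_mean[i]),
        )
        for i, t in enumerate(scores.term_ids)
    ]
    results.sort(key=lambda r: (r.q_value, -abs(r.stat)))
    return results


def flag_contaminants(store: AnnotationStore, exp: Experiment) -> Experiment:
    """Label each feature contaminant / annotated / none in feature_metadata.

    A feature covered by any contamination-type annotation is a
    ``contaminant``; otherwise ``annotated`` if it has any annotation, else
    ``none``.  The labels land in feature_metadata column
    ``annotation_status`` for use by filters and heatmap color bars.
    """
    labels = []
    for fid in exp.feature_ids:
        anns = store.feature_annotations(str(fid))
        if any(a.annotation_type == "contamination" for a in anns):
            labels.append("contaminant")
        elif anns:
            labels.append("annotated")
        else:
            labels.append("none")
    fmd = exp.feature_metadata.copy()
    fmd["annotation_status"] = labels
    out = exp.copy(feature_metadata=fmd)
    return out.with_history("flag_contaminants", {"n_annotations": len(store)})


def most_common_term(store: AnnotationStore, feature_id: str, candidate_terms) -> str:
    """The candidate term with the highest summed score for this feature.

    Falls back to ``"other"`` when the feature has no annotations or no
    candidate reaches a positive total; ties go to the earlier candidate in
    the given order.
    """
    candidate_terms = list(candidate_terms)
    if not candidate_terms:
        raise ValidationError("candidate_terms must be non-empty")
    totals = {t: 0.0 for t in candidate_terms}
    for ann in store.feature_annotations(str(feature_id)):
        w = TYPE_SCORES[ann.annotation_type]
        for t in ann.terms:
            if t in totals:
                totals[t] += w
    best = max(candidate_terms, key=lambda t: totals[t])  # max is stable: first wins ties
    if totals[best] <= 0:
        return "other"
    return best
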