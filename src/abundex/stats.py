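"""Permutation-based differential abundance and correlation tests.

Two-group tests compare a per-feature statistic (mean difference after an
optional rank or presence/absence transform) between sample groups; the
null distribution comes from random — or exhaustive — relabelings of the
samples.  Correlation tests relate a continuous sample covariate to each
feature the same way, permuting the covariate vector.

Multiple-testing control offers Benjamini-Hochberg step-up, filtered BH
(features whose discrete null support cannot reach the target level are
removed from the testing family first), and dsFDR — a discrete FDR
procedure that thresholds the test statistic directly:

    FDRhat(t) = min(1, E_perm[#{j : |s_perm_j| >= t}] / max(1, #{j : |s_obs_j| >= t}))

with the rejection threshold the smallest observed ``|s|`` at which
``FDRhat <= alpha``.  Working on the statistic scale rather than on
p-values avoids the power loss that coarse discrete p-value supports
inflict on step-up procedures with sparse count data.

p-value convention: Monte-Carlo nulls use the add-one rule
``p = (1 + #{b : |s_b| >= |s_obs|}) / (1 + B)`` so p is never 0; exhaustive
enumeration includes the observed labeling among the ``B`` assignments, so
``p = #{b : |s_b| >= |s_obs|} / B`` (the count is always >= 1).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field as dc_field
from itertools import combinations, permutations
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .experiment import Experiment, ValidationError

logger = logging.getLogger("abundex")

#: largest number of distinct assignments enumerated in exhaustive mode
EXHAUSTIVE_CAP = 20_000


# --------------------------------------------------------------------- #
# specs and results


@dataclass
class TestSpec:
    """Parameters of a two-group differential abundance test."""

    __test__ = False  # not a pytest class, despite the name

    field: str
    group1_values: Sequence
    group2_values: Optional[Sequence] = None  # None = all other samples
    transform: str = "rank"  # none | rank | binarize
    statistic: str | Callable = "meandiff"
    n_permutations: int = 1000
    alpha: float = 0.1
    fdr_method: str = "dsfdr"  # dsfdr | bh | filtered_bh
    seed: int = 0
    two_sided: bool = True
    exhaustive: bool = False

    def to_params(self) -> dict:
        d = dict(self.__dict__)
        d["group1_values"] = sorted(map(str, self.group1_values))
        d["group2_values"] = (
            None if self.group2_values is None else sorted(map(str, self.group2_values))
        )
        if callable(d["statistic"]):
            d["statistic"] = getattr(d["statistic"], "__name__", "user")
        return d


@dataclass
class DiffResult:
    """Per-feature output of a differential test, in input feature order."""

    feature_ids: list
    stat_obs: np.ndarray
    p_values: np.ndarray
    q_values: np.ndarray
    rejected: np.ndarray
    direction: np.ndarray  # 'group1' | 'group2'
    threshold: Optional[float] = None  # dsFDR statistic threshold
    spec: dict = dc_field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature_id": self.feature_ids,
                "stat": self.stat_obs,
                "p": self.p_values,
                "q": self.q_values,
                "rejected": self.rejected,
                "direction": self.direction,
            }
        )

    @property
    def significant_features(self) -> list:
        return [f for f, r in zip(self.feature_ids, self.rejected) if r]


# --------------------------------------------------------------------- #
# building blocks


def per_feature_transform(data: np.ndarray, transform: str) -> np.ndarray:
    """Optional pre-test transform of the selected-sample submatrix.

    ``rank`` uses mid-ranks within each feature across the selected samples
    only; ``binarize`` maps to presence/absence (> 0); ``none`` is identity.
    """
    if transform == "none" or transform is None:
        return np.asarray(data, dtype=float)
    if transform == "rank":
        return scipy.stats.rankdata(data, axis=0, method="average")
    if transform == "binarize":
        return (np.asarray(data) > 0).astype(float)
    raise ValidationError(f"unknown transform {transform!r}")


def meandiff_stat(x: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Mean(group1) - mean(group2) per feature; labels is a boolean vector."""
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValidationError("both groups must be non-empty")
    return x[labels].mean(axis=0) - x[~labels].mean(axis=0)


def _stat_over_labelings(x: np.ndarray, label_matrix: np.ndarray, statistic) -> np.ndarray:
    """Statistic vector for each row of a (B x n) boolean label matrix."""
    if statistic == "meandiff" or statistic is meandiff_stat:
        P = label_matrix.astype(float)
        n1 = P.sum(axis=1, keepdims=True)
        n2 = P.shape[1] - n1
        return (P @ x) / n1 - ((1.0 - P) @ x) / n2
    return np.vstack([statistic(x, row) for row in label_matrix])


def n_distinct_assignments(n: int, n1: int) -> int:
    return math.comb(n, n1)


def _exhaustive_label_matrix(n: int, n1: int) -> np.ndarray:
    count = n_distinct_assignments(n, n1)
    if count > EXHAUSTIVE_CAP:
        raise ValidationError(
            f"{count} distinct assignments exceed the exhaustive cap "
            f"({EXHAUSTIVE_CAP}); use random permutations instead"
        )
    out = np.zeros((count, n), dtype=bool)
    for b, pos in enumerate(combinations(range(n), n1)):
        out[b, list(pos)] = True
    return out


def permutation_null(
    x: np.ndarray,
    labels: np.ndarray,
    statistic="meandiff",
    n_permutations: int = 1000,
    seed: int = 0,
    exhaustive: bool = False,
) -> np.ndarray:
    """(B x F) matrix of the statistic under permuted group labels.

    Exhaustive mode enumerates every distinct assignment of group sizes
    exactly once (including the observed one); random mode draws uniform
    label shuffles from the seed.
    """
    labels = np.asarray(labels, dtype=bool)
    n = labels.size
    if exhaustive:
        label_matrix = _exhaustive_label_matrix(n, int(labels.sum()))
    else:
        rng = np.random.default_rng(seed)
        label_matrix = rng.permuted(
            np.tile(labels, (int(n_permutations), 1)), axis=1
        )
    return _stat_over_labelings(x, label_matrix, statistic)


def permutation_pvalues(
    s_obs: np.ndarray,
    S_perm: np.ndarray,
    two_sided: bool = True,
    exhaustive: bool = False,
) -> np.ndarray:
    """Permutation p per feature; see module docstring for the conventions."""
    if S_perm.shape[0] < 1:
        raise ValidationError("permutation null must have at least one row")
    B = S_perm.shape[0]
    if two_sided:
        count = (np.abs(S_perm) >= np.abs(s_obs)[None, :]).sum(axis=0)
    else:
        count = (S_perm >= s_obs[None, :]).sum(axis=0)
    if exhaustive:
        p = count / B
        # the observed labeling is enumerated, so count >= 1 when computed
        # through the same statistic path; guard against a foreign s_obs
        p = np.maximum(p, 1.0 / B)
    else:
        p = (1.0 + count) / (1.0 + B)
    return p


# --------------------------------------------------------------------- #
# multiple-testing control


def dsfdr_control(s_obs: np.ndarray, S_perm: np.ndarray, alpha: float = 0.1):
    """Discrete FDR control by thresholding the statistic directly.

    Returns ``(rejected, threshold, q_values)``.  ``threshold`` is the
    smallest observed ``|s|`` with estimated FDR <= alpha (None if no
    threshold qualifies, in which case nothing is rejected).  ``q_j`` is
    the best (smallest) estimated FDR over thresholds at or below
    ``|s_obs_j]``, hence monotone non-increasing in ``|s|``.
    """
    t_obs = np.abs(np.asarray(s_obs, dtype=float))
    F = t_obs.size
    B = S_perm.shape[0]
    candidates = np.unique(t_obs)  # ascending
    sorted_obs = np.sort(t_obs)
    sorted_perm = np.sort(np.abs(S_perm).ravel())

    # R(t) = #obs >= t ; V(t) = mean over permutations of #perm >= t
    R = F - np.searchsorted(sorted_obs, candidates, side="left")
    V = (sorted_perm.size - np.searchsorted(sorted_perm, candidates, side="left")) / B
    fdr_hat = np.minimum(1.0, V / np.maximum(1, R))

    ok = fdr_hat <= alpha
    if ok.any():
        threshold = float(candidates[np.argmax(ok)])  # smallest qualifying t
        rejected = t_obs >= threshold
    else:
        threshold = None
        rejected = np.zeros(F, dtype=bool)

    cummin = np.minimum.accumulate(fdr_hat)
    q = cummin[np.searchsorted(candidates, t_obs, side="right") - 1]
    return rejected, threshold, q


def bh_control(p_values: np.ndarray, alpha: float = 0.1):
    """Benjamini-Hochberg step-up. Returns ``(rejected, q_values)``."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    rejected = q <= alpha
    return rejected, q


def min_achievable_pvalues(S_perm: np.ndarray, exhaustive: bool = False) -> np.ndarray:
    """Smallest two-sided p each feature could attain given its null support.

    Evaluates the p-value rule at an observed statistic equal to the most
    extreme value of the feature's permutation null; a feature whose null is
    constant (e.g. present in a single sample after binarization) gets 1.
    """
    A = np.abs(S_perm)
    B = A.shape[0]
    ties_at_max = (A >= A.max(axis=0)[None, :]).sum(axis=0)
    if exhaustive:
        return ties_at_max / B
    return (1.0 + ties_at_max) / (1.0 + B)


def filtered_bh_control(p_values: np.ndarray, p_min_achievable: np.ndarray, alpha: float = 0.1):
    """BH restricted to features whose null support can reach ``alpha``.

    Features with ``p_min_achievable > alpha`` are removed from the testing
    family (they get q = 1, rejected = False); BH runs on the remainder.
    Shrinking the family can only lower BH's effective correction, so this
    never rejects fewer features than plain BH.
    """
    p = np.asarray(p_values, dtype=float)
    p_min = np.asarray(p_min_achievable, dtype=float)
    if p.shape != p_min.shape:
        raise ValidationError("p_values and p_min_achievable must have equal length")
    family = p_min <= alpha
    rejected = np.zeros(p.size, dtype=bool)
    q = np.ones(p.size)
    if family.any():
        rej_f, q_f = bh_control(p[family], alpha)
        rejected[family] = rej_f
        q[family] = q_f
    return rejected, q


# --------------------------------------------------------------------- #
# top-level tests


def _select_groups(exp: Experiment, spec: TestSpec):
    md = exp.sample_metadata
    if spec.field not in md.columns:
        raise ValidationError(
            f"field {spec.field!r} not in sample_metadata; available: {list(md.columns)}"
        )
    col = md[spec.field].astype(str)
    g1 = col.isin({str(v) for v in spec.group1_values}).to_numpy()
    if spec.group2_values is None:
        g2 = ~g1
    else:
        g2 = col.isin({str(v) for v in spec.group2_values}).to_numpy()
    if (g1 & g2).any():
        raise ValidationError("group1 and group2 overlap")
    if g1.sum() < 2 or g2.sum() < 2:
        raise ValidationError(
            f"need >= 2 samples per group, got {int(g1.sum())} and {int(g2.sum())}"
        )
    sel = np.flatnonzero(g1 | g2)
    labels = g1[sel]
    return sel, labels


def _apply_fdr(spec_dict, s_obs, S_perm, p, exhaustive, alpha, fdr_method):
    if fdr_method == "dsfdr":
        rejected, threshold, q = dsfdr_control(s_obs, S_perm, alpha)
    elif fdr_method == "bh":
        rejected, q = bh_control(p, alpha)
        threshold = None
    elif fdr_method == "filtered_bh":
        p_min = min_achievable_pvalues(S_perm, exhaustive)
        rejected, q = filtered_bh_control(p, p_min, alpha)
        threshold = None
    else:
        raise ValidationError(f"unknown fdr_method {fdr_method!r}")
    return rejected, threshold, q


def diff_abundance(exp: Experiment, spec: TestSpec) -> DiffResult:
    """Two-group permutation test over every feature, with FDR control."""
    sel, labels = _select_groups(exp, spec)
    x = per_feature_transform(exp.dense()[sel, :], spec.transform)
    s_obs = _stat_over_labelings(x, labels[None, :], spec.statistic)[0]
    S_perm = permutation_null(
        x,
        labels,
        statistic=spec.statistic,
        n_permutations=spec.n_permutations,
        seed=spec.seed,
        exhaustive=spec.exhaustive,
    )
    p = permutation_pvalues(s_obs, S_perm, spec.two_sided, spec.exhaustive)
    rejected, threshold, q = _apply_fdr(
        spec, s_obs, S_perm, p, spec.exhaustive, spec.alpha, spec.fdr_method
    )
    direction = np.where(s_obs >= 0, "group1", "group2")
    return DiffResult(
        feature_ids=list(exp.feature_ids),
        stat_obs=s_obs,
        p_values=p,
        q_values=q,
        rejected=rejected,
        direction=direction,
        threshold=threshold,
        spec=spec.to_params(),
    )


def _pearson_matrix(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Pearson correlation of each row of Y (B x n) with each column of X (n x F)."""
    Xc = X - X.mean(axis=0, keepdims=True)
    x_sd = X.std(axis=0, keepdims=True)
    zero_var = x_sd.ravel() == 0
    Xz = Xc / np.where(x_sd == 0, 1.0, x_sd)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    y_sd = Y.std(axis=1, keepdims=True)
    Yz = Yc / np.where(y_sd == 0, 1.0, y_sd)
    S = (Yz @ Xz) / X.shape[0]
    S[:, zero_var] = 0.0
    return S


def correlation_test(
    exp: Experiment,
    field: str,
    method: str | Callable = "spearman",
    n_permutations: int = 1000,
    alpha: float = 0.1,
    fdr_method: str = "dsfdr",
    seed: int = 0,
    exhaustive: bool = False,
    two_sided: bool = True,
) -> DiffResult:
    """Correlate a continuous sample covariate with every feature.

    ``method`` is ``spearman`` (mid-rank Pearson), ``pearson``, or a
    callable ``f(feature_values, covariate) -> float``.  The null permutes
    the covariate vector.  Samples with a missing covariate are dropped
    with a warning; zero-variance features get statistic 0 and p 1.
    """
    col = pd.to_numeric(exp.sample_metadata[field], errors="coerce")
    if col.notna().sum() == 0:
        raise ValidationError(f"field {field!r} has no numeric values")
    keep = col.notna().to_numpy()
    if not keep.all():
        logger.warning("dropping %d samples with missing %r", int((~keep).sum()), field)
    y = col.to_numpy(dtype=float)[keep]
    n = y.size
    if n < 3:
        raise ValidationError(f"need >= 3 samples with numeric {field!r}, got {n}")
    X = exp.dense()[keep, :]

    if method == "spearman":
        X = scipy.stats.rankdata(X, axis=0, method="average")
        y = scipy.stats.rankdata(y, method="average")
        stat_rows = _pearson_matrix
    elif method == "pearson":
        stat_rows = _pearson_matrix
    elif callable(method):
        def stat_rows(Xm, Ym):
            return np.vstack([[method(Xm[:, j], yrow) for j in range(Xm.shape[1])] for yrow in Ym])
    else:
        raise ValidationError(f"unknown correlation method {method!r}")

    if exhaustive:
        count = math.factorial(n)
        if count > EXHAUSTIVE_CAP:
            raise ValidationError(
                f"{count} permutations exceed the exhaustive cap ({EXHAUSTIVE_CAP}); "
                "use random permutations instead"
            )
        Y = np.array(list(permutations(y)), dtype=float)
    else:
        rng = np.random.default_rng(seed)
        Y = rng.permuted(np.tile(y, (int(n_permutations), 1)), axis=1)

    zero_var = X.std(axis=0) == 0
    s_obs = stat_rows(X, y[None, :])[0]
    s_obs[zero_var] = 0.0
    S_perm = stat_rows(X, Y)
    p = permutation_pvalues(s_obs, S_perm, two_sided, exhaustive)
    p[zero_var] = 1.0
    rejected, threshold, q = _apply_fdr(None, s_obs, S_perm, p, exhaustive, alpha, fdr_method)
    direction = np.where(s_obs >= 0, "group1", "group2")
    return DiffResult(
        feature_ids=list(exp.feature_ids),
        stat_obs=s_obs,
        p_values=p,
        q_values=q,
        rejected=rejected,
        direction=direction,
        threshold=threshold,
        spec={
            "field": field,
            "method": method if isinstance(method, str) else getattr(method, "__name__", "user"),
            "n_permutations": int(n_permutations),
            "alpha": float(alpha),
            "fdr_method": fdr_method,
            "seed": int(seed),
            "exhaustive": bool(exhaustive),
        },
    )
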