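"""Reordering of samples or features for display and analysis.

Metadata sorts, abundance/prevalence sorts, center-of-mass ordering along a
sample gradient, and hierarchical-clustering leaf ordering (single linkage
over log-transformed, per-item standardized profiles — the heatmap default).

All sorts are stable: ties keep the current order, so outputs are
deterministic and nested sorts compose (sorting by plate after sorting by
origin yields origin-major, plate-minor blocks).
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from .experiment import Experiment, ValidationError, experiment_op, reorder
from .filtering import _metadata_for_axis
from .transforms import DEFAULT_LOG_BASE, DEFAULT_MIN_CUTOFF

import logging

logger = logging.getLogger("abundex")


def _numeric_or_string_key(col) -> np.ndarray:
    """Sort numerically when every non-missing value parses as a number."""
    import pandas as pd

    numeric = pd.to_numeric(col, errors="coerce")
    if numeric.notna().to_numpy().all() or (numeric.isna() == col.isna()).all():
        return numeric.to_numpy()
    return col.astype(str).to_numpy()


@experiment_op
def sort_by_metadata(exp, axis: str, fields) -> Experiment:
    """Stable lexicographic sort by the listed metadata fields (major first)."""
    md = _metadata_for_axis(exp, axis)
    if isinstance(fields, str):
        fields = [fields]
    for f in fields:
        if f not in md.columns:
            raise KeyError(f"field {f!r} not on axis {axis!r}; available: {list(md.columns)}")
    order = np.arange(len(md))
    # apply minor keys first; mergesort keeps prior order among ties
    for f in reversed(list(fields)):
        key = _numeric_or_string_key(md[f])[order]
        order = order[np.argsort(key, kind="stable")]
    return reorder.__wrapped_op__(exp, order, axis=axis)


@experiment_op
def sort_by_abundance(exp, axis: str = "features", key: str = "total") -> Experiment:
    """Ascending sort by per-item total abundance or prevalence."""
    dense = exp.dense()
    data = dense if axis == "samples" else dense.T
    if key == "total":
        values = data.sum(axis=1)
    elif key == "prevalence":
        values = (data > 0).sum(axis=1)
    else:
        raise ValidationError(f"key must be 'total' or 'prevalence', got {key!r}")
    order = np.argsort(values, kind="stable")
    return reorder.__wrapped_op__(exp, order, axis=axis)


def center_of_mass(exp: Experiment, sample_subset=None) -> np.ndarray:
    """Per-feature center of mass over the 0-based positions of the subset.

    ``com(f) = sum_i i * x_if / sum_i x_if`` with ``i`` running over
    positions *within* the subset (not global sample indices).  Features
    with zero total over the subset get NaN.
    """
    dense = exp.dense()
    if sample_subset is None:
        sub = dense
    else:
        sub_idx = np.asarray(sample_subset, dtype=int)
        if sub_idx.size == 0:
            raise ValidationError("empty sample subset")
        sub = dense[sub_idx, :]
    positions = np.arange(sub.shape[0], dtype=float)
    totals = sub.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        com = (positions[:, None] * sub).sum(axis=0) / totals
    com[totals == 0] = np.nan
    return com


@experiment_op
def sort_center_of_mass(exp, sample_subset=None) -> Experiment:
    """Order features by where their abundance concentrates along the samples.

    Features with zero total over the subset carry no positional signal;
    they are placed last (in current order) with a warning.
    """
    com = center_of_mass(exp, sample_subset)
    n_zero = int(np.isnan(com).sum())
    if n_zero:
        logger.warning("%d features have zero total over the subset; placed last", n_zero)
    key = np.where(np.isnan(com), np.inf, com)
    order = np.argsort(key, kind="stable")
    return reorder.__wrapped_op__(exp, order, axis="features")


@experiment_op
def cluster_order(
    exp,
    axis: str = "features",
    linkage_method: str = "single",
    log_base: float = DEFAULT_LOG_BASE,
    min_cutoff: float = DEFAULT_MIN_CUTOFF,
) -> Experiment:
    """Reorder one axis by hierarchical-clustering leaf traversal.

    Pipeline: log transform -> per-item centering and unit-variance scaling
    (per-feature when clustering features, per-sample when clustering
    samples) -> Euclidean distances -> agglomerative tree (single linkage by
    default) -> dendrogram leaf order.  Only the ordering changes; the
    matrix values themselves are untouched.
    """
    if linkage_method not in ("single", "average", "complete"):
        raise ValidationError(f"unsupported linkage {linkage_method!r}")
    if axis == "features":
        n = exp.shape[1]
    elif axis == "samples":
        n = exp.shape[0]
    else:
        raise ValidationError(f"axis must be 'samples' or 'features', got {axis!r}")
    if n < 2:
        raise ValidationError(f"need at least 2 {axis} to cluster, got {n}")

    x = np.log(np.maximum(exp.dense(), min_cutoff)) / np.log(log_base)
    if axis == "features":
        profiles = x.T  # one row per feature; scale per feature
    else:
        profiles = x
    mu = profiles.mean(axis=1, keepdims=True)
    sd = profiles.std(axis=1, keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    profiles = (profiles - mu) / sd

    z = linkage(pdist(profiles, metric="euclidean"), method=linkage_method)
    order = leaves_list(z)
    return reorder.__wrapped_op__(exp, order, axis=axis)
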