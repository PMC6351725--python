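"""Normalizations and value transformations of the abundance matrix.

All functions return a new experiment and append one history record; the
input is never mutated.  Counts stay counts: only :func:`transform_clr`
produces negative values, and the result is flagged accordingly.
"""

from __future__ import annotations

import logging

import numpy as np
import scipy.sparse as sp

from .experiment import Experiment, ValidationError, experiment_op

logger = logging.getLogger("abundex")

DEFAULT_TOTAL = 10_000.0
DEFAULT_OUTLIER_FRACTION = 0.1
DEFAULT_LOG_BASE = 2.0
DEFAULT_MIN_CUTOFF = 1.0
DEFAULT_CLR_PSEUDOCOUNT = 1.0
DEFAULT_BINARIZE_CUTOFF = 0.0


def _row_sums(data) -> np.ndarray:
    if sp.issparse(data):
        return np.asarray(data.sum(axis=1)).ravel()
    return data.sum(axis=1)


def _scale_rows(data, factors: np.ndarray):
    """Multiply row i by factors[i], preserving sparsity."""
    if sp.issparse(data):
        return sp.diags(factors) @ data
    return data * factors[:, None]


@experiment_op
def normalize_tss(exp: Experiment, total: float = DEFAULT_TOTAL, drop_zero_samples: bool = False) -> Experiment:
    """Total-sum scaling: rescale every sample to sum to ``total``.

    Samples with zero total cannot be scaled; they raise unless
    ``drop_zero_samples`` is set, in which case they are removed with a
    logged warning.
    """
    if total <= 0:
        raise ValidationError(f"total must be positive, got {total}")
    sums = _row_sums(exp.data)
    zero = sums <= 0
    data, smd = exp.data, exp.sample_metadata
    if zero.any():
        if not drop_zero_samples:
            bad = list(exp.sample_ids[zero])
            raise ValidationError(f"samples with zero total cannot be normalized: {bad}")
        logger.warning("dropping %d all-zero samples before TSS", int(zero.sum()))
        keep = np.flatnonzero(~zero)
        data = data[keep, :]
        smd = smd.iloc[keep]
        sums = sums[keep]
    data = _scale_rows(data, total / sums)
    return exp.copy(data=data, sample_metadata=smd, normalized_total=float(total))


@experiment_op
def normalize_tss_excluding_outliers(
    exp: Experiment,
    total: float = DEFAULT_TOTAL,
    outlier_fraction: float = DEFAULT_OUTLIER_FRACTION,
) -> Experiment:
    """TSS where dominant features do not drive the scaling factor.

    Per sample, features whose within-sample relative abundance exceeds
    ``outlier_fraction`` are excluded from the denominator, iterating
    (relative abundance recomputed over the remaining features) until the
    excluded set is stable; the resulting factor ``total / included_sum`` is
    then applied to *all* features of the sample, excluded ones included.
    The iteration terminates because the excluded set only grows.
    """
    if not 0 < outlier_fraction <= 1:
        raise ValidationError(f"outlier_fraction must be in (0,1], got {outlier_fraction}")
    if total <= 0:
        raise ValidationError(f"total must be positive, got {total}")
    dense = exp.dense()
    n_s, n_f = dense.shape
    factors = np.empty(n_s)
    for i in range(n_s):
        x = dense[i]
        included = np.ones(n_f, dtype=bool)
        while True:
            s = x[included].sum()
            if s <= 0:
                raise ValidationError(
                    f"all features excluded as outliers in sample {exp.sample_ids[i]!r}"
                )
            newly = included & (x / s > outlier_fraction)
            if not newly.any():
                break
            included &= ~newly
        if not included.all():
            excluded_ids = list(exp.feature_ids[~included])
            logger.info(
                "sample %s: %d outlier features excluded from TSS denominator: %s",
                exp.sample_ids[i], len(excluded_ids), excluded_ids[:5],
            )
        factors[i] = total / s
    data = _scale_rows(exp.data, factors)
    return exp.copy(data=data, normalized_total=None)


@experiment_op
def transform_clr(exp: Experiment, clr_pseudocount: float = DEFAULT_CLR_PSEUDOCOUNT) -> Experiment:
    """Centered log-ratio transform with a pseudocount shift.

    Per sample: ``y_j = ln(x_j + c) - mean_j ln(x_j + c)``.  Output rows sum
    to zero; the matrix may contain negatives afterwards and is flagged
    non-count (dense storage).
    """
    if clr_pseudocount <= 0:
        raise ValidationError(f"clr_pseudocount must be positive, got {clr_pseudocount}")
    logx = np.log(exp.dense() + clr_pseudocount)
    y = logx - logx.mean(axis=1, keepdims=True)
    return exp.copy(data=y, sparse=False, non_negative=False, normalized_total=None)


@experiment_op
def transform_log(
    exp: Experiment,
    log_base: float = DEFAULT_LOG_BASE,
    min_cutoff: float = DEFAULT_MIN_CUTOFF,
) -> Experiment:
    """``y = log_base(max(x, min_cutoff))`` — the cutoff handles zero counts."""
    if min_cutoff <= 0:
        raise ValidationError(f"min_cutoff must be positive, got {min_cutoff}")
    if log_base <= 1:
        raise ValidationError(f"log_base must exceed 1, got {log_base}")
    y = np.log(np.maximum(exp.dense(), min_cutoff)) / np.log(log_base)
    non_negative = np.log(min_cutoff) >= 0
    return exp.copy(data=y, sparse=False, non_negative=bool(non_negative))


@experiment_op
def binarize(exp: Experiment, binarize_cutoff: float = DEFAULT_BINARIZE_CUTOFF) -> Experiment:
    """Presence/absence: 1 where ``x > binarize_cutoff`` (strict), else 0."""
    if sp.issparse(exp.data):
        data = sp.csr_matrix((exp.data > binarize_cutoff).astype(float))
    else:
        data = (exp.data > binarize_cutoff).astype(float)
    return exp.copy(data=data, normalized_total=None)


def scale_features_unit(exp: Experiment) -> np.ndarray:
    """Per-feature centering and unit-variance scaling (population sd).

    Returns a dense matrix; zero-variance features map to all-zeros.  Used
    as a pre-clustering step, so it returns the matrix rather than an
    experiment — the experiment's values are display values and stay put.
    """
    x = exp.dense()
    mu = x.mean(axis=0, keepdims=True)
    sd = x.std(axis=0, keepdims=True)
    sd_safe = np.where(sd == 0, 1.0, sd)
    y = (x - mu) / sd_safe
    y[:, (sd == 0).ravel()] = 0.0
    return y
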