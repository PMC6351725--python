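"""Subset samples or features by metadata values or data-derived criteria.

Boundary semantics throughout: thresholds keep ``>=`` (a feature with total
exactly at the minimum, or prevalence exactly at the minimum fraction, is
kept).  Filters never renormalize — re-normalization after e.g. contaminant
removal is an explicit separate :func:`~abundex.transforms.normalize_tss`
call.  All filters preserve the relative order of survivors.
"""

from __future__ import annotations

import logging

import numpy as np
import scipy.sparse as sp

from .experiment import Experiment, ValidationError, experiment_op, reorder

logger = logging.getLogger("abundex")


def _metadata_for_axis(exp: Experiment, axis: str):
    if axis == "samples":
        return exp.sample_metadata
    if axis == "features":
        return exp.feature_metadata
    raise ValidationError(f"axis must be 'samples' or 'features', got {axis!r}")


def _keep(exp: Experiment, mask: np.ndarray, axis: str, what: str) -> Experiment:
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        logger.warning("filter %s left zero %s", what, axis)
    return reorder.__wrapped_op__(exp, idx, axis=axis)


@experiment_op
def filter_by_metadata(exp, axis: str, field: str, values, negate: bool = False) -> Experiment:
    """Keep rows/columns whose ``field`` value is in ``values`` (or not, if negate)."""
    md = _metadata_for_axis(exp, axis)
    if field not in md.columns:
        raise KeyError(
            f"field {field!r} not found on axis {axis!r}; available: {list(md.columns)}"
        )
    mask = md[field].isin(set(values)).to_numpy()
    if negate:
        mask = ~mask
    return _keep(exp, mask, axis, f"by_metadata({field})")


def _feature_totals(exp: Experiment) -> np.ndarray:
    if sp.issparse(exp.data):
        return np.asarray(exp.data.sum(axis=0)).ravel()
    return exp.data.sum(axis=0)


@experiment_op
def filter_sum_abundance(exp, min_total: float) -> Experiment:
    """Keep features whose total across samples is ``>= min_total``.

    The threshold applies to the matrix's *current* values — normalize
    first if the cutoff refers to normalized reads.
    """
    return _keep(exp, _feature_totals(exp) >= min_total, "features", "sum_abundance")


@experiment_op
def filter_prevalence(exp, min_fraction: float, presence_cutoff: float = 0.0) -> Experiment:
    """Keep features present (value > cutoff) in at least ``min_fraction`` of samples."""
    if not 0 < min_fraction <= 1:
        raise ValidationError(f"min_fraction must be in (0,1], got {min_fraction}")
    if sp.issparse(exp.data):
        present = np.asarray((exp.data > presence_cutoff).sum(axis=0)).ravel()
    else:
        present = (exp.data > presence_cutoff).sum(axis=0)
    frac = present / max(exp.shape[0], 1)
    return _keep(exp, frac >= min_fraction, "features", "prevalence")


@experiment_op
def filter_feature_field_present(exp, field: str) -> Experiment:
    """Keep features whose ``field`` in feature_metadata is non-missing.

    Mirrors restricting a metabolomics table to features that carry a
    database curation.
    """
    if field not in exp.feature_metadata.columns:
        raise KeyError(
            f"field {field!r} not in feature_metadata; "
            f"available: {list(exp.feature_metadata.columns)}"
        )
    col = exp.feature_metadata[field]
    mask = col.notna().to_numpy() & (col.astype(str).str.len() > 0).to_numpy()
    return _keep(exp, mask, "features", f"field_present({field})")
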