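"""Central experiment object: abundance matrix + synchronized metadata.

An :class:`Experiment` joins a samples x features abundance matrix with a
per-sample and a per-feature metadata table, keeping all three in sync along
both axes.  Every mutating operation returns a *new* experiment and appends a
record to ``history``, so an exploratory session can be audited and replayed
from the pristine input.

Convention: samples are matrix **rows**, features are matrix **columns**.
Heatmap rendering transposes at display time (features drawn as rows).
"""

from __future__ import annotations

import datetime
import functools
import inspect
import json
import logging
from typing import Any, Callable, Iterable, Mapping

import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger("abundex")

EXPERIMENT_TYPES = ("amplicon", "ms1", "generic")

#: registry of replayable operations (op name -> wrapped callable)
OP_REGISTRY: dict[str, Callable] = {}


class ValidationError(ValueError):
    """Raised when data and metadata are inconsistent or a contract is broken."""


def _jsonify(value: Any) -> Any:
    """Coerce a parameter value into something JSON-serializable."""
    if isinstance(value, (np.integer,)):
        return int(value)
    if isinstance(value, (np.floating,)):
        return float(value)
    if isinstance(value, np.ndarray):
        return [_jsonify(v) for v in value.tolist()]
    if isinstance(value, (list, tuple)):
        return [_jsonify(v) for v in value]
    if isinstance(value, (set, frozenset)):
        return sorted(_jsonify(v) for v in value)
    if isinstance(value, Mapping):
        return {str(k): _jsonify(v) for k, v in value.items()}
    if value is None or isinstance(value, (bool, int, float, str)):
        return value
    raise ValidationError(f"history parameter not JSON-serializable: {value!r}")


class Experiment:
    """Abundance matrix joined with sample and feature metadata.

    Parameters
    ----------
    data :
        Non-negative matrix, samples x features.  Dense ndarray or any
        scipy sparse matrix (stored as CSR when ``sparse=True``).
    sample_metadata, feature_metadata :
        DataFrames indexed by unique sample / feature identifiers, one row
        per matrix row / column, in matrix order.
    sparse :
        Storage hint only: results of every operation are identical for
        sparse and dense storage.
    normalized_total :
        Per-sample total after total-sum scaling (e.g. 10 000), or ``None``
        if the matrix is unnormalized.
    experiment_type :
        ``amplicon`` (feature ids are nucleotide sequences), ``ms1``
        (feature ids encode m/z and retention time) or ``generic``.
    non_negative :
        False only after a transform that legitimately produces negative
        values (CLR); suppresses the non-negativity check.
    """

    def __init__(
        self,
        data,
        sample_metadata: pd.DataFrame,
        feature_metadata: pd.DataFrame,
        *,
        sparse: bool | None = None,
        normalized_total: float | None = None,
        history: list[dict] | None = None,
        experiment_type: str = "generic",
        non_negative: bool = True,
    ):
        if sparse is None:
            sparse = sp.issparse(data)
        if sp.issparse(data):
            data = sp.csr_matrix(data) if sparse else np.asarray(data.todense(), dtype=float)
        else:
            data = np.asarray(data, dtype=float)
            if sparse:
                data = sp.csr_matrix(data)
        self.data = data
        self.sample_metadata = sample_metadata
        self.feature_metadata = feature_metadata
        self.sparse = bool(sparse)
        self.normalized_total = normalized_total
        self.history = list(history) if history else []
        if experiment_type not in EXPERIMENT_TYPES:
            raise ValidationError(f"unknown experiment_type {experiment_type!r}")
        self.experiment_type = experiment_type
        self.non_negative = bool(non_negative)
        self.validate()

    # ------------------------------------------------------------------ #
    # invariants

    def validate(self) -> None:
        n_s, n_f = self.shape
        if len(self.sample_metadata) != n_s:
            raise ValidationError(
                f"sample_metadata has {len(self.sample_metadata)} rows "
                f"but the matrix has {n_s} samples"
            )
        if len(self.feature_metadata) != n_f:
            raise ValidationError(
                f"feature_metadata has {len(self.feature_metadata)} rows "
                f"but the matrix has {n_f} features"
            )
        if self.sample_metadata.index.has_duplicates:
            raise ValidationError("duplicate sample identifiers")
        if self.feature_metadata.index.has_duplicates:
            raise ValidationError("duplicate feature identifiers")
        if self.non_negative:
            mn = self.data.min() if self.size else 0
            if mn < 0:
                raise ValidationError(f"negative abundance value ({mn}) in count matrix")

    # ------------------------------------------------------------------ #
    # basic accessors

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def size(self) -> int:
        return self.data.shape[0] * self.data.shape[1]

    @property
    def sample_ids(self) -> pd.Index:
        return self.sample_metadata.index

    @property
    def feature_ids(self) -> pd.Index:
        return self.feature_metadata.index

    def dense(self) -> np.ndarray:
        """Dense float copy of the abundance matrix (samples x features)."""
        if sp.issparse(self.data):
            return np.asarray(self.data.todense(), dtype=float)
        return np.array(self.data, dtype=float)

    def copy(self, **overrides) -> "Experiment":
        kwargs = dict(
            data=self.data.copy(),
            sample_metadata=self.sample_metadata.copy(),
            feature_metadata=self.feature_metadata.copy(),
            sparse=self.sparse,
            normalized_total=self.normalized_total,
            history=list(self.history),
            experiment_type=self.experiment_type,
            non_negative=self.non_negative,
        )
        kwargs.update(overrides)
        data = kwargs.pop("data")
        smd = kwargs.pop("sample_metadata")
        fmd = kwargs.pop("feature_metadata")
        return Experiment(data, smd, fmd, **kwargs)

    def __repr__(self) -> str:
        n_s, n_f = self.shape
        return (
            f"Experiment({self.experiment_type}, {n_s} samples x {n_f} features, "
            f"{'sparse' if self.sparse else 'dense'}, {len(self.history)} ops)"
        )

    def equals(self, other: "Experiment", tol: float = 0.0) -> bool:
        """Data + metadata equality (history ignored)."""
        if self.shape != other.shape:
            return False
        if not self.sample_ids.equals(other.sample_ids):
            return False
        if not self.feature_ids.equals(other.feature_ids):
            return False
        a, b = self.dense(), other.dense()
        if tol == 0.0:
            return bool(np.array_equal(a, b))
        return bool(np.allclose(a, b, atol=tol, rtol=0))

    # ------------------------------------------------------------------ #
    # history

    def with_history(self, op_name: str, params: Mapping[str, Any]) -> "Experiment":
        """Return self with one appended history record (shallow: data shared)."""
        record = {
            "op_name": op_name,
            "params": _jsonify(params),
            "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        }
        # verify round-trips through JSON before committing
        json.dumps(record)
        new = Experiment.__new__(Experiment)
        new.__dict__.update(self.__dict__)
        new.history = list(self.history) + [record]
        return new


def record_history(exp: Experiment, op_name: str, params: Mapping[str, Any]) -> Experiment:
    """Append one history record; every other field unchanged."""
    return exp.with_history(op_name, params)


def experiment_op(fn: Callable) -> Callable:
    """Register ``fn`` as a replayable experiment operation.

    The wrapper appends a history record carrying the operation name and its
    bound, JSON-serialized parameters, so :func:`replay_history` can rebuild
    any experiment from the pristine input.
    """
    sig = inspect.signature(fn)
    name = fn.__name__

    @functools.wraps(fn)
    def wrapper(exp: Experiment, *args, **kwargs) -> Experiment:
        bound = sig.bind(exp, *args, **kwargs)
        bound.apply_defaults()
        params = {k: _jsonify(v) for k, v in bound.arguments.items() if k != "exp"}
        out = fn(exp, *args, **kwargs)
        return out.with_history(name, params)

    OP_REGISTRY[name] = wrapper
    wrapper.__wrapped_op__ = fn
    return wrapper


def replay_history(pristine: Experiment, history: Iterable[Mapping]) -> Experiment:
    """Re-apply a recorded operation sequence to the pristine input."""
    exp = pristine
    for record in history:
        name = record["op_name"]
        if name not in OP_REGISTRY:
            raise ValidationError(f"unknown operation in history: {name!r}")
        exp = OP_REGISTRY[name](exp, **record["params"])
    return exp


@experiment_op
def reorder(exp: Experiment, index_list, axis: str = "samples") -> Experiment:
    """Permute or subset one axis; metadata follows the matrix.

    ``index_list`` holds 0-based positions along ``axis`` — possibly a
    subset, never duplicated.
    """
    idx = np.asarray(index_list, dtype=int)
    if axis not in ("samples", "features"):
        raise ValidationError(f"axis must be 'samples' or 'features', got {axis!r}")
    n = exp.shape[0] if axis == "samples" else exp.shape[1]
    if idx.size and (idx.min() < 0 or idx.max() >= n):
        raise ValidationError(f"index out of range for axis with {n} items")
    if len(np.unique(idx)) != len(idx):
        raise ValidationError("duplicate indices in index_list")
    if axis == "samples":
        data = exp.data[idx, :]
        smd = exp.sample_metadata.iloc[idx]
        fmd = exp.feature_metadata
    else:
        data = exp.data[:, idx]
        smd = exp.sample_metadata
        fmd = exp.feature_metadata.iloc[idx]
    return exp.copy(data=data, sample_metadata=smd, feature_metadata=fmd)
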