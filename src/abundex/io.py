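"""Reading and writing abundance tables, metadata, and experiment bundles.

Supported table dialects:

``biom_json``
    BIOM format 1.0 (the JSON dialect).  BIOM stores observations
    (features) as rows and samples as columns; reading transposes into the
    package's samples x features orientation.  HDF5 BIOM 2.x can be read
    when ``h5py`` is importable (capability flag ``HAVE_HDF5``).
``tsv``
    Tab-delimited text with an id column and a header row.  Default
    orientation is features-as-rows (the classic QIIME export), switchable
    with ``orientation="samples"``.
``ms1_bucket``
    Metabolomics MS1 bucket table, comma- or tab-delimited, features as
    rows with ids of the form ``"<mz>_<rt>"``; m/z and retention time are
    parsed into feature-metadata columns ``MZ`` and ``RT`` (unparsable ids
    are kept, with missing MZ/RT and a warning).

Metadata files are tab-delimited with a header; the first column (or an
explicit ``id_column``) keys the rows.  Empty cells become the missing
marker (NaN), never the empty string.
"""

from __future__ import annotations

import datetime
import json
import logging
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .experiment import Experiment, ValidationError
from .filtering import filter_sum_abundance
from .transforms import normalize_tss

logger = logging.getLogger("abundex")

try:  # optional BIOM 2.x capability
    import h5py  # noqa: F401

    HAVE_HDF5 = True
except ImportError:  # pragma: no cover
    HAVE_HDF5 = False

DIALECTS = ("biom_json", "tsv", "ms1_bucket")


@dataclass
class TableSource:
    path: str
    dialect: str = "auto"


def detect_dialect(path: str) -> str:
    """Guess the table dialect from the file head; overridable by flag."""
    with open(path, "rb") as fh:
        head = fh.read(4096)
    stripped = head.lstrip()
    if stripped.startswith(b"{"):
        return "biom_json"
    if head.startswith(b"\x89HDF"):
        return "biom_hdf5"
    first_line = head.split(b"\n", 1)[0].decode("utf-8", "replace")
    if "\t" not in first_line and "," in first_line:
        return "ms1_bucket"
    return "tsv"


def _check_table(matrix: np.ndarray, sample_ids, feature_ids, path: str):
    if len(set(sample_ids)) != len(sample_ids):
        raise ValidationError(f"{path}: duplicate sample ids")
    if len(set(feature_ids)) != len(feature_ids):
        raise ValidationError(f"{path}: duplicate feature ids")
    if matrix.size and matrix.min() < 0:
        raise ValidationError(f"{path}: negative abundance values")


def _read_biom_json(path: str):
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as e:
            raise ValidationError(f"{path}: invalid BIOM-JSON at line {e.lineno}: {e.msg}")
    try:
        shape = doc["shape"]
        feature_ids = [r["id"] for r in doc["rows"]]
        sample_ids = [c["id"] for c in doc["columns"]]
        mat = np.zeros((shape[0], shape[1]), dtype=float)  # features x samples
        if doc["matrix_type"] == "sparse":
            for r, c, v in doc["data"]:
                mat[r, c] = v
        else:
            mat[:, :] = np.asarray(doc["data"], dtype=float)
    except (KeyError, TypeError) as e:
        raise ValidationError(f"{path}: malformed BIOM-JSON (missing field {e})")
    matrix = mat.T  # -> samples x features
    _check_table(matrix, sample_ids, feature_ids, path)
    return matrix, sample_ids, feature_ids


def _read_delimited(path: str, sep: str, orientation: str):
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except (pd.errors.ParserError, ValueError) as e:
        raise ValidationError(f"{path}: parse error: {e}")
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise ValidationError(f"{path}: duplicate ids")
    matrix = df.to_numpy(dtype=float)
    if orientation == "features":  # features as rows on disk
        matrix = matrix.T
        sample_ids = [str(c) for c in df.columns]
        feature_ids = [str(i) for i in df.index]
    elif orientation == "samples":
        sample_ids = [str(i) for i in df.index]
        feature_ids = [str(c) for c in df.columns]
    else:
        raise ValidationError(f"orientation must be 'features' or 'samples', got {orientation!r}")
    _check_table(matrix, sample_ids, feature_ids, path)
    return matrix, sample_ids, feature_ids


def _read_biom_hdf5(path: str):  # pragma: no cover - optional capability
    if not HAVE_HDF5:
        raise ValidationError("HDF5 BIOM support requires h5py")
    import h5py

    with h5py.File(path, "r") as f:
        feature_ids = [x.decode() for x in f["observation/ids"][:]]
        sample_ids = [x.decode() for x in f["sample/ids"][:]]
        grp = f["observation/matrix"]
        mat = sp.csr_matrix(
            (grp["data"][:], grp["indices"][:], grp["indptr"][:]),
            shape=(len(feature_ids), len(sample_ids)),
        )
    matrix = np.asarray(mat.todense()).T
    _check_table(matrix, sample_ids, feature_ids, path)
    return matrix, sample_ids, feature_ids


def read_table(source: TableSource | str, dialect: str = None, orientation: str = "features"):
    """Read an abundance table; returns ``(matrix, sample_ids, feature_ids)``.

    Orientation is normalized to samples x features regardless of the
    on-disk layout.
    """
    if isinstance(source, str):
        source = TableSource(source, dialect or "auto")
    elif dialect:
        source = TableSource(source.path, dialect)
    if not os.path.exists(source.path):
        raise FileNotFoundError(source.path)
    d = source.dialect
    if d == "auto":
        d = detect_dialect(source.path)
    if d == "biom_json":
        return _read_biom_json(source.path)
    if d == "biom_hdf5":
        return _read_biom_hdf5(source.path)
    if d == "tsv":
        return _read_delimited(source.path, "\t", orientation)
    if d == "ms1_bucket":
        with open(source.path) as fh:
            first = fh.readline()
        sep = "," if first.count(",") >= first.count("\t") else "\t"
        return _read_delimited(source.path, sep, orientation)
    raise ValidationError(f"unknown dialect {d!r}")


def read_metadata(path: str, id_column: str | None = None) -> pd.DataFrame:
    """Tab-delimited metadata keyed by ``id_column`` (default: first column).

    Columns where every non-missing value parses as a number are coerced to
    numeric; everything else stays string.  Handles LF and CRLF endings.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if id_column is None:
        id_column = df.columns[0]
    if id_column not in df.columns:
        raise ValidationError(f"{path}: id column {id_column!r} not in header")
    if df[id_column].duplicated().any():
        dups = df[id_column][df[id_column].duplicated()].tolist()
        raise ValidationError(f"{path}: duplicated identifiers: {dups[:5]}")
    df = df.set_index(id_column)
    df.index = df.index.astype(str)
    for col in df.columns:
        numeric = pd.to_numeric(df[col], errors="coerce")
        nonmissing = df[col].notna()
        if nonmissing.any() and numeric[nonmissing].notna().all():
            df[col] = numeric
    return df


def _parse_ms1_ids(feature_ids) -> pd.DataFrame:
    mz, rt = [], []
    n_bad = 0
    for fid in feature_ids:
        parts = str(fid).split("_")
        try:
            mz.append(float(parts[0]))
            rt.append(float(parts[1]))
        except (IndexError, ValueError):
            mz.append(np.nan)
            rt.append(np.nan)
            n_bad += 1
    if n_bad:
        logger.warning("%d MS1 feature ids did not parse as '<mz>_<rt>'", n_bad)
    return pd.DataFrame({"MZ": mz, "RT": rt}, index=[str(f) for f in feature_ids])


def assemble_experiment(
    table,
    sample_md: pd.DataFrame | None = None,
    feature_md: pd.DataFrame | None = None,
    experiment_type: str = "generic",
    normalize_total: float | None = None,
    min_feature_total: float | None = None,
    sparse: bool = False,
) -> Experiment:
    """Join a table triple with metadata into an :class:`Experiment`.

    Table samples missing from the metadata are kept with missing-marker
    rows (and a warning) — silently dropping them would change statistics;
    metadata rows absent from the table are dropped with a logged count.
    If requested, TSS normalization runs first and the low-total feature
    filter second, so the total threshold refers to normalized reads.
    """
    matrix, sample_ids, feature_ids = table
    sample_ids = [str(s) for s in sample_ids]
    feature_ids = [str(f) for f in feature_ids]

    def _align(md: pd.DataFrame | None, ids: list, what: str) -> pd.DataFrame:
        if md is None:
            return pd.DataFrame(index=pd.Index(ids, name=f"{what}_id"))
        md = md.copy()
        md.index = md.index.astype(str)
        overlap = md.index.intersection(ids)
        if len(overlap) == 0:
            raise ValidationError(
                f"no overlap between table {what} ids and metadata ids "
                "(wrong key column?)"
            )
        dropped = len(md) - len(overlap)
        if dropped:
            logger.info("dropping %d metadata rows absent from the table (%s)", dropped, what)
        missing = [i for i in ids if i not in md.index]
        if missing:
            logger.warning(
                "%d table %s have no metadata; kept with missing values", len(missing), what
            )
        return md.reindex(ids)

    smd = _align(sample_md, sample_ids, "samples")
    fmd = _align(feature_md, feature_ids, "features")
    if experiment_type == "ms1":
        ms1 = _parse_ms1_ids(feature_ids)
        for col in ("MZ", "RT"):
            if col not in fmd.columns:
                fmd[col] = ms1[col]
    exp = Experiment(
        matrix, smd, fmd, sparse=sparse, experiment_type=experiment_type
    ).with_history("assemble_experiment", {"experiment_type": experiment_type})
    if normalize_total is not None:
        exp = normalize_tss(exp, total=normalize_total)
    if min_feature_total is not None:
        exp = filter_sum_abundance(exp, min_total=min_feature_total)
    return exp


def load_experiment(
    table_path: str,
    sample_metadata_path: str | None = None,
    feature_metadata_path: str | None = None,
    dialect: str = "auto",
    orientation: str = "features",
    experiment_type: str = "generic",
    normalize_total: float | None = None,
    min_feature_total: float | None = None,
    sparse: bool = False,
) -> Experiment:
    """One-call loader: table + metadata files -> assembled Experiment."""
    table = read_table(TableSource(table_path, dialect), orientation=orientation)
    smd = read_metadata(sample_metadata_path) if sample_metadata_path else None
    fmd = read_metadata(feature_metadata_path) if feature_metadata_path else None
    if experiment_type == "generic" and dialect == "ms1_bucket":
        experiment_type = "ms1"
    return assemble_experiment(
        table, smd, fmd, experiment_type, normalize_total, min_feature_total, sparse
    )


# --------------------------------------------------------------------- #
# writing


def _write_biom_json(path: str, matrix: np.ndarray, sample_ids, feature_ids):
    rows, cols = np.nonzero(matrix.T)  # features x samples on disk
    data = [[int(r), int(c), float(matrix.T[r, c])] for r, c in zip(rows, cols)]
    doc = {
        "id": None,
        "format": "Biological Observation Matrix 1.0.0",
        "format_url": "http://biom-format.org",
        "type": "OTU table",
        "generated_by": "abundex",
        "date": datetime.datetime.now().isoformat(),
        "matrix_type": "sparse",
        "matrix_element_type": "float",
        "shape": [len(feature_ids), len(sample_ids)],
        "rows": [{"id": str(f), "metadata": None} for f in feature_ids],
        "columns": [{"id": str(s), "metadata": None} for s in sample_ids],
        "data": data,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def _write_delimited(path: str, sep: str, matrix, sample_ids, feature_ids):
    df = pd.DataFrame(matrix.T, index=[str(f) for f in feature_ids],
                      columns=[str(s) for s in sample_ids])
    df.index.name = "#feature_id"
    df.to_csv(path, sep=sep)


def write_experiment(exp: Experiment, out_prefix: str, dialect: str = "tsv") -> dict:
    """Write table + both metadata files + history JSON; returns the paths.

    Re-reading with :func:`load_experiment_bundle` reproduces the matrix
    and metadata.
    """
    os.makedirs(os.path.dirname(os.path.abspath(out_prefix)), exist_ok=True)
    matrix = exp.dense()
    paths = {}
    if dialect == "biom_json":
        paths["table"] = f"{out_prefix}.biom.json"
        _write_biom_json(paths["table"], matrix, exp.sample_ids, exp.feature_ids)
    elif dialect == "tsv":
        paths["table"] = f"{out_prefix}.table.tsv"
        _write_delimited(paths["table"], "\t", matrix, exp.sample_ids, exp.feature_ids)
    elif dialect == "ms1_bucket":
        paths["table"] = f"{out_prefix}.buckets.csv"
        _write_delimited(paths["table"], ",", matrix, exp.sample_ids, exp.feature_ids)
    else:
        raise ValidationError(f"unknown dialect {dialect!r}")
    paths["sample_metadata"] = f"{out_prefix}.samples.tsv"
    smd = exp.sample_metadata.copy()
    smd.index.name = smd.index.name or "sample_id"
    smd.to_csv(paths["sample_metadata"], sep="\t")
    paths["feature_metadata"] = f"{out_prefix}.features.tsv"
    fmd = exp.feature_metadata.copy()
    fmd.index.name = fmd.index.name or "feature_id"
    fmd.to_csv(paths["feature_metadata"], sep="\t")
    paths["history"] = f"{out_prefix}.history.json"
    with open(paths["history"], "w") as fh:
        json.dump(
            {
                "experiment_type": exp.experiment_type,
                "normalized_total": exp.normalized_total,
                "dialect": dialect,
                "history": exp.history,
            },
            fh,
            indent=1,
        )
    return paths


def load_experiment_bundle(prefix: str) -> Experiment:
    """Load an experiment written by :func:`write_experiment`."""
    with open(f"{prefix}.history.json") as fh:
        meta = json.load(fh)
    dialect = meta["dialect"]
    table_path = {
        "biom_json": f"{prefix}.biom.json",
        "tsv": f"{prefix}.table.tsv",
        "ms1_bucket": f"{prefix}.buckets.csv",
    }[dialect]
    table = read_table(TableSource(table_path, dialect))
    smd = read_metadata(f"{prefix}.samples.tsv")
    fmd = read_metadata(f"{prefix}.features.tsv")
    matrix, sample_ids, feature_ids = table
    exp = Experiment(
        matrix,
        smd.reindex([str(s) for s in sample_ids]),
        fmd.reindex([str(f) for f in feature_ids]),
        experiment_type=meta.get("experiment_type", "generic"),
        normalized_total=meta.get("normalized_total"),
        history=meta.get("history", []),
    )
    return exp
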