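"""Expression datasets: I/O, gene-ID translation, metric conversion, scores.

The internal orientation is always genes x observations.  Dense delimited
tables (TSV/CSV) and sparse triplet directories in the 10x convention
(Matrix Market matrix + features + barcodes, optionally gzipped) are both
supported on input; score tables are written as TSV.
"""

from __future__ import annotations

import gzip
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from sigcompass.errors import (
    AlignmentError,
    FormatError,
    SigcompassError,
    UnsupportedConversionError,
)

logger = logging.getLogger(__name__)

VALID_METRICS = ("counts", "cpm", "fpkm", "tpm", "log")
VALID_TECHNOLOGIES = ("microarray", "bulk_rnaseq", "scrnaseq", "spatial")
VALID_ID_TYPES = ("symbol", "ensembl", "entrez")


@dataclass
class ExpressionDataset:
    """Gene-by-observation expression matrix with annotations and scores.

    ``matrix`` is a pandas DataFrame indexed by gene id with one column per
    observation.  ``obs_annotations`` and ``scores`` are indexed by
    observation id; ``coordinates`` (spatial only) holds x/y per observation.
    """

    matrix: pd.DataFrame
    metric: str
    technology: str
    id_type: str = "symbol"
    obs_annotations: pd.DataFrame = None
    coordinates: pd.DataFrame | None = None
    scores: pd.DataFrame = None
    log_base_applied: bool = field(default=False, repr=False)

    def __post_init__(self):
        if self.metric not in VALID_METRICS:
            raise FormatError(f"unknown metric {self.metric!r}; valid: {VALID_METRICS}")
        if self.technology not in VALID_TECHNOLOGIES:
            raise FormatError(
                f"unknown technology {self.technology!r}; valid: {VALID_TECHNOLOGIES}"
            )
        if self.id_type not in VALID_ID_TYPES:
            raise FormatError(f"unknown id_type {self.id_type!r}; valid: {VALID_ID_TYPES}")
        if self.matrix.index.duplicated().any():
            dups = sorted(self.matrix.index[self.matrix.index.duplicated()].unique())
            raise FormatError(f"duplicate gene ids: {dups}")
        if self.obs_annotations is None:
            self.obs_annotations = pd.DataFrame(index=self.matrix.columns)
        if self.scores is None:
            self.scores = pd.DataFrame(index=self.matrix.columns)
        if not self.obs_annotations.index.equals(self.matrix.columns):
            raise AlignmentError("obs_annotations index must equal observation ids")
        if self.coordinates is not None and self.technology != "spatial":
            raise FormatError("coordinates are only valid for spatial technology")
        if self.metric == "counts":
            vals = self.matrix.to_numpy()
            if np.nanmin(vals) < 0 if vals.size else False:
                raise FormatError("counts metric requires non-negative entries")

    # -- basic properties ---------------------------------------------

    @property
    def gene_ids(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def obs_ids(self) -> list[str]:
        return list(self.matrix.columns)

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_obs(self) -> int:
        return self.matrix.shape[1]

    def copy(self) -> "ExpressionDataset":
        return replace(
            self,
            matrix=self.matrix.copy(),
            obs_annotations=self.obs_annotations.copy(),
            coordinates=None if self.coordinates is None else self.coordinates.copy(),
            scores=self.scores.copy(),
        )


def _sniff_delimiter(path: Path) -> str:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def read_dense_table(
    path: str | Path,
    orientation: str = "genes_rows",
    metric: str = "counts",
    technology: str = "bulk_rnaseq",
    id_type: str = "symbol",
) -> ExpressionDataset:
    """Read a delimited gene-by-observation (or transposed) table.

    The delimiter is auto-detected among tab and comma.  ``orientation``
    states whether genes are on rows or columns of the file; either way the
    returned dataset is genes x observations.
    """
    path = Path(path)
    if orientation not in ("genes_rows", "genes_cols"):
        raise FormatError(f"unknown orientation {orientation!r}")
    sep = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, index_col=0)
    if orientation == "genes_cols":
        df = df.T
    non_numeric = df.columns[[not pd.api.types.is_numeric_dtype(t) for t in df.dtypes]]
    if len(non_numeric):
        for col in non_numeric:
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            if len(bad):
                raise FormatError(
                    f"non-numeric value {bad.iloc[0]!r} at gene {bad.index[0]!r}, "
                    f"observation {col!r}"
                )
        df = df.apply(pd.to_numeric)
    df = df.astype(float)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ExpressionDataset(matrix=df, metric=metric, technology=technology, id_type=id_type)


def _open_maybe_gz(path: Path):
    return gzip.open(path, "rt") if path.suffix == ".gz" else open(path, encoding="utf-8")


def _find_file(directory: Path, stem_candidates: list[str]) -> Path:
    for stem in stem_candidates:
        for suffix in ("", ".gz"):
            p = directory / (stem + suffix)
            if p.exists():
                return p
    raise FormatError(f"none of {stem_candidates} found in {directory}")


def read_sparse_triplet(
    dir_path: str | Path,
    metric: str = "counts",
    technology: str = "scrnaseq",
    id_type: str = "symbol",
) -> ExpressionDataset:
    """Read a 10x-convention triplet directory (matrix.mtx + features + barcodes).

    An optional ``positions.csv`` (barcode, x, y) is joined by barcode and
    stored as spatial coordinates.
    """
    directory = Path(dir_path)
    mtx = _find_file(directory, ["matrix.mtx"])
    feats = _find_file(directory, ["features.tsv", "genes.tsv"])
    bars = _find_file(directory, ["barcodes.tsv"])

    with _open_maybe_gz(mtx) as fh:
        mat = scipy.io.mmread(fh)
    mat = scipy.sparse.coo_matrix(mat).toarray().astype(float)

    with _open_maybe_gz(feats) as fh:
        feat_rows = [line.rstrip("\n").split("\t") for line in fh if line.strip()]
    gene_ids = [r[1] if id_type == "symbol" and len(r) > 1 else r[0] for r in feat_rows]
    with _open_maybe_gz(bars) as fh:
        barcodes = [line.strip() for line in fh if line.strip()]

    if mat.shape[0] != len(gene_ids):
        raise FormatError(
            f"matrix has {mat.shape[0]} rows but features file lists {len(gene_ids)} genes"
        )
    if mat.shape[1] != len(barcodes):
        raise FormatError(
            f"matrix has {mat.shape[1]} columns but barcodes file lists {len(barcodes)}"
        )

    df = pd.DataFrame(mat, index=gene_ids, columns=barcodes)
    coordinates = None
    try:
        pos = _find_file(directory, ["positions.csv", "positions.tsv"])
    except FormatError:
        pos = None
    if pos is not None:
        sep = "\t" if pos.name.startswith("positions.tsv") else ","
        cdf = pd.read_csv(pos, sep=sep)
        cdf.columns = [c.lower() for c in cdf.columns]
        cdf = cdf.set_index(cdf.columns[0])[["x", "y"]]
        missing = set(barcodes) - set(cdf.index)
        if missing:
            raise FormatError(f"positions file missing barcodes: {sorted(missing)[:5]}")
        coordinates = cdf.loc[barcodes]
        technology = "spatial"
    return ExpressionDataset(
        matrix=df, metric=metric, technology=technology, id_type=id_type,
        coordinates=coordinates,
    )


def translate_gene_ids(
    ds: ExpressionDataset,
    mapping: pd.DataFrame,
    target_id_type: str = "symbol",
    collision_rule: str = "highest_total",
) -> ExpressionDataset:
    """Rename genes via a (from_id, to_id) mapping table.

    Unmapped genes are dropped (count logged).  Many-to-one collisions keep a
    single row per target id according to ``collision_rule``:
    ``highest_total`` keeps the source row with the largest total signal.
    """
    if collision_rule not in ("highest_total", "first"):
        raise SigcompassError(f"unknown collision rule {collision_rule!r}")
    cols = list(mapping.columns[:2])
    m = dict(zip(mapping[cols[0]].astype(str), mapping[cols[1]].astype(str)))
    present = [g for g in ds.gene_ids if g in m]
    if not present:
        raise SigcompassError("no genes mapped: empty intersection with mapping table")
    n_dropped = ds.n_genes - len(present)
    if n_dropped:
        logger.info("translate_gene_ids: dropping %d unmapped genes", n_dropped)

    sub = ds.matrix.loc[present].copy()
    targets = pd.Series([m[g] for g in present], index=sub.index)
    keep_rows: dict[str, str] = {}
    for src, tgt in targets.items():
        if tgt not in keep_rows:
            keep_rows[tgt] = src
        elif collision_rule == "highest_total":
            if sub.loc[src].sum() > sub.loc[keep_rows[tgt]].sum():
                keep_rows[tgt] = src
    n_collided = len(present) - len(keep_rows)
    if n_collided:
        logger.info("translate_gene_ids: %d rows collapsed by many-to-one collisions", n_collided)
    out = sub.loc[list(keep_rows.values())]
    out.index = list(keep_rows.keys())
    return replace(ds.copy(), matrix=out, id_type=target_id_type)


#: defined conversion paths: (source, target) -> converter
def _counts_to_cpm(df: pd.DataFrame, gene_lengths=None) -> pd.DataFrame:
    totals = df.sum(axis=0)
    zero = totals == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} all-zero observation(s); left all-zero in CPM", stacklevel=3
        )
    safe = totals.replace(0, 1.0)
    return df.div(safe, axis=1) * 1e6


def _fpkm_to_tpm(df: pd.DataFrame, gene_lengths=None) -> pd.DataFrame:
    totals = df.sum(axis=0)
    safe = totals.replace(0, 1.0)
    return df.div(safe, axis=1) * 1e6


def _counts_to_fpkm(df: pd.DataFrame, gene_lengths=None) -> pd.DataFrame:
    if gene_lengths is None:
        raise UnsupportedConversionError("counts->fpkm requires gene lengths")
    lengths = pd.Series(gene_lengths).reindex(df.index)
    if lengths.isna().any():
        raise UnsupportedConversionError("gene lengths missing for some genes")
    cpm = _counts_to_cpm(df)
    return cpm.div(lengths / 1e3, axis=0)


def transform_metric(
    ds: ExpressionDataset,
    target: str,
    gene_lengths=None,
    log_fn=None,
) -> ExpressionDataset:
    """Convert a dataset between expression metrics.

    Defined paths: counts->cpm, counts->fpkm (with gene lengths), fpkm->tpm,
    and any->log (log2(x+1) by default).  Conversions are per-observation and
    leave zero entries zero.  Undefined paths raise.
    """
    if target not in VALID_METRICS:
        raise UnsupportedConversionError(f"unknown target metric {target!r}")
    if ds.metric == target:
        return ds.copy()
    if target == "log":
        fn = log_fn or (lambda x: np.log2(x + 1.0))
        out = ds.copy()
        out.matrix = pd.DataFrame(
            fn(ds.matrix.to_numpy()), index=ds.matrix.index, columns=ds.matrix.columns
        )
        out.metric = "log"
        out.log_base_applied = True
        return out
    converters = {
        ("counts", "cpm"): _counts_to_cpm,
        ("counts", "fpkm"): _counts_to_fpkm,
        ("fpkm", "tpm"): _fpkm_to_tpm,
    }
    key = (ds.metric, target)
    if key not in converters:
        raise UnsupportedConversionError(
            f"no defined conversion path {ds.metric} -> {target}"
        )
    out = ds.copy()
    out.matrix = converters[key](ds.matrix, gene_lengths)
    out.metric = target
    return out


def attach_scores(ds: ExpressionDataset, result) -> ExpressionDataset:
    """Attach a ScoreResult's value column(s) to the dataset's score table.

    Re-attaching a signature overwrites its columns with a warning.
    """
    values = result.values if isinstance(result.values, pd.DataFrame) else result.values.to_frame(
        result.signature_name
    )
    unknown = set(values.index) - set(ds.obs_ids)
    if unknown:
        raise AlignmentError(
            f"score vector contains unknown observation ids: {sorted(unknown)[:5]}"
        )
    out = ds.copy()
    for col in values.columns:
        if col in out.scores.columns:
            warnings.warn(f"score column {col!r} recomputed; overwriting", stacklevel=2)
            out.scores = out.scores.drop(columns=[col])
        out.scores[col] = values[col].reindex(out.scores.index)
    return out


def write_scores(ds: ExpressionDataset, path: str | Path) -> None:
    """Write observation id, annotations and score columns as TSV.

    Column order is deterministic: annotations in their stored order, then
    score columns lexicographically.  Floats use 6 significant digits.
    """
    if ds.scores.shape[1] == 0:
        raise SigcompassError("dataset has no score columns to write")
    out = pd.concat(
        [ds.obs_annotations, ds.scores[sorted(ds.scores.columns)]], axis=1
    )
    out.index.name = "observation_id"
    out.to_csv(path, sep="\t", float_format="%.6g")
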