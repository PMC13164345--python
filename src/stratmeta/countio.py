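"""Readers, writers and validated containers for counts, sample metadata and gene sets.

Canonical interchange is TSV (genes as rows, header = sample ids); MatrixMarket
is supported for sparse inputs with ``.rownames`` / ``.colnames`` sidecar files.
Gene and sample identifiers are opaque strings; no identifier mapping is done.
Missing values are never allowed in count matrices — files fail fast with the
offending cell named.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse


class FormatError(ValueError):
    """Raised when an input file violates the format contract."""


def _check_unique(ids: Iterable[str], what: str) -> None:
    ids = pd.Index(ids)
    if ids.has_duplicates:
        dups = ids[ids.duplicated()].unique().tolist()
        raise FormatError(f"duplicate {what} ids: {dups[:5]}")


@dataclass
class CountMatrix:
    """Raw gene-by-sample counts: nonnegative integers, unique ids on both axes.

    ``counts`` is a pandas DataFrame with gene ids as index and sample ids as
    columns. Validation runs on construction; duplicates are an error (never
    collapsed by summation).
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        _check_unique(df.index, "gene")
        _check_unique(df.columns, "sample")
        if df.shape[1] < 2:
            raise FormatError("a count matrix needs at least 2 samples")
        values = df.to_numpy()
        if values.dtype.kind not in "iu":
            bad = np.where(~np.isfinite(values.astype(float)) |
                           (values.astype(float) != np.floor(values.astype(float))))
            if bad[0].size:
                g, s = df.index[bad[0][0]], df.columns[bad[1][0]]
                raise FormatError(f"non-integer or missing count at gene {g!r}, sample {s!r}")
            df = df.astype(np.int64)
        neg = np.where(df.to_numpy() < 0)
        if neg[0].size:
            g, s = df.index[neg[0][0]], df.columns[neg[1][0]]
            raise FormatError(f"negative count at gene {g!r}, sample {s!r}")
        df = df.astype(np.int64)
        df.index = df.index.rename("gene")
        df.columns = df.columns.rename(None)
        self.counts = df

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def subset_samples(self, sample_ids: Iterable[str]) -> "CountMatrix":
        return CountMatrix(self.counts.loc[:, list(sample_ids)])


@dataclass
class SampleTable:
    """Per-sample metadata: treatment label, optional cluster and covariate scores.

    Wraps a DataFrame indexed by sample id with at least a ``treatment`` column;
    an optional integer ``cluster`` column and any number of numeric covariate
    columns (e.g. PC1..PCn scores) may be present.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.table.index, "sample")
        if "treatment" not in self.table.columns:
            raise FormatError("sample table requires a 'treatment' column")
        self.table.index = self.table.index.rename("sample")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def treatment(self) -> pd.Series:
        return self.table["treatment"]

    def samples_with(self, treatment: str) -> list[str]:
        return list(self.table.index[self.table["treatment"] == treatment])

    def check_matches(self, m: CountMatrix) -> None:
        if set(self.table.index) != set(m.sample_ids):
            missing = set(m.sample_ids) - set(self.table.index)
            extra = set(self.table.index) - set(m.sample_ids)
            raise FormatError(
                f"sample table does not match count matrix "
                f"(missing {sorted(missing)[:5]}, extra {sorted(extra)[:5]})")


@dataclass
class GeneSetCollection:
    """Mapping of term id -> (description, set of member gene ids)."""

    sets: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, term: str) -> bool:
        return term in self.sets

    def members(self, term: str) -> frozenset[str]:
        return self.sets[term][1]

    def description(self, term: str) -> str:
        return self.sets[term][0]

    def term_ids(self) -> list[str]:
        return list(self.sets)


# ---------------------------------------------------------------------------
# header comments


def _write_header(handle: io.TextIOBase, header_comment: str | None) -> None:
    if header_comment:
        for line in header_comment.splitlines():
            handle.write(f"# {line}\n")


# ---------------------------------------------------------------------------
# count matrices


def read_counts(path: str | os.PathLike, format: str = "tsv") -> CountMatrix:
    """Read a count matrix from TSV or MatrixMarket (with id sidecars)."""
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        return CountMatrix(df)
    if format == "mtx":
        mat = scipy.io.mmread(os.fspath(path))
        genes = _read_id_sidecar(f"{os.fspath(path)}.rownames")
        samples = _read_id_sidecar(f"{os.fspath(path)}.colnames")
        dense = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat)
        if dense.shape != (len(genes), len(samples)):
            raise FormatError(
                f"MTX shape {dense.shape} does not match sidecars "
                f"({len(genes)} genes, {len(samples)} samples)")
        return CountMatrix(pd.DataFrame(dense, index=genes, columns=samples))
    raise ValueError(f"unknown count format {format!r}")


def write_counts(m: CountMatrix, path: str | os.PathLike, format: str = "tsv",
                 header_comment: str | None = None) -> None:
    if format == "tsv":
        with open(path, "w") as fh:
            _write_header(fh, header_comment)
            m.counts.to_csv(fh, sep="\t", index_label="gene")
        return
    if format == "mtx":
        sparse = scipy.sparse.csr_matrix(m.counts.to_numpy())
        scipy.io.mmwrite(os.fspath(path), sparse)
        _write_id_sidecar(f"{os.fspath(path)}.rownames", m.gene_ids)
        _write_id_sidecar(f"{os.fspath(path)}.colnames", m.sample_ids)
        return
    raise ValueError(f"unknown count format {format!r}")


def _read_id_sidecar(path: str) -> list[str]:
    with open(path) as fh:
        return [line.rstrip("\n") for line in fh if line.strip()]


def _write_id_sidecar(path: str, ids: list[str]) -> None:
    with open(path, "w") as fh:
        for i in ids:
            fh.write(f"{i}\n")


# ---------------------------------------------------------------------------
# sample tables and generic result tables


def read_samples(path: str | os.PathLike) -> SampleTable:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index = df.index.astype(str)
    return SampleTable(df)


def write_samples(s: SampleTable, path: str | os.PathLike,
                  header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        _write_header(fh, header_comment)
        s.table.to_csv(fh, sep="\t", index_label="sample")


def read_table(path: str | os.PathLike, index_col: int | None = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col, comment="#")


def write_table(df: pd.DataFrame, path: str | os.PathLike,
                header_comment: str | None = None,
                index_label: str = "gene") -> None:
    with open(path, "w") as fh:
        _write_header(fh, header_comment)
        df.to_csv(fh, sep="\t", index_label=index_label)


# ---------------------------------------------------------------------------
# gene sets (GMT)


def read_gmt(path: str | os.PathLike) -> GeneSetCollection:
    """Parse a GMT file: per line ``term<TAB>description<TAB>member...``.

    Blank member fields (e.g. from trailing tabs) are dropped; a line with
    fewer than three fields is an error reported with its line number.
    """
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has {len(fields)} fields, need >=3")
            term, desc = fields[0], fields[1]
            members = frozenset(f for f in fields[2:] if f.strip())
            if not members:
                raise FormatError(f"{path}:{lineno}: gene set {term!r} has no members")
            if term in sets:
                raise FormatError(f"{path}:{lineno}: duplicate term id {term!r}")
            sets[term] = (desc, members)
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for term, (desc, members) in collection.sets.items():
            fh.write("\t".join([term, desc, *sorted(members)]) + "\n")


def log_transform(m: CountMatrix, size_factors: Mapping[str, float] | pd.Series) -> pd.DataFrame:
    """log2(count / size_factor + 1), the exploratory transform used upstream
    of variable-gene selection, PCA and clustering."""
    sf = pd.Series(size_factors).reindex(m.sample_ids)
    if sf.isna().any():
        missing = list(sf.index[sf.isna()])
        raise ValueError(f"no size factor for samples {missing[:5]}")
    if (sf <= 0).any():
        bad = list(sf.index[sf <= 0])
        raise ValueError(f"nonpositive size factor for samples {bad[:5]}")
    return np.log2(m.counts.div(sf, axis=1) + 1.0)
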