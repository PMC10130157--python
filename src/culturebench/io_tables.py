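"""Readers, writers and validated in-memory containers for all tabular inputs.

Canonical orientation is samples as rows, taxa (or pathways) as columns.
All text formats are TSV: tab separator, '.' decimal, UTF-8, no quoting of
identifiers. BIOM v1 (JSON) feature tables are accepted through the same
reader interface.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("culturebench")

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")
ROLES = ("feces", "culture", "control")

METADATA_COLUMNS = ("sample_id", "donor", "medium", "time_h", "replicate", "role")


class TableValidationError(ValueError):
    """A tabular input violated a structural invariant."""


def _check_unique(labels, what: str) -> None:
    seen = pd.Index(labels)
    if seen.has_duplicates:
        dupes = seen[seen.duplicated()].unique().tolist()
        raise TableValidationError(f"duplicate {what} ids: {dupes}")


@dataclass
class FeatureTable:
    """Samples x taxa count table, the central object every metric consumes.

    ``data`` holds non-negative abundances with sample ids as the index and
    taxon ids as the columns. Samples whose row is entirely zero are dropped
    at validation time (they carry no compositional information).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.size == 0:
            raise TableValidationError("empty feature table")
        _check_unique(self.data.index, "sample")
        _check_unique(self.data.columns, "taxon")
        values = self.data.to_numpy(dtype=float)
        if np.isnan(values).any():
            r, c = np.argwhere(np.isnan(values))[0]
            raise TableValidationError(
                f"missing value at sample {self.data.index[r]!r}, "
                f"taxon {self.data.columns[c]!r}"
            )
        if (values < 0).any():
            r, c = np.argwhere(values < 0)[0]
            raise TableValidationError(
                f"negative count {values[r, c]} at sample "
                f"{self.data.index[r]!r}, taxon {self.data.columns[c]!r}"
            )
        empty = values.sum(axis=1) == 0
        if empty.any():
            dropped = self.data.index[empty].tolist()
            logger.warning("dropping %d all-zero sample(s): %s", len(dropped), dropped)
            self.data = self.data.loc[~empty]
        if self.data.shape[0] == 0:
            raise TableValidationError("no sample with a nonzero entry")

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list:
        return list(self.data.columns)

    @property
    def counts(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def __eq__(self, other) -> bool:
        return isinstance(other, FeatureTable) and self.data.equals(other.data)


@dataclass
class Taxonomy:
    """taxon_id -> lineage map over the ranks kingdom..genus.

    Missing or empty rank labels are mapped to the sentinel
    ``unclassified_<rank>`` so downstream aggregation never drops counts.
    """

    lineages: pd.DataFrame  # index taxon_id, columns RANKS

    def __post_init__(self) -> None:
        missing = [r for r in RANKS if r not in self.lineages.columns]
        if missing:
            raise TableValidationError(f"taxonomy missing rank column(s): {missing}")
        _check_unique(self.lineages.index, "taxon")
        self.lineages = self.lineages[list(RANKS)].copy()
        for rank in RANKS:
            col = self.lineages[rank].astype("string")
            blank = col.isna() | (col.str.strip() == "")
            if blank.any():
                logger.info(
                    "taxonomy: %d taxa unassigned at rank %s", int(blank.sum()), rank
                )
            self.lineages[rank] = col.where(~blank, f"unclassified_{rank}").astype(str)

    def label(self, taxon_id: str, rank: str) -> str:
        if rank not in RANKS:
            raise TableValidationError(f"unknown rank {rank!r}; expected one of {RANKS}")
        if taxon_id not in self.lineages.index:
            return f"unclassified_{rank}"
        return str(self.lineages.at[taxon_id, rank])


@dataclass
class SampleMetadata:
    """Per-sample experimental factors: donor, medium, time, replicate, role."""

    data: pd.DataFrame  # index sample_id

    def __post_init__(self) -> None:
        missing = [c for c in METADATA_COLUMNS[1:] if c not in self.data.columns]
        if missing:
            raise TableValidationError(f"metadata missing column(s): {missing}")
        _check_unique(self.data.index, "sample")
        bad_roles = sorted(set(self.data["role"]) - set(ROLES))
        if bad_roles:
            raise TableValidationError(
                f"unknown role(s) {bad_roles}; allowed roles are {list(ROLES)}"
            )
        feces = self.data["role"] == "feces"
        has_medium = self.data["medium"].notna() & (
            self.data["medium"].astype(str).str.strip() != ""
        )
        offending = self.data.index[feces & has_medium].tolist()
        if offending:
            logger.warning(
                "feces sample(s) %s carry a medium label; ignoring it", offending
            )
        self.data["medium"] = self.data["medium"].where(has_medium & ~feces, pd.NA)
        self.data["time_h"] = pd.to_numeric(self.data["time_h"])

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    def factor(self, name: str) -> pd.Series:
        if name not in self.data.columns:
            raise TableValidationError(f"unknown metadata factor {name!r}")
        return self.data[name]

    def subset(self, sample_ids) -> "SampleMetadata":
        return SampleMetadata(self.data.loc[list(sample_ids)].copy())


@dataclass
class PathwayTable:
    """Samples x functional-category abundance table (same discipline as counts)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        inner = FeatureTable(self.data)  # reuse count-table validation
        self.data = inner.data

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise dissimilarities with a metric tag."""

    ids: list
    values: np.ndarray
    metric: str = ""
    _tol: float = field(default=1e-10, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise TableValidationError(
                f"distance matrix shape {self.values.shape} does not match {n} ids"
            )
        if (self.values < -self._tol).any():
            raise TableValidationError("negative dissimilarity")
        if np.abs(np.diag(self.values)).max(initial=0.0) > self._tol:
            raise TableValidationError("nonzero diagonal")
        if np.abs(self.values - self.values.T).max(initial=0.0) > 1e-8:
            raise TableValidationError("asymmetric distance matrix")
        self.values = np.clip((self.values + self.values.T) / 2.0, 0.0, None)
        np.fill_diagonal(self.values, 0.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


# ---------------------------------------------------------------------------
# readers / writers


def _read_tsv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def _read_biom_v1(path) -> pd.DataFrame:
    """Minimal BIOM v1 (JSON) parser covering dense and sparse layouts.

    BIOM v1 stores observations (taxa) as rows; we transpose into the
    canonical samples-as-rows orientation.
    """
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    taxa = [r["id"] for r in doc["rows"]]
    samples = [c["id"] for c in doc["columns"]]
    mat = np.zeros((len(taxa), len(samples)))
    if doc.get("matrix_type") == "sparse":
        for i, j, v in doc["data"]:
            mat[int(i), int(j)] = v
    else:
        mat[:] = np.asarray(doc["data"], dtype=float)
    return pd.DataFrame(mat.T, index=samples, columns=taxa)


def read_feature_table(path, format: str = "tsv", sample_ids=None) -> FeatureTable:
    """Read a feature table from TSV or BIOM v1 JSON.

    ``sample_ids``, when given, disambiguates orientation: if the file's
    columns (not rows) match the known sample ids the table is transposed.
    Orientation is only auto-corrected when unambiguous, otherwise the file
    is taken at face value in canonical orientation.
    """
    if format == "biom":
        return FeatureTable(_read_biom_v1(path))
    if format != "tsv":
        raise ValueError(f"unknown feature-table format {format!r}")
    df = _read_tsv(path)
    if sample_ids is not None:
        known = set(map(str, sample_ids))
        rows_match = len(known & set(df.index)) > 0
        cols_match = len(known & set(df.columns)) > 0
        if cols_match and not rows_match:
            logger.info("feature table %s transposed into canonical orientation", path)
            df = df.T
        elif rows_match and cols_match:
            raise TableValidationError(
                "ambiguous orientation: sample ids appear in both rows and columns"
            )
    return FeatureTable(df.astype(float))


def write_feature_table(table: FeatureTable, path) -> None:
    df = table.data
    # preserve integer counts bit-exactly on round-trip
    if np.allclose(df.to_numpy() % 1, 0):
        df = df.astype(np.int64)
    df.to_csv(path, sep="\t", index_label="sample_id")


def read_metadata(path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns:
        raise TableValidationError("metadata missing column(s): ['sample_id']")
    df = df.set_index("sample_id")
    df.index = df.index.astype(str)
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path) -> None:
    meta.data.to_csv(path, sep="\t", index_label="sample_id")


def read_taxonomy(path) -> Taxonomy:
    return Taxonomy(_read_tsv(path))


def write_taxonomy(tax: Taxonomy, path) -> None:
    tax.lineages.to_csv(path, sep="\t", index_label="taxon_id")


def read_pathway_table(path) -> PathwayTable:
    return PathwayTable(_read_tsv(path).astype(float))


def write_pathway_table(table: PathwayTable, path) -> None:
    table.data.to_csv(path, sep="\t", index_label="sample_id")


def write_distance_matrix(d: DistanceMatrix, path) -> None:
    d.to_frame().to_csv(path, sep="\t", index_label="sample_id")


def read_distance_matrix(path, metric: str = "") -> DistanceMatrix:
    df = _read_tsv(path).astype(float)
    if list(df.index) != list(df.columns):
        raise TableValidationError("distance matrix row/column ids differ")
    return DistanceMatrix(list(df.index), df.to_numpy(), metric=metric)


def align(table: FeatureTable, meta: SampleMetadata) -> tuple[FeatureTable, SampleMetadata]:
    """Restrict table and metadata to their shared samples, in table order.

    Samples present on only one side are dropped (counted in the log);
    zero overlap is a hard error.
    """
    shared = [s for s in table.sample_ids if s in set(meta.sample_ids)]
    if not shared:
        raise TableValidationError("no overlapping samples between table and metadata")
    n_t = len(table.sample_ids) - len(shared)
    n_m = len(meta.sample_ids) - len(shared)
    if n_t or n_m:
        logger.warning("align: dropped %d table + %d metadata samples", n_t, n_m)
    return (
        FeatureTable(table.data.loc[shared].copy()),
        SampleMetadata(meta.data.loc[shared].copy()),
    )
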