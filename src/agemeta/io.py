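"""Domain types, TSV/GMT readers and writers, and fold-change quantile normalisation.

The atomic unit of the analysis is a differential-expression (DE) signature:
one log2 fold change and p-value per gene for a single dataset (one study x
genotype x tissue x sex x age combination). Datasets are linked to studies and
interventions through :class:`DatasetMetadata`, and gene sets (GO-term
stand-ins) are exchanged in the standard GMT format.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    DataError,
    EmptyInputError,
    FormatError,
    MetadataError,
    ParseError,
)

logger = logging.getLogger(__name__)

#: Closed vocabulary for the lifespan-effect label of an intervention.
LIFESPAN_EFFECTS = ("long", "short", "null", "candidate", "ageing")

DE_COLUMNS = ("gene_id", "log2fc", "pvalue")
METADATA_COLUMNS = (
    "dataset_id",
    "study_id",
    "intervention_id",
    "tissue",
    "sex",
    "age",
    "lifespan_effect",
)


@dataclass(frozen=True)
class DifferentialExpressionTable:
    """Per-gene log2 fold changes and p-values for one dataset.

    Parameters
    ----------
    dataset_id : str
        Unique identifier of the dataset the signature was derived from.
    data : pandas.DataFrame
        Columns ``gene_id``, ``log2fc``, ``pvalue`` and optionally ``padj``;
        one row per gene, gene ids unique, p-values in (0, 1], fold changes
        finite.
    """

    dataset_id: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in DE_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"DE table {self.dataset_id!r} lacks columns {missing}")
        if len(df) == 0:
            raise EmptyInputError(f"DE table {self.dataset_id!r} has no records")
        if df["gene_id"].duplicated().any():
            raise DataError(f"duplicate gene ids in DE table {self.dataset_id!r}")
        p = df["pvalue"].to_numpy(float)
        if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
            raise DataError(f"p-values outside (0, 1] in DE table {self.dataset_id!r}")
        if np.any(~np.isfinite(df["log2fc"].to_numpy(float))):
            raise DataError(f"non-finite log2fc in DE table {self.dataset_id!r}")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def genes(self) -> pd.Index:
        return pd.Index(self.data["gene_id"])

    def log2fc(self) -> pd.Series:
        """Fold changes indexed by gene id."""
        return pd.Series(
            self.data["log2fc"].to_numpy(float),
            index=self.data["gene_id"].to_numpy(),
            name=self.dataset_id,
        )

    def pvalues(self) -> pd.Series:
        return pd.Series(
            self.data["pvalue"].to_numpy(float),
            index=self.data["gene_id"].to_numpy(),
            name=self.dataset_id,
        )


@dataclass(frozen=True)
class DatasetMetadata:
    """Maps one dataset to its study, intervention, tissue and lifespan group."""

    dataset_id: str
    study_id: str
    intervention_id: str
    tissue: str
    lifespan_effect: str
    sex: str | None = None
    age: str | None = None

    def __post_init__(self) -> None:
        if self.lifespan_effect not in LIFESPAN_EFFECTS:
            raise MetadataError(
                f"dataset {self.dataset_id!r}: lifespan_effect "
                f"{self.lifespan_effect!r} not in {LIFESPAN_EFFECTS}"
            )


@dataclass(frozen=True)
class GeneSet:
    term_id: str
    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise DataError(f"gene set {self.term_id!r} is empty")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class GeneSetCatalogue:
    """A named collection of gene sets; sets may overlap."""

    terms: list[GeneSet]
    _index: dict[str, GeneSet] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._index = {t.term_id: t for t in self.terms}
        if len(self._index) != len(self.terms):
            raise DataError("duplicate term_id in catalogue")

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self._index

    def __getitem__(self, term_id: str) -> GeneSet:
        return self._index[term_id]

    def __iter__(self):
        return iter(self.terms)

    @property
    def term_ids(self) -> list[str]:
        return [t.term_id for t in self.terms]

    def subset(self, term_ids: Iterable[str]) -> "GeneSetCatalogue":
        wanted = set(term_ids)
        return GeneSetCatalogue([t for t in self.terms if t.term_id in wanted])


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_de_table(path, dataset_id: str | None = None) -> DifferentialExpressionTable:
    """Read one differential-expression table from TSV.

    The file must carry header columns ``gene_id``, ``log2fc``, ``pvalue`` and
    may carry ``padj``. Duplicate gene ids are collapsed by keeping the record
    with the smallest p-value (a warning is logged).
    """
    path = str(path)
    if dataset_id is None:
        import os

        dataset_id = os.path.splitext(os.path.basename(path))[0]
    try:
        raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False,
                          na_values=[""])
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path}: file is empty") from None
    missing = [c for c in DE_COLUMNS if c not in raw.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    if len(raw) == 0:
        raise EmptyInputError(f"{path}: no data rows")

    numeric_cols = ["log2fc", "pvalue"] + (["padj"] if "padj" in raw.columns else [])
    parsed = {}
    for col in numeric_cols:
        values = pd.to_numeric(raw[col], errors="coerce")
        bad = values.isna() & raw[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
            raise ParseError(
                f"{path}: non-numeric {col} value {raw[col][bad.idxmax()]!r} on line {line}"
            )
        parsed[col] = values.to_numpy(float)

    df = pd.DataFrame({"gene_id": raw["gene_id"].to_numpy()})
    for col in numeric_cols:
        df[col] = parsed[col]

    dup = df["gene_id"].duplicated(keep=False)
    if dup.any():
        n_dup = df.loc[dup, "gene_id"].nunique()
        logger.warning(
            "%s: %d gene id(s) duplicated; keeping the record with the smallest p-value",
            path,
            n_dup,
        )
        df = (
            df.sort_values(["gene_id", "pvalue"], kind="mergesort")
            .drop_duplicates("gene_id", keep="first")
            .sort_index()
            .reset_index(drop=True)
        )
    return DifferentialExpressionTable(dataset_id=dataset_id, data=df)


def write_de_table(table: DifferentialExpressionTable, path) -> None:
    table.data.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_metadata(path) -> dict[str, DatasetMetadata]:
    """Read dataset metadata TSV into a mapping dataset_id -> DatasetMetadata."""
    df = pd.read_csv(str(path), sep="\t", dtype=str, keep_default_na=False,
                     na_values=[""])
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing metadata column(s) {missing}")
    out: dict[str, DatasetMetadata] = {}
    for _, row in df.iterrows():
        md = DatasetMetadata(
            dataset_id=row["dataset_id"],
            study_id=row["study_id"],
            intervention_id=row["intervention_id"],
            tissue=row["tissue"],
            lifespan_effect=row["lifespan_effect"],
            sex=None if pd.isna(row["sex"]) else row["sex"],
            age=None if pd.isna(row["age"]) else row["age"],
        )
        if md.dataset_id in out:
            raise MetadataError(f"{path}: duplicate dataset_id {md.dataset_id!r}")
        out[md.dataset_id] = md
    return out


def write_metadata(metadata: Mapping[str, DatasetMetadata] | Iterable[DatasetMetadata], path) -> None:
    records = metadata.values() if isinstance(metadata, Mapping) else metadata
    rows = [
        {
            "dataset_id": m.dataset_id,
            "study_id": m.study_id,
            "intervention_id": m.intervention_id,
            "tissue": m.tissue,
            "sex": "" if m.sex is None else m.sex,
            "age": "" if m.age is None else m.age,
            "lifespan_effect": m.lifespan_effect,
        }
        for m in records
    ]
    pd.DataFrame(rows, columns=list(METADATA_COLUMNS)).to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )


def read_gmt(path) -> GeneSetCatalogue:
    """Read a gene-set catalogue in GMT format.

    Each line is ``term_id<TAB>description<TAB>gene1<TAB>gene2...``; duplicate
    genes within a line are deduplicated, duplicate term ids are an error.
    """
    terms: list[GeneSet] = []
    seen: set[str] = set()
    with open(str(path), encoding="utf-8") as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: line {i} has fewer than 3 fields")
            term_id, name = fields[0], fields[1]
            if term_id in seen:
                raise FormatError(f"{path}: duplicate term_id {term_id!r} on line {i}")
            seen.add(term_id)
            terms.append(GeneSet(term_id, name, frozenset(fields[2:])))
    if not terms:
        raise EmptyInputError(f"{path}: no gene sets")
    return GeneSetCatalogue(terms)


def write_gmt(catalogue: GeneSetCatalogue, path) -> None:
    with open(str(path), "w", encoding="utf-8", newline="\n") as fh:
        for t in catalogue:
            genes = "\t".join(sorted(t.genes))
            fh.write(f"{t.term_id}\t{t.name}\t{genes}\n")


# ---------------------------------------------------------------------------
# fold-change matrix and quantile normalisation
# ---------------------------------------------------------------------------

def fold_change_matrix(tables: Sequence[DifferentialExpressionTable]) -> pd.DataFrame:
    """Assemble a genes x datasets log2FC matrix over the shared gene set."""
    if not tables:
        raise EmptyInputError("no tables supplied")
    ids = [t.dataset_id for t in tables]
    if len(set(ids)) != len(ids):
        raise DataError("duplicate dataset ids among tables")
    columns = [t.log2fc() for t in tables]
    shared = columns[0].index
    for col in columns[1:]:
        shared = shared.intersection(col.index)
    if len(shared) == 0:
        raise DataError("no genes shared across all datasets")
    shared = shared.sort_values()
    return pd.DataFrame({c.name: c.loc[shared] for c in columns})


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalise columns so each shares the same value distribution.

    The reference distribution is the vector of row means of the column-wise
    sorted input; tied values within a column receive the mean of the reference
    values their rank span covers. Labels are preserved.
    """
    values = matrix.to_numpy(dtype=float)
    if values.size == 0:
        raise EmptyInputError("empty matrix")
    if np.isnan(values).any():
        raise DataError("missing values in fold-change matrix")
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    n = values.shape[0]
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty(n)
        assigned[order] = reference
        # ties: average the reference values spanned by each tied block
        s = pd.Series(assigned)
        out[:, j] = s.groupby(col).transform("mean").to_numpy()
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
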