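"""Core containers and tab-separated I/O.

Three containers travel through the whole pipeline:

``ExpressionMatrix``
    A genes x samples table of non-negative expression values plus a
    per-sample metadata table (tissue, genotype, condition).
``LabelSet``
    Gene labels, +1 for disease-associated and -1 for non-disease.
    Coverage may be partial; unlabeled genes are carried through scoring
    and ranking but excluded from training and metric computation.
``RankedList``
    Genes ordered by a score, descending, with deterministic
    lexicographic tie-breaking on gene id.

All files are tab-separated UTF-8 text with a mandatory header row and
"." as the decimal separator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConsistencyError,
    ContractError,
    DegenerateInputError,
    DomainError,
    FormatError,
)

logger = logging.getLogger(__name__)

CONDITIONS = ("normal", "case")
METADATA_COLUMNS = ("tissue", "genotype", "condition")


# ---------------------------------------------------------------------------
# ExpressionMatrix
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with aligned sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with one column per sample id.
        All entries must be finite and >= 0.
    metadata
        DataFrame indexed by sample id with columns ``tissue``,
        ``genotype`` and ``condition`` ("normal" or "case"), one row per
        sample, in the same order as the columns of ``values``.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants ---------------------------------------------------------

    def validate(self) -> None:
        v, m = self.values, self.metadata
        if v.index.has_duplicates:
            dup = v.index[v.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene ids: {dup[:5]}")
        if v.columns.has_duplicates:
            dup = v.columns[v.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dup[:5]}")
        arr = v.to_numpy(dtype=float, copy=False)
        if arr.size and not np.isfinite(arr).all():
            raise DomainError("expression matrix contains non-finite values")
        if arr.size and (arr < 0).any():
            raise DomainError("expression values must be >= 0")
        missing = [s for s in v.columns if s not in m.index]
        if missing:
            raise ConsistencyError(
                f"samples present in matrix but absent from metadata: {missing[:5]}"
            )
        if m.index.has_duplicates:
            dup = m.index[m.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate metadata rows for samples: {dup[:5]}")
        for col in METADATA_COLUMNS:
            if col not in m.columns:
                raise FormatError(f"metadata lacks required column '{col}'")
        bad = set(m["condition"]) - set(CONDITIONS)
        if bad:
            raise FormatError(f"invalid condition values: {sorted(bad)}")
        # align metadata row order to matrix column order, dropping extras
        extra = [s for s in m.index if s not in set(v.columns)]
        if extra:
            logger.warning("dropping %d metadata rows without matrix columns", len(extra))
        self.metadata = m.loc[list(v.columns)]
        # canonical index names so round trips are identities
        self.values.index.name = "gene_id"
        self.values.columns.name = None
        self.metadata.index.name = "sample_id"

    # -- views --------------------------------------------------------------

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def tissues(self) -> list[str]:
        """Tissue names in order of first appearance in the metadata."""
        return list(dict.fromkeys(self.metadata["tissue"]))

    def samples_where(
        self,
        tissue: str | None = None,
        condition: str | None = None,
        genotype: str | None = None,
    ) -> list[str]:
        """Sample ids matching every given metadata predicate, in matrix order."""
        mask = pd.Series(True, index=self.metadata.index)
        if tissue is not None:
            mask &= self.metadata["tissue"] == tissue
        if condition is not None:
            mask &= self.metadata["condition"] == condition
        if genotype is not None:
            mask &= self.metadata["genotype"] == genotype
        return list(self.metadata.index[mask])

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        genes = list(genes)
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise ContractError(f"unknown gene ids: {missing[:5]}")
        return ExpressionMatrix(self.values.loc[genes].copy(), self.metadata.copy())

    def subset_samples(self, samples: Iterable[str]) -> "ExpressionMatrix":
        samples = [s for s in self.sample_ids if s in set(samples)]
        return ExpressionMatrix(self.values[samples].copy(), self.metadata.loc[samples].copy())


def check_genotype_condition(
    expr: ExpressionMatrix, normal_genotypes: Sequence[str] | None = None
) -> str | None:
    """Verify that condition is a function of genotype.

    When ``normal_genotypes`` is None the mapping is inferred: exactly one
    genotype must carry condition "normal" and every sample of every
    genotype must agree with the mapping.  Returns the normal genotype
    (or None when a list was supplied).
    """
    m = expr.metadata
    per_geno = m.groupby("genotype", sort=False)["condition"].unique()
    mixed = [g for g, conds in per_geno.items() if len(conds) > 1]
    if mixed:
        raise ConsistencyError(f"genotypes with mixed conditions: {mixed}")
    normals = [g for g, conds in per_geno.items() if conds[0] == "normal"]
    if normal_genotypes is not None:
        expected = set(normal_genotypes)
        if set(normals) != expected:
            raise ConsistencyError(
                f"normal genotypes {sorted(normals)} do not match declared {sorted(expected)}"
            )
        return None
    if len(normals) != 1:
        raise ConsistencyError(
            f"expected exactly one normal genotype, found {sorted(normals)}"
        )
    return normals[0]


# ---------------------------------------------------------------------------
# LabelSet
# ---------------------------------------------------------------------------

@dataclass
class LabelSet:
    """Partial gene labels: +1 disease-associated, -1 non-disease."""

    labels: pd.Series  # index: gene_id, values in {+1, -1}

    def __post_init__(self) -> None:
        s = self.labels
        if s.index.has_duplicates:
            dup = s.index[s.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene ids in labels: {dup[:5]}")
        vals = set(pd.unique(s)) if len(s) else set()
        if vals - {1, -1}:
            raise FormatError(f"labels must be +1 or -1, got {sorted(vals - {1, -1})}")
        self.labels = s.astype(int)
        self.labels.index.name = "gene_id"

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.labels.index)

    @property
    def n_pos(self) -> int:
        return int((self.labels == 1).sum())

    @property
    def n_neg(self) -> int:
        return int((self.labels == -1).sum())

    def require_both_classes(self) -> None:
        if self.n_pos == 0 or self.n_neg == 0:
            raise DegenerateInputError(
                f"both classes required, got {self.n_pos} positive / {self.n_neg} negative"
            )

    def restrict_to(self, genes: Iterable[str]) -> "LabelSet":
        """Labels for the given genes only (silently drops the rest)."""
        keep = [g for g in self.labels.index if g in set(genes)]
        return LabelSet(self.labels.loc[keep].copy())

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, int]) -> "LabelSet":
        return cls(pd.Series(mapping, dtype=int))


# ---------------------------------------------------------------------------
# RankedList
# ---------------------------------------------------------------------------

@dataclass
class RankedList:
    """Genes ordered by descending score with 1-based consecutive ranks.

    Ties in score are broken by ascending lexicographic gene id so that
    any two runs over the same scores produce the identical list.
    """

    entries: pd.DataFrame  # columns: rank, gene_id, score

    def __post_init__(self) -> None:
        e = self.entries
        for col in ("rank", "gene_id", "score"):
            if col not in e.columns:
                raise FormatError(f"ranked list lacks column '{col}'")
        e = e[["rank", "gene_id", "score"]].reset_index(drop=True)
        if e["gene_id"].duplicated().any():
            raise FormatError("duplicate gene ids in ranked list")
        ranks = e["rank"].to_numpy()
        if len(e) and not np.array_equal(ranks, np.arange(1, len(e) + 1)):
            raise FormatError("ranks must be 1..N consecutive")
        scores = e["score"].to_numpy(dtype=float)
        if len(e) > 1 and (np.diff(scores) > 0).any():
            raise FormatError("scores must be non-increasing with rank")
        self.entries = e

    def __len__(self) -> int:
        return len(self.entries)

    @classmethod
    def from_scores(cls, scores: pd.Series) -> "RankedList":
        """Rank genes by score, descending, lexicographic gene-id tie-break."""
        df = pd.DataFrame({"gene_id": scores.index.astype(str), "score": scores.to_numpy(dtype=float)})
        df = df.sort_values(["score", "gene_id"], ascending=[False, True], kind="mergesort")
        df = df.reset_index(drop=True)
        df.insert(0, "rank", np.arange(1, len(df) + 1))
        return cls(df)

    def top_set(self, n: int) -> set[str]:
        if n > len(self):
            raise ContractError(f"top_n={n} exceeds list length {len(self)}")
        return set(self.entries["gene_id"].iloc[:n])

    @property
    def gene_ids(self) -> list[str]:
        return list(self.entries["gene_id"])


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_expression(
    matrix_path: str | Path,
    metadata_path: str | Path,
    normal_genotypes: Sequence[str] | None = None,
    check_conditions: bool = True,
) -> ExpressionMatrix:
    """Read an expression matrix and its sample metadata from TSV files.

    The matrix file has gene ids in the first column and one column per
    sample; the metadata file has columns sample_id, tissue, genotype,
    condition.  Metadata rows are aligned to the matrix column order.
    """
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    if "sample_id" not in meta.columns:
        raise FormatError("metadata must have a 'sample_id' column")
    meta = meta.set_index("sample_id")
    em = ExpressionMatrix(values, meta)
    if check_conditions:
        check_genotype_condition(em, normal_genotypes)
    return em


def write_expression(expr: ExpressionMatrix, matrix_path: str | Path, metadata_path: str | Path) -> None:
    expr.values.to_csv(matrix_path, sep="\t", index_label="gene_id")
    expr.metadata.to_csv(metadata_path, sep="\t", index_label="sample_id")


def read_labels(path: str | Path) -> LabelSet:
    """Read a two-column (gene_id, label) TSV; labels must be +1/-1."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["gene_id", "label"]:
        raise FormatError("labels file must have header columns gene_id, label")
    if df.empty:
        logger.info("labels file %s is empty", path)
        return LabelSet(pd.Series([], dtype=int, index=pd.Index([], dtype=str)))
    try:
        parsed = df["label"].str.replace("−", "-", regex=False).astype(int)
    except ValueError as exc:
        raise FormatError(f"non-integer label in {path}: {exc}") from None
    ls = LabelSet(pd.Series(parsed.to_numpy(), index=df["gene_id"].astype(str)))
    logger.info(
        "read %d labels from %s: %d disease (+1), %d non-disease (-1)",
        len(ls), path, ls.n_pos, ls.n_neg,
    )
    return ls


def write_labels(labels: LabelSet, path: str | Path) -> None:
    pd.DataFrame({"gene_id": labels.labels.index, "label": labels.labels.to_numpy()}).to_csv(
        path, sep="\t", index=False
    )


def read_ranked_list(path: str | Path) -> RankedList:
    df = pd.read_csv(path, sep="\t")
    df["gene_id"] = df["gene_id"].astype(str)
    return RankedList(df)


def write_ranked_list(ranked: RankedList, path: str | Path) -> None:
    ranked.entries.to_csv(path, sep="\t", index=False)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Genes x contrasts score table, gene ids in the first column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index_label="gene_id")
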