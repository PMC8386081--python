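"""Pre-processing: zero filter, normalization, per-tissue variance selection.

The filter reproduces a common pre-processing recipe for multi-tissue
expression data: genes with any zero value are removed (an l0-norm
filter), samples are normalized to a common library total, genes are
ranked by their within-tissue expression variance, and the union of the
top-k genes of every tissue is retained.  Only high-variance genes carry
signal any downstream differential-expression score can see; the rest
are discarded to cut the problem size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import ExpressionMatrix
from .errors import ContractError, DegenerateInputError, DomainError

logger = logging.getLogger(__name__)

NORMALIZE_MODES = ("none", "per_sample_total", "log2", "both")
DEFAULT_TOTAL = 1e6


@dataclass
class FilterReport:
    """Bookkeeping for one `select_genes` run."""

    n_input_genes: int
    n_after_zero_filter: int
    per_tissue_top_k: dict[str, list[str]]
    n_union: int

    def summary_frame(self) -> pd.DataFrame:
        rows = [("input_genes", self.n_input_genes), ("after_zero_filter", self.n_after_zero_filter)]
        rows += [(f"top_k[{t}]", len(g)) for t, g in self.per_tissue_top_k.items()]
        rows.append(("union", self.n_union))
        return pd.DataFrame(rows, columns=["stage", "n_genes"])


def zero_filter(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Keep exactly the genes whose expression is > 0 in every sample."""
    keep = (expr.values.to_numpy() > 0).all(axis=1)
    return ExpressionMatrix(expr.values.loc[keep].copy(), expr.metadata.copy())


def normalize(
    expr: ExpressionMatrix, mode: str = "both", total: float = DEFAULT_TOTAL
) -> ExpressionMatrix:
    """Rescale and/or log-transform expression values.

    per_sample_total rescales each sample column to sum to ``total``
    (counts-per-million when total=1e6); log2 replaces every value by its
    base-2 logarithm; both applies the total rescale first.  Gene and
    sample sets are unchanged.
    """
    if mode not in NORMALIZE_MODES:
        raise ContractError(f"unknown normalize mode {mode!r}; expected one of {NORMALIZE_MODES}")
    if mode == "none":
        return ExpressionMatrix(expr.values.copy(), expr.metadata.copy())
    v = expr.values.to_numpy(dtype=float).copy()
    if mode in ("per_sample_total", "both"):
        sums = v.sum(axis=0)
        if (sums <= 0).any():
            raise DomainError("per_sample_total requires every sample column to have positive total")
        v = v / sums * total
    if mode in ("log2", "both"):
        if (v <= 0).any():
            raise DomainError("log2 normalization requires strictly positive values; apply zero_filter first")
        v = np.log2(v)
    out = pd.DataFrame(v, index=expr.values.index, columns=expr.values.columns)
    return ExpressionMatrix(out, expr.metadata.copy())


def variance_top_k(expr: ExpressionMatrix, tissue: str, k: int) -> list[str]:
    """The k genes with the largest sample variance within one tissue.

    Variance is the unbiased estimate (divisor n-1) over that tissue's
    samples only.  Ties at the cutoff are broken by ascending
    lexicographic gene id.  Returned in (variance desc, gene_id asc) order.
    """
    if k < 1 or k > expr.n_genes:
        raise ContractError(f"k={k} out of range 1..{expr.n_genes}")
    samples = expr.samples_where(tissue=tissue)
    if not samples:
        raise ContractError(f"tissue {tissue!r} not present in metadata")
    if len(samples) < 2:
        raise DegenerateInputError(f"tissue {tissue!r} has {len(samples)} sample(s); need >= 2 for variance")
    var = expr.values[samples].var(axis=1, ddof=1)
    order = pd.DataFrame({"var": var.to_numpy(), "gene_id": var.index.astype(str)})
    order = order.sort_values(["var", "gene_id"], ascending=[False, True], kind="mergesort")
    return list(order["gene_id"].iloc[:k])


def select_genes(
    expr: ExpressionMatrix,
    k: int = 4000,
    variance_normalize: str = "both",
    output_normalize: str = "per_sample_total",
    total: float = DEFAULT_TOTAL,
) -> tuple[ExpressionMatrix, FilterReport]:
    """Full filter: zero filter, per-tissue top-k by variance, union.

    Variance ranking is computed on ``variance_normalize``-scaled data
    (default: per-sample total then log2, so the ranking is library-size-
    and scale-stable), while the returned matrix is on the
    ``output_normalize`` scale (default: linear per-sample total, the
    scale fold-change scoring needs).  Gene order of the result follows
    the input matrix.
    """
    n_input = expr.n_genes
    filtered = zero_filter(expr)
    n_zero = filtered.n_genes
    ranked_basis = normalize(filtered, variance_normalize, total)
    k_eff = min(k, ranked_basis.n_genes)
    if k_eff < k:
        logger.warning("top-k capped at %d genes surviving the zero filter (requested %d)", k_eff, k)
    per_tissue: dict[str, list[str]] = {}
    union: set[str] = set()
    for tissue in expr.tissues:
        top = variance_top_k(ranked_basis, tissue, k_eff)
        per_tissue[tissue] = top
        union |= set(top)
    out = normalize(filtered, output_normalize, total)
    keep = [g for g in out.gene_ids if g in union]
    result = out.subset_genes(keep)
    report = FilterReport(
        n_input_genes=n_input,
        n_after_zero_filter=n_zero,
        per_tissue_top_k=per_tissue,
        n_union=len(union),
    )
    logger.info(
        "select_genes: %d -> %d after zero filter -> %d in union of top-%d per tissue",
        n_input, n_zero, report.n_union, k,
    )
    return result, report
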