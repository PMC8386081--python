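"""Differential-expression scoring over two-group contrasts.

A *contrast* is a named pair of disjoint sample groups.  Three families
cover the standard multi-tissue grid:

* intra-tissue ``normal_case`` (NC): normals vs pooled cases of one tissue,
* inter-tissue ``normal_normal`` (NN): normals of tissue A vs normals of B,
* inter-tissue ``case_case`` (CC): pooled cases of A vs pooled cases of B.

Two per-gene scores are provided.  The fold-change (FC) score of a gene
is the mean, over all cross pairs (a, b) of samples drawn from the two
groups, of max(a/b, b/a) — the reciprocal is taken so every pairwise
fold change is at least 1, hence the score is >= 1 with equality only
when every pair is equal.  The t score is |t| of the Welch two-sample
test, so larger always means more differential.

A FeatureTable collects one score column per contrast; its rows are the
feature vectors x_g = (p_g1, ..., p_gn) fed to the neuron.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import ExpressionMatrix
from .errors import ContractError, DegenerateInputError, DomainError

logger = logging.getLogger(__name__)

FAMILIES = ("normal_case", "normal_normal", "case_case")
FAMILY_CODES = {"normal_case": "NC", "normal_normal": "NN", "case_case": "CC"}


@dataclass(frozen=True)
class ContrastSpec:
    """A named two-group comparison (e.g. Str_Cor_NN)."""

    name: str
    group_a: tuple[str, ...]
    group_b: tuple[str, ...]
    family: str

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ContractError(f"unknown contrast family {self.family!r}")
        if not self.group_a or not self.group_b:
            raise ContractError(f"contrast {self.name}: both groups must be non-empty")
        if set(self.group_a) & set(self.group_b):
            raise ContractError(f"contrast {self.name}: groups must be disjoint")

    def check_against(self, expr: ExpressionMatrix) -> None:
        known = set(expr.sample_ids)
        missing = [s for s in self.group_a + self.group_b if s not in known]
        if missing:
            raise ContractError(f"contrast {self.name}: unknown samples {missing[:5]}")


@dataclass
class FeatureTable:
    """Genes x contrasts differential-expression scores."""

    table: pd.DataFrame  # index: gene_id, columns: contrast names

    def __post_init__(self) -> None:
        if self.table.isna().any().any():
            raise DomainError("feature table contains missing cells")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def contrast_names(self) -> list[str]:
        return list(self.table.columns)

    def matrix_for(self, genes: list[str]) -> np.ndarray:
        missing = [g for g in genes if g not in self.table.index]
        if missing:
            raise ContractError(f"genes absent from feature table: {missing[:5]}")
        return self.table.loc[genes].to_numpy(dtype=float)


def _group_values(expr: ExpressionMatrix, samples: tuple[str, ...]) -> np.ndarray:
    return expr.values[list(samples)].to_numpy(dtype=float)


def fc_score(expr: ExpressionMatrix, contrast: ContrastSpec) -> pd.Series:
    """Mean pairwise fold change, reciprocal-corrected to be >= 1.

    For gene g with group values a_1..a_m and b_1..b_n the score is
    mean over all m*n pairs of max(a_i/b_j, b_j/a_i).  The operation is
    symmetric in the two groups; group order is canonicalized internally
    so the symmetry holds bit-exactly.
    """
    contrast.check_against(expr)
    ga, gb = contrast.group_a, contrast.group_b
    # canonical order: makes fc_score(A,B) and fc_score(B,A) bitwise identical
    if sorted(gb) < sorted(ga):
        ga, gb = gb, ga
    a = _group_values(expr, ga)
    b = _group_values(expr, gb)
    if (a <= 0).any() or (b <= 0).any():
        raise DomainError(
            f"contrast {contrast.name}: fold change requires strictly positive expression"
        )
    ratios = a[:, :, None] / b[:, None, :]
    fc = np.maximum(ratios, 1.0 / ratios)
    score = fc.reshape(fc.shape[0], -1).mean(axis=1)
    return pd.Series(score, index=expr.values.index, name=contrast.name)


def ttest_score(expr: ExpressionMatrix, contrast: ContrastSpec) -> pd.Series:
    """|t| of the Welch (unequal-variance) two-sample test, per gene.

    Genes with zero variance in both groups score 0 when the group means
    are equal; otherwise the infinite statistic is replaced by the
    largest finite score in the vector (logged).
    """
    contrast.check_against(expr)
    a = _group_values(expr, contrast.group_a)
    b = _group_values(expr, contrast.group_b)
    na, nb = a.shape[1], b.shape[1]
    if na < 2 or nb < 2:
        raise DegenerateInputError(
            f"contrast {contrast.name}: Welch t needs >= 2 samples per group, got ({na}, {nb})"
        )
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    se = np.sqrt(va / na + vb / nb)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.abs(ma - mb) / se
    zero_se = se == 0
    t[zero_se & (ma == mb)] = 0.0
    inf_mask = np.isinf(t) | (zero_se & (ma != mb))
    if inf_mask.any():
        finite = t[np.isfinite(t)]
        ceiling = float(finite.max()) if finite.size else 1.0
        logger.warning(
            "contrast %s: %d gene(s) with zero pooled variance and unequal means; "
            "score set to max finite |t| = %g", contrast.name, int(inf_mask.sum()), ceiling,
        )
        t[inf_mask] = ceiling
    return pd.Series(t, index=expr.values.index, name=contrast.name)


def standard_contrasts(expr: ExpressionMatrix) -> list[ContrastSpec]:
    """The standard contrast grid over the matrix's tissues.

    Per tissue one intra-tissue normal-vs-case contrast (cases pooled
    over all case genotypes), then per unordered tissue pair one
    normal-normal and one case-case inter-tissue contrast; with T
    tissues that is T + 2*C(T,2) contrasts (9 for T=3).  A contrast
    whose groups cannot be formed is omitted with a warning.
    """
    tissues = expr.tissues
    contrasts: list[ContrastSpec] = []

    def _try_add(name: str, ga: list[str], gb: list[str], family: str) -> None:
        if not ga or not gb:
            logger.warning("omitting contrast %s: an empty sample group", name)
            return
        contrasts.append(ContrastSpec(name, tuple(ga), tuple(gb), family))

    for t in tissues:
        _try_add(
            f"{t}_{t}_NC",
            expr.samples_where(tissue=t, condition="normal"),
            expr.samples_where(tissue=t, condition="case"),
            "normal_case",
        )
    for ta, tb in itertools.combinations(tissues, 2):
        _try_add(
            f"{ta}_{tb}_NN",
            expr.samples_where(tissue=ta, condition="normal"),
            expr.samples_where(tissue=tb, condition="normal"),
            "normal_normal",
        )
    for ta, tb in itertools.combinations(tissues, 2):
        _try_add(
            f"{ta}_{tb}_CC",
            expr.samples_where(tissue=ta, condition="case"),
            expr.samples_where(tissue=tb, condition="case"),
            "case_case",
        )
    return contrasts


def build_feature_table(
    expr: ExpressionMatrix, contrasts: list[ContrastSpec], method: str = "fc"
) -> FeatureTable:
    """Score every gene under every contrast; columns follow input order."""
    if not contrasts:
        raise ContractError("at least one contrast required")
    scorers = {"fc": fc_score, "ttest": ttest_score}
    if method not in scorers:
        raise ContractError(f"unknown scoring method {method!r}; expected one of {sorted(scorers)}")
    scorer = scorers[method]
    cols = {c.name: scorer(expr, c) for c in contrasts}
    table = pd.DataFrame(cols, index=expr.values.index)[[c.name for c in contrasts]]
    return FeatureTable(table)


def read_contrast_file(path, expr: ExpressionMatrix) -> list[ContrastSpec]:
    """Build contrasts from a TSV with columns
    name, family, tissue_a, condition_a, tissue_b, condition_b."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    needed = ["name", "family", "tissue_a", "condition_a", "tissue_b", "condition_b"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ContractError(f"contrast file lacks columns {missing}")
    out = []
    for row in df.itertuples(index=False):
        ga = expr.samples_where(tissue=row.tissue_a, condition=row.condition_a)
        gb = expr.samples_where(tissue=row.tissue_b, condition=row.condition_b)
        out.append(ContrastSpec(row.name, tuple(ga), tuple(gb), row.family))
    return out
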