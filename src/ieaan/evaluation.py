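"""Ranked-list evaluation: ROC/AUC, precision-recall/AP, top-N overlap.

Conventions (fixed so every number in the package is reproducible):

* AUC is the Mann-Whitney probability P(score_pos > score_neg) with
  half credit for ties — identical to the trapezoidal area under the
  tie-aware ROC curve.
* AUPR is average precision: the mean, over positives ranked by
  descending score (gene-id tie-break), of the precision at each
  positive's rank.  No curve interpolation.
* overlap degree of two ranked lists at depth N is
  |top-N(a) ∩ top-N(b)| / N.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .data_io import LabelSet, RankedList
from .errors import ContractError, DegenerateInputError


@dataclass
class EvaluationResult:
    auc: float | None = None
    aupr: float | None = None
    roc_points: list[tuple[float, float]] | None = None
    pr_points: list[tuple[float, float]] | None = None
    n_pos: int = 0
    n_neg: int = 0


def _align(scores: pd.Series, labels: LabelSet) -> tuple[pd.Series, pd.Series]:
    """Scores and labels over their common genes; both classes required."""
    common = [g for g in scores.index if g in labels.labels.index]
    if not common:
        raise DegenerateInputError("no scored gene carries a label")
    s = scores.loc[common].astype(float)
    y = labels.labels.loc[common]
    sub = LabelSet(y.copy())
    sub.require_both_classes()
    return s, y


def auc_score(scores: pd.Series, labels: LabelSet) -> float:
    """Tie-aware Mann-Whitney AUC of scores against ±1 labels."""
    s, y = _align(scores, labels)
    ranks = rankdata(s.to_numpy())
    pos = y.to_numpy() == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    numerator = ranks[pos].sum() - n_pos * (n_pos + 1) / 2
    return float(numerator / (n_pos * n_neg))


def roc_auc(scores: pd.Series, labels: LabelSet) -> EvaluationResult:
    """AUC plus the tie-aware ROC polyline from (0,0) to (1,1)."""
    s, y = _align(scores, labels)
    pos = (y.to_numpy() == 1).astype(float)
    n_pos, n_neg = int(pos.sum()), int(len(pos) - pos.sum())
    order = np.argsort(-s.to_numpy(), kind="mergesort")
    sv = s.to_numpy()[order]
    pv = pos[order]
    # one ROC vertex per distinct score value
    distinct = np.r_[np.nonzero(np.diff(sv))[0], len(sv) - 1]
    tp = np.cumsum(pv)[distinct]
    fp = (distinct + 1) - tp
    points = [(0.0, 0.0)] + [(f / n_neg, t / n_pos) for f, t in zip(fp, tp)]
    return EvaluationResult(
        auc=auc_score(scores, labels), roc_points=points, n_pos=n_pos, n_neg=n_neg
    )


def pr_aupr(scores: pd.Series, labels: LabelSet) -> EvaluationResult:
    """Average precision plus the (recall, precision) points per rank."""
    s, y = _align(scores, labels)
    df = pd.DataFrame({"gene_id": s.index.astype(str), "score": s.to_numpy(), "pos": y.to_numpy() == 1})
    df = df.sort_values(["score", "gene_id"], ascending=[False, True], kind="mergesort")
    posv = df["pos"].to_numpy()
    n_pos, n_neg = int(posv.sum()), int(len(posv) - posv.sum())
    tp = np.cumsum(posv)
    k = np.arange(1, len(posv) + 1)
    precision = tp / k
    recall = tp / n_pos
    ap = math.fsum(precision[posv]) / n_pos
    points = list(zip(recall.tolist(), precision.tolist()))
    return EvaluationResult(aupr=ap, pr_points=points, n_pos=n_pos, n_neg=n_neg)


def evaluate(scores: pd.Series, labels: LabelSet) -> EvaluationResult:
    """Both metrics and both curves in one result."""
    r = roc_auc(scores, labels)
    p = pr_aupr(scores, labels)
    return EvaluationResult(
        auc=r.auc, aupr=p.aupr, roc_points=r.roc_points, pr_points=p.pr_points,
        n_pos=r.n_pos, n_neg=r.n_neg,
    )


def overlap_degree(list_a: RankedList, list_b: RankedList, top_n: int) -> float:
    """|top-N(a) ∩ top-N(b)| / N for two rankings of the same universe."""
    if set(list_a.gene_ids) != set(list_b.gene_ids):
        raise ContractError("ranked lists must cover the same gene universe")
    return len(list_a.top_set(top_n) & list_b.top_set(top_n)) / top_n


def overlap_matrix(lists: dict[str, RankedList], top_n: int) -> pd.DataFrame:
    """Symmetric pairwise overlap-degree matrix; diagonal = 1."""
    if len(lists) < 2:
        raise ContractError("overlap matrix needs at least 2 ranked lists")
    names = list(lists)
    mat = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            d = overlap_degree(lists[a], lists[b], top_n)
            mat.loc[a, b] = mat.loc[b, a] = d
    return mat


def consensus_genes(lists: dict[str, RankedList], top_n: int) -> set[str]:
    """Genes present in the top-N of every list."""
    if not lists:
        raise ContractError("at least one ranked list required")
    sets = [rl.top_set(top_n) for rl in lists.values()]
    return set.intersection(*sets)
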