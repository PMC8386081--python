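"""Stability of the ranking under sample resampling.

The experiment: repeatedly drop a fixed number of samples from every
tissue-genotype replicate group, recompute the fold-change feature
table on the surviving samples, re-initialize and retrain the neuron,
re-rank all genes, and measure the pairwise top-N overlap degree of the
rankings across repeats.  A method whose top genes survive the loss of
a quarter of the replicates is considered stable.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

from .data_io import ExpressionMatrix, LabelSet, RankedList
from .errors import ConfigurationError, DegenerateInputError
from .evaluation import overlap_degree
from .neuron import auc_init, rank_genes, train
from .scoring import build_feature_table, standard_contrasts

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RobustnessConfig:
    n_repeats: int = 5
    drop_count: int = 2
    top_n: int = 500
    per_group: bool = True     # drop per tissue-genotype group vs globally
    method: str = "fc"
    eta: float = 1e-3
    max_iter: int = 10000
    tol: float = 1e-8
    targets: str = "pm1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_repeats < 2:
            raise ConfigurationError("n_repeats must be >= 2 for pairwise overlaps")
        if self.drop_count < 0:
            raise ConfigurationError("drop_count must be >= 0")
        if self.top_n < 1:
            raise ConfigurationError("top_n must be >= 1")


@dataclass
class RobustnessReport:
    n_repeats: int
    dropped_samples: list[list[str]]
    pairwise_overlaps: dict[tuple[int, int], float]
    mean_overlap: float
    seed: int
    ranked_lists: list[RankedList] = field(repr=False, default_factory=list)


def _drop_samples(expr: ExpressionMatrix, drop_count: int, per_group: bool, rng) -> list[str]:
    """Sample ids to remove for one repeat (deterministic given rng state)."""
    if drop_count == 0:
        return []
    if per_group:
        dropped: list[str] = []
        groups = expr.metadata.groupby(["tissue", "genotype"], sort=True).groups
        for key in sorted(groups):
            members = sorted(map(str, groups[key]))
            if len(members) <= drop_count:
                raise DegenerateInputError(
                    f"group {key} has {len(members)} sample(s); cannot drop {drop_count}"
                )
            dropped.extend(rng.choice(members, size=drop_count, replace=False))
        return dropped
    members = sorted(expr.sample_ids)
    if len(members) <= drop_count:
        raise DegenerateInputError("cannot drop more samples than exist")
    return list(rng.choice(members, size=drop_count, replace=False))


def resample_run(
    expr: ExpressionMatrix, labels: LabelSet, config: RobustnessConfig
) -> RobustnessReport:
    """Run the drop/recompute/retrain/re-rank loop and summarize overlaps.

    ``expr`` should already be filtered (strictly positive values, gene
    set fixed); the gene universe is identical across repeats, only the
    sample set changes.
    """
    children = np.random.SeedSequence(config.seed).spawn(config.n_repeats)
    dropped_all: list[list[str]] = []
    ranked: list[RankedList] = []
    for r in range(config.n_repeats):
        rng = np.random.default_rng(children[r])
        dropped = _drop_samples(expr, config.drop_count, config.per_group, rng)
        survivors = [s for s in expr.sample_ids if s not in set(dropped)]
        sub = expr.subset_samples(survivors)
        contrasts = standard_contrasts(sub)
        features = build_feature_table(sub, contrasts, config.method)
        sub_labels = labels.restrict_to(features.gene_ids)
        model0 = auc_init(features, sub_labels, eta=config.eta)
        model, _ = train(
            model0, features, sub_labels,
            eta=config.eta, max_iter=config.max_iter, tol=config.tol, targets=config.targets,
        )
        ranked.append(rank_genes(model, features))
        dropped_all.append(sorted(dropped))
        logger.info("repeat %d/%d: dropped %d sample(s)", r + 1, config.n_repeats, len(dropped))

    overlaps = {
        (i, j): overlap_degree(ranked[i], ranked[j], config.top_n)
        for i, j in itertools.combinations(range(config.n_repeats), 2)
    }
    mean = float(np.mean(list(overlaps.values())))
    return RobustnessReport(
        n_repeats=config.n_repeats,
        dropped_samples=dropped_all,
        pairwise_overlaps=overlaps,
        mean_overlap=mean,
        seed=config.seed,
        ranked_lists=ranked,
    )
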