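import numpy as np
import pandas as pd
import pytest

from ieaan import ExpressionMatrix, LabelSet


def make_expression(values: dict[str, list[float]], meta_rows: list[tuple]) -> ExpressionMatrix:
    """Build an ExpressionMatrix from {gene: row} and
    (sample_id, tissue, genotype, condition) tuples."""
    meta = pd.DataFrame(
        meta_rows, columns=["sample_id", "tissue", "genotype", "condition"]
    ).set_index("sample_id")
    df = pd.DataFrame.from_dict(values, orient="index", columns=list(meta.index), dtype=float)
    return ExpressionMatrix(df, meta)


def random_expression(rng, n_genes=8, tissues=("T1", "T2"), reps=3) -> ExpressionMatrix:
    """Small random strictly-positive matrix: per tissue, `reps` normal +
    `reps` case samples."""
    rows = []
    for t in tissues:
        for cond, geno in (("normal", "G0"), ("case", "G1")):
            for r in range(reps):
                rows.append((f"{t}_{geno}_{r}", t, geno, cond))
    meta = pd.DataFrame(rows, columns=["sample_id", "tissue", "genotype", "condition"]).set_index("sample_id")
    vals = np.exp(rng.normal(1.0, 1.0, size=(n_genes, len(meta))))
    genes = [f"g{i:03d}" for i in range(n_genes)]
    return ExpressionMatrix(pd.DataFrame(vals, index=genes, columns=meta.index), meta)


@pytest.fixture
def two_tissue_expr() -> ExpressionMatrix:
    """Deterministic 5-gene, 8-sample matrix over two tissues."""
    rng = np.random.default_rng(7)
    return random_expression(rng, n_genes=5)


@pytest.fixture
def labels_small() -> LabelSet:
    return LabelSet(pd.Series({"g000": 1, "g001": 1, "g002": -1, "g003": -1}))
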