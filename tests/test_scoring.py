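"""Fold-change and Welch-t scoring, contrast grid, feature table."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ieaan import (
    ContrastSpec,
    DegenerateInputError,
    DomainError,
    build_feature_table,
    fc_score,
    standard_contrasts,
    ttest_score,
)

from conftest import make_expression, random_expression


def _contrast_from_rows(a_vals, b_vals, gene="g1"):
    """One-gene matrix with explicit group values and the matching contrast."""
    na, nb = len(a_vals), len(b_vals)
    rows = [(f"a{i}", "T1", "G0", "normal") for i in range(na)]
    rows += [(f"b{i}", "T1", "G1", "case") for i in range(nb)]
    expr = make_expression({gene: list(a_vals) + list(b_vals)}, rows)
    spec = ContrastSpec(
        "test", tuple(f"a{i}" for i in range(na)), tuple(f"b{i}" for i in range(nb)), "normal_case"
    )
    return expr, spec


def brute_force_fc(a_vals, b_vals):
    """Independent enumeration of mean max(a/b, b/a) over all cross pairs."""
    pairs = [max(a / b, b / a) for a in a_vals for b in b_vals]
    return sum(pairs) / len(pairs)


class TestFcScore:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ((2, 2), (2, 2), 1.0),
            ((4,), (2,), 2.0),
            ((2,), (4,), 2.0),                       # reciprocal rule symmetry
            ((1, 2), (3, 6), (3 + 6 + 1.5 + 3) / 4),  # = 3.375 by enumeration
        ],
    )
    def test_worked_examples(self, a, b, expected):
        expr, spec = _contrast_from_rows(a, b)
        assert fc_score(expr, spec).iloc[0] == pytest.approx(expected, rel=1e-12)

    def test_matches_enumeration_on_random_fixtures(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            a = rng.uniform(0.1, 10, size=rng.integers(1, 5))
            b = rng.uniform(0.1, 10, size=rng.integers(1, 5))
            expr, spec = _contrast_from_rows(a, b)
            got = fc_score(expr, spec).iloc[0]
            assert got == pytest.approx(brute_force_fc(a, b), rel=1e-12)
            assert got >= 1.0

    def test_symmetry_is_exact(self, two_tissue_expr):
        groups = two_tissue_expr.sample_ids
        fwd = ContrastSpec("f", tuple(groups[:3]), tuple(groups[3:6]), "normal_case")
        rev = ContrastSpec("f", tuple(groups[3:6]), tuple(groups[:3]), "normal_case")
        a, b = fc_score(two_tissue_expr, fwd), fc_score(two_tissue_expr, rev)
        assert (a.to_numpy() == b.to_numpy()).all()

    def test_gene_scale_invariance_and_group_scaling(self):
        # multiplying all samples by c>0 leaves the score; multiplying only
        # group_a by c>=1 (identical groups) yields exactly c
        expr, spec = _contrast_from_rows((2.0, 2.0), (2.0, 2.0))
        scaled, _ = _contrast_from_rows((10.0, 10.0), (10.0, 10.0))
        assert fc_score(expr, spec).iloc[0] == fc_score(scaled, spec).iloc[0] == 1.0
        bumped, _ = _contrast_from_rows((6.0, 6.0), (2.0, 2.0))
        assert fc_score(bumped, spec).iloc[0] == pytest.approx(3.0, rel=1e-12)

    def test_zero_expression_rejected(self):
        expr, spec = _contrast_from_rows((0.0, 1.0), (1.0, 1.0))
        with pytest.raises(DomainError):
            fc_score(expr, spec)


class TestTtestScore:
    def test_identical_groups_score_zero(self):
        expr, spec = _contrast_from_rows((1.0, 2.0, 3.0), (1.0, 2.0, 3.0))
        assert ttest_score(expr, spec).iloc[0] == 0.0

    def test_welch_worked_example(self):
        expr, spec = _contrast_from_rows((1.0, 2.0, 3.0), (4.0, 5.0, 6.0))
        expected = abs(stats.ttest_ind([1, 2, 3], [4, 5, 6], equal_var=False).statistic)
        got = ttest_score(expr, spec).iloc[0]
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(3.674, abs=1e-3)

    def test_matches_scipy_on_random_fixtures(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            a = rng.normal(0, 1, size=4)
            b = rng.normal(1, 2, size=6)
            expr, spec = _contrast_from_rows(np.exp(a), np.exp(b))
            expected = abs(stats.ttest_ind(np.exp(a), np.exp(b), equal_var=False).statistic)
            assert ttest_score(expr, spec).iloc[0] == pytest.approx(expected, rel=1e-12)

    def test_small_group_rejected(self):
        expr, spec = _contrast_from_rows((1.0,), (1.0, 2.0, 3.0, 4.0, 5.0))
        with pytest.raises(DegenerateInputError):
            ttest_score(expr, spec)

    def test_constant_unequal_genes_get_max_finite(self, caplog):
        rows = [(f"a{i}", "T1", "G0", "normal") for i in range(2)]
        rows += [(f"b{i}", "T1", "G1", "case") for i in range(2)]
        expr = make_expression({"flat": [1, 1, 2, 2], "noisy": [1, 2, 3, 5]}, rows)
        spec = ContrastSpec("c", ("a0", "a1"), ("b0", "b1"), "normal_case")
        scores = ttest_score(expr, spec)
        assert np.isfinite(scores).all()
        assert scores["flat"] == scores.drop("flat").max()


class TestStandardContrasts:
    def _grid(self, n_tissues):
        rng = np.random.default_rng(0)
        tissues = tuple(f"T{i}" for i in range(n_tissues))
        return standard_contrasts(random_expression(rng, n_genes=3, tissues=tissues))

    @pytest.mark.parametrize("n_tissues, expected", [(3, 9), (2, 4), (1, 1)])
    def test_grid_size(self, n_tissues, expected):
        contrasts = self._grid(n_tissues)
        assert len(contrasts) == expected
        # independent enumeration: T intra + 2 * C(T,2) inter
        assert expected == n_tissues + 2 * len(list(itertools.combinations(range(n_tissues), 2)))

    def test_families_and_names(self):
        contrasts = self._grid(3)
        names = [c.name for c in contrasts]
        assert names[:3] == ["T0_T0_NC", "T1_T1_NC", "T2_T2_NC"]
        assert "T0_T1_NN" in names and "T0_T1_CC" in names
        by_family = {f: sum(c.family == f for c in contrasts) for f in
                     ("normal_case", "normal_normal", "case_case")}
        assert by_family == {"normal_case": 3, "normal_normal": 3, "case_case": 3}

    def test_tissue_without_cases_omitted(self, caplog):
        rows = [("s1", "T1", "G0", "normal"), ("s2", "T1", "G0", "normal"),
                ("s3", "T2", "G0", "normal"), ("s4", "T2", "G1", "case")]
        expr = make_expression({"g1": [1, 2, 3, 4]}, rows)
        contrasts = standard_contrasts(expr)
        names = [c.name for c in contrasts]
        assert "T1_T1_NC" not in names       # T1 has no cases
        assert "T2_T2_NC" in names and "T1_T2_NN" in names


class TestFeatureTable:
    def test_single_cell_matches_oracle(self):
        expr, spec = _contrast_from_rows((1, 2), (3, 6))
        ft = build_feature_table(expr, [spec], "fc")
        assert ft.table.shape == (1, 1)
        assert ft.table.iloc[0, 0] == pytest.approx(3.375, rel=1e-12)

    def test_column_order_follows_input(self, two_tissue_expr):
        contrasts = standard_contrasts(two_tissue_expr)
        ft = build_feature_table(two_tissue_expr, contrasts, "fc")
        assert ft.contrast_names == [c.name for c in contrasts]
        assert (ft.table.to_numpy() >= 1.0).all()

    def test_constant_gene_scores_one_everywhere(self):
        rows = [(f"a{i}", "T1", "G0", "normal") for i in range(2)]
        rows += [(f"b{i}", "T1", "G1", "case") for i in range(2)]
        expr = make_expression({"flat": [2.0] * 4}, rows)
        ft = build_feature_table(expr, standard_contrasts(expr), "fc")
        assert (ft.table.loc["flat"] == 1.0).all()
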