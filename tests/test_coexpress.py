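import numpy as np
import pandas as pd
import pytest
from scipy import stats

from wallcomp import (
    ExpressionMatrix,
    call_degs,
    correlation_network,
    filter_expressed,
    kmeans_pearson,
    normalize_tgr,
    simulate_expression_matrix,
    top_coexpressed,
)
from wallcomp.coexpress import network_to_edges
from wallcomp.composition_io import ValidationError


def matrix_from(values, columns=None, groups=None):
    df = pd.DataFrame(values)
    if columns:
        df.columns = columns
    df.index = [f"g{i}" for i in range(len(df))]
    return ExpressionMatrix(values=df, sample_groups=groups or {})


class TestNormalizeTGR:
    def test_worked_median_of_ratios(self):
        """{g1:(4,16), g2:(9,36), g3:(1,4)}: geometric means (8,18,2);
        ratios are 0.5 everywhere in sample 1 and 2 in sample 2."""
        m = matrix_from([[4, 16], [9, 36], [1, 4]])
        out = normalize_tgr(m)
        assert out.size_factors.tolist() == pytest.approx([0.5, 2.0])
        assert out.values.iloc[:, 0].tolist() == pytest.approx([8, 18, 2])
        assert out.values.iloc[:, 1].tolist() == pytest.approx([8, 18, 2])

    def test_doubled_sample_equalized(self):
        """sample2 = 2 x sample1: size factors in ratio 2:1 and the
        normalized columns coincide."""
        rng = np.random.default_rng(0)
        x = rng.uniform(1, 100, 20)
        m = matrix_from(np.column_stack([x, 2 * x]))
        out = normalize_tgr(m)
        f = out.size_factors
        assert f.iloc[1] / f.iloc[0] == pytest.approx(2.0)
        assert np.allclose(out.values.iloc[:, 0], out.values.iloc[:, 1])

    def test_per_sample_scaling_invariance_up_to_global_constant(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(1, 100, size=(20, 4))
        scale = np.array([1.0, 2.0, 0.5, 3.0])
        n1 = normalize_tgr(matrix_from(base))
        n2 = normalize_tgr(matrix_from(base * scale))
        g = scale.prod() ** 0.25  # geometric mean of the scalings
        assert np.allclose(n2.values, n1.values * g)

    def test_identical_samples_unit_factors(self):
        m = matrix_from(np.tile([[5.0], [9.0], [2.0]], (1, 3)))
        out = normalize_tgr(m)
        assert np.allclose(out.size_factors, 1.0)

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        m = matrix_from(rng.uniform(1, 50, size=(15, 5)))
        once = normalize_tgr(m)
        twice = normalize_tgr(once)
        assert np.allclose(twice.size_factors, 1.0)
        assert np.allclose(once.values, twice.values)

    def test_no_all_positive_gene_errors(self):
        m = matrix_from([[0, 5], [3, 0]])
        with pytest.raises(ValidationError, match="pseudo-reference"):
            normalize_tgr(m)

    def test_gene_gm_variant(self):
        m = matrix_from([[4, 16]])
        out = normalize_tgr(m, method="gene_gm")
        assert out.values.iloc[0].tolist() == pytest.approx([0.5, 2.0])


class TestFilterExpressed:
    @pytest.mark.parametrize(
        "row,kept", [([16.0, 1.0], True), ([15.99, 15.99], False),
                     ([0.0, 0.0], False), ([1.0, 400.0], True)]
    )
    def test_boundary_inclusive_at_16(self, row, kept):
        m = matrix_from([row])
        assert (filter_expressed(m) == ["g0"]) is kept


class TestCallDEGs:
    def _matrix(self, a_vals, b_vals):
        values = [list(a) + list(b) for a, b in zip(a_vals, b_vals)]
        cols = ["A_r1", "A_r2", "B_r1", "B_r2"]
        groups = {"A_r1": "A", "A_r2": "A", "B_r1": "B", "B_r2": "B"}
        return matrix_from(values, cols, groups)

    def _padj(self, genes, values):
        return pd.DataFrame({"A_vs_B": values}, index=genes)

    def test_all_three_boundaries_are_degs(self):
        m = self._matrix([(10, 10)], [(20, 20)])  # fold exactly 2, max 20
        calls = call_degs(m, self._padj(["g0"], [0.01]), [("A", "B")])
        assert calls[0].is_deg and calls[0].fold_change == 2.0
        assert calls[0].direction == "up"

    def test_fold_below_threshold_not_deg(self):
        m = self._matrix([(10, 10)], [(19, 19)])
        calls = call_degs(m, self._padj(["g0"], [0.001]), [("A", "B")])
        assert not calls[0].is_deg

    def test_low_expression_not_deg(self):
        m = self._matrix([(2, 2)], [(8, 8)])  # fold 4 but max TGR 8 < 16
        calls = call_degs(m, self._padj(["g0"], [0.001]), [("A", "B")])
        assert not calls[0].is_deg

    def test_padj_above_threshold_not_deg(self):
        m = self._matrix([(10, 10)], [(40, 40)])
        calls = call_degs(m, self._padj(["g0"], [0.011]), [("A", "B")])
        assert not calls[0].is_deg

    def test_zero_mean_requires_pseudocount(self):
        m = self._matrix([(0, 0)], [(40, 40)])
        with pytest.raises(ValidationError, match="pseudocount"):
            call_degs(m, self._padj(["g0"], [0.001]), [("A", "B")])
        with pytest.warns(UserWarning):
            calls = call_degs(m, self._padj(["g0"], [0.001]), [("A", "B")],
                              pseudocount=1.0)
        assert calls[0].fold_change == pytest.approx(41.0)

    def test_recall_on_planted_folds(self):
        """Genes planted at fold 4 with truth padj are all recalled."""
        deg_spec = [(g, ("A", "B"), 4.0) for g in range(10)]
        m, truth = simulate_expression_matrix(
            100, [("A", 8), ("B", 8)], deg_spec=deg_spec, seed=3,
        )
        calls = call_degs(normalize_tgr(m), truth.padj, [("A", "B")])
        planted = {f"g{g:05d}" for g in range(10)}
        called = {c.gene for c in calls if c.is_deg}
        assert planted <= called

    def test_null_matrix_no_degs(self):
        m, truth = simulate_expression_matrix(
            50, [("A", 4), ("B", 4)],
            deg_spec=[(0, ("A", "B"), 1.0)], seed=5,
        )
        calls = call_degs(m, truth.padj, [("A", "B")])
        assert not any(c.is_deg for c in calls)


class TestKmeansPearson:
    def test_anticorrelated_groups_separate(self):
        t = np.linspace(0, 1, 8)
        rng = np.random.default_rng(0)
        up = [t * 10 + rng.normal(0, 0.2, 8) + 5 for _ in range(10)]
        down = [-t * 10 + rng.normal(0, 0.2, 8) + 20 for _ in range(10)]
        m = matrix_from(list(up) + list(down))
        assign = kmeans_pearson(m, 2, seed=0)
        first = {assign[f"g{i}"] for i in range(10)}
        second = {assign[f"g{i}"] for i in range(10, 20)}
        assert len(first) == 1 and len(second) == 1 and first != second

    def test_k_equals_n_genes_singletons(self):
        rng = np.random.default_rng(1)
        m = matrix_from(rng.uniform(1, 50, (5, 6)))
        assign = kmeans_pearson(m, 5, seed=0)
        assert sorted(assign.values()) == [0, 1, 2, 3, 4]

    def test_seed_determinism_and_constant_rows_dropped(self):
        rng = np.random.default_rng(2)
        vals = rng.uniform(1, 50, (12, 6))
        vals[3] = 7.0  # constant row
        m = matrix_from(vals)
        with pytest.warns(UserWarning, match="constant"):
            a = kmeans_pearson(m, 3, seed=4)
        with pytest.warns(UserWarning):
            b = kmeans_pearson(m, 3, seed=4)
        assert a == b and "g3" not in a

    def test_k_below_two_rejected(self):
        m = matrix_from(np.random.default_rng(0).uniform(1, 9, (4, 4)))
        with pytest.raises(ValidationError):
            kmeans_pearson(m, 1)


class TestCorrelationNetwork:
    def test_perfect_pair_significant(self):
        x = np.arange(8.0)
        m = matrix_from([x, 2 * x + 1, [5, 1, 4, 2, 3, 5, 1, 2]])
        net = correlation_network(m)
        i, j = net.nodes.index("g0"), net.nodes.index("g1")
        assert net.r[i, j] == pytest.approx(1.0)
        assert net.mask[i, j]

    def test_critical_r_at_alpha_001_n8(self):
        """Two-sided alpha=0.01 at df=6 corresponds to |r| ~= 0.834."""
        tcrit = stats.t.ppf(1 - 0.005, 6)
        rcrit = tcrit / np.sqrt(6 + tcrit**2)
        assert rcrit == pytest.approx(0.8343, abs=5e-4)
        rng = np.random.default_rng(0)
        x = rng.normal(size=8) + 10.0
        for target, expect in ((rcrit + 0.02, True), (rcrit - 0.02, False)):
            y = 10.0 + target * (x - x.mean()) / x.std() + np.sqrt(
                1 - target**2
            ) * _orthogonal_noise(x, rng)
            m = matrix_from([x, y])
            net = correlation_network(m)
            assert abs(net.r[0, 1]) == pytest.approx(target, abs=1e-6)
            assert bool(net.mask[0, 1]) is expect

    def test_too_few_samples_rejected(self):
        m = matrix_from([[1, 2], [2, 1]])
        with pytest.raises(ValidationError):
            correlation_network(m)

    def test_constant_gene_excluded(self):
        m = matrix_from([[1, 2, 3, 4], [5, 5, 5, 5], [2, 1, 4, 3]])
        with pytest.warns(UserWarning, match="constant"):
            net = correlation_network(m)
        assert "g1" not in net.nodes

    def test_edge_list_shape(self):
        rng = np.random.default_rng(3)
        m = matrix_from(rng.uniform(1, 9, (5, 6)))
        edges = network_to_edges(correlation_network(m))
        assert len(edges) == 10  # 5 choose 2


def _orthogonal_noise(x, rng):
    z = rng.normal(size=len(x))
    xs = (x - x.mean()) / x.std()
    z = z - (z @ xs) / (xs @ xs) * xs
    z = z - z.mean()
    return z / z.std()


class TestTopCoexpressed:
    def _net_with_hub(self):
        rng = np.random.default_rng(4)
        t = rng.normal(size=12) + 10.0
        hub = t
        partners = [t + rng.normal(0, 0.05, 12) for _ in range(10)]
        noise = [rng.normal(size=12) + 10.0 for _ in range(5)]
        m = matrix_from([hub] + partners + noise)
        return correlation_network(m)

    def test_hub_ranked_first(self):
        net = self._net_with_hub()
        top = top_coexpressed(net, 3)
        assert top[0] == "g0"

    def test_empty_mask_empty_ranking(self):
        rng = np.random.default_rng(5)
        m = matrix_from(rng.uniform(1, 9, size=(3, 50)))
        net = correlation_network(m)
        if not net.mask.any():
            with pytest.warns(UserWarning):
                assert top_coexpressed(net, 10) == []

    def test_lexicographic_tie_break(self):
        x = np.arange(6.0)
        m = matrix_from([x, x * 3 + 1])  # r = 1 both ways: equal scores
        net = correlation_network(m)
        assert top_coexpressed(net, 2) == ["g0", "g1"]
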