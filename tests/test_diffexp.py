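import numpy as np
import pytest
from scipy import stats
from statsmodels.stats.multitest import multipletests

from conftest import make_dataset
from helpers import bh_stepup, wilcoxon_exact_two_sided
from scprank.diffexp import (
    baseline_rankings,
    deg_per_celltype,
    normalize_counts,
    pseudo_bulk_deg,
)


def two_group_dataset(rng, n_genes, n_per_group, shift_gene=None, shift=0.0):
    """One cell type, n_per_group disease + control cells, Poisson counts."""
    lam = np.full((n_genes, 2 * n_per_group), 5.0)
    if shift_gene is not None:
        lam[shift_gene, :n_per_group] *= np.exp(shift)
    counts = rng.poisson(lam)
    conditions = ["disease"] * n_per_group + ["control"] * n_per_group
    return make_dataset(counts, ["A"] * 2 * n_per_group, conditions)


class TestNormalize:
    def test_equal_library_sizes_give_log1p(self):
        counts = np.array([[1, 1], [2, 2], [3, 3]])
        ds = make_dataset(counts, ["A", "A"], ["disease", "control"])
        normalize_counts(ds)
        np.testing.assert_allclose(ds.normalized, np.log1p(counts))

    def test_depth_scaling_invariance(self):
        base = np.array([2, 0, 4, 1])
        counts = np.column_stack([base, 3 * base])
        ds = make_dataset(counts, ["A", "A"], ["disease", "control"])
        normalize_counts(ds)
        np.testing.assert_allclose(ds.normalized[:, 0], ds.normalized[:, 1])

    def test_zero_count_cell_named(self):
        ds = make_dataset(
            np.array([[1, 0], [2, 0]]), ["A", "A"], ["disease", "control"]
        )
        with pytest.raises(ValueError, match="c2"):
            normalize_counts(ds)


class TestWilcoxonKernel:
    def test_matches_exact_permutation_oracle_small_groups(self):
        """Tie-free data, group sizes <= 8: p equals exhaustive enumeration."""
        rng = np.random.default_rng(42)
        for _ in range(25):
            n1, n2 = rng.integers(3, 9, size=2)
            x = rng.normal(size=n1)
            y = rng.normal(size=n2)
            p_impl = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto").pvalue
            p_oracle = wilcoxon_exact_two_sided(x, y)
            assert abs(p_impl - p_oracle) <= 1e-10

    def test_bh_matches_naive_stepup(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = rng.uniform(size=rng.integers(1, 40))
            # a few ulps: the reference evaluates p/(i/m), the oracle p*m/i
            np.testing.assert_allclose(
                multipletests(p, method="fdr_bh")[1], bh_stepup(p), rtol=0, atol=1e-15
            )


class TestDegPerCelltype:
    def test_null_distributions_give_empty_table(self):
        ds = two_group_dataset(np.random.default_rng(1), 30, 15)
        tab = deg_per_celltype(ds, "A", alpha=0.05)
        assert len(tab) == 0

    def test_planted_shift_is_detected(self):
        ds = two_group_dataset(np.random.default_rng(2), 51, 20, shift_gene=0, shift=2.0)
        tab = deg_per_celltype(ds, "A", alpha=0.05)
        assert "G1" in tab.genes
        # effect sign convention: disease over control
        assert tab.table.set_index("gene").loc["G1", "effect"] > 0

    def test_alpha_one_returns_all_tested_genes(self):
        ds = two_group_dataset(np.random.default_rng(3), 20, 10)
        tab = deg_per_celltype(ds, "A", alpha=1.0, min_pct=0.0)
        assert len(tab) == 20

    def test_insufficient_cells_returns_empty_with_warning(self, caplog):
        ds = make_dataset(
            np.ones((3, 4)), ["A", "A", "A", "A"],
            ["disease", "control", "control", "control"],
        )
        tab = deg_per_celltype(ds, "A", min_cells=3)
        assert len(tab) == 0

    def test_invariant_to_cell_ordering(self):
        rng = np.random.default_rng(4)
        ds = two_group_dataset(rng, 40, 12, shift_gene=5, shift=1.5)
        perm = rng.permutation(ds.n_cells)
        shuffled = make_dataset(
            ds.counts[:, perm],
            list(ds.cell_meta["cell_type"].iloc[perm]),
            list(ds.cell_meta["condition"].iloc[perm]),
            gene_ids=list(ds.gene_ids),
            cell_ids=[ds.cell_ids[i] for i in perm],
        )
        t1 = deg_per_celltype(ds, "A", alpha=1.0, min_pct=0.0).table
        t2 = deg_per_celltype(shuffled, "A", alpha=1.0, min_pct=0.0).table
        assert (t1["gene"] == t2["gene"]).all()
        np.testing.assert_allclose(t1["p_value"], t2["p_value"])


class TestPseudoBulk:
    def test_single_cell_type_equals_per_type_table(self):
        ds = two_group_dataset(np.random.default_rng(5), 30, 12, shift_gene=2, shift=2.0)
        per = deg_per_celltype(ds, "A", alpha=1.0, min_pct=0.0).table
        bulk = pseudo_bulk_deg(ds, alpha=1.0, min_pct=0.0).table
        assert (per["gene"] == bulk["gene"]).all()
        np.testing.assert_allclose(per["p_value"], bulk["p_value"])

    def test_opposite_shifts_attenuate_pooled_effect(self):
        rng = np.random.default_rng(6)
        n = 15
        lam_a = np.full((10, 2 * n), 5.0)
        lam_b = np.full((10, 2 * n), 5.0)
        lam_a[0, :n] *= 4.0   # up in disease for type A
        lam_b[0, :n] /= 4.0   # down in disease for type B
        counts = np.concatenate([rng.poisson(lam_a), rng.poisson(lam_b)], axis=1)
        ds = make_dataset(
            counts,
            ["A"] * 2 * n + ["B"] * 2 * n,
            (["disease"] * n + ["control"] * n) * 2,
        )
        eff_a = deg_per_celltype(ds, "A", alpha=1.0, min_pct=0.0).table.set_index("gene").loc["G1", "effect"]
        eff_b = deg_per_celltype(ds, "B", alpha=1.0, min_pct=0.0).table.set_index("gene").loc["G1", "effect"]
        eff_bulk = pseudo_bulk_deg(ds, alpha=1.0, min_pct=0.0).table.set_index("gene").loc["G1", "effect"]
        assert abs(eff_bulk) < max(abs(eff_a), abs(eff_b))

    def test_empty_condition_rejected_at_construction(self):
        with pytest.raises(ValueError, match="disease"):
            make_dataset(np.ones((2, 2)), ["A", "A"], ["control", "control"])


class TestBaselines:
    def test_deg_count_ordering(self, small_bundle):
        data = small_bundle["data"]
        normalize_counts(data)
        tables = {ct: deg_per_celltype(data, ct) for ct in data.cell_types}
        base = baseline_rankings(data, tables).set_index("cell_type")
        best = base.sort_values("rank_by_degs").index[0]
        assert base.loc[best, "n_degs"] == base["n_degs"].max()

    def test_proportion_difference_arithmetic(self):
        # disease: A 8, B 1, C 1 / control: A 5, B 2.5, C 2.5 (scaled by 4)
        types = ["A"] * 8 + ["B"] + ["C"] + ["A"] * 10 + ["B"] * 5 + ["C"] * 5
        conds = ["disease"] * 10 + ["control"] * 20
        ds = make_dataset(np.ones((2, 30)), types, conds)
        base = baseline_rankings(ds, {}).set_index("cell_type")
        assert base.loc["A", "prop_diff"] == pytest.approx(0.3)
        assert base.sort_values("rank_by_prop").index[0] == "A"

    def test_equal_proportions_tie_break_alphabetical(self):
        types = ["A", "B", "A", "B"]
        conds = ["disease", "disease", "control", "control"]
        ds = make_dataset(np.ones((2, 4)), types, conds)
        base = baseline_rankings(ds, {}).set_index("cell_type")
        assert (base["prop_diff"] == 0).all()
        assert base.sort_values("rank_by_prop").index.tolist() == ["A", "B"]
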