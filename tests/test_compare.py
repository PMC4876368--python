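"""Effect sizes, edge categories, module-wise Spearman, shrinkage classes."""

import numpy as np
import pytest

from climenet import (
    ModulePartition,
    SubjectStack,
    categorize_edges,
    edge_effect_size,
    modulewise_spearman,
    shrinkage_comparison,
)


def _stack_from_edge(values, M=3, i=0, j=1, kind="full"):
    mats = []
    for v in values:
        m = np.eye(M)
        m[i, j] = m[j, i] = v
        mats.append(m)
    return SubjectStack(mats, kind=kind)


def _effect_matrix(values: np.ndarray):
    """EdgeEffectSizes with given symmetric effect values, mean_z = values."""
    from climenet.compare import EdgeEffectSizes

    v = np.asarray(values, dtype=float)
    v = (v + v.T) / 2
    out = v.copy()
    np.fill_diagonal(out, np.nan)
    return EdgeEffectSizes(values=out, mean_z=out.copy())


class TestEdgeEffectSize:
    def test_hand_computed_three_subject_case(self):
        # subject values 0.1, 0.2, 0.3 -> z = atanh -> mean/SD ~= 1.952
        es = edge_effect_size(_stack_from_edge([0.1, 0.2, 0.3]))
        z = np.arctanh([0.1, 0.2, 0.3])
        expected = z.mean() / z.std(ddof=1)
        assert es.values[0, 1] == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(1.952, abs=2e-3)

    def test_identical_values_give_missing_effect(self):
        with pytest.warns(UserWarning, match="zero variance"):
            es = edge_effect_size(_stack_from_edge([0.4, 0.4, 0.4]))
        assert np.isnan(es.values[0, 1])

    def test_symmetric_values_give_zero_effect(self):
        es = edge_effect_size(_stack_from_edge([-0.3, 0.3]))
        assert es.values[0, 1] == pytest.approx(0.0, abs=1e-15)

    def test_values_at_one_rejected(self):
        with pytest.raises(ValueError, match="Fisher"):
            edge_effect_size(_stack_from_edge([0.5, 1.0]))

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError, match="2 subjects"):
            SubjectStack([np.eye(3)])


class TestCategorizeEdges:
    def test_identical_inputs_only_C_and_D(self):
        es = _effect_matrix(np.array([[0, 0.8, 0.1],
                                      [0.8, 0, 0.2],
                                      [0.1, 0.2, 0]]))
        table = categorize_edges(es, es, threshold=0.5)
        assert table.proportions["A"] == 0 and table.proportions["B"] == 0
        assert table.proportions["C"] == pytest.approx(1 / 3)
        assert table.proportions["D"] == pytest.approx(2 / 3)

    def test_full_only_edge_is_category_B(self):
        full = _effect_matrix(np.array([[0, 0.6], [0.6, 0]]))
        partial = _effect_matrix(np.array([[0, 0.1], [0.1, 0]]))
        table = categorize_edges(full, partial, threshold=0.5)
        assert table.category[0, 1] == "B"

    def test_proportions_sum_to_one(self):
        rng = np.random.default_rng(0)
        full = _effect_matrix(rng.normal(size=(6, 6)))
        partial = _effect_matrix(rng.normal(size=(6, 6)))
        table = categorize_edges(full, partial, threshold=0.5)
        assert sum(table.proportions.values()) == pytest.approx(1.0, abs=1e-12)

    def test_swap_symmetry_relabels_A_and_B(self):
        rng = np.random.default_rng(1)
        full = _effect_matrix(rng.normal(size=(8, 8)))
        partial = _effect_matrix(rng.normal(size=(8, 8)))
        t1 = categorize_edges(full, partial, 0.5)
        t2 = categorize_edges(partial, full, 0.5)
        assert t1.proportions["A"] == t2.proportions["B"]
        assert t1.proportions["B"] == t2.proportions["A"]
        assert t1.proportions["C"] == t2.proportions["C"]

    def test_mixed_sign_category_C_counts_as_inconsistent(self):
        # both significant but with opposite signs: category C, sign-inconsistent
        full = _effect_matrix(np.array([[0, 0.9], [0.9, 0]]))
        partial = _effect_matrix(np.array([[0, -0.9], [-0.9, 0]]))
        table = categorize_edges(full, partial, 0.5)
        assert table.category[0, 1] == "C"
        assert table.sign_consistency["C"] == 0.0

    def test_missing_effects_excluded_and_counted(self):
        full = _effect_matrix(np.array([[0, 0.6, 0.2],
                                        [0.6, 0, np.nan],
                                        [0.2, np.nan, 0]]))
        partial = _effect_matrix(np.full((3, 3), 0.1))
        table = categorize_edges(full, partial, 0.5)
        assert table.n_classified == 2 and table.n_excluded == 1


class TestModulewiseSpearman:
    def test_ten_module_partition_yields_55_blocks(self):
        M = 30
        labels = [f"mod{k % 10}" for k in range(M)]
        part = ModulePartition(labels)
        rng = np.random.default_rng(2)
        A = rng.normal(size=(M, M))
        A = (A + A.T) / 2
        B = rng.normal(size=(M, M))
        B = (B + B.T) / 2
        res = modulewise_spearman(A, B, part)
        assert len(res["blocks"]) == 55
        assert res["blocks"]["within"].sum() == 10

    def test_monotone_transform_gives_rho_one(self):
        M = 8
        part = ModulePartition(["a"] * 4 + ["b"] * 4)
        rng = np.random.default_rng(3)
        A = rng.normal(size=(M, M))
        A = (A + A.T) / 2
        B = np.exp(A)  # strictly monotone transform
        res = modulewise_spearman(A, B, part)
        assert np.allclose(res["blocks"]["rho"].dropna(), 1.0)

    def test_sign_flip_gives_rho_minus_one(self):
        M = 6
        part = ModulePartition(["a"] * 6)
        rng = np.random.default_rng(4)
        A = rng.normal(size=(M, M))
        A = (A + A.T) / 2
        res = modulewise_spearman(A, -A, part)
        assert res["blocks"]["rho"].iloc[0] == pytest.approx(-1.0)

    def test_tiny_block_reported_missing(self):
        part = ModulePartition(["a", "a", "b"])  # within-a has 1 edge only
        A = np.zeros((3, 3))
        res = modulewise_spearman(A, A, part)
        blk = res["blocks"]
        row = blk[(blk.module_a == "a") & (blk.module_b == "a")].iloc[0]
        assert np.isnan(row["rho"]) and row["note"] == "fewer than 3 edges"

    def test_within_vs_between_pvalue_present(self):
        M = 20
        labels = ["a"] * 5 + ["b"] * 5 + ["c"] * 5 + ["d"] * 5
        rng = np.random.default_rng(5)
        base = rng.normal(size=(M, M))
        base = (base + base.T) / 2
        noisy = base + 0.5 * rng.normal(size=(M, M))
        res = modulewise_spearman(base, (noisy + noisy.T) / 2,
                                  ModulePartition(labels))
        assert 0.0 <= res["p_value"] <= 1.0


class TestShrinkageComparison:
    def test_identical_inputs_full_retention(self):
        es = _effect_matrix(np.array([[0, 0.7, -0.4],
                                      [0.7, 0, 0.1],
                                      [-0.4, 0.1, 0]]))
        res = shrinkage_comparison(es, es)
        for cls, kept in res["retention"].items():
            if not np.isnan(kept):
                assert kept == 1.0

    def test_halved_effects_cross_class_boundaries(self):
        vals = np.array([[0, 0.8, 0.4], [0.8, 0, -0.6], [0.4, -0.6, 0]])
        loose = _effect_matrix(vals)
        tight = _effect_matrix(vals * 0.5)
        res = shrinkage_comparison(loose, tight)
        # 0.8 -> 0.4: significant positive lost; -0.6 -> -0.3: negative lost
        assert res["retention"]["significant_positive"] == 0.0
        assert res["retention"]["significant_negative"] == 0.0

    def test_single_moderate_negative_edge_lost(self):
        loose = _effect_matrix(np.array([[0, -0.4], [-0.4, 0]]))
        tight = _effect_matrix(np.array([[0, -0.05], [-0.05, 0]]))
        res = shrinkage_comparison(loose, tight)
        assert res["transitions"].loc["moderate_negative", "null"] == 1
        assert res["retention"]["moderate_negative"] == 0.0
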