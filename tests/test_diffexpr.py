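import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from memtype import diffexpr
from memtype.diffexpr import DEGCriteria, bh_adjust, call_direction, compute_contrast
from tests.conftest import reference_bh


def brute_force_permutation_p(vals_a, vals_b, pseudocount=1.0):
    """Independent oracle: enumerate every choice of group-A labels."""
    la = [math.log2(v + pseudocount) for v in vals_a]
    lb = [math.log2(v + pseudocount) for v in vals_b]
    pooled = la + lb
    n_a = len(la)
    obs = abs(sum(lb) / len(lb) - sum(la) / n_a)
    hits = total = 0
    for idx in combinations(range(len(pooled)), n_a):
        a = [pooled[i] for i in idx]
        b = [pooled[i] for i in range(len(pooled)) if i not in idx]
        stat = abs(sum(b) / len(b) - sum(a) / len(a))
        hits += stat >= obs - 1e-12
        total += 1
    return hits / total


def make_design(fpkm_by_condition, n_reps=None):
    """Matrix/sheet from {condition: genes×reps FPKM array}."""
    conditions = list(fpkm_by_condition)
    arrays = {c: np.atleast_2d(np.asarray(v, float)) for c, v in
              fpkm_by_condition.items()}
    sheet = pd.DataFrame(
        [(f"{c}_{r}", c, r) for c in conditions
         for r in range(1, arrays[c].shape[1] + 1)],
        columns=["sample_id", "condition", "replicate"])
    data = {}
    for c in conditions:
        for r in range(arrays[c].shape[1]):
            data[f"{c}_{r + 1}"] = arrays[c][:, r]
    n_genes = len(next(iter(data.values())))
    index = pd.Index([f"g{i}" for i in range(n_genes)], name="gene_id")
    return pd.DataFrame(data, index=index), sheet


class TestFoldChange:
    def test_pseudocount_arithmetic(self):
        matrix, sheet = make_design({"A": [[10, 10]], "B": [[40, 40]]})
        table = compute_contrast(matrix, sheet, "A", "B")
        assert table["log2fc"].iloc[0] == pytest.approx(math.log2(41 / 11))

    def test_null_case_fc_zero_p_one(self):
        matrix, sheet = make_design({"A": [[7, 7]], "B": [[7, 7]]})
        table = compute_contrast(matrix, sheet, "A", "B", method="permutation")
        assert table["log2fc"].iloc[0] == 0.0
        assert table["p_value"].iloc[0] == 1.0

    def test_condition_absent_is_hard_error(self):
        matrix, sheet = make_design({"A": [[1, 2]], "B": [[3, 4]]})
        with pytest.raises(ValueError, match="ZZ"):
            compute_contrast(matrix, sheet, "A", "ZZ")

    def test_single_replicate_instructs_precomputed(self):
        matrix, sheet = make_design({"A": [[1]], "B": [[3]]})
        with pytest.raises(ValueError, match="precomputed"):
            compute_contrast(matrix, sheet, "A", "B", method="permutation")


class TestPermutationTest:
    def test_two_plus_two_matches_full_enumeration(self):
        rng = np.random.default_rng(42)
        genes = rng.gamma(2.0, 10.0, size=(25, 4))
        matrix, sheet = make_design({"A": genes[:, :2], "B": genes[:, 2:]})
        table = compute_contrast(matrix, sheet, "A", "B", method="permutation")
        for i in range(len(genes)):
            expected = brute_force_permutation_p(genes[i, :2], genes[i, 2:])
            assert table["p_value"].iloc[i] == pytest.approx(expected)

    def test_three_plus_three_matches_full_enumeration(self):
        rng = np.random.default_rng(3)
        genes = rng.gamma(2.0, 10.0, size=(10, 6))
        matrix, sheet = make_design({"A": genes[:, :3], "B": genes[:, 3:]})
        table = compute_contrast(matrix, sheet, "A", "B", method="permutation")
        for i in range(len(genes)):
            expected = brute_force_permutation_p(genes[i, :3], genes[i, 3:])
            assert table["p_value"].iloc[i] == pytest.approx(expected)

    def test_monte_carlo_agrees_with_exact_within_3se(self):
        # 6+6 replicates exceeds the 10-sample enumeration cut-off, so the
        # implementation goes Monte-Carlo; the oracle still enumerates.
        rng = np.random.default_rng(5)
        genes = np.abs(rng.normal(20, 6, size=(6, 12)))
        genes[:3, 6:] *= 2.0  # some genuine shifts
        matrix, sheet = make_design({"A": genes[:, :6], "B": genes[:, 6:]})
        table = compute_contrast(matrix, sheet, "A", "B", method="permutation",
                                 seed=123, n_permutations=10_000)
        for i in range(len(genes)):
            exact = brute_force_permutation_p(genes[i, :6], genes[i, 6:])
            se = math.sqrt(max(exact * (1 - exact), 1e-6) / 10_000)
            assert abs(table["p_value"].iloc[i] - exact) <= 3 * se + 2e-4


class TestPooledTest:
    def test_zero_variance_degenerates_to_indicator(self):
        matrix, sheet = make_design({"A": [[4, 4], [9, 9]],
                                     "B": [[32, 32], [9, 9]]})
        table = compute_contrast(matrix, sheet, "A", "B", method="pooled")
        assert table["p_value"].tolist() == [0.0, 1.0]

    def test_matches_hand_computed_z(self):
        vals = {"A": [[8, 12], [10, 10]], "B": [[30, 50], [11, 9]]}
        matrix, sheet = make_design(vals)
        table = compute_contrast(matrix, sheet, "A", "B", method="pooled")
        log = np.log2(matrix.to_numpy() + 1.0)
        resid = log - np.repeat(log.reshape(2, 2, 2).mean(axis=2), 2, axis=1) \
            .reshape(2, 4)
        var = (resid ** 2).sum() / (2 * 2 * (2 - 1))
        diff = log[:, 2:].mean(axis=1) - log[:, :2].mean(axis=1)
        from scipy.stats import norm
        expected = 2 * norm.sf(np.abs(diff) / np.sqrt(var))
        np.testing.assert_allclose(table["p_value"], expected, rtol=1e-12)


class TestExpressedMean:
    def test_worked_example(self):
        matrix, sheet = make_design({"A": [[0, 0], [10, 10], [20, 20]],
                                     "B": [[5, 5], [0, 0], [1, 1]]})
        # all genes expressed somewhere; mean over {0, 10, 20} in A
        assert diffexpr.expressed_mean(matrix, sheet, "A") == pytest.approx(10.0)

    def test_never_expressed_gene_excluded(self):
        matrix, sheet = make_design({"A": [[0, 0], [10, 10]],
                                     "B": [[0, 0], [30, 30]]})
        assert diffexpr.expressed_mean(matrix, sheet, "A") == pytest.approx(10.0)

    def test_all_zero_matrix_is_hard_error(self):
        matrix, sheet = make_design({"A": [[0, 0]], "B": [[0, 0]]})
        with pytest.raises(ValueError, match="expressed"):
            diffexpr.expressed_mean(matrix, sheet, "A")

    def test_matches_direct_recomputation(self, noisy_sim):
        matrix, sheet, _ = noisy_sim
        for condition in ("C1", "D1", "D2"):
            cols = sheet.loc[sheet["condition"] == condition, "sample_id"]
            by_cond = {
                c: matrix[sheet.loc[sheet["condition"] == c, "sample_id"]]
                .mean(axis=1)
                for c in sheet["condition"].unique()
            }
            expressed = pd.concat(by_cond, axis=1).gt(0).any(axis=1)
            direct = matrix.loc[expressed, cols].mean(axis=1).mean()
            assert diffexpr.expressed_mean(matrix, sheet, condition) \
                == pytest.approx(direct, rel=1e-12)


class TestBenjaminiHochberg:
    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=60))
    def test_agrees_with_reference_implementation(self, p):
        np.testing.assert_allclose(bh_adjust(p), reference_bh(p), atol=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=2,
                    max_size=40))
    def test_preserves_p_order(self, p):
        q = bh_adjust(p)
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-15).all()


class TestCallDirection:
    @staticmethod
    def row(log2fc, q, mean_a=50.0, mean_b=50.0):
        return pd.DataFrame({"gene_id": ["g"], "log2fc": [log2fc],
                             "p_value": [q], "q_value": [q],
                             "mean_fpkm_a": [mean_a], "mean_fpkm_b": [mean_b]})

    @pytest.mark.parametrize("log2fc,q,mean_a,mean_b,expected", [
        (1.0, 0.05, 50.0, 50.0, "+"),      # every threshold inclusive
        (-1.0, 0.05, 50.0, 50.0, "-"),
        (2.0, 0.01, 50.0, 1.0, "="),       # floor filter fails on stress side
        (-1.5, 0.001, 50.0, 50.0, "-"),
        (0.9, 0.001, 50.0, 50.0, "="),     # fold change short of threshold
        (3.0, 0.051, 50.0, 50.0, "="),     # q beyond threshold
    ])
    def test_three_part_criterion(self, log2fc, q, mean_a, mean_b, expected):
        criteria = DEGCriteria()
        called = call_direction(self.row(log2fc, q, mean_a, mean_b),
                                criteria, floor_value_up=10.0,
                                floor_value_down=10.0)
        assert called["call"].iloc[0] == expected

    def test_floor_fraction_example(self):
        # stress-side mean at 10% of the expressed mean, floor demands 20%
        criteria = DEGCriteria()
        expressed_mean_value = 100.0
        called = call_direction(
            self.row(2.0, 0.01, mean_a=50.0, mean_b=10.0), criteria,
            floor_value_up=criteria.floor_fraction * expressed_mean_value,
            floor_value_down=criteria.floor_fraction * expressed_mean_value)
        assert called["call"].iloc[0] == "="

    def test_unset_q_is_hard_error(self):
        table = self.row(2.0, 0.01)
        table["q_value"] = np.nan
        with pytest.raises(ValueError, match="q_value"):
            call_direction(table, DEGCriteria(), 1.0, 1.0)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.floats(min_value=1e-6, max_value=0.05),
           st.floats(min_value=1.0, max_value=4.0))
    def test_monotone_in_thresholds(self, tighter_q, higher_fc):
        """Tightening q or raising the fc threshold never creates a call."""
        rng = np.random.default_rng(0)
        table = pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(50)],
            "log2fc": rng.normal(0, 2, 50),
            "p_value": rng.uniform(0, 1, 50),
            "q_value": rng.uniform(0, 1, 50),
            "mean_fpkm_a": rng.uniform(0, 100, 50),
            "mean_fpkm_b": rng.uniform(0, 100, 50),
        })
        base = call_direction(table, DEGCriteria(), 5.0, 5.0)["call"]
        tight = call_direction(
            table, DEGCriteria(q_threshold=tighter_q, fc_threshold=higher_fc),
            5.0, 5.0)["call"]
        flipped = (base == "=") & (tight != "=")
        assert not flipped.any()


def test_gene_order_permutation_invariance(noisy_sim):
    matrix, sheet, _ = noisy_sim
    table = compute_contrast(matrix, sheet, "C1", "D1")
    shuffled = compute_contrast(matrix.sample(frac=1, random_state=1),
                                sheet, "C1", "D1")
    merged = table.set_index("gene_id").join(
        shuffled.set_index("gene_id"), lsuffix="_a", rsuffix="_b")
    for col in ("log2fc", "p_value", "q_value", "mean_fpkm_a", "mean_fpkm_b"):
        np.testing.assert_allclose(merged[f"{col}_a"], merged[f"{col}_b"],
                                   rtol=1e-9)


def test_precomputed_mode_ingests_table_and_fills_means(tiny_design):
    matrix, sheet = tiny_design
    pre = pd.DataFrame({"gene_id": ["g1", "g2", "g3"],
                        "log2fc": [2.0, 0.0, -1.0],
                        "p_value": [0.001, 0.9, 0.04]})
    table = compute_contrast(matrix, sheet, "C1", "D1", method="precomputed",
                             precomputed=pre)
    np.testing.assert_allclose(table["log2fc"], pre["log2fc"])
    np.testing.assert_allclose(table["q_value"], reference_bh(pre["p_value"]))
    assert table["mean_fpkm_a"].tolist() == [10.0, 20.0, 0.0]
    assert table["mean_fpkm_b"].tolist() == [40.0, 20.0, 0.0]
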