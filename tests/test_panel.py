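"""RPM normalization, two-group comparison, Z-scores, intersection."""

import numpy as np
import pandas as pd
import pytest

from npforge.panel import (compare_groups, compute_rpm, intersect_regulated,
                           zscore_matrix)
from oracles import pooled_t_statistic


def _design(samples_a, samples_b, sex="female"):
    rows = [{"sample_id": s, "group": "normal", "sex": sex} for s in samples_a]
    rows += [{"sample_id": s, "group": "csm", "sex": sex} for s in samples_b]
    return pd.DataFrame(rows).set_index("sample_id", drop=False)


class TestRpm:
    def test_single_gene_takes_whole_million(self):
        counts = pd.DataFrame({"s1": [10]}, index=["g1"])
        assert compute_rpm(counts).iloc[0, 0] == pytest.approx(1e6)

    def test_columns_sum_to_one_million(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.integers(0, 500, size=(50, 4)),
                              index=[f"g{i}" for i in range(50)],
                              columns=list("abcd"))
        rpm = compute_rpm(counts)
        assert np.allclose(rpm.sum(axis=0), 1e6, rtol=1e-6)

    def test_matches_per_column_arithmetic_oracle(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(rng.integers(0, 100, size=(20, 3)),
                              index=[f"g{i}" for i in range(20)],
                              columns=list("xyz"))
        rpm = compute_rpm(counts, pseudocount=1.0)
        for col in counts.columns:
            shifted = counts[col].to_numpy() + 1.0
            expected = shifted * 1e6 / shifted.sum()
            assert np.allclose(rpm[col].to_numpy(), expected)

    def test_preserves_within_column_rank_order(self):
        rng = np.random.default_rng(2)
        counts = pd.DataFrame(rng.integers(0, 1000, size=(30, 2)),
                              index=[f"g{i}" for i in range(30)],
                              columns=["a", "b"])
        rpm = compute_rpm(counts)
        for col in counts.columns:
            assert (counts[col].rank(method="average")
                    == rpm[col].rank(method="average")).all()

    def test_zero_count_column_rejected(self):
        counts = pd.DataFrame({"s1": [0, 0]}, index=["g1", "g2"])
        with pytest.raises(ValueError, match="zero-count"):
            compute_rpm(counts)

    def test_negative_counts_rejected(self):
        counts = pd.DataFrame({"s1": [5, -1]}, index=["g1", "g2"])
        with pytest.raises(ValueError, match="non-negative"):
            compute_rpm(counts)


class TestCompareGroups:
    def test_identical_groups_are_null(self):
        rpm = pd.DataFrame([[10.0, 10.0, 10.0, 10.0, 10.0, 10.0]],
                           index=["g1"],
                           columns=["a1", "a2", "a3", "b1", "b2", "b3"])
        design = _design(["a1", "a2", "a3"], ["b1", "b2", "b3"])
        cmp = compare_groups(rpm, design, "normal", "csm")
        row = cmp.loc["g1"]
        assert row["t_stat"] == 0.0 and row["p_value"] == 1.0
        assert row["fold_change"] == 1.0 and row["direction"] == "ns"

    def test_matches_textbook_pooled_formula(self):
        xs, ys = [10.0, 10.5, 9.5, 10.0], [2.0, 2.0, 3.0]
        rpm = pd.DataFrame([xs + ys], index=["g1"],
                           columns=["a1", "a2", "a3", "a4", "b1", "b2", "b3"])
        design = _design(["a1", "a2", "a3", "a4"], ["b1", "b2", "b3"])
        cmp = compare_groups(rpm, design, "normal", "csm")
        t_expected, p_expected = pooled_t_statistic(xs, ys)
        assert cmp.loc["g1", "t_stat"] == pytest.approx(t_expected)
        assert cmp.loc["g1", "p_value"] == pytest.approx(p_expected)
        assert cmp.loc["g1", "direction"] == "down"
        assert cmp.loc["g1", "se_b"] == pytest.approx(
            np.std(ys, ddof=1) / np.sqrt(3))

    def test_relabeling_flips_t_keeps_p(self):
        rng = np.random.default_rng(3)
        rpm = pd.DataFrame(rng.uniform(1, 100, size=(25, 7)),
                           index=[f"g{i}" for i in range(25)],
                           columns=["a1", "a2", "a3", "a4", "b1", "b2", "b3"])
        design = _design(["a1", "a2", "a3", "a4"], ["b1", "b2", "b3"])
        ab = compare_groups(rpm, design, "normal", "csm")
        ba = compare_groups(rpm, design, "csm", "normal")
        assert np.allclose(ab["p_value"], ba["p_value"])
        assert np.allclose(ab["t_stat"], -ba["t_stat"])
        assert np.allclose(ab["fold_change"], 1 / ba["fold_change"])

    def test_small_groups_rejected(self):
        rpm = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g"],
                           columns=["a1", "b1", "b2"])
        design = _design(["a1"], ["b1", "b2"])
        with pytest.raises(ValueError, match=">= 2 samples"):
            compare_groups(rpm, design, "normal", "csm")

    def test_significance_tiers(self):
        rng = np.random.default_rng(4)
        base = rng.normal(100, 2, size=4)
        rpm = pd.DataFrame([list(base) + list(base[:3] / 4 + rng.normal(0, 0.5, 3))],
                           index=["g1"],
                           columns=["a1", "a2", "a3", "a4", "b1", "b2", "b3"])
        design = _design(["a1", "a2", "a3", "a4"], ["b1", "b2", "b3"])
        cmp = compare_groups(rpm, design, "normal", "csm")
        assert cmp.loc["g1", "p_value"] < 0.01
        assert cmp.loc["g1", "significance"] == "**"


class TestZscore:
    def test_rows_standardised(self):
        rng = np.random.default_rng(5)
        rpm = pd.DataFrame(rng.uniform(1, 50, size=(10, 6)),
                           index=[f"g{i}" for i in range(10)],
                           columns=[f"s{i}" for i in range(6)])
        z = zscore_matrix(rpm)
        assert np.allclose(z.mean(axis=1), 0.0, atol=1e-9)
        assert np.allclose(z.std(axis=1, ddof=1), 1.0, atol=1e-9)

    def test_two_sample_row_arithmetic(self):
        rpm = pd.DataFrame([[2.0, 4.0]], index=["g"], columns=["a", "b"])
        z = zscore_matrix(rpm)
        s = 1.0 / np.sqrt(2.0)  # (x - mean) / sd with sd = sqrt(2)
        assert np.allclose(z.values, [[-s, s]])

    def test_constant_gene_dropped(self, caplog):
        rpm = pd.DataFrame([[3.0, 3.0, 3.0], [1.0, 2.0, 3.0]],
                           index=["flat", "var"], columns=list("abc"))
        with caplog.at_level("INFO", logger="npforge.panel"):
            z = zscore_matrix(rpm)
        assert list(z.index) == ["var"]
        assert any("flat" in r.message for r in caplog.records)


class TestIntersect:
    @staticmethod
    def _cmp(genes, pvals, folds):
        return pd.DataFrame({"p_value": pvals, "fold_change": folds},
                            index=genes)

    def test_disjoint_significant_sets_intersect_empty(self):
        genes = ["g1", "g2"]
        a = self._cmp(genes, [0.01, 0.9], [0.3, 0.3])
        b = self._cmp(genes, [0.9, 0.01], [0.3, 0.3])
        assert intersect_regulated(a, b, "down") == []

    def test_shared_down_gene_found(self):
        genes = ["g1", "g2", "g3"]
        a = self._cmp(genes, [0.01, 0.01, 0.2], [0.3, 3.0, 0.3])
        b = self._cmp(genes, [0.04, 0.01, 0.01], [0.5, 4.0, 0.2])
        assert intersect_regulated(a, b, "down") == ["g1"]
        assert intersect_regulated(a, b, "up") == ["g2"]

    def test_mismatched_universe_rejected(self):
        a = self._cmp(["g1"], [0.01], [0.3])
        b = self._cmp(["g2"], [0.01], [0.3])
        with pytest.raises(ValueError, match="universe"):
            intersect_regulated(a, b, "down")
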