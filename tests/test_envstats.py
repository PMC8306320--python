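"""Normality screening, Pearson correlation tables, keystone-environment
networks and ANOVA/LSD against hand computations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rivernet.envstats import (
    correlate,
    correlation_matrix,
    edge_sign_ratio,
    group_compare,
    keystone_env_network,
    normality_transform,
)
from rivernet.synth import PlantedDesign, generate_env_table, generate_planted_counts


class TestNormalityTransform:
    def test_normal_variable_untransformed(self):
        rng = np.random.default_rng(1)
        table = pd.DataFrame({"x": rng.standard_normal(60)})
        out, report = normality_transform(table)
        assert not report.loc["x", "transformed"]
        pd.testing.assert_series_equal(out["x"], table["x"])

    def test_lognormal_flagged_and_fixed(self):
        rng = np.random.default_rng(2)
        table = pd.DataFrame({"x": np.exp(rng.standard_normal(60) * 1.5)})
        out, report = normality_transform(table)
        assert report.loc["x", "transformed"]
        _, p_after = stats.shapiro(out["x"])
        assert p_after >= 0.05

    def test_zeros_get_shift(self):
        rng = np.random.default_rng(3)
        x = np.exp(rng.standard_normal(60) * 2)
        x[0] = 0.0
        out, report = normality_transform(pd.DataFrame({"x": x}))
        assert report.loc["x", "shift"] > 0
        assert np.isfinite(out["x"]).all()

    def test_constant_variable_skipped(self):
        table = pd.DataFrame({"c": np.full(20, 3.0)})
        out, report = normality_transform(table)
        assert not report.loc["c", "transformed"]
        assert (out["c"] == 3.0).all()


class TestCorrelate:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame({"x": rng.standard_normal(20)})
        long = correlate(df, df)
        assert long.loc[0, "r"] == pytest.approx(1.0)

    def test_hand_computed_five_points(self):
        """Closed-form Pearson on a 5-point table."""
        left = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0, 5.0]})
        right = pd.DataFrame({"b": [2.0, 1.0, 4.0, 3.0, 6.0]})
        long = correlate(left, right)
        x, y = left["a"], right["b"]
        r_hand = (((x - x.mean()) * (y - y.mean())).sum()
                  / np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()))
        assert long.loc[0, "r"] == pytest.approx(r_hand, abs=1e-12)

    def test_symmetry(self):
        rng = np.random.default_rng(5)
        a = pd.DataFrame(rng.standard_normal((15, 2)), columns=["u", "v"])
        b = pd.DataFrame(rng.standard_normal((15, 2)), columns=["x", "y"])
        ab = correlation_matrix(correlate(a, b))
        ba = correlation_matrix(correlate(b, a))
        pd.testing.assert_frame_equal(ab, ba.T, check_names=False)

    def test_pairwise_deletion_is_local(self):
        """Removing a missing-value row only changes cells involving it."""
        rng = np.random.default_rng(6)
        left = pd.DataFrame(rng.standard_normal((12, 2)), columns=["a", "b"])
        right = pd.DataFrame(rng.standard_normal((12, 2)), columns=["x", "y"])
        right_missing = right.copy()
        right_missing.loc[0, "x"] = np.nan
        full = correlate(left, right).set_index(["row", "column"])
        part = correlate(left, right_missing).set_index(["row", "column"])
        # cells not involving x are identical
        for key in [("a", "y"), ("b", "y")]:
            assert part.loc[key, "r"] == pytest.approx(full.loc[key, "r"], abs=1e-12)
        assert part.loc[("a", "x"), "n"] == 11

    def test_small_n_cells_empty(self):
        left = pd.DataFrame({"a": [1.0, 2.0, np.nan, np.nan]})
        right = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0]})
        long = correlate(left, right)
        assert np.isnan(long.loc[0, "r"]) and not long.loc[0, "significant"]

    def test_planted_block_env_cell_significant(self):
        matrix = generate_planted_counts(PlantedDesign(seed=0))
        env = generate_env_table(matrix, 0, 0.9, ["DOC"], seed=1, n_noise_vars=1)
        member = matrix.attrs["block_membership"]
        block = [t for t, b in member.items() if b == 0]
        block_mean = matrix.relative_abundance()[block].mean(axis=1).to_frame("block1")
        long = correlate(block_mean, env).set_index("column")
        assert long.loc["DOC", "significant"] and long.loc["DOC", "r"] > 0.5
        assert not long.loc["noise1", "significant"] or abs(long.loc["noise1", "r"]) < 0.4


class TestKeystoneEnvNetwork:
    def test_no_keystones_empty(self, planted_matrix):
        env = generate_env_table(planted_matrix, 0, 0.9, ["DOC"], seed=1)
        net = keystone_env_network([], planted_matrix, env)
        assert net.n_edges == 0

    def test_planted_association_found(self, planted_matrix):
        env = generate_env_table(planted_matrix, 0, 0.95, ["DOC"], seed=2, n_noise_vars=2)
        member = planted_matrix.attrs["block_membership"]
        block = [t for t, b in member.items() if b == 0]
        net = keystone_env_network(block, planted_matrix, env, r_min=0.6, alpha=0.01)
        doc_edges = [e for e in net.graph.edges if "DOC" in e]
        assert len(doc_edges) > 0
        noise_edges = [e for e in net.graph.edges if "noise1" in e or "noise2" in e]
        assert not noise_edges

    def test_edge_signs_match_correlation(self, planted_matrix):
        env = generate_env_table(planted_matrix, 0, -0.9, ["As"], seed=3)
        member = planted_matrix.attrs["block_membership"]
        block = [t for t, b in member.items() if b == 0]
        net = keystone_env_network(block, planted_matrix, env, r_min=0.5, alpha=0.05)
        for u, v, d in net.graph.edges(data=True):
            assert d["sign"] == np.sign(d["correlation"])
        ratio = edge_sign_ratio(net)
        assert ratio["negative"] + ratio["positive"] == net.n_edges


class TestGroupCompare:
    def test_identical_groups_f_near_zero(self):
        y = pd.Series([1.0, 2.0, 3.0] * 3)
        g = pd.Series(["a"] * 3 + ["b"] * 3 + ["c"] * 3)
        out = group_compare(y, g)
        assert out["F"] == pytest.approx(0.0, abs=1e-12)
        assert out["p"] == pytest.approx(1.0)

    def test_large_shift_detected(self):
        rng = np.random.default_rng(7)
        a = rng.standard_normal(10)
        b = rng.standard_normal(10) + 5.0
        out = group_compare(pd.Series(np.r_[a, b]), pd.Series(["a"] * 10 + ["b"] * 10))
        assert out["p"] < 0.001

    def test_two_group_lsd_equals_pooled_t(self):
        rng = np.random.default_rng(8)
        a = rng.standard_normal(8)
        b = rng.standard_normal(12) + 0.7
        out = group_compare(pd.Series(np.r_[a, b]), pd.Series(["a"] * 8 + ["b"] * 12))
        t_ref, p_ref = stats.ttest_ind(a, b, equal_var=True)
        assert out["pairwise"].loc[0, "p"] == pytest.approx(p_ref, abs=1e-12)
        assert out["p"] == pytest.approx(p_ref, abs=1e-10)  # F = t^2 for 2 groups

    def test_textbook_three_group_anova(self):
        """Hand-computed sums of squares for a small balanced design."""
        data = {"a": [4.0, 5.0, 6.0], "b": [6.0, 7.0, 8.0], "c": [8.0, 9.0, 10.0]}
        y = pd.Series(sum(data.values(), []))
        g = pd.Series(sum(([k] * 3 for k in data), []))
        out = group_compare(y, g)
        # grand mean 7; SSB = 3[(5-7)^2+(7-7)^2+(9-7)^2] = 24; SSW = 6;
        # F = (24/2)/(6/6) = 12
        assert out["F"] == pytest.approx(12.0, abs=1e-10)
        assert out["mse"] == pytest.approx(1.0, abs=1e-12)

    def test_singleton_group_excluded(self):
        y = pd.Series([1.0, 2.0, 3.0, 4.0, 10.0])
        g = pd.Series(["a", "a", "b", "b", "c"])
        out = group_compare(y, g)
        pairs = set(map(tuple, out["pairwise"][["group_a", "group_b"]].values))
        assert pairs == {("a", "b")}

    def test_single_usable_group_rejected(self):
        y = pd.Series([1.0, 2.0, 5.0])
        g = pd.Series(["a", "a", "b"])
        with pytest.raises(ValueError, match="2 groups"):
            group_compare(y, g)
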