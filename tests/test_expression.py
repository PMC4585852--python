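import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from riborestore import expression
from riborestore.config import ExpressionParams


def _flags(matrix, **overrides):
    shape = matrix.shape
    base = {
        "above_background": pd.DataFrame(np.ones(shape, bool),
                                         index=matrix.index, columns=matrix.columns),
        "good_spot": pd.DataFrame(np.ones(shape, bool),
                                  index=matrix.index, columns=matrix.columns),
        "saturated": pd.DataFrame(np.zeros(shape, bool),
                                  index=matrix.index, columns=matrix.columns),
        "outlier": pd.DataFrame(np.zeros(shape, bool),
                                index=matrix.index, columns=matrix.columns),
    }
    base.update(overrides)
    return base


class TestFilterProbes:
    def test_above_background_quorum(self):
        m = pd.DataFrame(np.ones((1, 13)), index=["g"],
                         columns=[f"s{i}" for i in range(13)])
        flags = _flags(m)
        flags["above_background"].iloc[0, 4:] = False  # 4/13 = 30.8% above
        assert list(expression.filter_probes(m, flags).index) == ["g"]
        flags["above_background"].iloc[0, 3:] = False  # 3/13 = 23.1%
        assert len(expression.filter_probes(m, flags)) == 0

    def test_one_saturated_sample_removes_gene(self):
        m = pd.DataFrame(np.ones((2, 4)), index=["g1", "g2"],
                         columns=list("abcd"))
        flags = _flags(m)
        flags["saturated"].loc["g1", "b"] = True
        assert list(expression.filter_probes(m, flags).index) == ["g2"]

    def test_duplicate_probes_median_summarized(self):
        m = pd.DataFrame([[1.0], [2.0], [9.0]], index=["g", "g", "g"],
                         columns=["s"])
        out = expression.filter_probes(m, _flags(m))
        assert out.loc["g", "s"] == 2.0

    def test_bad_fraction_errors(self):
        m = pd.DataFrame([[1.0]], index=["g"], columns=["s"])
        with pytest.raises(ValueError):
            expression.filter_probes(m, _flags(m), above_background_frac=1.5)


class TestQuantileNormalization:
    def test_mean_of_order_statistics(self):
        m = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]})
        out = expression.normalize_quantile(m)
        assert np.allclose(out["a"], [2.5, 3.5, 4.5])
        assert np.allclose(out["b"], [2.5, 3.5, 4.5])

    def test_identical_samples_unchanged(self):
        m = pd.DataFrame({"a": [3.0, 1.0, 2.0], "b": [3.0, 1.0, 2.0]})
        out = expression.normalize_quantile(m)
        assert np.allclose(out, m)

    def test_sorted_columns_identical_after(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.normal(size=(50, 4)) + rng.normal(size=4) * 2)
        out = expression.normalize_quantile(m).to_numpy()
        ref = np.sort(out[:, 0])
        for j in range(1, 4):
            assert np.allclose(np.sort(out[:, j]), ref)

    def test_ties_averaged(self):
        m = pd.DataFrame({"a": [1.0, 1.0, 5.0], "b": [2.0, 3.0, 4.0]})
        out = expression.normalize_quantile(m)
        # the two tied values in column a share the mean of the two
        # smallest reference values
        assert out["a"].iloc[0] == out["a"].iloc[1]

    def test_all_missing_sample_errors(self):
        m = pd.DataFrame({"a": [1.0, 2.0], "b": [np.nan, np.nan]})
        with pytest.raises(ValueError, match="b"):
            expression.normalize_quantile(m)

    def test_matches_limma_reference(self, tmp_path):
        """Cross-check against limma::normalizeQuantiles on a small matrix."""
        rng = np.random.default_rng(5)
        m = pd.DataFrame(rng.normal(8, 2, size=(7, 4)),
                         index=[f"g{i}" for i in range(7)],
                         columns=[f"s{j}" for j in range(4)])
        ours = expression.normalize_quantile(m)
        csv = tmp_path / "m.csv"
        m.to_csv(csv)
        script = tmp_path / "qn.R"
        script.write_text(textwrap.dedent(f"""
            suppressMessages(library(limma))
            m <- as.matrix(read.csv("{csv}", row.names=1))
            write.csv(normalizeQuantiles(m), "{tmp_path}/out.csv")
        """))
        subprocess.run(["Rscript", str(script)], check=True,
                       capture_output=True)
        theirs = pd.read_csv(tmp_path / "out.csv", index_col=0)
        assert np.allclose(ours.to_numpy(), theirs.to_numpy(), atol=1e-8)


class TestDetectability:
    def test_first_quartile_rule(self):
        m = pd.DataFrame({"a": np.arange(1.0, 101.0),
                          "b": np.arange(1.0, 101.0)},
                         index=[f"g{i}" for i in range(100)])
        kept = expression.detectable_genes(m)
        q1 = np.quantile(np.arange(1.0, 101.0), 0.25)
        expected = {f"g{i}" for i in range(100) if i + 1 >= q1}
        assert kept == expected

    def test_all_equal_all_detectable(self):
        m = pd.DataFrame(np.ones((5, 3)), index=[f"g{i}" for i in range(5)])
        assert expression.detectable_genes(m) == {f"g{i}" for i in range(5)}

    def test_union_across_levels(self):
        idx = [f"g{i}" for i in range(8)]
        tc = pd.DataFrame({"a": np.arange(8.0), "b": np.arange(8.0)}, index=idx)
        tl = tc.iloc[::-1].set_axis(idx)  # reversed: low TC genes are high TL
        union = expression.detectable_union(tc, tl)
        assert union == set(idx)  # every gene detectable at one level


class TestTE:
    def test_equal_levels_zero(self):
        m = pd.DataFrame(np.random.default_rng(0).normal(size=(4, 3)))
        te, _ = expression.compute_te(m, m)
        assert np.allclose(te, 0.0)

    def test_one_log2_unit_is_twofold(self):
        m = pd.DataFrame(np.zeros((2, 2)))
        te, _ = expression.compute_te(m + 1.0, m)
        assert np.allclose(te, 1.0)

    def test_antisymmetry(self):
        rng = np.random.default_rng(1)
        a = pd.DataFrame(rng.normal(size=(10, 4)))
        b = pd.DataFrame(rng.normal(size=(10, 4)))
        te_ab, _ = expression.compute_te(a, b)
        te_ba, _ = expression.compute_te(b, a)
        assert np.allclose(te_ab + te_ba, 0.0)

    def test_normal_breadth_matches_closed_form(self):
        # IQR of N(0,1) = 2 * Phi^-1(0.75) ~ 1.349
        rng = np.random.default_rng(2)
        tl = pd.DataFrame(rng.normal(size=(100_000, 1)))
        tc = pd.DataFrame(np.zeros((100_000, 1)))
        _, summary = expression.compute_te(tl, tc)
        assert summary["iqr"].iloc[0] == pytest.approx(1.3490, abs=0.02)

    def test_misaligned_indices_error(self):
        a = pd.DataFrame(np.zeros((2, 2)), index=["g1", "g2"])
        b = pd.DataFrame(np.zeros((2, 2)), index=["g1", "g3"])
        with pytest.raises(ValueError, match="misaligned"):
            expression.compute_te(a, b)


class TestClustering:
    def test_planted_blocks_recovered(self):
        rng = np.random.default_rng(4)
        block1 = rng.normal(0, 1, size=(200, 1)) + rng.normal(0, 0.1, (200, 5))
        block2 = rng.normal(0, 1, size=(200, 1)) + rng.normal(0, 0.1, (200, 5))
        profiles = pd.DataFrame(
            np.hstack([block1, block2]),
            columns=[f"a{i}" for i in range(5)] + [f"b{i}" for i in range(5)])
        level_of = {c: ("TC" if c.startswith("a") else "TL")
                    for c in profiles.columns}
        params = ExpressionParams(kmeans_k=2, seed=0)
        out = expression.cluster_profiles(profiles, level_of, params)
        labels = out["kmeans_labels"]
        la = {labels[f"a{i}"] for i in range(5)}
        lb = {labels[f"b{i}"] for i in range(5)}
        assert len(la) == 1 and len(lb) == 1 and la != lb
        assert out["n_translatome_coclustered"] == 5

    def test_anticorrelated_distance_is_two(self):
        x = np.arange(10.0)
        profiles = pd.DataFrame({"p": x, "q": -x, "r": x + 0.001 * x**2})
        out = expression.cluster_profiles(
            profiles, {"p": "TC", "q": "TL", "r": "TC"},
            ExpressionParams(kmeans_k=2, seed=0))
        # Ward linkage on Pearson distance: the anti-correlated pair merges last
        assert out["linkage"][-1, 2] > 1.0

    def test_constant_profile_errors_with_name(self):
        profiles = pd.DataFrame({"p": [1.0, 2.0, 3.0], "q": [1.0, 1.0, 1.0],
                                 "r": [2.0, 1.0, 3.0]})
        with pytest.raises(ValueError, match="q"):
            expression.cluster_profiles(profiles, {"p": "TC", "q": "TL",
                                                   "r": "TC"})


class TestQpcr:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["gene_id", "sample", "ct"])

    def test_reference_mean_delta(self):
        t = self._table([("tgt", "s1", 20.0), ("r1", "s1", 18.0),
                         ("r2", "s1", 20.0), ("r3", "s1", 22.0)])
        rel = expression.normalize_qpcr(t, ["r1", "r2", "r3"])
        assert rel.loc["s1", "tgt"] == pytest.approx(1.0)

    def test_one_cycle_below_reference_doubles(self):
        t = self._table([("tgt", "s1", 19.0), ("r1", "s1", 20.0)])
        rel = expression.normalize_qpcr(t, ["r1"])
        assert rel.loc["s1", "tgt"] == pytest.approx(2.0)

    def test_triplicates_averaged_first(self):
        t = self._table([("tgt", "s1", 19.0), ("tgt", "s1", 20.0),
                         ("tgt", "s1", 21.0), ("r1", "s1", 20.0)])
        rel = expression.normalize_qpcr(t, ["r1"])
        assert rel.loc["s1", "tgt"] == pytest.approx(1.0)

    def test_missing_reference_errors(self):
        t = self._table([("tgt", "s1", 19.0)])
        with pytest.raises(ValueError, match="HPRT1"):
            expression.normalize_qpcr(t, ["HPRT1"])


@settings(max_examples=25, deadline=None, derandomize=True)
@given(arrays(np.float64, (6, 3), unique=True,
              elements=st.floats(-50, 50, allow_nan=False)))
def test_quantile_normalization_properties(x):
    """Tie-free input: sorted columns become identical, within-column
    ranks are preserved, and the transform is idempotent."""
    m = pd.DataFrame(x)
    once = expression.normalize_quantile(m)
    ref = np.sort(once.to_numpy()[:, 0])
    for j in range(3):
        assert np.allclose(np.sort(once.to_numpy()[:, j]), ref, atol=1e-9)
        assert (np.argsort(once.to_numpy()[:, j])
                == np.argsort(x[:, j])).all()
    twice = expression.normalize_quantile(once)
    assert np.allclose(once, twice, atol=1e-9)
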