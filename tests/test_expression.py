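"""Expression levels, rank-sum comparisons, fold changes and the two CV
flavours (indiv-CV across patients, g-CV across genes)."""
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from g4scape.expression import (
    ExpressionMatrix,
    boxplot_summary,
    g_cv,
    group_compare,
    indiv_cv,
    log2fc_set_contrast,
    log_mean_expression,
    paired_condition_test,
    tumor_normal_log2fc,
)


def matrix(values: dict, conditions: dict) -> ExpressionMatrix:
    df = pd.DataFrame(values).T
    meta = pd.DataFrame(
        {
            "tissue": ["t"] * len(df.columns),
            "condition": [conditions[c] for c in df.columns],
            "patient_id": [f"p{i}" for i in range(len(df.columns))],
        },
        index=df.columns,
    )
    return ExpressionMatrix(df, meta)


def simple_matrix(gene_rows, n_normal, n_tumor):
    cols = [f"n{i}" for i in range(n_normal)] + [f"t{i}" for i in range(n_tumor)]
    df = pd.DataFrame.from_dict(gene_rows, orient="index")
    df.columns = cols
    meta = pd.DataFrame(
        {
            "tissue": "t",
            "condition": ["normal"] * n_normal + ["tumor"] * n_tumor,
            "patient_id": [f"p{i}" for i in range(n_normal)]
            + [f"p{i}" for i in range(n_tumor)],
        },
        index=cols,
    )
    return ExpressionMatrix(df, meta)


class TestLogMean:
    def test_analytic(self):
        m = simple_matrix({"g1": [1, 3]}, 2, 0)
        assert log_mean_expression(m)["g1"] == pytest.approx(1.5)

    def test_all_zero_gene(self):
        m = simple_matrix({"g1": [0, 0]}, 2, 0)
        assert log_mean_expression(m)["g1"] == 0.0

    def test_matches_direct_recomputation(self):
        rng = np.random.default_rng(8)
        vals = rng.lognormal(1.0, 1.0, size=(200, 20))
        m = simple_matrix({f"g{i}": vals[i] for i in range(200)}, 20, 0)
        direct = np.log2(vals + 1).mean(axis=1)
        got = log_mean_expression(m)
        assert np.allclose(got.to_numpy(), direct)

    def test_empty_selection_errors(self):
        m = simple_matrix({"g1": [1, 2]}, 2, 0)
        with pytest.raises(ValueError):
            log_mean_expression(m, samples=[])


def rank_sum_exact_oracle(x, y):
    """Two-sided p by enumerating all assignments of pooled ranks."""
    pooled = list(x) + list(y)
    n = len(x)
    ranks = {v: r for r, v in enumerate(sorted(pooled), start=1)}
    obs = sum(ranks[v] for v in x)
    all_ranks = list(ranks[v] for v in pooled)
    stats = [sum(c) for c in combinations(all_ranks, n)]
    mean = np.mean(stats)
    extreme = sum(abs(s - mean) >= abs(obs - mean) - 1e-9 for s in stats)
    return extreme / len(stats)


class TestGroupCompare:
    def test_identical_groups(self):
        res = group_compare([1, 2, 3], [1, 2, 3])
        assert res.p_value == pytest.approx(1.0)

    def test_exact_small_sample(self):
        res = group_compare([1, 2, 3], [11, 12, 13])
        assert res.method == "exact"
        assert res.p_value == pytest.approx(0.1)
        assert res.p_value == pytest.approx(rank_sum_exact_oracle([1, 2, 3], [11, 12, 13]))

    def test_all_tied_degenerate(self, caplog):
        with caplog.at_level("WARNING"):
            res = group_compare([5, 5, 5], [5, 5])
        assert res.p_value == 1.0

    def test_shifted_lognormal_highly_significant(self):
        rng = np.random.default_rng(3)
        x = rng.lognormal(1.0, 0.5, size=500)
        y = rng.lognormal(2.0, 0.5, size=500)
        assert group_compare(y, x).p_value < 1e-10

    def test_exact_vs_asymptotic_agree(self):
        """The continuity-corrected normal approximation tracks exact
        enumeration for small untied groups: typical error ~0.01, worst-case
        pointwise error a few hundredths at these sizes."""
        from scipy import stats as sps

        rng = np.random.default_rng(17)
        devs = []
        for _ in range(50):
            nx, ny = rng.integers(5, 13, size=2)
            pooled = rng.permutation(np.arange(1000))[: nx + ny].astype(float)
            x, y = pooled[:nx], pooled[nx:]
            exact = group_compare(x, y).p_value
            approx = sps.mannwhitneyu(x, y, alternative="two-sided",
                                      method="asymptotic").pvalue
            devs.append(abs(exact - approx))
        assert np.median(devs) < 0.01
        assert max(devs) < 0.05

    def test_too_small_group_errors(self):
        with pytest.raises(ValueError):
            group_compare([1.0], [2.0, 3.0])


class TestLog2FC:
    def test_analytic(self):
        m = simple_matrix({"g1": [1, 1, 3, 3]}, 2, 2)
        assert tumor_normal_log2fc(m)["g1"] == pytest.approx(1.0)

    def test_equal_means_zero(self):
        m = simple_matrix({"g1": [2, 2, 2, 2]}, 2, 2)
        assert tumor_normal_log2fc(m)["g1"] == 0.0

    def test_label_swap_antisymmetry(self):
        rng = np.random.default_rng(4)
        rows = {f"g{i}": rng.lognormal(1, 1, size=8) for i in range(20)}
        m = simple_matrix(rows, 4, 4)
        swapped_meta = m.sample_meta.copy()
        swapped_meta["condition"] = swapped_meta["condition"].map(
            {"normal": "tumor", "tumor": "normal"}
        )
        m_swapped = ExpressionMatrix(m.values, swapped_meta)
        assert np.allclose(
            tumor_normal_log2fc(m).to_numpy(), -tumor_normal_log2fc(m_swapped).to_numpy()
        )

    def test_missing_condition_errors(self):
        m = simple_matrix({"g1": [1, 2]}, 2, 0)
        with pytest.raises(ValueError):
            tumor_normal_log2fc(m)

    def test_set_contrast_detects_differential_shift(self):
        rng = np.random.default_rng(9)
        rows = {}
        for i in range(40):
            base = rng.lognormal(1, 0.2, size=10)
            shift = 4.0 if i < 20 else 1.0
            rows[f"g{i}"] = np.concatenate([base, base * shift])
        m = simple_matrix(rows, 10, 10)
        fc = tumor_normal_log2fc(m)
        res = log2fc_set_contrast(fc, [f"g{i}" for i in range(20)],
                                  [f"g{i}" for i in range(20, 40)])
        assert res.mean_with > res.mean_without
        assert res.p_value < 1e-6


class TestIndivCV:
    @pytest.mark.parametrize("row,expected", [([5, 5, 5], 0.0), ([1, 2, 3], 50.0),
                                              ([2, 4, 6], 50.0)])
    def test_analytic_and_scale_invariance(self, row, expected):
        m = simple_matrix({"g1": row}, 3, 0)
        assert indiv_cv(m, "normal").cv["g1"] == pytest.approx(expected)

    def test_zero_mean_excluded(self):
        m = simple_matrix({"g1": [0, 0, 0], "g2": [1, 2, 3]}, 3, 0)
        res = indiv_cv(m, "normal")
        assert res.n_excluded == 1
        assert "g1" not in res.cv.index

    def test_single_sample_errors(self):
        m = simple_matrix({"g1": [1.0]}, 1, 0)
        with pytest.raises(ValueError):
            indiv_cv(m, "normal")


class TestGCV:
    def test_equal_genes_zero(self):
        m = simple_matrix({"g1": [4.0], "g2": [4.0], "g3": [4.0]}, 1, 0)
        assert g_cv(m, ["g1", "g2", "g3"]).cv["n0"] == 0.0

    def test_analytic(self):
        m = simple_matrix({"g1": [1.0], "g2": [2.0], "g3": [3.0]}, 1, 0)
        assert g_cv(m, ["g1", "g2", "g3"]).cv["n0"] == pytest.approx(50.0)

    def test_empty_gene_set_errors(self):
        m = simple_matrix({"g1": [1.0]}, 1, 0)
        with pytest.raises(ValueError):
            g_cv(m, ["absent"])


@given(st.lists(st.floats(min_value=0.1, max_value=1e4), min_size=3, max_size=30),
       st.floats(min_value=0.01, max_value=100.0))
@settings(max_examples=100, deadline=None, derandomize=True)
def test_cv_scale_invariance_property(values, scale):
    """CV is invariant to positive rescaling of its input vector."""
    m1 = simple_matrix({"g1": values}, len(values), 0)
    m2 = simple_matrix({"g1": [v * scale for v in values]}, len(values), 0)
    a = indiv_cv(m1, "normal").cv["g1"]
    b = indiv_cv(m2, "normal").cv["g1"]
    assert a == pytest.approx(b, rel=1e-9)


class TestPairedTest:
    def test_identical_vectors(self):
        v = np.arange(20, dtype=float)
        res = paired_condition_test(v, v)
        assert res.p_value == 1.0
        assert res.mean_difference == 0.0

    def test_fewer_than_fifteen_pairs_refused(self):
        v = np.arange(14, dtype=float)
        with pytest.raises(ValueError, match="at least 15"):
            paired_condition_test(v, v)

    def test_zero_variance_shift_flagged(self, caplog):
        v = np.arange(20, dtype=float)
        with caplog.at_level("WARNING"):
            res = paired_condition_test(v, v - 5.0)
        assert res.degenerate
        assert res.direction == "decrease"

    def test_noisy_shift_detected(self):
        rng = np.random.default_rng(5)
        normal = rng.normal(50, 3, size=20)
        tumor = normal - 5.0 + rng.normal(0, 1, size=20)
        res = paired_condition_test(normal, tumor)
        assert res.p_value < 0.001
        assert res.direction == "decrease"

    def test_named_pairing(self):
        cn = pd.Series(np.arange(20, dtype=float), index=[f"n{i}" for i in range(20)])
        ct = pd.Series(np.arange(20, dtype=float) + 1, index=[f"t{i}" for i in range(20)])
        res = paired_condition_test(cn, ct, pairing=[(f"n{i}", f"t{i}") for i in range(20)])
        assert res.degenerate  # constant +1 shift
        assert res.n_pairs == 20


def test_boxplot_summary_iqr_whiskers():
    v = np.concatenate([np.arange(1, 101, dtype=float), [1000.0]])
    s = boxplot_summary(v)
    assert s["median"] == pytest.approx(np.median(v))
    assert s["whisker_high"] <= s["q3"] + 1.5 * (s["q3"] - s["q1"])
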