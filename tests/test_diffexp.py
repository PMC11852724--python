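"""Differential expression: estimators, BH oracle, gates, symmetries."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from cortiscope.diffexp import (
    NBDifferentialExpression,
    bh_adjust,
    call_degs,
    low_count_filter,
    nb_wald_test,
    size_factors,
)
from cortiscope.io import CountMatrix
from cortiscope.simulate import CohortSpec, GroupSpec, simulate_cohort

SETTINGS = settings(max_examples=40, derandomize=True, deadline=None)


class TestSizeFactors:
    def test_identical_samples_unit_factors(self):
        mat = pd.DataFrame({"s1": [3, 8, 2], "s2": [3, 8, 2]})
        np.testing.assert_allclose(size_factors(mat).to_numpy(), [1.0, 1.0])

    def test_doubled_sample_sqrt2(self):
        """s2 = 2 x s1 exactly: median-of-ratios gives (1/sqrt2, sqrt2)."""
        mat = pd.DataFrame({"s1": [4, 10, 6], "s2": [8, 20, 12]})
        np.testing.assert_allclose(
            size_factors(mat).to_numpy(), [1 / np.sqrt(2), np.sqrt(2)], rtol=1e-12
        )

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(1)
        mat = pd.DataFrame(
            rng.integers(1, 200, size=(50, 4)), columns=list("abcd")
        )
        f = size_factors(mat)
        g = size_factors(mat[["c", "a", "d", "b"]])
        for col in "abcd":
            assert f[col] == pytest.approx(g[col])

    def test_no_common_nonzero_gene_errors(self):
        mat = pd.DataFrame({"s1": [1, 0], "s2": [0, 1]})
        with pytest.raises(ValueError, match="no gene nonzero"):
            size_factors(mat)


class TestLowCountFilter:
    def test_all_zero_gene_filtered(self):
        mat = pd.DataFrame({"s1": [0, 5], "s2": [0, 5]}, index=["g0", "g1"])
        keep = low_count_filter(mat, min_total=10)
        assert not keep["g0"] and keep["g1"]

    def test_boundary_is_inclusive(self):
        mat = pd.DataFrame({"s1": [4], "s2": [6]}, index=["g"])
        assert low_count_filter(mat, min_total=10)["g"]
        assert not low_count_filter(mat, min_total=11)["g"]

    def test_counted_on_generated_fixture(self):
        rng = np.random.default_rng(0)
        low = rng.integers(0, 2, size=(30, 4))  # row sums <= 4
        high = rng.integers(10, 50, size=(170, 4))
        mat = pd.DataFrame(np.vstack([low, high]))
        assert int(low_count_filter(mat, 10).sum()) == 170


def _bh_oracle(p):
    """Independent oracle: p_adj_i = smallest level at which BH rejects i."""
    p = np.asarray(p, float)
    m = len(p)
    candidates = sorted({p[j] * m / k for j in range(m) for k in range(1, m + 1)} | {1.0})

    def rejected_at(alpha):
        order = np.sort(p)
        # tiny slack guards float round-trip through the candidate grid
        ks = [
            k
            for k in range(1, m + 1)
            if order[k - 1] <= alpha * k / m * (1 + 1e-12) + 1e-15
        ]
        if not ks:
            return np.zeros(m, bool)
        return p <= order[max(ks) - 1]

    out = np.empty(m)
    for i in range(m):
        out[i] = min(a for a in candidates if a <= 1.0 and rejected_at(a)[i]) if any(
            rejected_at(a)[i] for a in candidates
        ) else 1.0
    return np.minimum(out, 1.0)


class TestBHAdjust:
    def test_hand_computed_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.04, 0.05]), [0.04, 0.04, 0.05, 0.05]
        )

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_ties_all_equal(self):
        np.testing.assert_allclose(bh_adjust([0.2] * 5), [0.2] * 5)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_brute_force_oracle_on_grid(self):
        """Step-up BH equals the rejection-threshold oracle for m <= 6."""
        grid = [0.001, 0.02, 0.04, 0.2, 0.6, 1.0]
        for m in (1, 2, 3):
            for combo in itertools.product(grid, repeat=m):
                np.testing.assert_allclose(
                    bh_adjust(list(combo)), _bh_oracle(list(combo)), atol=1e-12
                )
        rng = np.random.default_rng(0)
        for _ in range(50):
            p = rng.uniform(size=rng.integers(4, 7))
            np.testing.assert_allclose(bh_adjust(p), _bh_oracle(p), atol=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40), st.integers(0, 10**6))
    @SETTINGS
    def test_matches_statsmodels(self, p, seed):
        expected = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(bh_adjust(p), expected, atol=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=20))
    @SETTINGS
    def test_order_equivariance_and_bounds(self, p):
        adj = bh_adjust(p)
        assert ((adj >= np.asarray(p) - 1e-15) & (adj <= 1.0)).all()
        perm = np.random.default_rng(0).permutation(len(p))
        np.testing.assert_allclose(bh_adjust(np.asarray(p)[perm]), adj[perm])


class TestCallDegs:
    def _table(self, lfc, padj):
        return pd.DataFrame({"log2fc": [lfc], "p_adj": [padj]}, index=["g"])

    @pytest.mark.parametrize(
        "lfc,padj,strict,expected",
        [
            (2.0, 0.01, True, "ns"),  # boundary: strict >
            (3.0, 0.049, True, "up"),
            (-3.0, 0.049, True, "down"),
            (2.0, 0.05, False, "up"),  # inclusive reading
            (3.0, 0.06, True, "ns"),
        ],
    )
    def test_gates(self, lfc, padj, strict, expected):
        status = call_degs(self._table(lfc, padj), strict=strict)
        assert status["g"] == expected

    def test_filtered_gene_status(self):
        table = pd.DataFrame({"log2fc": [np.nan], "p_adj": [np.nan]}, index=["g"])
        assert call_degs(table)["g"] == "filtered"


def _cohort(seed, n1=8, n2=8, planted=(), dispersion=0.1, n_genes=2000):
    spec = CohortSpec(
        n_genes=n_genes,
        groups=[GroupSpec("a", "case", "t", n1), GroupSpec("b", "control", "t", n2)],
        dispersion=dispersion,
        planted_degs=list(planted),
        seed=seed,
    )
    return simulate_cohort(spec)


class TestNBWald:
    def test_identical_groups_zero_lfc(self):
        counts = pd.DataFrame(
            {f"s{i}": [40, 7, 300] for i in range(8)},
            index=["g1", "g2", "g3"],
            dtype=np.int64,
        )
        table = nb_wald_test(counts, [f"s{i}" for i in range(4)], [f"s{i}" for i in range(4, 8)])
        np.testing.assert_allclose(table["log2fc"], 0.0, atol=1e-12)
        table["p_adj"] = table["p"]
        assert (call_degs(table) == "ns").all()

    def test_label_swap_negates_lfc(self, two_group_cohort):
        cm, _ = two_group_cohort
        case = cm.samples_in_group("tumor")
        ctrl = cm.samples_in_group("normal")
        keep = low_count_filter(cm.counts)
        t1 = nb_wald_test(cm.counts.loc[keep], case, ctrl)
        t2 = nb_wald_test(cm.counts.loc[keep], ctrl, case)
        np.testing.assert_allclose(t1["log2fc"], -t2["log2fc"], atol=1e-10)
        np.testing.assert_allclose(t1["p"], t2["p"], atol=1e-10)

    def test_requires_two_samples_per_group(self, two_group_cohort):
        cm, _ = two_group_cohort
        with pytest.raises(ValueError, match=">= 2 samples"):
            nb_wald_test(cm.counts, ["tumor_1"], cm.samples_in_group("normal"))

    def test_planted_lfc_recovery(self, two_group_cohort):
        """Median estimated log2FC of planted +4 genes within +-0.5 of 4."""
        cm, truth = two_group_cohort
        res = NBDifferentialExpression(cm, "tumor", "normal").fit()
        up = truth.up_genes("tumor")
        med = res.table.loc[up, "log2fc"].median()
        assert abs(med - 4.0) < 0.5
        down = truth.down_genes("tumor")
        assert abs(res.table.loc[down, "log2fc"].median() + 4.0) < 0.5

    def test_scaling_one_sample_leaves_calls_stable(self, two_group_cohort):
        """Library-size changes are absorbed by the size factors."""
        cm, _ = two_group_cohort
        scaled = cm.counts.copy()
        scaled["tumor_3"] = scaled["tumor_3"] * 2
        cm2 = CountMatrix(counts=scaled, sample_meta=cm.sample_meta.copy())
        r1 = NBDifferentialExpression(cm, "tumor", "normal").fit()
        r2 = NBDifferentialExpression(cm2, "tumor", "normal").fit()
        s1 = set(r1.up) | {f"-{g}" for g in r1.down}
        s2 = set(r2.up) | {f"-{g}" for g in r2.down}
        union = len(s1 | s2)
        assert union == 0 or len(s1 & s2) / union >= 0.9

    def test_label_swap_maps_up_to_down(self, two_group_cohort):
        cm, _ = two_group_cohort
        r1 = NBDifferentialExpression(cm, "tumor", "normal").fit()
        r2 = NBDifferentialExpression(
            cm,
            "normal",
            "tumor",
        ).fit()
        assert set(r1.up) == set(r2.down)
        assert set(r1.down) == set(r2.up)

    def test_null_type_one_error(self):
        """Raw p < 0.05 fraction near nominal on null cohorts (5 replicates)."""
        tot = sig = 0
        for rep in range(5):
            cm, _ = _cohort(3000 + rep)
            res = NBDifferentialExpression(cm, "a", "b").fit()
            p = res.table["p"].dropna()
            tot += len(p)
            sig += int((p < 0.05).sum())
        frac = sig / tot
        se = np.sqrt(0.05 * 0.95 / tot)
        assert abs(frac - 0.05) < 4 * se

    def test_summary_mentions_gates_and_counts(self, two_group_cohort):
        cm, _ = two_group_cohort
        res = NBDifferentialExpression(cm, "tumor", "normal").fit()
        text = res.summary()
        assert "up:" in text and "|log2FC| 2.0" in text
        assert str(len(res.up)) in text
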