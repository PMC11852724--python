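"""Therapy scoring: BES formula, target proportions, clustering, GD2."""

import numpy as np
import pandas as pd
import pytest

from cortiscope.io import CountMatrix, DrugModel
from cortiscope.pal import cnr, normalized_expression
from cortiscope.simulate import default_cohort_spec, simulate_cohort, simulate_pathways
from cortiscope.therapy import (
    bes,
    bes_matrix,
    cluster_bes,
    gd2_signature,
    target_upregulation_proportion,
)


def _drug(targets, pathways=()):
    return DrugModel("D", frozenset(targets), frozenset(pathways))


class TestBes:
    def test_neutral_targets_score_zero(self):
        ratios = pd.Series({"a": 1.0, "b": 1.0})
        assert bes(_drug(["a", "b"]), ratios) == pytest.approx(0.0)

    def test_single_target_cnr4(self):
        assert bes(_drug(["a"]), pd.Series({"a": 4.0})) == pytest.approx(2.0)

    def test_log_linearity_in_target_cnr(self):
        ratios = pd.Series({"a": 3.0, "b": 5.0})
        base = bes(_drug(["a", "b"]), ratios)
        doubled = bes(_drug(["a", "b"]), ratios * 2)
        assert doubled - base == pytest.approx(1.0)

    def test_duplicate_target_invariance(self):
        """A target listed twice in the model does not change the mean."""
        ratios = pd.Series({"a": 8.0, "b": 2.0})
        d1 = DrugModel("D", frozenset({"a", "b"}))
        # frozenset already dedups; simulate duplication through equal values
        ratios2 = pd.Series({"a": 8.0, "a2": 8.0, "b": 2.0})
        d2 = DrugModel("D", frozenset({"a", "a2", "b"}))
        assert bes(d2, ratios2) != bes(d1, ratios)  # mean over 3 vs 2 targets
        d3 = DrugModel("D", frozenset({"a", "b"}))
        assert bes(d3, ratios) == pytest.approx(bes(d1, ratios))

    def test_pathway_term(self):
        pal_values = pd.Series({"P1": 100.0, "P2": -50.0})
        drug = _drug(["a"], ["P1", "P2"])
        score = bes(drug, pd.Series({"a": 1.0}), pal_values)
        assert score == pytest.approx((1.0 - 0.5) / 2)

    def test_no_measurable_targets_raises(self):
        with pytest.raises(ValueError, match="no measurable"):
            bes(_drug(["missing"]), pd.Series({"a": 1.0}))

    def test_weights(self):
        drug = _drug(["a"], ["P1"])
        score = bes(
            drug, pd.Series({"a": 4.0}), pd.Series({"P1": 100.0}), w_gene=2.0, w_pathway=0.5
        )
        assert score == pytest.approx(2 * 2.0 + 0.5 * 1.0)


class TestTargetProportions:
    def _cnr_frame(self, rows, n_samples):
        return pd.DataFrame(
            rows, index=list(rows.keys()), columns=[f"s{i}" for i in range(n_samples)]
        )

    def test_all_samples_up(self):
        frame = pd.DataFrame([[2.0] * 6], index=["a"])
        t = target_upregulation_proportion(_drug(["a"]), frame)
        assert t.loc["a", "proportion"] == "6/6"

    def test_boundary_is_strict(self):
        frame = pd.DataFrame([[1.0] * 4], index=["a"])
        t = target_upregulation_proportion(_drug(["a"]), frame)
        assert t.loc["a", "proportion"] == "0/4"

    def test_planted_fifteen_of_sixteen(self):
        values = [2.0] * 15 + [0.5]
        frame = pd.DataFrame([values], index=["a"])
        t = target_upregulation_proportion(_drug(["a"]), frame)
        assert t.loc["a", "proportion"] == "15/16"


class TestClusterBes:
    def test_planted_populations_recovered(self):
        rng = np.random.default_rng(0)
        a = rng.normal(5, 0.1, size=(4, 6))
        b = rng.normal(-5, 0.1, size=(4, 5))
        matrix = pd.DataFrame(
            np.hstack([a, b]), columns=[f"s{i}" for i in range(11)]
        )
        labels = cluster_bes(matrix, 2)
        assert len(set(labels.iloc[:6])) == 1
        assert len(set(labels.iloc[6:])) == 1
        assert labels.iloc[0] != labels.iloc[-1]

    def test_duplicated_sample_same_cluster(self):
        rng = np.random.default_rng(1)
        m = pd.DataFrame(rng.normal(size=(5, 4)), columns=list("abcd"))
        m["a2"] = m["a"]
        labels = cluster_bes(m, 2)
        assert labels["a"] == labels["a2"]

    def test_single_cluster(self):
        m = pd.DataFrame(np.eye(3), columns=list("abc"))
        assert set(cluster_bes(m, 1)) == {1}

    def test_too_many_clusters(self):
        m = pd.DataFrame(np.eye(3), columns=list("abc"))
        with pytest.raises(ValueError):
            cluster_bes(m, 4)


class TestGd2:
    @pytest.fixture(scope="class")
    def cohort(self):
        return simulate_cohort(default_cohort_spec(seed=31))

    def test_formula_cases(self):
        counts = pd.DataFrame(
            {
                "case": [40, 10, 100],
                "c1": [10, 10, 100],
                "c2": [10, 10, 100],
            },
            index=["ST8SIA1", "B4GALNT1", "other"],
            dtype=np.int64,
        )
        meta = pd.DataFrame(
            {
                "tissue": ["t"] * 3,
                "condition": ["case", "control", "control"],
                "group": ["tumor", "normal", "normal"],
            },
            index=["case", "c1", "c2"],
        )
        cm = CountMatrix(counts=counts, sample_meta=meta)
        norm = normalized_expression(cm)
        ratios = cnr(norm["case"], norm[["c1", "c2"]], pseudocount=0)
        expected = 0.5 * (np.log2(ratios["ST8SIA1"]) + np.log2(ratios["B4GALNT1"]))
        [score] = gd2_signature(cm, ["case"], ["c1", "c2"], pseudocount=0)
        assert score.score == pytest.approx(expected)
        assert score.call == ("positive" if expected > 0 else "negative")

    def test_gene_symmetry(self):
        counts = pd.DataFrame(
            {
                "case": [40, 10, 50],
                "c1": [10, 10, 50],
                "c2": [10, 10, 50],
            },
            index=["ST8SIA1", "B4GALNT1", "x"],
            dtype=np.int64,
        )
        swapped = counts.rename(index={"ST8SIA1": "B4GALNT1", "B4GALNT1": "ST8SIA1"})
        meta = pd.DataFrame(
            {
                "tissue": ["t"] * 3,
                "condition": ["case", "control", "control"],
                "group": ["g"] * 3,
            },
            index=["case", "c1", "c2"],
        )
        s1 = gd2_signature(CountMatrix(counts=counts, sample_meta=meta), ["case"], ["c1", "c2"])
        s2 = gd2_signature(CountMatrix(counts=swapped, sample_meta=meta), ["case"], ["c1", "c2"])
        assert s1[0].score == pytest.approx(s2[0].score)

    def test_missing_signature_gene(self, cohort):
        cm, _ = cohort
        with pytest.raises(ValueError, match="absent"):
            gd2_signature(cm, cm.samples_in_group("lung_tumor"), cm.samples_in_group("lung_normal"))


class TestBesMatrixRanking:
    def test_planted_up_drugs_outrank_neutral(self):
        """Drugs targeting planted-up genes beat neutral-target drugs in
        >= 95% of simulated case samples."""
        cm, truth = simulate_cohort(default_cohort_spec(seed=41))
        pathways, _ = simulate_pathways(truth, seed=5)
        up = truth.up_genes("pituitary_tumor")[:3]
        planted = {g for d in truth.degs.values() for g in d}
        neutral = sorted(set(truth.gene_ids) - planted)[:3]
        drugs = [
            DrugModel("up_drug", frozenset(up)),
            DrugModel("neutral_drug", frozenset(neutral)),
        ]
        matrix = bes_matrix(
            cm,
            cm.samples_in_group("pituitary_tumor"),
            cm.samples_in_group("pituitary_normal"),
            drugs,
        )
        wins = (matrix.loc["up_drug"] > matrix.loc["neutral_drug"]).mean()
        assert wins >= 0.95
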