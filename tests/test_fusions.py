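"""Fusion screen: filter rules, classification geometry, recurrence."""

import numpy as np
import pandas as pd
import pytest

from cortiscope.fusions import (
    as_candidates,
    candidates_to_frame,
    classify,
    filter_mitochondrial,
    filter_support,
    recurrence_table,
    screen_fusions,
)
from cortiscope.io import FusionRecord
from cortiscope.simulate import simulate_fusion_tables


def _record(left="A", right="B", j=10, s=10, sample="s1"):
    return FusionRecord(
        fusion_name=f"{left}--{right}",
        left_gene=left,
        right_gene=right,
        left_breakpoint=("chr1", 100, "+"),
        right_breakpoint=("chr2", 200, "+"),
        junction_read_count=j,
        spanning_frag_count=s,
        sample_id=sample,
    )


def _ann(rows):
    df = pd.DataFrame(
        rows, columns=["gene_id", "symbol", "chromosome", "start", "end", "strand"]
    ).set_index("gene_id")
    df["is_mitochondrial"] = df["chromosome"] == "chrM"
    return df


class TestSupportFilter:
    @pytest.mark.parametrize(
        "j,s,mode,removed",
        [
            (2, 2, "and", True),  # both fail to exceed 2
            (5, 0, "and", False),  # junction exceeds 2
            (3, 3, "and", False),
            (5, 0, "or", True),  # OR variant: one failing suffices
            (3, 3, "or", False),
        ],
    )
    def test_rules(self, j, s, mode, removed):
        out = filter_support(as_candidates([_record(j=j, s=s)]), mode=mode)
        assert (out[0].fate == "removed_low_support") == removed

    def test_invalid_mode(self):
        with pytest.raises(ValueError):
            filter_support(as_candidates([_record()]), mode="xor")


class TestMitochondrialFilter:
    ANN = _ann(
        [
            ("A", "A", "chr1", 100, 2000, "+"),
            ("B", "B", "chr2", 100, 2000, "+"),
            ("M", "MT-G1", "chrM", 1, 900, "+"),
        ]
    )

    def test_mitochondrial_partner_removed(self):
        out = filter_mitochondrial(as_candidates([_record(left="M")]), self.ANN)
        assert out[0].fate == "removed_mitochondrial"

    def test_nuclear_pair_unchanged(self):
        out = filter_mitochondrial(as_candidates([_record()]), self.ANN)
        assert out[0].fate == "retained"

    def test_unknown_gene_treated_nuclear(self):
        out = filter_mitochondrial(as_candidates([_record(left="ZZZ")]), self.ANN)
        assert out[0].fate == "retained"


class TestClassify:
    ANN = _ann(
        [
            # + strand read-through pair: A upstream of B, 5 kb gap
            ("A", "A", "chr1", 10_000, 20_000, "+"),
            ("B", "B", "chr1", 25_000, 35_000, "+"),
            # - strand pair: transcription right-to-left, D (higher coords) is 5'
            ("C", "C", "chr1", 100_000, 110_000, "-"),
            ("D", "D", "chr1", 120_000, 130_000, "-"),
            # overlapping same-strand pair
            ("E", "E", "chr2", 10_000, 30_000, "+"),
            ("F", "F", "chr2", 20_000, 40_000, "+"),
            # far gene and other chromosome
            ("G", "G", "chr1", 5_000_000, 5_010_000, "+"),
            ("H", "H", "chr3", 10_000, 20_000, "+"),
            # opposite strand neighbor of A
            ("I", "I", "chr1", 40_000, 50_000, "-"),
        ]
    )

    def _cls(self, left, right, **kw):
        cand = as_candidates([_record(left=left, right=right)])[0]
        return classify(cand, self.ANN, **kw)

    def test_adjacent_same_strand_correct_orientation(self):
        assert self._cls("A", "B") == "read_through"

    def test_minus_strand_orientation(self):
        assert self._cls("D", "C") == "read_through"
        # wrong 5'/3' order on the minus strand is not a read-through
        assert self._cls("C", "D") == "chromosomal_rearrangement"

    def test_wrong_order_plus_strand(self):
        assert self._cls("B", "A") == "chromosomal_rearrangement"

    def test_different_chromosomes(self):
        assert self._cls("A", "H") == "chromosomal_rearrangement"

    def test_opposite_strands(self):
        assert self._cls("A", "I") == "chromosomal_rearrangement"

    def test_gap_above_threshold(self):
        assert self._cls("A", "G") == "chromosomal_rearrangement"
        assert self._cls("A", "G", rt_max_gap=10_000_000) == "read_through"

    def test_overlapping_same_strand_is_transcript_variant(self):
        assert self._cls("E", "F") == "transcript_variant"

    def test_unannotated_partner(self):
        assert self._cls("A", "ZZZ") == "unclassified"


class TestScreenProperties:
    def _random_records(self, n, rng):
        genes = ["A", "B", "M", "ZZZ"]
        return [
            _record(
                left=genes[rng.integers(len(genes))],
                right=genes[rng.integers(len(genes))],
                j=int(rng.integers(0, 6)),
                s=int(rng.integers(0, 6)),
                sample=f"s{rng.integers(3)}",
            )
            for _ in range(n)
        ]

    def test_filter_order_independence(self):
        ann = TestMitochondrialFilter.ANN
        rng = np.random.default_rng(0)
        records = self._random_records(200, rng)
        a = filter_mitochondrial(filter_support(as_candidates(records)), ann)
        b = filter_support(filter_mitochondrial(as_candidates(records), ann))
        assert [c.fate for c in a] == [c.fate for c in b]

    def test_every_record_has_a_fate(self):
        ann = TestMitochondrialFilter.ANN
        records = self._random_records(100, np.random.default_rng(1))
        out = screen_fusions(records, ann)
        assert len(out) == len(records)
        assert all(
            c.fate in {"retained", "removed_low_support", "removed_mitochondrial"}
            for c in out
        )
        assert all(
            (c.classification is not None) == (c.fate == "retained") for c in out
        )

    def test_generator_truth_recovered_exactly(self, annotation):
        """Screen reproduces the planted fates and classes for 100% of
        candidates of every planted kind."""
        tables, truth = simulate_fusion_tables(
            annotation,
            [f"s{i}" for i in range(8)],
            plant={
                "read_through": 6,
                "transcript_variant": 2,
                "rearrangement": 6,
                "mitochondrial": 3,
                "low_support": 5,
            },
            seed=9,
            recurrent=[("read_through", 4)],
        )
        records = [r for s in sorted(tables) for r in tables[s]]
        out = screen_fusions(records, annotation)
        by_key = {(c.record.fusion_name, c.record.sample_id): c for c in out}
        for planted in truth:
            c = by_key[(planted.record.fusion_name, planted.record.sample_id)]
            assert c.fate == planted.intended_fate
            if planted.intended_fate == "retained":
                assert c.classification == planted.intended_class


class TestRecurrence:
    def test_pair_counts_distinct_samples(self):
        records = [
            _record(sample="s1"),
            _record(sample="s2"),
            _record(sample="s2"),  # same sample counted once
            _record(sample="s3"),
            _record(left="X", right="Y", sample="s1"),
        ]
        ann = TestMitochondrialFilter.ANN
        out = screen_fusions(records, ann)
        table = recurrence_table(out)
        top = table.iloc[0]
        assert (top["left_gene"], top["right_gene"], top["n_samples"]) == ("A", "B", 3)
        assert recurrence_table(out, recurrent_only=True)["n_samples"].min() > 1

    def test_planted_recurrent_pair_tops_table(self, annotation):
        tables, truth = simulate_fusion_tables(
            annotation,
            [f"s{i}" for i in range(8)],
            plant={"rearrangement": 3},
            seed=13,
            recurrent=[("rearrangement", 5)],
        )
        records = [r for s in sorted(tables) for r in tables[s]]
        out = screen_fusions(records, annotation)
        table = recurrence_table(out)
        assert table.iloc[0]["n_samples"] == 5

    def test_frame_conservation(self):
        ann = TestMitochondrialFilter.ANN
        records = [_record(sample=f"s{i}") for i in range(5)]
        frame = candidates_to_frame(screen_fusions(records, ann))
        assert len(frame) == 5
        assert set(frame["fate"]) <= {
            "retained",
            "removed_low_support",
            "removed_mitochondrial",
        }
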