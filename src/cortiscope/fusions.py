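"""Support filtering, classification and recurrence of fusion candidates.

Raw fusion calls are screened in two steps: candidates whose junction
and spanning read support both fail to exceed 2 are removed as
low-confidence (an OR variant over the two counts is available), and
candidates with a mitochondrial partner gene are discarded. Retained
candidates are classified from the partner loci:

* ``transcript_variant`` — the partner loci overlap on the same strand
  (the call is a splice variant of one locus, not a fusion);
* ``read_through`` — same chromosome, same strand, the 5' partner lies
  upstream of the 3' partner in transcription orientation, and the
  inter-locus gap does not exceed ``rt_max_gap`` (default 100 kb);
* ``chromosomal_rearrangement`` — everything else (different
  chromosomes, opposite strands, wrong orientation, or a larger gap);
* ``unclassified`` — a partner missing from the annotation.

When both removal rules apply to one record the low-support fate is
reported; each filter assigns fates through that fixed priority, which
makes the two filters commute. Recurrence counts the distinct samples
carrying the same ordered gene pair among retained candidates.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import pandas as pd

from .io import FusionRecord

__all__ = [
    "FusionCandidate",
    "filter_support",
    "filter_mitochondrial",
    "classify",
    "screen_fusions",
    "recurrence_table",
    "candidates_to_frame",
]

RETAINED = "retained"
REMOVED_LOW_SUPPORT = "removed_low_support"
REMOVED_MITOCHONDRIAL = "removed_mitochondrial"

# fixed priority so the two filters commute on records failing both
_FATE_RANK = {RETAINED: 0, REMOVED_MITOCHONDRIAL: 1, REMOVED_LOW_SUPPORT: 2}

DEFAULT_RT_MAX_GAP = 100_000
SUPPORT_CUTOFF = 2


@dataclass
class FusionCandidate:
    """A fusion call annotated with its screen fate and classification."""

    record: FusionRecord
    fate: str = RETAINED
    classification: str | None = None  # only set while retained
    recurrence: int | None = None
    manually_reviewed: bool = False

    @property
    def gene_pair(self) -> tuple[str, str]:
        return self.record.gene_pair


def as_candidates(records: Iterable[FusionRecord]) -> list[FusionCandidate]:
    return [FusionCandidate(record=r) for r in records]


def _worsen(candidate: FusionCandidate, fate: str) -> FusionCandidate:
    if _FATE_RANK[fate] > _FATE_RANK[candidate.fate]:
        return replace(candidate, fate=fate, classification=None)
    return candidate


def filter_support(
    candidates: Sequence[FusionCandidate],
    cutoff: int = SUPPORT_CUTOFF,
    mode: str = "and",
) -> list[FusionCandidate]:
    """Mark low-support candidates.

    ``mode="and"`` (default) removes a candidate when the junction read
    count and the spanning fragment count both fail to exceed ``cutoff``;
    ``mode="or"`` removes it when either does.
    """
    if mode not in ("and", "or"):
        raise ValueError(f"mode must be 'and' or 'or', got {mode!r}")
    out = []
    for cand in candidates:
        low_j = cand.record.junction_read_count <= cutoff
        low_s = cand.record.spanning_frag_count <= cutoff
        low = (low_j and low_s) if mode == "and" else (low_j or low_s)
        out.append(_worsen(cand, REMOVED_LOW_SUPPORT) if low else cand)
    return out


def _lookup(annotation: pd.DataFrame, gene: str) -> pd.Series | None:
    if gene in annotation.index:
        return annotation.loc[gene]
    hits = annotation.index[annotation["symbol"] == gene]
    if len(hits):
        return annotation.loc[hits[0]]
    return None


def filter_mitochondrial(
    candidates: Sequence[FusionCandidate], annotation: pd.DataFrame
) -> list[FusionCandidate]:
    """Mark candidates with a mitochondrial partner gene.

    Partners absent from the annotation are treated as
    non-mitochondrial (the classification step reports them as
    unclassified instead).
    """
    out = []
    for cand in candidates:
        mito = False
        for gene in cand.gene_pair:
            row = _lookup(annotation, gene)
            if row is not None and bool(row["is_mitochondrial"]):
                mito = True
        out.append(_worsen(cand, REMOVED_MITOCHONDRIAL) if mito else cand)
    return out


def classify(
    candidate: FusionCandidate,
    annotation: pd.DataFrame,
    rt_max_gap: int = DEFAULT_RT_MAX_GAP,
) -> str:
    """Classify one retained candidate from its partner gene loci."""
    left = _lookup(annotation, candidate.record.left_gene)
    right = _lookup(annotation, candidate.record.right_gene)
    if left is None or right is None:
        return "unclassified"
    same_chrom = left["chromosome"] == right["chromosome"]
    same_strand = left["strand"] == right["strand"]
    if same_chrom and same_strand:
        overlap = left["start"] <= right["end"] and right["start"] <= left["end"]
        if overlap:
            return "transcript_variant"
        if left["strand"] == "+":
            # transcription left-to-right: the 5' (left) partner must end
            # upstream of the 3' partner's start
            ordered = left["end"] < right["start"]
            gap = right["start"] - left["end"] - 1
        else:
            # transcription right-to-left: upstream means higher coordinates
            ordered = left["start"] > right["end"]
            gap = left["start"] - right["end"] - 1
        if ordered and gap <= rt_max_gap:
            return "read_through"
    return "chromosomal_rearrangement"


def screen_fusions(
    records: Iterable[FusionRecord],
    annotation: pd.DataFrame,
    rt_max_gap: int = DEFAULT_RT_MAX_GAP,
    support_mode: str = "and",
    support_cutoff: int = SUPPORT_CUTOFF,
) -> list[FusionCandidate]:
    """Full screen: support filter, mitochondrial filter, classification,
    recurrence annotation. Every input record appears exactly once in
    the output with a fate."""
    candidates = as_candidates(records)
    candidates = filter_support(candidates, cutoff=support_cutoff, mode=support_mode)
    candidates = filter_mitochondrial(candidates, annotation)
    candidates = [
        replace(c, classification=classify(c, annotation, rt_max_gap))
        if c.fate == RETAINED
        else c
        for c in candidates
    ]
    recurrence = _recurrence_counts(candidates)
    return [
        replace(c, recurrence=recurrence.get(c.gene_pair)) if c.fate == RETAINED else c
        for c in candidates
    ]


def _recurrence_counts(candidates: Sequence[FusionCandidate]) -> dict[tuple[str, str], int]:
    samples: dict[tuple[str, str], set[str]] = {}
    for cand in candidates:
        if cand.fate != RETAINED:
            continue
        samples.setdefault(cand.gene_pair, set()).add(cand.record.sample_id)
    return {pair: len(ids) for pair, ids in samples.items()}


def recurrence_table(
    candidates: Sequence[FusionCandidate], recurrent_only: bool = False
) -> pd.DataFrame:
    """Distinct-sample counts per ordered gene pair among retained calls.

    Sorted by recurrence (descending) then fusion name. With
    ``recurrent_only`` the table keeps pairs seen in more than one
    sample.
    """
    counts = _recurrence_counts(candidates)
    rows = [
        {"left_gene": pair[0], "right_gene": pair[1], "n_samples": n}
        for pair, n in counts.items()
        if not recurrent_only or n > 1
    ]
    table = pd.DataFrame(rows, columns=["left_gene", "right_gene", "n_samples"])
    return table.sort_values(
        ["n_samples", "left_gene", "right_gene"],
        ascending=[False, True, True],
        kind="stable",
    ).reset_index(drop=True)


def candidates_to_frame(candidates: Sequence[FusionCandidate]) -> pd.DataFrame:
    rows = []
    for c in candidates:
        r = c.record
        rows.append(
            {
                "sample_id": r.sample_id,
                "fusion_name": r.fusion_name,
                "left_gene": r.left_gene,
                "right_gene": r.right_gene,
                "left_breakpoint": ":".join(map(str, r.left_breakpoint)),
                "right_breakpoint": ":".join(map(str, r.right_breakpoint)),
                "junction_read_count": r.junction_read_count,
                "spanning_frag_count": r.spanning_frag_count,
                "fate": c.fate,
                "classification": c.classification if c.classification else "",
                "recurrence": c.recurrence if c.recurrence is not None else "",
                "manually_reviewed": c.manually_reviewed,
            }
        )
    return pd.DataFrame(rows)
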