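"""Case-to-normal ratios (CNR) and pathway activation levels (PAL).

CNR for a gene is its expression in a case sample (or group average)
divided by its mean expression across the control group. PAL aggregates
the log10 CNRs of a pathway's members weighted by their
activator/repressor roles (ARR in {-1, 0, +1}):

    PAL_p = 100 * sum_n ARR_np * lg(CNR_n) / sum_n |ARR_np|

Ambiguous members (ARR = 0) and members without a measured CNR
contribute to neither the numerator nor the denominator. A single
activator at CNR = 10 therefore yields PAL = 100; positive PAL means
the pathway's net activity is up in the case versus the controls.

Expression is size-factor-normalized counts; a pseudocount (default 1)
guards zero expression. Both per-sample and group-averaged PAL are
provided; for groups the case samples are averaged first, then CNR and
PAL are evaluated on the averaged profile.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .diffexp import size_factors
from .io import CountMatrix, PathwayModel

__all__ = [
    "cnr",
    "pal",
    "pal_table",
    "per_sample_pal",
    "group_pal",
    "normalized_expression",
]


def normalized_expression(counts: CountMatrix | pd.DataFrame) -> pd.DataFrame:
    """Counts divided by median-of-ratios size factors."""
    mat = counts.counts if isinstance(counts, CountMatrix) else counts
    return mat / size_factors(mat)


def cnr(
    case_expression: pd.Series,
    control_matrix: pd.DataFrame,
    pseudocount: float = 1.0,
) -> pd.Series:
    """Case-to-normal ratio per gene.

    ``case_expression`` is one (normalized) expression profile;
    ``control_matrix`` holds the normalized control profiles as columns.
    Only genes present in both enter the result:
    cnr = (case + pseudocount) / (control mean + pseudocount).
    """
    if control_matrix.shape[1] == 0:
        raise ValueError("control group is empty")
    genes = case_expression.index.intersection(control_matrix.index)
    if len(genes) == 0:
        raise ValueError("no shared genes between case and controls")
    control_mean = control_matrix.loc[genes].mean(axis=1)
    values = (case_expression.loc[genes] + pseudocount) / (control_mean + pseudocount)
    if (values <= 0).any():
        bad = values.index[values <= 0][0]
        raise ValueError(f"non-positive CNR for gene {bad!r}; check pseudocount")
    return values.rename("cnr")


def pal(pathway: PathwayModel, cnr_values: pd.Series) -> tuple[float, int]:
    """Pathway activation level and the number of contributing members.

    Contributing members are those with |ARR| = 1 and a measured CNR.
    Raises ``ValueError`` for a degenerate pathway (no contributors).
    """
    numerator = 0.0
    n_contributing = 0
    for gene, arr in pathway.members.items():
        if arr == 0 or gene not in cnr_values.index:
            continue
        numerator += arr * np.log10(cnr_values[gene])
        n_contributing += 1
    if n_contributing == 0:
        raise ValueError(f"degenerate pathway {pathway.pathway_id!r}: no contributing members")
    return 100.0 * numerator / n_contributing, n_contributing


def pal_table(
    pathways: Mapping[str, PathwayModel], cnr_values: pd.Series
) -> pd.DataFrame:
    """PAL for every scoreable pathway; degenerate pathways are absent."""
    rows = []
    for pid in sorted(pathways):
        try:
            value, n = pal(pathways[pid], cnr_values)
        except ValueError:
            continue
        rows.append({"pathway_id": pid, "pal": value, "n_contributing": n})
    return pd.DataFrame(rows, columns=["pathway_id", "pal", "n_contributing"]).set_index(
        "pathway_id"
    )


def per_sample_pal(
    counts: CountMatrix,
    case_samples: Sequence[str],
    control_samples: Sequence[str],
    pathways: Mapping[str, PathwayModel],
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """PAL per pathway (rows) per case sample (columns)."""
    norm = normalized_expression(counts)
    controls = norm.loc[:, list(control_samples)]
    columns = {}
    for sample in case_samples:
        ratios = cnr(norm[sample], controls, pseudocount)
        columns[sample] = pal_table(pathways, ratios)["pal"]
    return pd.DataFrame(columns)


def group_pal(
    counts: CountMatrix,
    case_samples: Sequence[str],
    control_samples: Sequence[str],
    pathways: Mapping[str, PathwayModel],
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Group-averaged PAL: case samples averaged before CNR and PAL."""
    if not case_samples or not control_samples:
        raise ValueError("both groups must be non-empty")
    norm = normalized_expression(counts)
    case_mean = norm.loc[:, list(case_samples)].mean(axis=1)
    ratios = cnr(case_mean, norm.loc[:, list(control_samples)], pseudocount)
    return pal_table(pathways, ratios)
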