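"""Over-representation analysis of DEG lists against gene-set collections.

One-sided hypergeometric test per term with the tested-gene universe as
the background, BH-adjusted across the tested terms. Terms are
intersected with the background before testing, and terms whose
background membership falls outside [min_size, max_size] are skipped.
"""

from __future__ import annotations

from typing import Collection

import numpy as np
import pandas as pd
from scipy import stats

from .diffexp import bh_adjust
from .io import GeneSetCollection

__all__ = ["ora"]


def ora(
    deg_list: Collection[str],
    collection: GeneSetCollection,
    background: Collection[str],
    min_size: int = 5,
    max_size: int = 2000,
) -> pd.DataFrame:
    """Hypergeometric over-representation test of a gene list.

    Per term: k = list genes in term, K = background genes in term,
    n = list size, N = background size; p = P(X >= k) for
    X ~ Hypergeom(N, K, n). Returns a DataFrame sorted by adjusted p
    with columns term_id, name, k, K, n, N, gene_ratio, p, p_adj.
    """
    background_set = set(background)
    if not background_set:
        raise ValueError("empty background")
    degs = set(deg_list)
    outside = degs - background_set
    if outside:
        raise ValueError(f"DEG(s) outside the background: {sorted(outside)[:5]}")
    n = len(degs)
    N = len(background_set)
    rows = []
    for term_id in sorted(collection):
        gene_set = collection[term_id]
        term_genes = gene_set.genes & background_set
        K = len(term_genes)
        if K < min_size or K > max_size:
            continue
        k = len(term_genes & degs)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {
                "term_id": term_id,
                "name": gene_set.name,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "gene_ratio": k / n if n else np.nan,
                "p": min(p, 1.0),
            }
        )
    table = pd.DataFrame(
        rows, columns=["term_id", "name", "k", "K", "n", "N", "gene_ratio", "p"]
    )
    if len(table):
        table["p_adj"] = bh_adjust(table["p"].to_numpy())
        table = table.sort_values(["p_adj", "p", "term_id"], kind="stable")
    else:
        table["p_adj"] = pd.Series(dtype=float)
    return table.set_index("term_id")
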