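"""Sample-level structure: variance-stabilized PCA and normal-like exclusion.

Counts are size-factor normalized and log2(x + 1) transformed as a
variance-stabilizing surrogate, PCA is run on the top-variance genes,
and tumor samples whose PC-space position is closer to the normal-group
centroid than to their own (leave-one-out) centroid are flagged for
exclusion before differential expression. The exclusion rule is this
package's quantitative operationalization of a screen that is otherwise
done by visual inspection of the PCA plot; reports label it as such.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .diffexp import size_factors
from .io import CountMatrix

__all__ = ["PcaResult", "vst_transform", "pca", "exclude_normal_like"]


@dataclass
class PcaResult:
    """Sample scores, explained-variance fractions and the genes used."""

    scores: pd.DataFrame  # samples x components
    explained_variance_ratio: np.ndarray
    genes_used: list[str]

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def vst_transform(
    counts: CountMatrix | pd.DataFrame, factors: pd.Series | None = None
) -> pd.DataFrame:
    """log2(normalized count + 1), the variance-stabilizing surrogate.

    ``factors`` overrides the median-of-ratios size factors; scaling a
    sample's counts and its factor by the same constant leaves its
    transformed column unchanged.
    """
    mat = counts.counts if isinstance(counts, CountMatrix) else counts
    if factors is None:
        factors = size_factors(mat)
    return np.log2(mat / factors.loc[mat.columns] + 1.0)


def pca(transformed: pd.DataFrame, n_top_genes: int = 500, n_components: int | None = None) -> PcaResult:
    """Centered PCA of samples on the top-variance genes.

    Genes are ranked by variance across samples and the top
    ``n_top_genes`` retained (all genes, with a warning, if fewer are
    available). Components carry a deterministic sign: the
    largest-|loading| gene of each component has a positive loading.
    """
    if transformed.shape[1] < 2:
        raise ValueError("PCA needs >= 2 samples")
    variances = transformed.var(axis=1, ddof=1)
    if len(variances) < n_top_genes:
        warnings.warn(
            f"only {len(variances)} genes available, fewer than the "
            f"{n_top_genes} requested; using all",
            stacklevel=2,
        )
        n_top_genes = len(variances)
    top = variances.sort_values(ascending=False, kind="stable").index[:n_top_genes]
    genes_used = sorted(top)

    # samples x genes, column-centered
    x = transformed.loc[genes_used].to_numpy(dtype=float).T
    x = x - x.mean(axis=0, keepdims=True)
    n_samples = x.shape[0]
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    max_k = min(n_samples, x.shape[1])
    k = max_k if n_components is None else min(n_components, max_k)

    # sign convention: largest-|loading| entry of each component positive
    for comp in range(k):
        pivot = np.argmax(np.abs(vt[comp]))
        if vt[comp, pivot] < 0:
            vt[comp] *= -1.0
            u[:, comp] *= -1.0

    scores = u[:, :k] * s[:k]
    eigvals = s**2 / max(n_samples - 1, 1)
    total_var = x.var(axis=0, ddof=1).sum()
    ratio = eigvals[:k] / total_var if total_var > 0 else np.zeros(k)
    return PcaResult(
        scores=pd.DataFrame(
            scores,
            index=transformed.columns,
            columns=[f"PC{i + 1}" for i in range(k)],
        ),
        explained_variance_ratio=ratio,
        genes_used=genes_used,
    )


def exclude_normal_like(
    result: PcaResult,
    tumor_ids: Sequence[str],
    normal_ids: Sequence[str],
    k_components: int = 2,
) -> list[str]:
    """Tumor samples closer to the normal centroid than to their own.

    Distances are Euclidean in the first ``k_components`` PC scores; the
    tumor centroid is computed leave-one-out for the sample under test.
    A singleton tumor group makes leave-one-out undefined: nothing is
    excluded and a warning is issued.
    """
    tumor_ids, normal_ids = list(tumor_ids), list(normal_ids)
    if not tumor_ids or not normal_ids:
        raise ValueError("both tumor and normal groups must be non-empty")
    if len(tumor_ids) < 2:
        warnings.warn("singleton tumor group: leave-one-out undefined, no exclusions", stacklevel=2)
        return []
    k = min(k_components, result.n_components)
    scores = result.scores.iloc[:, :k]
    normal_centroid = scores.loc[normal_ids].mean(axis=0).to_numpy()
    tumor_scores = scores.loc[tumor_ids].to_numpy()
    tumor_sum = tumor_scores.sum(axis=0)
    excluded = []
    for i, sample in enumerate(tumor_ids):
        own = tumor_scores[i]
        loo_centroid = (tumor_sum - own) / (len(tumor_ids) - 1)
        d_normal = np.linalg.norm(own - normal_centroid)
        d_tumor = np.linalg.norm(own - loo_centroid)
        if d_normal < d_tumor:
            excluded.append(sample)
    return excluded
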