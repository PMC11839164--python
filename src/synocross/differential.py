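"""Rank-sum differential expression and directional two-comparison overlap.

``wilcoxon_de`` mirrors the standard single-cell marker-test convention:
genes are pre-filtered by expression fraction and log2 fold change, tested
with a two-sided Wilcoxon rank-sum (normal approximation with tie
correction), and Benjamini-Hochberg adjusted over the tested genes.  Fold
changes are computed on expm1-scale group means with a pseudocount of 1.

``directional_overlap`` implements the two-comparison Venn logic: genes
significant in both comparisons are "shared", and of those, the ones with
the same fold-change sign in both are "shared same-direction".
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .config import PipelineConfig
from .errors import ValidationError


def _resolve_cells(adata: ad.AnnData, cells) -> np.ndarray:
    """Accept boolean masks, positional indices, or obs_names."""
    arr = np.asarray(cells)
    if arr.dtype == bool:
        if arr.size != adata.n_obs:
            raise ValidationError("cells", "boolean mask length != number of cells")
        return np.flatnonzero(arr)
    if np.issubdtype(arr.dtype, np.integer):
        return arr
    idx = adata.obs_names.get_indexer(arr)
    if (idx < 0).any():
        missing = list(np.asarray(arr)[idx < 0][:5])
        raise ValidationError("cells", f"unknown cell ids: {missing}")
    return idx


def wilcoxon_de(
    adata: ad.AnnData, cells_a, cells_b, config: PipelineConfig
) -> pd.DataFrame:
    """Differential expression of group A vs group B.

    Returns a gene-indexed table with columns ``log2fc``, ``pval``,
    ``padj``, ``direction`` (up/down from the sign of log2fc), ``pct_a``
    and ``pct_b`` for the genes that pass the expression-fraction and
    fold-change filters.
    """
    ia = _resolve_cells(adata, cells_a)
    ib = _resolve_cells(adata, cells_b)
    if ia.size == 0 or ib.size == 0:
        raise ValidationError("cells", "both cell groups must be non-empty")
    if np.intersect1d(ia, ib).size:
        raise ValidationError("cells", "cell groups must be disjoint")

    def dense(idx):
        x = adata.X[idx]
        return x.toarray() if sp.issparse(x) else np.asarray(x, dtype=np.float64)

    xa, xb = dense(ia), dense(ib)
    pct_a = (xa > 0).mean(axis=0)
    pct_b = (xb > 0).mean(axis=0)
    mean_a = np.expm1(xa).mean(axis=0)
    mean_b = np.expm1(xb).mean(axis=0)
    log2fc = np.log2(mean_a + 1.0) - np.log2(mean_b + 1.0)

    keep = (np.maximum(pct_a, pct_b) >= config.de_min_pct) & (
        np.abs(log2fc) >= config.de_lfc_threshold
    )
    genes = adata.var_names[keep]
    if keep.sum() == 0:
        return pd.DataFrame(
            columns=["log2fc", "pval", "padj", "direction", "pct_a", "pct_b"]
        )
    res = mannwhitneyu(
        xa[:, keep], xb[:, keep], axis=0, alternative="two-sided", method="asymptotic"
    )
    pval = np.atleast_1d(res.pvalue)
    padj = multipletests(pval, method="fdr_bh")[1]
    lfc = log2fc[keep]
    return pd.DataFrame(
        {
            "log2fc": lfc,
            "pval": pval,
            "padj": padj,
            "direction": np.where(lfc >= 0, "up", "down"),
            "pct_a": pct_a[keep],
            "pct_b": pct_b[keep],
        },
        index=pd.Index(genes, name="gene"),
    )


@dataclass(frozen=True)
class OverlapResult:
    """Venn partition of two significant DEG sets with directionality."""

    exclusive_a: frozenset
    exclusive_b: frozenset
    shared: frozenset
    shared_same_direction: frozenset

    @property
    def counts(self) -> dict[str, int]:
        return {
            "exclusive_a": len(self.exclusive_a),
            "exclusive_b": len(self.exclusive_b),
            "shared": len(self.shared),
            "shared_same_direction": len(self.shared_same_direction),
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"gene": g, "set": name}
            for name, genes in (
                ("exclusive_a", self.exclusive_a),
                ("exclusive_b", self.exclusive_b),
                ("shared", self.shared),
            )
            for g in sorted(genes)
        ]
        df = pd.DataFrame(rows, columns=["gene", "set"])
        df["same_direction"] = df["gene"].isin(self.shared_same_direction)
        return df


def directional_overlap(
    a: pd.DataFrame, b: pd.DataFrame, config: PipelineConfig
) -> OverlapResult:
    """Compare two DEG tables at the padj < alpha cutoff.

    ``exclusive_a``, ``exclusive_b`` and ``shared`` partition the union of
    the two significant sets; ``shared_same_direction`` keeps the shared
    genes whose fold-change sign agrees between the comparisons.
    """
    sig_a = set(a.index[a["padj"] < config.alpha])
    sig_b = set(b.index[b["padj"] < config.alpha])
    shared = sig_a & sig_b
    same = {
        g for g in shared if str(a.at[g, "direction"]) == str(b.at[g, "direction"])
    }
    return OverlapResult(
        exclusive_a=frozenset(sig_a - sig_b),
        exclusive_b=frozenset(sig_b - sig_a),
        shared=frozenset(shared),
        shared_same_direction=frozenset(same),
    )
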