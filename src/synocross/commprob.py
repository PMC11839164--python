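"""Cluster-to-cluster communication probabilities.

For each condition, each cluster's expression of every ligand/receptor
gene is summarized by Tukey's trimean ``(Q1 + 2*Q2 + Q3) / 4`` (type-7
linear-interpolation quantiles).  The trimean is a robust summary that is
driven to zero unless a gene is expressed in a substantial fraction of the
cluster's cells.  Heteromeric complexes are summarized by the geometric
mean of their subunit trimeans.  The communication probability from a
sender cluster with ligand level ``L`` to a receiver cluster with receptor
level ``R`` is the saturating mass-action (Hill) response

    P = L * R / (kh + L * R),

with half-saturation constant ``kh``.  Clusters with fewer than
``min_cells`` cells in the condition are ineligible and contribute no
communication.  Significance is assessed by permuting cluster labels of
the condition's cells (restricted to eligible clusters) ``n_perm`` times
and recomputing the tensor; the p-value is the +1-corrected exceedance
fraction, so p is in ``(0, 1]`` and never exactly zero.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .config import PipelineConfig
from .data import COMPARTMENTS, CompartmentMap, clusters_sorted
from .errors import SynocrossError, ValidationError
from .lrdb import LRDatabase


def trimean(values) -> float:
    """Tukey's trimean of a non-empty 1-D sample.

    Quantiles use linear interpolation (the type-7 convention), which
    matters at small n: e.g. ``[0, 0, 0, 0, 10]`` has Q1 = Q2 = Q3 = 0 and
    hence trimean 0 — a gene expressed in under a quarter of a cluster's
    cells contributes nothing.
    """
    v = np.asarray(values, dtype=np.float64)
    if v.ndim != 1 or v.size == 0:
        raise ValidationError("values", "trimean requires a non-empty 1-D sample")
    q1, q2, q3 = np.quantile(v, (0.25, 0.5, 0.75))
    return float((q1 + 2.0 * q2 + q3) / 4.0)


def hill_probability(l: float, r: float, kh: float) -> float:
    """Saturating response ``l*r / (kh + l*r)``; in [0, 1), monotone in l and r."""
    if kh <= 0:
        raise ValidationError("kh", "must be > 0")
    lr = l * r
    return lr / (kh + lr)


@dataclass
class ClusterSummaryMatrix:
    """Per-cluster trimean expression for one condition.

    ``values`` is clusters x genes; ``counts`` the per-cluster cell count
    within the condition; ``eligible`` flags clusters meeting ``min_cells``.
    Ineligible clusters keep their summaries for inspection but are
    excluded from probability computation.
    """

    condition: str
    values: pd.DataFrame
    counts: pd.Series
    eligible: pd.Series

    @property
    def clusters(self) -> list[str]:
        return list(self.values.index)


def _dense(adata: ad.AnnData, rows: np.ndarray, gene_idx: np.ndarray) -> np.ndarray:
    x = adata.X[rows][:, gene_idx]
    return x.toarray() if sp.issparse(x) else np.asarray(x, dtype=np.float64)


def _trimean_by_cluster(x: np.ndarray, codes: np.ndarray, n_clusters: int) -> np.ndarray:
    """Trimean of each gene column within each coded cluster; empty -> 0."""
    out = np.zeros((n_clusters, x.shape[1]), dtype=np.float64)
    for c in range(n_clusters):
        block = x[codes == c]
        if block.shape[0]:
            q = np.quantile(block, (0.25, 0.5, 0.75), axis=0)
            out[c] = (q[0] + 2.0 * q[1] + q[2]) / 4.0
    return out


def cluster_summaries(
    adata: ad.AnnData,
    condition: str,
    config: PipelineConfig,
    genes: list[str] | None = None,
) -> ClusterSummaryMatrix:
    """Trimean summary of every cluster's expression within one condition."""
    cond = adata.obs["condition"].astype(str).to_numpy()
    if condition not in cond:
        raise ValidationError("condition", f"{condition!r} not present in dataset")
    clusters = clusters_sorted(adata)
    rows = np.flatnonzero(cond == condition)
    labels = adata.obs["cluster"].astype(str).to_numpy()[rows]
    codes = np.searchsorted(np.array(clusters), labels)
    if genes is None:
        gene_idx = np.arange(adata.n_vars)
        gene_names = list(adata.var_names)
    else:
        lookup = {g: i for i, g in enumerate(adata.var_names)}
        missing = [g for g in genes if g not in lookup]
        if missing:
            raise ValidationError("genes", f"unknown genes: {missing}")
        gene_idx = np.array([lookup[g] for g in genes])
        gene_names = list(genes)
    x = _dense(adata, rows, gene_idx)
    tm = _trimean_by_cluster(x, codes, len(clusters))
    counts = pd.Series(
        np.bincount(codes, minlength=len(clusters)), index=clusters, name="n_cells"
    )
    eligible = counts >= config.min_cells
    return ClusterSummaryMatrix(
        condition=condition,
        values=pd.DataFrame(tm, index=clusters, columns=gene_names),
        counts=counts,
        eligible=eligible.rename("eligible"),
    )


def complex_level(summary: ClusterSummaryMatrix, subunits, cluster: str) -> float:
    """Geometric mean of the subunit trimeans; zero if any subunit is zero."""
    subunits = list(subunits)
    missing = [g for g in subunits if g not in summary.values.columns]
    if missing:
        raise ValidationError("subunits", f"unknown genes: {missing}")
    if cluster not in summary.values.index:
        raise ValidationError("cluster", f"unknown cluster {cluster!r}")
    vals = summary.values.loc[cluster, subunits].to_numpy(dtype=np.float64)
    if np.any(vals == 0):
        return 0.0
    return float(np.exp(np.log(vals).mean()))


def _complex_levels(tm: np.ndarray, subunit_idx: list[np.ndarray]) -> np.ndarray:
    """Complex level per cluster (rows of tm) per interaction."""
    out = np.empty((tm.shape[0], len(subunit_idx)), dtype=np.float64)
    for k, idx in enumerate(subunit_idx):
        sub = tm[:, idx]
        if idx.size == 1:
            out[:, k] = sub[:, 0]
        else:
            any_zero = (sub == 0).any(axis=1)
            safe = np.where(sub > 0, sub, 1.0)
            out[:, k] = np.exp(np.log(safe).mean(axis=1))
            out[any_zero, k] = 0.0
    return out


def _probabilities(tm: np.ndarray, lig_idx, rec_idx, kh: float) -> np.ndarray:
    """P[s, r, k] from a trimean matrix over the same cluster ordering."""
    L = _complex_levels(tm, lig_idx)  # clusters x K
    R = _complex_levels(tm, rec_idx)
    lr = L[:, None, :] * R[None, :, :]
    return lr / (kh + lr)


def _perm_rng(seed: int, condition: str) -> np.random.Generator:
    """Permutation stream, split per condition from the root seed.

    The split rule (CRC-32 of the condition name as a second seed word) is
    part of the documented contract: identical seed + condition reproduce
    the exact permutation sequence.
    """
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(condition.encode())])
    )


@dataclass
class CommunicationTensor:
    """Sender x receiver x interaction probabilities for one condition.

    ``prob`` and ``pval`` share shape (n_clusters, n_clusters, n_interactions)
    over ``clusters`` (sorted) and the database's interaction order.
    Ineligible clusters have all probabilities 0 and p-values 1.
    """

    condition: str
    clusters: list[str]
    interaction_ids: list[str]
    interaction_pathways: list[str]
    prob: np.ndarray
    pval: np.ndarray
    eligible: np.ndarray
    db_fingerprint: str
    provenance: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per (sender, receiver, interaction)."""
        s_idx, r_idx, k_idx = np.meshgrid(
            np.arange(len(self.clusters)),
            np.arange(len(self.clusters)),
            np.arange(len(self.interaction_ids)),
            indexing="ij",
        )
        clusters = np.array(self.clusters)
        ids = np.array(self.interaction_ids)
        paths = np.array(self.interaction_pathways)
        return pd.DataFrame(
            {
                "condition": self.condition,
                "sender": clusters[s_idx.ravel()],
                "receiver": clusters[r_idx.ravel()],
                "interaction_id": ids[k_idx.ravel()],
                "pathway": paths[k_idx.ravel()],
                "probability": self.prob.ravel(),
                "p_value": self.pval.ravel(),
            }
        )


def _prepare(adata, db: LRDatabase, condition: str, config: PipelineConfig):
    cond = adata.obs["condition"].astype(str).to_numpy()
    if condition not in cond:
        raise ValidationError("condition", f"{condition!r} not present in dataset")
    lr_genes = db.genes
    lookup = {g: i for i, g in enumerate(adata.var_names)}
    missing = [g for g in lr_genes if g not in lookup]
    if missing:
        raise ValidationError(
            "database", f"database not bound to dataset genes; missing: {missing}"
        )
    clusters = clusters_sorted(adata)
    rows = np.flatnonzero(cond == condition)
    labels = adata.obs["cluster"].astype(str).to_numpy()[rows]
    codes = np.searchsorted(np.array(clusters), labels)
    counts = np.bincount(codes, minlength=len(clusters))
    eligible = counts >= config.min_cells
    gene_pos = {g: i for i, g in enumerate(lr_genes)}
    lig_idx = [
        np.array([gene_pos[g] for g in it.ligand_subunits]) for it in db.interactions
    ]
    rec_idx = [
        np.array([gene_pos[g] for g in it.receptor_subunits]) for it in db.interactions
    ]
    gene_idx = np.array([lookup[g] for g in lr_genes])
    x = _dense(adata, rows, gene_idx)
    return clusters, codes, eligible, x, lig_idx, rec_idx


def _observed_and_pvalues(clusters, codes, eligible, x, lig_idx, rec_idx, config, condition):
    n_c = len(clusters)
    n_k = len(lig_idx)
    elig_codes = np.flatnonzero(eligible)
    # Restrict to cells of eligible clusters: ineligible clusters neither
    # contribute probabilities nor enter the permutation pool, so removing
    # one cannot perturb unmasked entries.
    keep = np.isin(codes, elig_codes)
    x_e = x[keep]
    codes_e = codes[keep]
    remap = -np.ones(n_c, dtype=int)
    remap[elig_codes] = np.arange(elig_codes.size)
    codes_r = remap[codes_e]

    tm = _trimean_by_cluster(x_e, codes_r, elig_codes.size)
    p_obs = _probabilities(tm, lig_idx, rec_idx, config.kh)

    rng = _perm_rng(config.seed, condition)
    exceed = np.zeros_like(p_obs)
    for _ in range(config.n_perm):
        perm = rng.permutation(codes_r)
        tm_p = _trimean_by_cluster(x_e, perm, elig_codes.size)
        p_star = _probabilities(tm_p, lig_idx, rec_idx, config.kh)
        exceed += p_star >= p_obs
    pval_e = (1.0 + exceed) / (1.0 + config.n_perm)

    prob = np.zeros((n_c, n_c, n_k), dtype=np.float64)
    pval = np.ones((n_c, n_c, n_k), dtype=np.float64)
    ix = np.ix_(elig_codes, elig_codes, np.arange(n_k))
    prob[ix] = p_obs
    pval[ix] = pval_e
    return prob, pval


def permutation_significance(
    adata: ad.AnnData, db: LRDatabase, condition: str, config: PipelineConfig
) -> np.ndarray:
    """Permutation p-values for every (sender, receiver, interaction) entry.

    Cluster labels of the condition's cells (in eligible clusters) are
    shuffled ``n_perm`` times; ``p = (1 + #{P* >= P_obs}) / (1 + n_perm)``.
    Deterministic given ``config.seed``.
    """
    clusters, codes, eligible, x, lig_idx, rec_idx = _prepare(
        adata, db, condition, config
    )
    _, pval = _observed_and_pvalues(
        clusters, codes, eligible, x, lig_idx, rec_idx, config, condition
    )
    return pval


def communication_tensor(
    adata: ad.AnnData,
    db: LRDatabase,
    condition: str,
    compartments: CompartmentMap,
    config: PipelineConfig,
) -> CommunicationTensor:
    """Full communication tensor with permutation p-values for one condition."""
    clusters, codes, eligible, x, lig_idx, rec_idx = _prepare(
        adata, db, condition, config
    )
    compartments.check_covers(clusters)
    for comp in COMPARTMENTS:
        members = [c for c in clusters if compartments[c] == comp]
        if not any(eligible[clusters.index(c)] for c in members):
            raise SynocrossError(
                f"no eligible cluster in the {comp!r} compartment "
                f"for condition {condition!r} (min_cells={config.min_cells})"
            )
    prob, pval = _observed_and_pvalues(
        clusters, codes, eligible, x, lig_idx, rec_idx, config, condition
    )
    return CommunicationTensor(
        condition=condition,
        clusters=clusters,
        interaction_ids=[it.interaction_id for it in db.interactions],
        interaction_pathways=[it.pathway for it in db.interactions],
        prob=prob,
        pval=pval,
        eligible=eligible,
        db_fingerprint=db.fingerprint(),
        provenance={
            "n_perm": config.n_perm,
            "seed": config.seed,
            "kh": config.kh,
            "min_cells": config.min_cells,
            "alpha": config.alpha,
        },
    )
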