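"""Independent brute-force oracles used by the test suite.

Everything here is written as straight-line loops over Python floats, on
purpose: no shared code with the package's vectorized implementation
beyond the documented permutation-stream contract (seed splitting and the
order in which labels are shuffled), which is part of the reproducibility
guarantee being tested.
"""

from __future__ import annotations

import math
import zlib

import numpy as np
import scipy.sparse as sp


def quantile_type7(values, q):
    """Linear-interpolation (type-7) quantile by direct sorting."""
    s = sorted(float(v) for v in values)
    n = len(s)
    if n == 1:
        return s[0]
    h = (n - 1) * q
    lo = math.floor(h)
    hi = min(lo + 1, n - 1)
    return s[lo] + (h - lo) * (s[hi] - s[lo])


def trimean_oracle(values):
    return (
        quantile_type7(values, 0.25)
        + 2.0 * quantile_type7(values, 0.5)
        + quantile_type7(values, 0.75)
    ) / 4.0


def geometric_mean_oracle(values):
    vals = [float(v) for v in values]
    if any(v == 0.0 for v in vals):
        return 0.0
    prod = 1.0
    for v in vals:
        prod *= v
    return prod ** (1.0 / len(vals))


def hill_oracle(l, r, kh):
    return (l * r) / (kh + l * r)


def tensor_oracle(adata, db, condition, config):
    """Loop-based recomputation of probabilities and permutation p-values.

    Returns (prob, pval) arrays over sorted clusters x db interaction
    order, matching the package's tensor layout.
    """
    cond = adata.obs["condition"].astype(str).to_numpy()
    clusters = sorted(set(adata.obs["cluster"].astype(str)))
    rows = [i for i in range(adata.n_obs) if cond[i] == condition]
    labels = [str(adata.obs["cluster"].iloc[i]) for i in rows]
    x = adata.X[rows]
    x = x.toarray() if sp.issparse(x) else np.asarray(x, dtype=float)
    gene_pos = {g: j for j, g in enumerate(adata.var_names)}

    counts = {c: labels.count(c) for c in clusters}
    eligible = [c for c in clusters if counts[c] >= config.min_cells]
    # permutation pool: cells of eligible clusters, dataset order
    keep = [i for i, lab in enumerate(labels) if lab in eligible]
    x_e = x[keep]
    labels_e = [labels[i] for i in keep]
    codes_e = np.array([eligible.index(lab) for lab in labels_e])

    def probabilities(codes):
        tm = {}
        for ci, c in enumerate(eligible):
            cells = [i for i in range(len(codes)) if codes[i] == ci]
            tm[c] = [
                trimean_oracle([x_e[i, j] for i in cells]) for j in range(x_e.shape[1])
            ]
        p = {}
        for it in db.interactions:
            for s in eligible:
                lig = geometric_mean_oracle(
                    [tm[s][gene_pos[g]] for g in it.ligand_subunits]
                )
                for r in eligible:
                    rec = geometric_mean_oracle(
                        [tm[r][gene_pos[g]] for g in it.receptor_subunits]
                    )
                    p[(s, r, it.interaction_id)] = hill_oracle(lig, rec, config.kh)
        return p

    # oracle uses the full gene -> column map of the LR submatrix the
    # implementation extracts: rebuild x_e restricted to db genes so the
    # column lookup below is valid
    lr_genes = db.genes
    col = {g: k for k, g in enumerate(lr_genes)}
    x_e = x_e[:, [gene_pos[g] for g in lr_genes]]
    gene_pos = col

    p_obs = probabilities(codes_e)
    rng = np.random.default_rng(
        np.random.SeedSequence([int(config.seed), zlib.crc32(condition.encode())])
    )
    exceed = {key: 0 for key in p_obs}
    for _ in range(config.n_perm):
        perm = rng.permutation(codes_e)
        p_star = probabilities(perm)
        for key in p_obs:
            if p_star[key] >= p_obs[key]:
                exceed[key] += 1

    n_c = len(clusters)
    n_k = len(db.interactions)
    prob = np.zeros((n_c, n_c, n_k))
    pval = np.ones((n_c, n_c, n_k))
    for (s, r, iid), p in p_obs.items():
        si, ri = clusters.index(s), clusters.index(r)
        ki = [it.interaction_id for it in db.interactions].index(iid)
        prob[si, ri, ki] = p
        pval[si, ri, ki] = (1.0 + exceed[(s, r, iid)]) / (1.0 + config.n_perm)
    return prob, pval


def overlap_oracle(table_a, table_b, alpha):
    """Brute-force set enumeration of the directional Venn partition."""
    sig_a = {g for g in table_a.index if table_a.at[g, "padj"] < alpha}
    sig_b = {g for g in table_b.index if table_b.at[g, "padj"] < alpha}
    shared = {g for g in sig_a if g in sig_b}
    return {
        "exclusive_a": {g for g in sig_a if g not in sig_b},
        "exclusive_b": {g for g in sig_b if g not in sig_a},
        "shared": shared,
        "shared_same_direction": {
            g for g in shared if table_a.at[g, "direction"] == table_b.at[g, "direction"]
        },
    }
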