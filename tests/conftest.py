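import numpy as np
import pandas as pd
import pytest

import synocross as sx


@pytest.fixture
def pcfg():
    return sx.PipelineConfig()


def csf_scenario(seed: int) -> sx.SynthConfig:
    """Injury-induced stromal->immune CSF pathway (two ligands, one receptor)
    planted among decoys: fibroblasts send Csf1, pericytes send Il34, and
    macrophages carry the receptor, only in the injured condition."""
    return sx.SynthConfig(
        seed=seed,
        planted=(
            sx.PlantedSignal(
                pathway="CSF",
                ligand_subunits=("Csf1",),
                receptor_subunits=("Csf1r",),
                sender_cluster="FibroLining",
                receiver_cluster="Macrophage",
                conditions_active=("ACLR7",),
                fold_effect=8.0,
                exclusive=True,
            ),
            sx.PlantedSignal(
                pathway="CSF",
                ligand_subunits=("Il34",),
                receptor_subunits=("Csf1r",),
                sender_cluster="Pericyte",
                receiver_cluster="Macrophage",
                conditions_active=("ACLR7",),
                fold_effect=6.0,
                exclusive=True,
            ),
        ),
    )


def toy_two_cluster_dataset(n_per_cluster=10, ligand_value=1.0, receptor_value=1.0):
    """20-cell toy: ligand expressed only in the stromal cluster, receptor
    only in the immune cluster, both constant within their cluster."""
    genes = ["Lg", "Rg", "Other"]
    n = 2 * n_per_cluster
    x = np.zeros((n, 3))
    x[:n_per_cluster, 0] = ligand_value
    x[n_per_cluster:, 1] = receptor_value
    obs = pd.DataFrame(
        {
            "cluster": ["A"] * n_per_cluster + ["B"] * n_per_cluster,
            "condition": ["Sham"] * n,
        },
        index=[f"c{i}" for i in range(n)],
    )
    adata = sx.make_dataset(x, obs, genes)
    cmap = sx.CompartmentMap({"A": "stromal", "B": "immune"})
    db = sx.LRDatabase(
        (
            sx.LRInteraction("Lg__Rg", "TOY", ("Lg",), ("Rg",)),
        )
    )
    return adata, db, cmap


def make_tensor(prob, pval, clusters, pathways_per_interaction, ids=None):
    """Assemble a CommunicationTensor directly from arrays (for unit tests)."""
    prob = np.asarray(prob, dtype=float)
    pval = np.asarray(pval, dtype=float)
    n_k = prob.shape[2]
    return sx.CommunicationTensor(
        condition="Sham",
        clusters=list(clusters),
        interaction_ids=list(ids) if ids else [f"i{k}" for k in range(n_k)],
        interaction_pathways=list(pathways_per_interaction),
        prob=prob,
        pval=pval,
        eligible=np.ones(len(clusters), dtype=bool),
        db_fingerprint="test",
    )


@pytest.fixture
def small_simulated():
    """One small seeded simulation shared by read-only tests."""
    cfg = sx.SynthConfig(
        seed=11,
        clusters=(
            sx.ClusterSpec("Fibro", "stromal", 40),
            sx.ClusterSpec("Peri", "stromal", 30),
            sx.ClusterSpec("Mac", "immune", 40),
            sx.ClusterSpec("T", "immune", 30),
        ),
        n_genes=300,
        n_decoys=10,
        planted=(
            sx.PlantedSignal(
                pathway="CSF",
                ligand_subunits=("Csf1",),
                receptor_subunits=("Csf1r",),
                sender_cluster="Fibro",
                receiver_cluster="Mac",
                conditions_active=("ACLR7",),
                fold_effect=8.0,
                exclusive=True,
            ),
        ),
    )
    return sx.simulate_dataset(cfg)
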