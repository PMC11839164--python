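"""Seeded synthetic single-cell data with planted directional signaling.

The generator emulates a Sham-vs-injury synovial design: >=2 conditions,
>=4 clusters spanning the stromal and immune compartments, negative-
binomial counts (variance = mu + mu^2/dispersion), and planted
ligand/receptor expression programs with known sender, receiver, pathway
and condition-specific induction.  Counts are library-size normalized to
10,000 and log1p-transformed (the LogNormalize convention); raw counts
are retained alongside.

A planted signal raises the mean of its ligand genes in the sender
cluster and of its receptor genes in the receiver cluster by
``fold_effect`` in its active conditions.  With ``exclusive=True`` the
planted genes are silent (mean 0) outside their planted cluster and
outside their active conditions — the structure of a ligand confined to
the stromal compartment and a receptor confined to the immune
compartment, which makes reverse-direction communication exactly zero.
With the default ``exclusive=False`` they sit at the baseline mean
everywhere else.

All randomness derives from one root seed through named
``numpy.random.SeedSequence`` spawns (counts first, then decoy gene
choice), so identical configs are bit-identical across calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import yaml

from .data import COMPARTMENTS, IMMUNE, STROMAL, CompartmentMap, make_dataset, write_dataset
from .errors import ValidationError
from .lrdb import LRDatabase, LRInteraction

SCALE_FACTOR = 1e4


@dataclass(frozen=True)
class ClusterSpec:
    name: str
    compartment: str
    cells_per_condition: int


@dataclass(frozen=True)
class PlantedSignal:
    """A ligand-receptor program planted with known direction and induction."""

    pathway: str
    ligand_subunits: tuple[str, ...]
    receptor_subunits: tuple[str, ...]
    sender_cluster: str
    receiver_cluster: str
    conditions_active: tuple[str, ...]
    fold_effect: float
    exclusive: bool = False

    def __post_init__(self):
        if set(self.ligand_subunits) & set(self.receptor_subunits):
            raise ValidationError(
                "ligand_subunits", "ligand and receptor gene sets must be disjoint"
            )
        if not self.fold_effect > 1:
            raise ValidationError("fold_effect", "must be > 1")

    @property
    def interaction_id(self) -> str:
        return "_".join(self.ligand_subunits) + "__" + "_".join(self.receptor_subunits)


@dataclass(frozen=True)
class SynthConfig:
    """Study-design parameters of the synthetic dataset."""

    seed: int = 0
    conditions: tuple[str, ...] = ("Sham", "ACLR7")
    clusters: tuple[ClusterSpec, ...] = (
        ClusterSpec("FibroLining", STROMAL, 150),
        ClusterSpec("Pericyte", STROMAL, 100),
        ClusterSpec("Macrophage", IMMUNE, 150),
        ClusterSpec("TCell", IMMUNE, 100),
    )
    n_genes: int = 2000
    nb_mean: float = 0.5
    nb_dispersion: float = 2.0
    planted: tuple[PlantedSignal, ...] = ()
    n_decoys: int = 20

    def __post_init__(self):
        if len(self.conditions) < 2:
            raise ValidationError("conditions", "need at least 2 conditions")
        if len(set(self.conditions)) != len(self.conditions):
            raise ValidationError("conditions", "condition names must be unique")
        names = [c.name for c in self.clusters]
        if len(set(names)) != len(names):
            raise ValidationError("clusters", "cluster names must be unique")
        comps = {c.compartment for c in self.clusters}
        for c in self.clusters:
            if c.compartment not in COMPARTMENTS:
                raise ValidationError(
                    "clusters", f"unknown compartment {c.compartment!r}"
                )
            if c.cells_per_condition < 1:
                raise ValidationError("clusters", "cells_per_condition must be >= 1")
        if not {STROMAL, IMMUNE} <= comps:
            raise ValidationError(
                "clusters", "need at least one stromal and one immune cluster"
            )
        if self.n_genes < 1:
            raise ValidationError("n_genes", "must be >= 1")
        if not self.nb_mean > 0:
            raise ValidationError("nb_mean", "must be > 0")
        if not self.nb_dispersion > 0:
            raise ValidationError("nb_dispersion", "must be > 0")
        if self.n_decoys < 0:
            raise ValidationError("n_decoys", "must be >= 0")
        cluster_set = set(names)
        for sig in self.planted:
            if sig.sender_cluster not in cluster_set:
                raise ValidationError(
                    "planted", f"unknown sender cluster {sig.sender_cluster!r}"
                )
            if sig.receiver_cluster not in cluster_set:
                raise ValidationError(
                    "planted", f"unknown receiver cluster {sig.receiver_cluster!r}"
                )
            for cond in sig.conditions_active:
                if cond not in self.conditions:
                    raise ValidationError(
                        "planted", f"unknown active condition {cond!r}"
                    )
        planted_genes = self.planted_genes()
        if len(planted_genes) + 2 * self.n_decoys > self.n_genes:
            raise ValidationError(
                "n_genes",
                "too small for the planted genes plus decoy interactions",
            )

    def planted_genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for sig in self.planted:
            for g in sig.ligand_subunits + sig.receptor_subunits:
                seen.setdefault(g)
        return list(seen)

    @property
    def compartment_map(self) -> CompartmentMap:
        return CompartmentMap({c.name: c.compartment for c in self.clusters})

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


@dataclass(frozen=True)
class GroundTruth:
    """What the pipeline should recover from a planted configuration.

    ``expected_top[(direction, condition)]`` names the planted pathway that
    should rank first in that direction for that condition (largest
    fold_effect among matching, active signals), or is absent when no
    signal qualifies.  ``edges`` records each planted sender->receiver edge
    with its active conditions.
    """

    expected_top: dict = field(default_factory=dict)
    edges: tuple = ()

    @property
    def empty(self) -> bool:
        return not self.expected_top and not self.edges

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"direction": d, "condition": c, "pathway": pw}
            for (d, c), pw in self.expected_top.items()
        ]
        return pd.DataFrame(rows, columns=["direction", "condition", "pathway"])


def ground_truth_ranking(config: SynthConfig) -> GroundTruth:
    """Expected top pathway per direction and condition, from the config alone."""
    comp = {c.name: c.compartment for c in config.clusters}
    expected: dict = {}
    directions = {
        "stromal_to_immune": (STROMAL, IMMUNE),
        "immune_to_stromal": (IMMUNE, STROMAL),
    }
    for dname, (s_comp, r_comp) in directions.items():
        for cond in config.conditions:
            best = None
            for sig in config.planted:
                if cond not in sig.conditions_active:
                    continue
                if comp[sig.sender_cluster] != s_comp or comp[sig.receiver_cluster] != r_comp:
                    continue
                if best is None or sig.fold_effect > best.fold_effect:
                    best = sig
            if best is not None:
                expected[(dname, cond)] = best.pathway
    edges = tuple(
        (sig.pathway, sig.sender_cluster, sig.receiver_cluster, sig.conditions_active)
        for sig in config.planted
    )
    return GroundTruth(expected_top=expected, edges=edges)


def _mean_matrix(config: SynthConfig, gene_names: list[str]) -> dict:
    """Per (cluster, condition): vector of negative-binomial means."""
    gene_pos = {g: i for i, g in enumerate(gene_names)}
    base = np.full(len(gene_names), config.nb_mean, dtype=np.float64)
    # exclusive planted genes are silent everywhere except their planted slots
    for sig in config.planted:
        if sig.exclusive:
            for g in sig.ligand_subunits + sig.receptor_subunits:
                base[gene_pos[g]] = 0.0
    means = {
        (cl.name, cond): base.copy()
        for cl in config.clusters
        for cond in config.conditions
    }
    for sig in config.planted:
        targets = [
            (sig.sender_cluster, sig.ligand_subunits),
            (sig.receiver_cluster, sig.receptor_subunits),
        ]
        for cluster, genes in targets:
            for cond in config.conditions:
                mu = means[(cluster, cond)]
                for g in genes:
                    j = gene_pos[g]
                    if cond in sig.conditions_active:
                        mu[j] = max(mu[j], config.nb_mean * sig.fold_effect)
                    elif not sig.exclusive:
                        mu[j] = max(mu[j], config.nb_mean)
    return means


def simulate_dataset(
    config: SynthConfig,
) -> tuple[ad.AnnData, LRDatabase, CompartmentMap, GroundTruth]:
    """Draw a seeded synthetic dataset with its database, map and truth."""
    root = np.random.SeedSequence(config.seed)
    ss_counts, ss_decoys = root.spawn(2)
    rng_counts = np.random.default_rng(ss_counts)
    rng_decoys = np.random.default_rng(ss_decoys)

    planted_genes = config.planted_genes()
    n_background = config.n_genes - len(planted_genes)
    gene_names = planted_genes + [f"G{i:05d}" for i in range(n_background)]
    means = _mean_matrix(config, gene_names)

    theta = config.nb_dispersion
    blocks, obs_rows = [], []
    cell_counter = 0
    for cond in config.conditions:
        for cl in config.clusters:
            mu = means[(cl.name, cond)]
            p = np.where(mu > 0, theta / (theta + mu), 1.0)
            block = rng_counts.negative_binomial(
                theta, p[None, :], size=(cl.cells_per_condition, config.n_genes)
            )
            blocks.append(block)
            for _ in range(cl.cells_per_condition):
                obs_rows.append((f"C{cell_counter:06d}", cl.name, cond))
                cell_counter += 1
    counts = np.vstack(blocks).astype(np.float64)
    lib = counts.sum(axis=1, keepdims=True)
    lib[lib == 0] = 1.0
    normalized = np.log1p(counts / lib * SCALE_FACTOR)
    obs = pd.DataFrame(obs_rows, columns=["cell_id", "cluster", "condition"]).set_index(
        "cell_id"
    )
    adata = make_dataset(normalized, obs, gene_names, counts=counts)

    interactions = [
        LRInteraction(
            interaction_id=sig.interaction_id,
            pathway=sig.pathway,
            ligand_subunits=sig.ligand_subunits,
            receptor_subunits=sig.receptor_subunits,
        )
        for sig in config.planted
    ]
    background = gene_names[len(planted_genes):]
    decoy_genes = rng_decoys.choice(
        len(background), size=2 * config.n_decoys, replace=False
    )
    for d in range(config.n_decoys):
        lig = background[decoy_genes[2 * d]]
        rec = background[decoy_genes[2 * d + 1]]
        interactions.append(
            LRInteraction(
                interaction_id=f"{lig}__{rec}",
                pathway=f"Decoy{d:02d}",
                ligand_subunits=(lig,),
                receptor_subunits=(rec,),
            )
        )
    db = LRDatabase(tuple(interactions))
    return adata, db, config.compartment_map, ground_truth_ranking(config)


def write_simulation(
    outdir: str | Path,
    adata: ad.AnnData,
    db: LRDatabase,
    compartments: CompartmentMap,
    truth: GroundTruth,
    config: SynthConfig,
) -> list[Path]:
    """Write the full simulated bundle as Matrix Market + TSV + YAML files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = write_dataset(outdir, adata)
    db.write_tsv(outdir / "lr_database.tsv")
    compartments.write_tsv(outdir / "compartments.tsv")
    truth.to_frame().to_csv(outdir / "ground_truth.tsv", sep="\t", index=False)
    config.to_yaml(outdir / "synth_config.yaml")
    written += [
        outdir / "lr_database.tsv",
        outdir / "compartments.tsv",
        outdir / "ground_truth.tsv",
        outdir / "synth_config.yaml",
    ]
    return written


def synth_config_from_dict(d: dict) -> SynthConfig:
    """Build a SynthConfig from the YAML/CLI dictionary dialect."""
    clusters = tuple(
        ClusterSpec(
            name=c["name"],
            compartment=c["compartment"],
            cells_per_condition=int(c.get("cells", c.get("cells_per_condition"))),
        )
        for c in d.get("clusters", [])
    ) or SynthConfig.__dataclass_fields__["clusters"].default
    planted = tuple(
        PlantedSignal(
            pathway=p["pathway"],
            ligand_subunits=tuple(str(p.get("ligand", "")).split("_"))
            if "ligand" in p
            else tuple(p["ligand_subunits"]),
            receptor_subunits=tuple(str(p.get("receptor", "")).split("_"))
            if "receptor" in p
            else tuple(p["receptor_subunits"]),
            sender_cluster=p.get("sender", p.get("sender_cluster")),
            receiver_cluster=p.get("receiver", p.get("receiver_cluster")),
            conditions_active=tuple(p.get("active", p.get("conditions_active", ()))),
            fold_effect=float(p["fold_effect"]),
            exclusive=bool(p.get("exclusive", False)),
        )
        for p in d.get("planted", [])
    )
    kwargs = {}
    for key in ("seed", "n_genes", "nb_mean", "nb_dispersion", "n_decoys"):
        if key in d:
            kwargs[key] = d[key]
    if "conditions" in d:
        kwargs["conditions"] = tuple(d["conditions"])
    return SynthConfig(clusters=clusters, planted=planted, **kwargs)
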