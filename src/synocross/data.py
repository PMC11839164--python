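"""Expression dataset container, compartment map, and standard-format I/O.

The in-memory substrate of the pipeline is an :class:`anndata.AnnData`
with log-normalized expression in ``X``, raw counts (when available) in
``layers["counts"]``, and per-cell ``cluster`` and ``condition`` labels in
``obs``.  On disk, datasets are Matrix Market matrices plus TSV metadata.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .errors import FormatError, ValidationError

STROMAL = "stromal"
IMMUNE = "immune"
COMPARTMENTS = (STROMAL, IMMUNE)


def make_dataset(
    normalized,
    cells: pd.DataFrame,
    gene_names: Iterable[str],
    counts=None,
) -> ad.AnnData:
    """Assemble an AnnData from a normalized matrix and cell metadata.

    ``cells`` must carry ``cluster`` and ``condition`` columns; its index
    becomes the cell identifiers.
    """
    var = pd.DataFrame(index=pd.Index(list(gene_names), name="gene_id"))
    adata = ad.AnnData(
        X=sp.csr_matrix(normalized, dtype=np.float64),
        obs=cells.copy(),
        var=var,
    )
    if counts is not None:
        adata.layers["counts"] = sp.csr_matrix(counts, dtype=np.float64)
    validate_dataset(adata)
    return adata


def validate_dataset(adata: ad.AnnData) -> None:
    """Check the dataset invariants; raise :class:`ValidationError` if broken."""
    for col in ("cluster", "condition"):
        if col not in adata.obs.columns:
            raise ValidationError(col, "missing per-cell metadata column")
        if adata.obs[col].isna().any():
            raise ValidationError(col, "contains missing values")
    if adata.var_names.duplicated().any():
        raise ValidationError("gene_id", "gene names must be unique")
    x = adata.X.data if sp.issparse(adata.X) else np.asarray(adata.X)
    if not np.all(np.isfinite(x)):
        raise ValidationError("matrix", "expression values must be finite")
    if x.size and x.min() < 0:
        raise ValidationError("matrix", "expression values must be non-negative")


def conditions_in_order(adata: ad.AnnData) -> list[str]:
    """Condition names in order of first appearance (first = reference)."""
    return list(pd.unique(adata.obs["condition"].astype(str)))


def clusters_sorted(adata: ad.AnnData) -> list[str]:
    return sorted(pd.unique(adata.obs["cluster"].astype(str)))


def write_dataset(outdir: str | Path, adata: ad.AnnData) -> list[Path]:
    """Write normalized.mtx, counts.mtx (if present), cells.tsv, genes.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    p = outdir / "normalized.mtx"
    scipy.io.mmwrite(p, sp.coo_matrix(adata.X))
    written.append(p)
    if "counts" in adata.layers:
        p = outdir / "counts.mtx"
        scipy.io.mmwrite(p, sp.coo_matrix(adata.layers["counts"]).astype(np.int64))
        written.append(p)
    cells = adata.obs[["cluster", "condition"]].copy()
    cells.insert(0, "cell_id", adata.obs_names)
    p = outdir / "cells.tsv"
    cells.to_csv(p, sep="\t", index=False)
    written.append(p)
    p = outdir / "genes.tsv"
    pd.DataFrame({"gene_id": adata.var_names}).to_csv(p, sep="\t", index=False)
    written.append(p)
    return written


def read_dataset(
    matrix: str | Path,
    cells: str | Path,
    genes: str | Path,
    counts: str | Path | None = None,
) -> ad.AnnData:
    """Read a dataset from Matrix Market + TSV files (or a single .h5ad)."""
    matrix = Path(matrix)
    if matrix.suffix == ".h5ad":
        adata = ad.read_h5ad(matrix)
        validate_dataset(adata)
        return adata
    for p in (matrix, Path(cells), Path(genes)):
        if not p.exists():
            raise FileNotFoundError(str(p))
    x = sp.csr_matrix(scipy.io.mmread(matrix))
    cells_df = pd.read_csv(cells, sep="\t")
    for col in ("cell_id", "cluster", "condition"):
        if col not in cells_df.columns:
            raise FormatError(f"cells table is missing column '{col}'")
    genes_df = pd.read_csv(genes, sep="\t")
    if "gene_id" not in genes_df.columns:
        raise FormatError("genes table is missing column 'gene_id'")
    obs = cells_df.set_index("cell_id")[["cluster", "condition"]]
    counts_m = None
    if counts is not None and Path(counts).exists():
        counts_m = sp.csr_matrix(scipy.io.mmread(counts))
    return make_dataset(x, obs, genes_df["gene_id"].astype(str), counts=counts_m)


@dataclass(frozen=True)
class CompartmentMap:
    """Total assignment of clusters to the stromal or immune compartment."""

    mapping: Mapping[str, str]

    def __post_init__(self):
        for cluster, comp in self.mapping.items():
            if comp not in COMPARTMENTS:
                raise ValidationError(
                    "compartment",
                    f"cluster {cluster!r} assigned to unknown compartment {comp!r}",
                )

    def __getitem__(self, cluster: str) -> str:
        try:
            return self.mapping[cluster]
        except KeyError:
            raise ValidationError(
                "compartments", f"cluster {cluster!r} has no compartment assignment"
            ) from None

    def __contains__(self, cluster: str) -> bool:
        return cluster in self.mapping

    @property
    def clusters(self) -> list[str]:
        return list(self.mapping)

    def clusters_of(self, compartment: str) -> list[str]:
        return [c for c, k in self.mapping.items() if k == compartment]

    def check_covers(self, clusters: Iterable[str]) -> None:
        missing = [c for c in clusters if c not in self.mapping]
        if missing:
            raise ValidationError(
                "compartments", f"clusters without compartment: {missing}"
            )

    def write_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"cluster": list(self.mapping), "compartment": list(self.mapping.values())}
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "CompartmentMap":
        df = pd.read_csv(path, sep="\t")
        for col in ("cluster", "compartment"):
            if col not in df.columns:
                raise FormatError(f"compartment table is missing column '{col}'")
        return cls(dict(zip(df["cluster"].astype(str), df["compartment"].astype(str))))
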