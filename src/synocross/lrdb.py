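"""Ligand-receptor interaction databases.

Interactions pair a (possibly heteromeric) ligand with a receptor complex
and are grouped into named signaling pathways (e.g. the CSF pathway holds
Csf1->Csf1r and Il34->Csf1r).  On disk a database is a TSV with columns
``interaction_id``, ``pathway``, ``ligand``, ``receptor``; complex
subunits are joined by ``"_"`` (``Csf2ra_Csf2rb``).
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

_COLUMNS = ("interaction_id", "pathway", "ligand", "receptor")


@dataclass(frozen=True)
class LRInteraction:
    interaction_id: str
    pathway: str
    ligand_subunits: tuple[str, ...]
    receptor_subunits: tuple[str, ...]

    def __post_init__(self):
        if not self.ligand_subunits:
            raise ValidationError("ligand_subunits", "must be non-empty")
        if not self.receptor_subunits:
            raise ValidationError("receptor_subunits", "must be non-empty")

    @property
    def genes(self) -> tuple[str, ...]:
        return self.ligand_subunits + self.receptor_subunits


@dataclass(frozen=True)
class LRDatabase:
    interactions: tuple[LRInteraction, ...] = ()

    def __post_init__(self):
        ids = [i.interaction_id for i in self.interactions]
        if len(ids) != len(set(ids)):
            dup = sorted({x for x in ids if ids.count(x) > 1})
            raise ValidationError("interaction_id", f"duplicate ids: {dup}")

    def __len__(self) -> int:
        return len(self.interactions)

    @property
    def pathways(self) -> dict[str, list[str]]:
        """Pathway name -> interaction ids, preserving interaction order."""
        idx: dict[str, list[str]] = {}
        for it in self.interactions:
            idx.setdefault(it.pathway, []).append(it.interaction_id)
        return idx

    @property
    def genes(self) -> list[str]:
        """All genes referenced by any interaction, in order of first use."""
        seen: dict[str, None] = {}
        for it in self.interactions:
            for g in it.genes:
                seen.setdefault(g)
        return list(seen)

    def fingerprint(self) -> str:
        """Stable hash of the database contents, for provenance checks."""
        h = hashlib.sha256()
        for it in self.interactions:
            h.update(
                "\t".join(
                    (
                        it.interaction_id,
                        it.pathway,
                        "_".join(it.ligand_subunits),
                        "_".join(it.receptor_subunits),
                    )
                ).encode()
            )
            h.update(b"\n")
        return h.hexdigest()[:16]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "interaction_id": [i.interaction_id for i in self.interactions],
                "pathway": [i.pathway for i in self.interactions],
                "ligand": ["_".join(i.ligand_subunits) for i in self.interactions],
                "receptor": ["_".join(i.receptor_subunits) for i in self.interactions],
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def read_lr_table(path: str | Path) -> LRDatabase:
    """Read a ligand-receptor TSV into an :class:`LRDatabase`.

    An empty file (header only, or zero bytes) yields an empty database.
    A missing required column raises :class:`FormatError` naming it.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        return LRDatabase()
    for col in _COLUMNS:
        if col not in df.columns:
            raise FormatError(f"ligand-receptor table is missing column '{col}'")
    interactions = tuple(
        LRInteraction(
            interaction_id=row.interaction_id,
            pathway=row.pathway,
            ligand_subunits=tuple(row.ligand.split("_")),
            receptor_subunits=tuple(row.receptor.split("_")),
        )
        for row in df.itertuples()
    )
    return LRDatabase(interactions)


def bind_to_genes(db: LRDatabase, genes) -> tuple[LRDatabase, list[str]]:
    """Drop interactions whose subunits are absent from ``genes``.

    Returns the filtered database (interaction order preserved) and one
    warning string per dropped interaction; warnings are also logged.
    Idempotent: binding a bound database is a no-op.
    """
    present = set(genes)
    kept, warnings = [], []
    for it in db.interactions:
        missing = [g for g in it.genes if g not in present]
        if missing:
            msg = (
                f"dropping interaction {it.interaction_id!r} "
                f"(pathway {it.pathway!r}): missing genes {missing}"
            )
            warnings.append(msg)
            logger.warning(msg)
        else:
            kept.append(it)
    return LRDatabase(tuple(kept)), warnings
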