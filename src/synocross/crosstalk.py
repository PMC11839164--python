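"""Directional stromal-immune crosstalk scoring.

Communication probabilities are aggregated to pathway level, keeping only
entries whose permutation p-value falls below the significance threshold.
Each (sender, receiver) pair belongs to one of four compartment-direction
classes — stromal->immune, immune->stromal, stromal->stromal,
immune->immune — and a pathway's crosstalk fraction in a direction is its
class sum divided by its total over all four classes.  "Multi-directional"
is the sum of the two cross-compartment directions.  Pathways are ranked
by crosstalk fraction; injured-vs-reference induction ratios compare a
pathway's directional score across conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd

from .config import PipelineConfig
from .data import IMMUNE, STROMAL, CompartmentMap
from .errors import SynocrossError, ValidationError
from .commprob import CommunicationTensor

S2I = "stromal_to_immune"
I2S = "immune_to_stromal"
S2S = "stromal_to_stromal"
I2I = "immune_to_immune"
MULTI = "multi"
CLASSES = (S2I, I2S, S2S, I2I)
DIRECTIONS = (S2I, I2S, MULTI)

_FLAG_FINITE = "finite"
_FLAG_INFINITE = "infinite"
_FLAG_UNDEFINED = "undefined"


@dataclass
class PathwayScoreTable:
    """Per-pathway directional scores and crosstalk fractions, one condition.

    ``scores`` is indexed by pathway with columns: the four class sums,
    ``multi``, ``total``, ``frac_<class>``, ``frac_multi`` and a
    ``zero_total`` flag.  Conservation holds by construction:
    ``total`` is the exact sum of the four class scores.
    """

    condition: str
    scores: pd.DataFrame
    db_fingerprint: str
    provenance: dict = field(default_factory=dict)


def pathway_scores(
    tensor: CommunicationTensor,
    compartments: CompartmentMap,
    config: PipelineConfig,
) -> PathwayScoreTable:
    """Aggregate significant probabilities to pathway-level direction classes."""
    compartments.check_covers(tensor.clusters)
    comp = np.array([compartments[c] for c in tensor.clusters])
    stromal = comp == STROMAL
    class_masks = {
        S2I: np.outer(stromal, ~stromal),
        I2S: np.outer(~stromal, stromal),
        S2S: np.outer(stromal, stromal),
        I2I: np.outer(~stromal, ~stromal),
    }
    sig = tensor.pval < config.alpha
    contrib = np.where(sig, tensor.prob, 0.0)

    pathways = list(dict.fromkeys(tensor.interaction_pathways))
    path_arr = np.array(tensor.interaction_pathways)
    rows = []
    for pw in pathways:
        k_mask = path_arr == pw
        per_pair = contrib[:, :, k_mask].sum(axis=2)
        class_sums = {cls: float(per_pair[m].sum()) for cls, m in class_masks.items()}
        total = class_sums[S2I] + class_sums[I2S] + class_sums[S2S] + class_sums[I2I]
        multi = class_sums[S2I] + class_sums[I2S]
        row = {"pathway": pw, **class_sums, MULTI: multi, "total": total}
        if total > 0:
            for cls in CLASSES:
                row[f"frac_{cls}"] = class_sums[cls] / total
            row["frac_multi"] = multi / total
            row["zero_total"] = False
        else:
            for cls in CLASSES:
                row[f"frac_{cls}"] = 0.0
            row["frac_multi"] = 0.0
            row["zero_total"] = True
        rows.append(row)
    scores = pd.DataFrame(rows).set_index("pathway")
    return PathwayScoreTable(
        condition=tensor.condition,
        scores=scores,
        db_fingerprint=tensor.db_fingerprint,
        provenance=dict(tensor.provenance),
    )


def rank_crosstalk(table: PathwayScoreTable, direction: str) -> list[str]:
    """Pathways ordered by crosstalk relevance in one direction.

    Sort key: crosstalk fraction (desc), then directional score (desc),
    then pathway name; zero-total pathways always come last.  The result
    is a total order independent of input pathway order.
    """
    if direction not in DIRECTIONS:
        raise ValidationError("direction", f"must be one of {DIRECTIONS}")
    frac_col = f"frac_{direction}" if direction != MULTI else "frac_multi"
    df = table.scores
    order = sorted(
        df.index,
        key=lambda pw: (
            bool(df.at[pw, "zero_total"]),
            -float(df.at[pw, frac_col]),
            -float(df.at[pw, direction]),
            pw,
        ),
    )
    return order


@dataclass
class InductionTable:
    """Alternate/reference score ratios per pathway and direction.

    ``table`` columns: pathway, direction, reference_score, alternate_score,
    ratio, flag.  Flags: ``finite`` (reference > 0), ``infinite``
    (reference 0, alternate > 0), ``undefined`` (both 0).  In epsilon mode
    the ratio column holds ``(alt + eps) / (ref + eps)`` for every row and
    the flag still records the underlying case.
    """

    reference_condition: str
    alternate_condition: str
    table: pd.DataFrame
    db_fingerprint: str


def induction_ratios(
    reference: PathwayScoreTable,
    alternate: PathwayScoreTable,
    config: PipelineConfig,
) -> InductionTable:
    """Per pathway x direction ratio of directional scores alternate/reference."""
    if reference.db_fingerprint != alternate.db_fingerprint:
        raise SynocrossError(
            "score tables come from different ligand-receptor databases "
            f"({reference.db_fingerprint} vs {alternate.db_fingerprint})"
        )
    pathways = list(
        dict.fromkeys(list(reference.scores.index) + list(alternate.scores.index))
    )
    rows = []
    for pw in pathways:
        for direction in DIRECTIONS:
            col = direction
            if config.ratio_on_fractions:
                col = "frac_multi" if direction == MULTI else f"frac_{direction}"
            ref = float(reference.scores.at[pw, col]) if pw in reference.scores.index else 0.0
            alt = float(alternate.scores.at[pw, col]) if pw in alternate.scores.index else 0.0
            if ref > 0:
                flag, ratio = _FLAG_FINITE, alt / ref
            elif alt > 0:
                flag, ratio = _FLAG_INFINITE, np.inf
            else:
                flag, ratio = _FLAG_UNDEFINED, np.nan
            if config.use_epsilon_ratios:
                ratio = (alt + config.epsilon) / (ref + config.epsilon)
            rows.append(
                {
                    "pathway": pw,
                    "direction": direction,
                    "reference_score": ref,
                    "alternate_score": alt,
                    "ratio": ratio,
                    "flag": flag,
                }
            )
    return InductionTable(
        reference_condition=reference.condition,
        alternate_condition=alternate.condition,
        table=pd.DataFrame(rows),
        db_fingerprint=reference.db_fingerprint,
    )


def hierarchy_edges(
    tensor: CommunicationTensor, pathway: str, config: PipelineConfig
) -> pd.DataFrame:
    """Sender->receiver edge list for one pathway's significant communication.

    Edge weight is the pathway's summed probability over entries with
    p < alpha for that (sender, receiver) pair; zero-weight pairs are
    omitted.  This is the numeric content of a hierarchy plot, where line
    thickness encodes strength of communication.
    """
    if pathway not in set(tensor.interaction_pathways):
        raise ValidationError("pathway", f"unknown pathway {pathway!r}")
    k_mask = np.array(tensor.interaction_pathways) == pathway
    contrib = np.where(tensor.pval < config.alpha, tensor.prob, 0.0)
    weights = contrib[:, :, k_mask].sum(axis=2)
    senders, receivers = np.nonzero(weights > 0)
    return pd.DataFrame(
        {
            "sender": [tensor.clusters[i] for i in senders],
            "receiver": [tensor.clusters[j] for j in receivers],
            "weight": weights[senders, receivers],
        }
    )


def composition_summary(adata: ad.AnnData) -> pd.DataFrame:
    """Cell count and within-condition proportion per condition x cluster.

    Every cluster appears under every condition; clusters absent from a
    condition carry count 0 and proportion 0.
    """
    obs = adata.obs[["condition", "cluster"]].astype(str)
    conditions = list(pd.unique(obs["condition"]))
    clusters = sorted(pd.unique(obs["cluster"]))
    counts = (
        obs.groupby(["condition", "cluster"], observed=False)
        .size()
        .reindex(pd.MultiIndex.from_product([conditions, clusters]), fill_value=0)
    )
    rows = []
    for cond in conditions:
        block = counts.loc[cond]
        n = int(block.sum())
        for cl in clusters:
            c = int(block[cl])
            rows.append(
                {
                    "condition": cond,
                    "cluster": cl,
                    "count": c,
                    "proportion": c / n if n else 0.0,
                }
            )
    return pd.DataFrame(rows)
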