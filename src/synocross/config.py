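"""Pipeline-wide parameters.

All thresholds that govern the communication and differential-expression
stages live in one frozen dataclass so that every run records exactly the
values it used.  Defaults follow the conventions of the methodology being
re-implemented: Tukey-trimean cluster summaries, a minimum of 10 cells per
cluster, a Hill half-saturation constant of 0.5 on log-normalized
expression, 100 label permutations, and a 0.05 significance threshold.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

from .errors import ValidationError


@dataclass(frozen=True)
class PipelineConfig:
    """Parameters shared by the communication, crosstalk and DE stages.

    Parameters
    ----------
    kh
        Hill half-saturation constant for the communication probability
        ``L*R / (kh + L*R)``; dimensionless on the scale of products of
        log-normalized expression. Must be > 0.
    min_cells
        Clusters with fewer cells (within a condition) are ineligible and
        contribute no communication.
    alpha
        Significance threshold applied to permutation p-values (and to
        adjusted p-values in the DE overlap stage).
    n_perm
        Number of cluster-label permutations for the significance test.
    seed
        Root seed for every stochastic step of a run.
    epsilon
        Pseudo-score used when ``use_epsilon_ratios`` is on, so that
        induction ratios with a zero reference score become large finite
        numbers instead of flags.
    de_min_pct
        A gene is tested for differential expression only if expressed in
        at least this fraction of cells in one of the two groups.
    de_lfc_threshold
        Minimum absolute log2 fold change for a gene to be tested.
    use_epsilon_ratios
        Replace infinite/undefined induction ratios with
        ``(alternate + epsilon) / (reference + epsilon)``.
    ratio_on_fractions
        Compute induction ratios on crosstalk fractions instead of summed
        probabilities.
    """

    kh: float = 0.5
    min_cells: int = 10
    alpha: float = 0.05
    n_perm: int = 100
    seed: int = 0
    epsilon: float = 1e-9
    de_min_pct: float = 0.10
    de_lfc_threshold: float = 0.25
    use_epsilon_ratios: bool = False
    ratio_on_fractions: bool = False

    def __post_init__(self) -> None:
        if not self.kh > 0:
            raise ValidationError("kh", "must be > 0")
        if self.min_cells < 1:
            raise ValidationError("min_cells", "must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha", "must lie in (0, 1)")
        if self.n_perm < 1:
            raise ValidationError("n_perm", "must be >= 1")
        if not self.epsilon > 0:
            raise ValidationError("epsilon", "must be > 0")
        if not 0 <= self.de_min_pct <= 1:
            raise ValidationError("de_min_pct", "must lie in [0, 1]")
        if self.de_lfc_threshold < 0:
            raise ValidationError("de_lfc_threshold", "must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(sorted(unknown)[0], "unknown pipeline parameter")
        return cls(**d)
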