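"""Run configuration shared by search, network construction, and the CLI."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from typing import Any

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    """All tunable parameters of a similarity search, with their defaults.

    fc_threshold: minimum absolute fold-change (SIR outside
        [1/fc_threshold, fc_threshold]) for a metabolite to count.
    permutations: label permutations of the query used to build the null
        score distribution.
    min_overlap: minimum post-filter shared metabolites for a comparison to
        qualify as a hit; below it the match is reported as "no hit".
    unknowns: whether unresolved metabolite identifiers participate in
        matching ("keep") or are excluded ("drop").
    statistic: ranking statistic — the signed hybrid score ("pm"), squared
        Pearson correlation ("r2"), biweight midcorrelation magnitude
        ("bicor"), or Fisher overlap significance ("fet").
    alpha: significance cut-off on the permutation p-value for is_hit.
    signed_null: pool signed permutation scores instead of magnitudes.
    bonferroni: divide alpha by the library size (off by default).
    max_fet2p / min_r2: network edge filters.
    """

    fc_threshold: float = 1.5
    permutations: int = 30
    min_overlap: int = 3
    unknowns: str = "keep"
    statistic: str = "pm"
    alpha: float = 0.05
    seed: int = 0
    scale: str = "ratio"
    max_fet2p: float = 0.007
    min_r2: float = 0.09
    signed_null: bool = False
    bonferroni: bool = False
    exclude_self: bool = True

    def __post_init__(self) -> None:
        if self.fc_threshold < 1.0:
            raise ValueError("fc_threshold must be >= 1")
        if self.permutations < 0:
            raise ValueError("permutations must be >= 0")
        if self.min_overlap < 0:
            raise ValueError("min_overlap must be >= 0")
        if self.unknowns not in ("keep", "drop"):
            raise ValueError("unknowns must be 'keep' or 'drop'")
        if self.statistic not in ("pm", "r2", "bicor", "fet"):
            raise ValueError("statistic must be one of pm, r2, bicor, fet")
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must be in (0, 1]")
        if self.scale not in ("ratio", "log2", "log10", "ln"):
            raise ValueError("scale must be one of ratio, log2, log10, ln")

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    def with_(self, **kwargs: Any) -> "RunConfig":
        return replace(self, **kwargs)
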