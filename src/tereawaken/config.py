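"""Pipeline-wide thresholds and parameters.

Defaults follow the published analysis settings: differential calls use a
1.5 linear fold-change cutoff with BH-adjusted p < 0.05; TE-copy/gene
proximity uses a +/-30 kb window around the TSS with 10,000 background
resamples; the TE accessibility-enrichment null uses 1,000 shuffles of
+/-1 kb padded copies; ATAC peaks shorter than 300 bp are discarded; Tn5
insertion sites are the fragment 5' ends shifted by +4 (+ strand) and
-5 (- strand).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any


@dataclass
class PipelineConfig:
    fc_cutoff: float = 1.5
    alpha: float = 0.05
    proximity_window: int = 30_000
    te_pad: int = 1_000
    n_shuffles_atac: int = 1_000
    n_resamples_proximity: int = 10_000
    min_peak_len: int = 300
    tn5_shift: tuple[int, int] = (4, -5)
    fos_flank_width: int = 35
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.fc_cutoff <= 1:
            raise ValueError("fc_cutoff must exceed 1")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        for name in (
            "proximity_window",
            "te_pad",
            "n_shuffles_atac",
            "n_resamples_proximity",
            "fos_flank_width",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.min_peak_len < 0:
            raise ValueError("min_peak_len must be non-negative")

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        d = dict(d)
        if "tn5_shift" in d:
            d["tn5_shift"] = tuple(d["tn5_shift"])
        return cls(**d)
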