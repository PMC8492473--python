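"""Feature x sample count matrices.

A thin wrapper over a pandas DataFrame tagged with the feature kind.
Gene- and copy-level counts are integers; family-level counts may be
fractional because multi-mapping reads are distributed across candidate
families.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

FEATURE_KINDS = {"gene", "te_family", "te_copy", "peak", "element"}


@dataclass
class CountMatrix:
    counts: pd.DataFrame  # features (index) x samples (columns)
    kind: str
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        if self.kind in {"gene", "te_copy"}:
            arr = self.counts.to_numpy()
            if not np.allclose(arr, np.round(arr)):
                raise ValueError(f"{self.kind}-level counts must be integers")
        if not self.counts.index.is_unique:
            raise ValueError("duplicate feature ids")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def to_tsv(self, path: str | Path) -> None:
        df = self.counts.copy()
        df.insert(0, "kind", self.kind)
        df.to_csv(path, sep="\t", index_label="feature_id")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col="feature_id")
        kinds = df.pop("kind").unique()
        if len(kinds) != 1:
            raise ValueError(f"mixed feature kinds in {path}: {kinds}")
        return cls(df, str(kinds[0]))

    @staticmethod
    def concat(matrices: list["CountMatrix"], kind: str) -> "CountMatrix":
        """Stack matrices sharing samples (e.g. genes + TE families
        normalized together)."""
        df = pd.concat([m.counts for m in matrices], axis=0)
        return CountMatrix(df, kind)
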