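"""Shared feature-vector container and naming helpers."""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence

import numpy as np


@dataclass(frozen=True)
class FeatureVector:
    """Named descriptor values for one sequence under one encoder."""

    names: List[str]
    values: np.ndarray
    encoder: str

    def __post_init__(self) -> None:
        if len(self.names) != len(self.values):
            raise ValueError("names and values must have equal length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("descriptor names must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"{self.encoder}: non-finite descriptor value")

    def __len__(self) -> int:
        return len(self.names)

    def as_dict(self) -> dict:
        return dict(zip(self.names, self.values.tolist()))


def concat(vectors: Sequence[FeatureVector], encoder: str) -> FeatureVector:
    names: List[str] = []
    chunks = []
    for v in vectors:
        names.extend(v.names)
        chunks.append(v.values)
    return FeatureVector(names, np.concatenate(chunks), encoder)
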