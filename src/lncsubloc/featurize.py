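"""Build named feature matrices (pandas DataFrames) for sequence sets."""

from __future__ import annotations

from typing import Callable, Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .composition import (
    COMPOSITION_FAMILY_NAMES,
    composition_family,
    composition_features,
)
from .correlation import (
    CORRELATION_FAMILY_NAMES,
    all_features,
    correlation_family,
    correlation_features,
)
from .seqio import NucleotideSequence

#: selectors accepted by `feature_matrix` besides individual family names
GROUPS = {
    "composition": composition_features,
    "correlation": correlation_features,
    "all": all_features,
}


def _encoder_for(selector: str) -> Callable:
    if selector in GROUPS:
        return GROUPS[selector]
    if selector in COMPOSITION_FAMILY_NAMES:
        return lambda s: composition_family(s, selector)
    if selector in CORRELATION_FAMILY_NAMES:
        return lambda s: correlation_family(s, selector)
    raise KeyError(
        f"unknown feature selector {selector!r}; expected one of "
        f"{sorted(GROUPS)} or a family abbreviation"
    )


def feature_matrix(
    seqs: Sequence[NucleotideSequence],
    families: str | Sequence[str] = "all",
) -> pd.DataFrame:
    """Descriptor matrix with sequence ids as index, descriptor names as columns.

    *families* may be ``"composition"``, ``"correlation"``, ``"all"``, a
    single family abbreviation (e.g. ``"DNC"``, ``"MAC"``) or a list of
    selectors whose vectors are concatenated in the given order.
    """
    if isinstance(families, str):
        families = [families]
    encoders = [_encoder_for(f) for f in families]
    rows: List[np.ndarray] = []
    names: Optional[List[str]] = None
    ids = []
    for seq in seqs:
        vecs = [enc(seq) for enc in encoders]
        row_names = [n for v in vecs for n in v.names]
        if names is None:
            names = row_names
        elif row_names != names:
            raise RuntimeError("descriptor names differ between sequences")
        rows.append(np.concatenate([v.values for v in vecs]))
        ids.append(seq.id)
    return pd.DataFrame(rows, index=pd.Index(ids, name="id"), columns=names)
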