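"""Physicochemical property tables for di- and trinucleotides.

Each table assigns 12 properties (indexed ``p1``..``p12``) to every k-mer
(k = 2 or 3).  The bundled defaults span helical geometry (twist, tilt,
roll, shift, slide, rise), nearest-neighbour duplex thermodynamics
(enthalpy, entropy, free energy) and simple composition (GC, purine and
keto fractions); the trinucleotide physical values are the means of the two
overlapping dinucleotide steps.  Values are standardized per property to
mean 0 and standard deviation 1 over all 4^k k-mers at load time, so any
substitute table on the documented format behaves identically under
affine rescaling of its raw values.

Table file format: TSV, one row per k-mer, first column ``kmer``, then one
column per property.  All 4^k k-mers must be present.  A sidecar
(``property_names.tsv``) documents the p-index to property-name mapping.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Dict, List

import numpy as np
import pandas as pd

N_PROPERTIES = 12

_BASE_CODE = np.full(128, -1, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i


def kmer_order(k: int) -> List[str]:
    """All 4^k k-mers in lexicographic order."""
    return ["".join(t) for t in itertools.product("ACGT", repeat=k)]


def encode_kmers(residues: str, k: int) -> np.ndarray:
    """Lexicographic index of each overlapping k-mer (length L-k+1 array)."""
    codes = _BASE_CODE[np.frombuffer(residues.encode("ascii"), dtype=np.uint8)]
    if codes.min(initial=0) < 0:
        raise ValueError("sequence contains non-ACGT residues")
    idx = codes[: len(codes) - k + 1].copy()
    for j in range(1, k):
        idx = idx * 4 + codes[j : len(codes) - k + 1 + j]
    return idx


@dataclass(frozen=True)
class PropertyTable:
    """Standardized property values for all k-mers of one size.

    ``matrix`` has shape (4^k, 12); row order is lexicographic k-mer order,
    column j holds property p{j+1}.
    """

    k: int
    property_names: List[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        expected = (4**self.k, N_PROPERTIES)
        if self.matrix.shape != expected:
            raise ValueError(f"property matrix must have shape {expected}")
        mu = self.matrix.mean(axis=0)
        sd = self.matrix.std(axis=0)
        if np.abs(mu).max() > 1e-9 or np.abs(sd - 1).max() > 1e-9:
            raise ValueError("property table is not standardized to mean 0, sd 1")

    def value(self, kmer: str, prop: int) -> float:
        """Standardized value of property ``p{prop}`` (1-based) for *kmer*."""
        row = encode_kmers(kmer, self.k)[0]
        return float(self.matrix[row, prop - 1])

    def profile(self, residues: str) -> np.ndarray:
        """Property profile of a sequence: (L-k+1, 12) standardized values."""
        if len(residues) < self.k:
            raise ValueError(f"sequence shorter than k={self.k}")
        return self.matrix[encode_kmers(residues, self.k)]


def _standardize(raw: np.ndarray) -> np.ndarray:
    mu = raw.mean(axis=0)
    sd = raw.std(axis=0)
    if (sd == 0).any():
        raise ValueError("property column is constant; cannot standardize")
    return (raw - mu) / sd


def load_property_table(path: str | Path | None = None, k: int = 2) -> PropertyTable:
    """Load and standardize a property table (bundled default if *path* is None)."""
    if path is None:
        name = {2: "dinucleotide_properties.tsv", 3: "trinucleotide_properties.tsv"}[k]
        ref = resources.files("lncsubloc.data").joinpath(name)
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    if "kmer" not in df.columns:
        raise ValueError("property table must have a 'kmer' column")
    kl = df["kmer"].str.len().unique()
    if len(kl) != 1 or kl[0] != k:
        raise ValueError(f"expected k-mers of length {k}")
    order = kmer_order(k)
    missing = set(order) - set(df["kmer"])
    if missing:
        raise ValueError(f"property table incomplete; missing {sorted(missing)[:4]}...")
    df = df.set_index("kmer").loc[order]
    prop_cols = list(df.columns)
    if len(prop_cols) != N_PROPERTIES:
        raise ValueError(f"expected {N_PROPERTIES} property columns, got {len(prop_cols)}")
    matrix = _standardize(df.to_numpy(dtype=float))
    return PropertyTable(k=k, property_names=prop_cols, matrix=matrix)


_CACHE: Dict[int, PropertyTable] = {}


def default_table(k: int) -> PropertyTable:
    """Bundled standardized table for k in {2, 3} (cached)."""
    if k not in (2, 3):
        raise ValueError("k must be 2 or 3")
    if k not in _CACHE:
        _CACHE[k] = load_property_table(None, k)
    return _CACHE[k]
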