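"""Composition-based sequence descriptors (123 per sequence).

Nine descriptor families computed from residue content and arrangement:

=====================  ======  ====================================
family (prefix)        dim     definition
=====================  ======  ====================================
DNC                    16      dinucleotide composition
RCK                    10      reverse-complement dinucleotide classes
NRI                    4       longest homopolymer run / length
ENT_seq                1       Shannon entropy of base frequencies
ENT                    4       per-base entropy terms -p log2 p
DDN                    4       mean gap between base occurrences / length
PDNC                   19      type-I pseudo dinucleotide composition
PTNC                   65      type-I pseudo trinucleotide composition
=====================  ======  ====================================

All composition vectors depend on residue content only, never on absolute
sequence length, and the frequency-style families each sum to 1.
"""

from __future__ import annotations

from typing import List, Optional

import numpy as np

from .errors import SequenceTooShortError
from .features import FeatureVector, concat
from .properties import PropertyTable, default_table, encode_kmers, kmer_order

DINUCLEOTIDES = kmer_order(2)
TRINUCLEOTIDES = kmer_order(3)
BASES = "ACGT"

#: reverse-complement equivalence classes of the 16 dinucleotides, keyed by
#: their lexicographically smallest member
RC_CLASSES = [
    ("AA", ("AA", "TT")),
    ("AC", ("AC", "GT")),
    ("AG", ("AG", "CT")),
    ("AT", ("AT",)),
    ("CA", ("CA", "TG")),
    ("CC", ("CC", "GG")),
    ("CG", ("CG",)),
    ("GA", ("GA", "TC")),
    ("GC", ("GC",)),
    ("TA", ("TA",)),
]

PSEUDO_WEIGHT = 0.05
PDNC_LAMBDA = 3
PTNC_LAMBDA = 1


def _residues(seq) -> str:
    return seq if isinstance(seq, str) else seq.residues


def _require_length(residues: str, minimum: int, encoder: str) -> None:
    if len(residues) < minimum:
        raise SequenceTooShortError(
            f"{encoder}: sequence of length {len(residues)} shorter than minimum {minimum}"
        )


def kmer_frequencies(residues: str, k: int) -> np.ndarray:
    """Overlapping k-mer frequencies in lexicographic order (sums to 1)."""
    idx = encode_kmers(residues, k)
    return np.bincount(idx, minlength=4**k) / len(idx)


def dinucleotide_composition(seq) -> FeatureVector:
    """16 dinucleotide frequencies, count / (L - 1)."""
    residues = _residues(seq)
    _require_length(residues, 2, "DNC")
    values = kmer_frequencies(residues, 2)
    return FeatureVector([f"DNC_{d}" for d in DINUCLEOTIDES], values, "DNC")


def rc_kmer_composition(seq) -> FeatureVector:
    """10 reverse-complement dinucleotide class frequencies."""
    residues = _residues(seq)
    _require_length(residues, 2, "RCK")
    freqs = kmer_frequencies(residues, 2)
    by_dinuc = dict(zip(DINUCLEOTIDES, freqs))
    names, values = [], []
    for key, members in RC_CLASSES:
        names.append(f"RCK_{key}")
        values.append(sum(by_dinuc[m] for m in members))
    return FeatureVector(names, np.array(values), "RCK")


def nucleotide_repeat_index(seq) -> FeatureVector:
    """Longest homopolymer run of each base divided by sequence length."""
    residues = _residues(seq)
    _require_length(residues, 1, "NRI")
    longest = dict.fromkeys(BASES, 0)
    run_base, run_len = residues[0], 0
    for ch in residues:
        if ch == run_base:
            run_len += 1
        else:
            run_base, run_len = ch, 1
        if run_len > longest[run_base]:
            longest[run_base] = run_len
    L = len(residues)
    return FeatureVector(
        [f"NRI_{b}" for b in BASES],
        np.array([longest[b] / L for b in BASES]),
        "NRI",
    )


def entropy_features(seq) -> FeatureVector:
    """Shannon entropy of the base distribution plus the 4 per-base terms.

    The per-base term is -p_b log2 p_b with the 0 log 0 = 0 convention;
    the sequence-level entropy is their sum.
    """
    residues = _residues(seq)
    _require_length(residues, 1, "ENT")
    p = np.array([residues.count(b) for b in BASES]) / len(residues)
    terms = np.where(p > 0, -p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    values = np.concatenate([[terms.sum()], terms])
    return FeatureVector(["ENT_seq"] + [f"ENT_{b}" for b in BASES], values, "ENT")


def distance_distribution(seq) -> FeatureVector:
    """Mean gap between consecutive occurrences of each base, / length.

    Bases occurring fewer than twice contribute 0.
    """
    residues = _residues(seq)
    _require_length(residues, 1, "DDN")
    L = len(residues)
    values = []
    arr = np.frombuffer(residues.encode("ascii"), dtype=np.uint8)
    for b in BASES:
        pos = np.flatnonzero(arr == ord(b))
        if len(pos) < 2:
            values.append(0.0)
        else:
            values.append(float(np.diff(pos).mean()) / L)
    return FeatureVector([f"DDN_{b}" for b in BASES], np.array(values), "DDN")


def _theta_factors(
    profile: np.ndarray, lam: int
) -> np.ndarray:
    """Type-I sequence-order factors.

    theta_j is the mean over positions i of the mean squared difference of
    the 12 standardized property values between the k-mers at i and i+j.
    """
    thetas = np.empty(lam)
    for j in range(1, lam + 1):
        diff = profile[:-j] - profile[j:]
        thetas[j - 1] = np.mean(diff * diff)
    return thetas


def pseudo_composition(
    seq,
    k: int,
    lam: Optional[int] = None,
    weight: float = PSEUDO_WEIGHT,
    table: Optional[PropertyTable] = None,
    prefix: Optional[str] = None,
) -> FeatureVector:
    """Type-I (parallel-correlation) pseudo k-mer composition.

    The first 4^k entries are down-weighted k-mer frequencies, the last
    ``lam`` entries are weighted sequence-order factors computed from the
    standardized physicochemical property profile; the vector sums to 1.
    Defaults: k=2 with lambda=3 (dim 19), k=3 with lambda=1 (dim 65).
    """
    if k not in (2, 3):
        raise ValueError("k must be 2 or 3")
    if lam is None:
        lam = PDNC_LAMBDA if k == 2 else PTNC_LAMBDA
    if lam < 1:
        raise ValueError("lambda must be >= 1")
    if weight <= 0:
        raise ValueError("weight must be > 0")
    prefix = prefix or ("PDNC" if k == 2 else "PTNC")
    residues = _residues(seq)
    _require_length(residues, k + lam + 1, prefix)
    table = table or default_table(k)
    freqs = kmer_frequencies(residues, k)
    thetas = _theta_factors(table.profile(residues), lam)
    denom = freqs.sum() + weight * thetas.sum()
    values = np.concatenate([freqs / denom, weight * thetas / denom])
    names = [f"{prefix}_{m}" for m in kmer_order(k)] + [
        f"{prefix}_theta{j}" for j in range(1, lam + 1)
    ]
    return FeatureVector(names, values, prefix)


_FAMILIES = (
    ("DNC", dinucleotide_composition),
    ("RCK", rc_kmer_composition),
    ("NRI", nucleotide_repeat_index),
    ("ENT", entropy_features),
    ("DDN", distance_distribution),
    ("PDNC", lambda s: pseudo_composition(s, k=2)),
    ("PTNC", lambda s: pseudo_composition(s, k=3)),
)

COMPOSITION_FAMILY_NAMES = [name for name, _ in _FAMILIES]
COMPOSITION_DIM = 123


def composition_features(seq) -> FeatureVector:
    """All 123 composition descriptors in fixed family order."""
    parts: List[FeatureVector] = []
    for name, fn in _FAMILIES:
        try:
            parts.append(fn(seq))
        except SequenceTooShortError:
            raise
        except Exception as exc:  # pragma: no cover - defensive re-labeling
            raise type(exc)(f"{name}: {exc}") from exc
    out = concat(parts, "composition")
    assert len(out) == COMPOSITION_DIM
    return out


def composition_family(seq, family: str) -> FeatureVector:
    """Compute a single composition family by prefix name."""
    for name, fn in _FAMILIES:
        if name == family:
            return fn(seq)
    raise KeyError(f"unknown composition family {family!r}")
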