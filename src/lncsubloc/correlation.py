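"""Correlation-based sequence descriptors (1,100 per sequence).

Each family turns a sequence into 12 parallel numeric profiles — the
standardized physicochemical property values of its overlapping k-mers —
and summarizes lagged (co)variation of those profiles:

==========  ======  ==========================================================
family      dim     definition
==========  ======  ==========================================================
TCC         264     trinucleotide cross-covariance, ordered property pairs
DACC        288     dinucleotide auto + cross covariance
TACC        288     trinucleotide auto + cross covariance
TAC         24      trinucleotide autocovariance
NMBAC       24      normalized Moreau-Broto autocorrelation (dinucleotide)
MAC         24      Moran autocorrelation (dinucleotide)
GAC         24      Geary autocorrelation (dinucleotide)
SC_PTNC     65      type-II (serial) pseudo trinucleotide composition
SC_PDNC     17      type-II (serial) pseudo dinucleotide composition
PC_PTNC     65      type-I (parallel) pseudo trinucleotide composition
PC_PDNC     17      type-I (parallel) pseudo dinucleotide composition
==========  ======  ==========================================================

Lags run from 1 to ``max_lag`` (default 2); with 12 properties this yields
the family dimensions above (12*11*2 = 264, 12*12*2 = 288, 12*2 = 24).
Descriptors are computed on the given strand only.
"""

from __future__ import annotations

from typing import List, Optional

import numpy as np

from .composition import kmer_frequencies, pseudo_composition
from .errors import SequenceTooShortError
from .features import FeatureVector, concat
from .properties import N_PROPERTIES, PropertyTable, default_table, kmer_order

DEFAULT_MAX_LAG = 2

AC = "AC"
MORAN = "MORAN"
GEARY = "GEARY"
NMB = "NMB"

PARALLEL = "PARALLEL"
SERIAL = "SERIAL"

CORRELATION_DIM = 1100
COMBINED_DIM = 1223


def _residues(seq) -> str:
    return seq if isinstance(seq, str) else seq.residues


def property_profile(seq, table: PropertyTable, prop: Optional[int] = None) -> np.ndarray:
    """Standardized property values along the sequence.

    Returns the (L-k+1, 12) profile matrix, or a single property's series
    when *prop* (1-based) is given.
    """
    residues = _residues(seq)
    if len(residues) < table.k:
        raise SequenceTooShortError(
            f"profile: length {len(residues)} < k={table.k}"
        )
    profile = table.profile(residues)
    if prop is None:
        return profile
    return profile[:, prop - 1]


def _check_series_length(residues: str, k: int, max_lag: int, encoder: str) -> None:
    n = len(residues) - k + 1
    if n <= max_lag + 1:
        raise SequenceTooShortError(
            f"{encoder}: profile of {n} points too short for max_lag={max_lag}"
        )


def _lagged_cov(profile: np.ndarray, d: int) -> np.ndarray:
    """12x12 matrix of lag-d cross-covariances between centered profiles."""
    n = profile.shape[0]
    centered = profile - profile.mean(axis=0)
    return centered[:-d].T @ centered[d:] / (n - d)


def auto_correlation(
    seq,
    table: PropertyTable,
    scheme: str = AC,
    max_lag: int = DEFAULT_MAX_LAG,
    prefix: Optional[str] = None,
) -> FeatureVector:
    """Lagged autocorrelation of each property profile (dim 12 * max_lag).

    Schemes: ``AC`` plain autocovariance; ``MORAN`` autocovariance divided
    by the (1/N) variance; ``GEARY`` mean squared lag difference over twice
    the (1/(N-1)) variance; ``NMB`` mean raw lagged product.  Zero-variance
    profiles yield 0 for MORAN and GEARY.
    """
    residues = _residues(seq)
    prefix = prefix or f"{scheme}{table.k}"
    _check_series_length(residues, table.k, max_lag, prefix)
    profile = table.profile(residues)
    n = profile.shape[0]
    mean = profile.mean(axis=0)
    centered = profile - mean
    # a constant profile is degenerate by definition; detect it exactly
    # rather than via the (possibly rounding-polluted) computed variance
    constant = np.ptp(profile, axis=0) == 0
    var_n = np.where(constant, 0.0, (centered**2).mean(axis=0))
    var_n1 = np.where(constant, 0.0, (centered**2).sum(axis=0) / (n - 1))
    names: List[str] = []
    values: List[float] = []
    for c in range(N_PROPERTIES):
        for d in range(1, max_lag + 1):
            if scheme == AC:
                v = float(centered[:-d, c] @ centered[d:, c] / (n - d))
            elif scheme == MORAN:
                cov = float(centered[:-d, c] @ centered[d:, c] / (n - d))
                v = cov / var_n[c] if var_n[c] > 0 else 0.0
            elif scheme == GEARY:
                if var_n1[c] > 0:
                    num = float(((profile[:-d, c] - profile[d:, c]) ** 2).sum()) / (
                        2 * (n - d)
                    )
                    v = num / var_n1[c]
                else:
                    v = 0.0
            elif scheme == NMB:
                v = float(profile[:-d, c] @ profile[d:, c] / (n - d))
            else:
                raise ValueError(f"unknown autocorrelation scheme {scheme!r}")
            names.append(f"{prefix}_p{c + 1}_lag{d}")
            values.append(v)
    return FeatureVector(names, np.array(values), prefix)


def cross_correlation(
    seq,
    table: PropertyTable,
    max_lag: int = DEFAULT_MAX_LAG,
    prefix: str = "TCC",
) -> FeatureVector:
    """Lagged cross-covariance for all ordered property pairs (c1 != c2)."""
    residues = _residues(seq)
    _check_series_length(residues, table.k, max_lag, prefix)
    profile = table.profile(residues)
    covs = [_lagged_cov(profile, d) for d in range(1, max_lag + 1)]
    names: List[str] = []
    values: List[float] = []
    for c1 in range(N_PROPERTIES):
        for c2 in range(N_PROPERTIES):
            if c1 == c2:
                continue
            for d in range(1, max_lag + 1):
                names.append(f"{prefix}_p{c1 + 1}_p{c2 + 1}_lag{d}")
                values.append(float(covs[d - 1][c1, c2]))
    return FeatureVector(names, np.array(values), prefix)


def auto_cross_correlation(
    seq,
    table: PropertyTable,
    max_lag: int = DEFAULT_MAX_LAG,
    prefix: Optional[str] = None,
) -> FeatureVector:
    """Auto terms (c1 = c2) followed by cross terms (c1 != c2); dim 288.

    Auto descriptors are named ``<prefix>_p{c}_lag{d}``, cross descriptors
    ``<prefix>_p{c1}_p{c2}_lag{d}``.
    """
    prefix = prefix or ("DACC" if table.k == 2 else "TACC")
    auto = auto_correlation(seq, table, scheme=AC, max_lag=max_lag, prefix=prefix)
    cross = cross_correlation(seq, table, max_lag=max_lag, prefix=prefix)
    return concat([auto, cross], prefix)


def _tau_factors(series: np.ndarray, lam: int) -> np.ndarray:
    """Type-II sequence-order factors: mean lagged product of one property."""
    taus = np.empty(lam)
    for j in range(1, lam + 1):
        taus[j - 1] = float(series[:-j] @ series[j:]) / (len(series) - j)
    return taus


def pseudo_correlation(
    seq,
    k: int,
    mode: str = PARALLEL,
    lam: int = 1,
    weight: float = 0.05,
    table: Optional[PropertyTable] = None,
    designated_property: int = 1,
) -> FeatureVector:
    """Pseudo k-mer composition in parallel (type-I) or serial (type-II) form.

    PARALLEL pools all 12 properties into each sequence-order factor;
    SERIAL keeps a per-property factor for the designated property
    (default p1).  With lambda=1 the dimensions are 17 (k=2) and 65 (k=3).
    """
    if mode == PARALLEL:
        prefix = "PC_PDNC" if k == 2 else "PC_PTNC"
        return pseudo_composition(seq, k=k, lam=lam, weight=weight, table=table, prefix=prefix)
    if mode != SERIAL:
        raise ValueError(f"unknown pseudo-correlation mode {mode!r}")
    prefix = "SC_PDNC" if k == 2 else "SC_PTNC"
    residues = _residues(seq)
    if len(residues) < k + lam + 1:
        raise SequenceTooShortError(
            f"{prefix} (mode={mode}, k={k}): length {len(residues)} < {k + lam + 1}"
        )
    table = table or default_table(k)
    freqs = kmer_frequencies(residues, k)
    series = table.profile(residues)[:, designated_property - 1]
    taus = _tau_factors(series, lam)
    denom = freqs.sum() + weight * taus.sum()
    values = np.concatenate([freqs / denom, weight * taus / denom])
    names = [f"{prefix}_{m}" for m in kmer_order(k)] + [
        f"{prefix}_tau{j}" for j in range(1, lam + 1)
    ]
    return FeatureVector(names, values, prefix)


CORRELATION_FAMILY_NAMES = [
    "TCC",
    "DACC",
    "TACC",
    "TAC",
    "NMBAC",
    "MAC",
    "GAC",
    "SC_PTNC",
    "SC_PDNC",
    "PC_PTNC",
    "PC_PDNC",
]


def correlation_family(
    seq, family: str, max_lag: int = DEFAULT_MAX_LAG
) -> FeatureVector:
    """Compute one correlation family by its abbreviation."""
    d2 = default_table(2)
    d3 = default_table(3)
    if family == "TCC":
        return cross_correlation(seq, d3, max_lag, prefix="TCC")
    if family == "DACC":
        return auto_cross_correlation(seq, d2, max_lag, prefix="DACC")
    if family == "TACC":
        return auto_cross_correlation(seq, d3, max_lag, prefix="TACC")
    if family == "TAC":
        return auto_correlation(seq, d3, AC, max_lag, prefix="TAC")
    if family == "NMBAC":
        return auto_correlation(seq, d2, NMB, max_lag, prefix="NMBAC")
    if family == "MAC":
        return auto_correlation(seq, d2, MORAN, max_lag, prefix="MAC")
    if family == "GAC":
        return auto_correlation(seq, d2, GEARY, max_lag, prefix="GAC")
    if family == "SC_PTNC":
        return pseudo_correlation(seq, k=3, mode=SERIAL, table=d3)
    if family == "SC_PDNC":
        return pseudo_correlation(seq, k=2, mode=SERIAL, table=d2)
    if family == "PC_PTNC":
        return pseudo_correlation(seq, k=3, mode=PARALLEL, table=d3)
    if family == "PC_PDNC":
        return pseudo_correlation(seq, k=2, mode=PARALLEL, table=d2)
    raise KeyError(f"unknown correlation family {family!r}")


def correlation_features(seq, max_lag: int = DEFAULT_MAX_LAG) -> FeatureVector:
    """All 1,100 correlation descriptors in fixed family order."""
    parts = [correlation_family(seq, fam, max_lag) for fam in CORRELATION_FAMILY_NAMES]
    out = concat(parts, "correlation")
    assert len(out) == CORRELATION_DIM
    return out


def all_features(seq) -> FeatureVector:
    """Combined composition + correlation vector (dim 1,223)."""
    from .composition import composition_features

    out = concat([composition_features(seq), correlation_features(seq)], "all")
    assert len(out) == COMBINED_DIM
    return out
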