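"""Independent straight-line reference implementations used as test oracles.

Everything here is written as direct loops over the definitions, sharing no
code path with the package's vectorized encoders.
"""

from __future__ import annotations

import itertools
from typing import Dict, List, Sequence

BASES = "ACGT"


def kmer_counts(seq: str, k: int) -> Dict[str, int]:
    counts = {"".join(t): 0 for t in itertools.product(BASES, repeat=k)}
    for i in range(len(seq) - k + 1):
        counts[seq[i : i + k]] += 1
    return counts


def dinuc_composition(seq: str) -> Dict[str, float]:
    counts = kmer_counts(seq, 2)
    return {d: c / (len(seq) - 1) for d, c in counts.items()}


def revcomp(kmer: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    return "".join(comp[b] for b in reversed(kmer))


def rc_classes(seq: str) -> Dict[str, float]:
    freqs = dinuc_composition(seq)
    merged: Dict[str, float] = {}
    for d, f in freqs.items():
        key = min(d, revcomp(d))
        merged[key] = merged.get(key, 0.0) + f
    return merged


def longest_runs(seq: str) -> Dict[str, int]:
    out = {b: 0 for b in BASES}
    for b in BASES:
        best = cur = 0
        for ch in seq:
            cur = cur + 1 if ch == b else 0
            best = max(best, cur)
        out[b] = best
    return out


def mean_gap(seq: str) -> Dict[str, float]:
    out = {}
    for b in BASES:
        pos = [i for i, ch in enumerate(seq) if ch == b]
        if len(pos) < 2:
            out[b] = 0.0
        else:
            gaps = [pos[i + 1] - pos[i] for i in range(len(pos) - 1)]
            out[b] = (sum(gaps) / len(gaps)) / len(seq)
    return out


_TABLE_CACHE: Dict[int, Dict[str, List[float]]] = {}


def table_lookup(table) -> Dict[str, List[float]]:
    """Plain python dict of k-mer -> 12 standardized values for a table."""
    key = id(table)
    if key not in _TABLE_CACHE:
        order = ["".join(t) for t in itertools.product(BASES, repeat=table.k)]
        _TABLE_CACHE[key] = {
            m: [float(v) for v in row] for m, row in zip(order, table.matrix)
        }
    return _TABLE_CACHE[key]


def property_series(seq: str, table, prop: int) -> List[float]:
    k = table.k
    lut = table_lookup(table)
    return [lut[seq[i : i + k]][prop - 1] for i in range(len(seq) - k + 1)]


def _mean(x: Sequence[float]) -> float:
    return sum(x) / len(x)


def autocovariance(x: Sequence[float], d: int) -> float:
    m = _mean(x)
    n = len(x)
    return sum((x[i] - m) * (x[i + d] - m) for i in range(n - d)) / (n - d)


def moran(x: Sequence[float], d: int) -> float:
    m = _mean(x)
    n = len(x)
    var = sum((v - m) ** 2 for v in x) / n
    if var == 0:
        return 0.0
    return autocovariance(x, d) / var


def geary(x: Sequence[float], d: int) -> float:
    m = _mean(x)
    n = len(x)
    var = sum((v - m) ** 2 for v in x) / (n - 1)
    if var == 0:
        return 0.0
    num = sum((x[i] - x[i + d]) ** 2 for i in range(n - d)) / (2 * (n - d))
    return num / var


def moreau_broto(x: Sequence[float], d: int) -> float:
    n = len(x)
    return sum(x[i] * x[i + d] for i in range(n - d)) / (n - d)


def cross_covariance(x: Sequence[float], y: Sequence[float], d: int) -> float:
    mx, my = _mean(x), _mean(y)
    n = len(x)
    return sum((x[i] - mx) * (y[i + d] - my) for i in range(n - d)) / (n - d)


def pseudo_type1(seq: str, k: int, lam: int, w: float, table) -> List[float]:
    """Type-I pseudo k-mer composition evaluated directly from the formulas."""
    n_kmers = len(seq) - k + 1
    counts = kmer_counts(seq, k)
    order = ["".join(t) for t in itertools.product(BASES, repeat=k)]
    freqs = [counts[m] / n_kmers for m in order]
    lut = table_lookup(table)
    thetas = []
    for j in range(1, lam + 1):
        total = 0.0
        for i in range(n_kmers - j):
            a, b = lut[seq[i : i + k]], lut[seq[i + j : i + j + k]]
            total += _mean([(x - y) ** 2 for x, y in zip(a, b)])
        thetas.append(total / (n_kmers - j))
    denom = sum(freqs) + w * sum(thetas)
    return [f / denom for f in freqs] + [w * t / denom for t in thetas]


def pseudo_type2(seq: str, k: int, lam: int, w: float, table, prop: int = 1) -> List[float]:
    """Type-II (serial) pseudo composition with one designated property."""
    n_kmers = len(seq) - k + 1
    counts = kmer_counts(seq, k)
    order = ["".join(t) for t in itertools.product(BASES, repeat=k)]
    freqs = [counts[m] / n_kmers for m in order]
    x = property_series(seq, table, prop)
    taus = []
    for j in range(1, lam + 1):
        taus.append(sum(x[i] * x[i + j] for i in range(n_kmers - j)) / (n_kmers - j))
    denom = sum(freqs) + w * sum(taus)
    return [f / denom for f in freqs] + [w * t / denom for t in taus]


def auc_pair_counting(labels: Sequence[int], scores: Sequence[float]) -> float:
    """O(n^2) Mann-Whitney AUC with ties counting one half."""
    pos = [s for lab, s in zip(labels, scores) if lab == 1]
    neg = [s for lab, s in zip(labels, scores) if lab == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def random_sequence(rng, length: int) -> str:
    return "".join(rng.choice(list(BASES), size=length))
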