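"""Dataset construction: labels from expression ratios, filtering, redundancy
reduction and stratified train/validation splitting.

The localization label of a gene in a cell line is derived from the sign of
its cytoplasmic/nuclear relative concentration index (CNRCI), the log2 ratio
of cytoplasmic to nuclear expression (FPKM).  Positive CNRCI means
cytoplasm, negative means nucleus; a CNRCI of exactly zero (or one that is
undefined because a compartment had zero expression) carries no signal and
the record is dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import StratificationError
from .seqio import NucleotideSequence

CYTOPLASM = "cytoplasm"
NUCLEUS = "nucleus"
TRAIN = "train"
VALIDATION = "validation"

DEFAULT_MAX_LENGTH = 10_000
DEFAULT_IDENTITY_THRESHOLD = 0.90
DEFAULT_TEST_FRACTION = 0.2


@dataclass(frozen=True)
class LocalizationRecord:
    """One gene in one cell line, with its CNRCI and derived label."""

    gene_id: str
    cell_line: str
    cnrci: float
    label: str

    def __post_init__(self) -> None:
        if not math.isfinite(self.cnrci) or self.cnrci == 0.0:
            raise ValueError("labeled records require a finite, non-zero CNRCI")
        expected = CYTOPLASM if self.cnrci > 0 else NUCLEUS
        if self.label != expected:
            raise ValueError(f"label {self.label!r} inconsistent with CNRCI {self.cnrci}")


@dataclass
class CellLineDataset:
    """Labeled sequences for one cell line plus the train/validation split."""

    cell_line: str
    entries: List[Tuple[NucleotideSequence, str]]
    split: Dict[str, str] = field(default_factory=dict)

    @property
    def ids(self) -> List[str]:
        return [seq.id for seq, _ in self.entries]

    def subset(self, part: str) -> List[Tuple[NucleotideSequence, str]]:
        return [(s, lab) for s, lab in self.entries if self.split.get(s.id) == part]

    def to_manifest(self) -> pd.DataFrame:
        rows = [
            {
                "id": seq.id,
                "cell_line": self.cell_line,
                "length": len(seq),
                "label": lab,
                "split": self.split.get(seq.id, ""),
            }
            for seq, lab in self.entries
        ]
        return pd.DataFrame(rows)


def compute_cnrci(cyt_fpkm: float, nuc_fpkm: float) -> float:
    """log2 ratio of cytoplasmic to nuclear FPKM.

    Returns NaN when either compartment has zero expression, which marks
    the record for exclusion downstream.  Negative expression is a domain
    error.
    """
    if not (math.isfinite(cyt_fpkm) and math.isfinite(nuc_fpkm)):
        raise ValueError("FPKM values must be finite")
    if cyt_fpkm < 0 or nuc_fpkm < 0:
        raise ValueError("FPKM values must be non-negative")
    if cyt_fpkm == 0 or nuc_fpkm == 0:
        return float("nan")
    return math.log2(cyt_fpkm / nuc_fpkm)


def assign_labels(
    records: Iterable[Tuple[str, float]], cell_line: str = ""
) -> Tuple[List[LocalizationRecord], int]:
    """Label (gene_id, cnrci) pairs by CNRCI sign.

    Strictly positive CNRCI -> cytoplasm, strictly negative -> nucleus;
    zero or non-finite values are dropped.  Returns the labeled records
    and the number of dropped inputs.
    """
    labeled: List[LocalizationRecord] = []
    dropped = 0
    for gene_id, cnrci in records:
        if not math.isfinite(cnrci) or cnrci == 0.0:
            dropped += 1
            continue
        label = CYTOPLASM if cnrci > 0 else NUCLEUS
        labeled.append(LocalizationRecord(gene_id, cell_line, float(cnrci), label))
    return labeled, dropped


def read_cnrci_table(path: str | Path) -> pd.DataFrame:
    """Read a delimited CNRCI table (TSV/CSV autodetected).

    Expected columns: ``gene_id``, ``cell_line`` and either ``cnrci`` or the
    pair ``cyt_fpkm``/``nuc_fpkm`` (from which CNRCI is computed).
    """
    df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"gene_id", "cell_line"}
    if not required.issubset(df.columns):
        raise ValueError(f"CNRCI table must contain columns {sorted(required)}")
    if "cnrci" not in df.columns:
        if not {"cyt_fpkm", "nuc_fpkm"}.issubset(df.columns):
            raise ValueError("CNRCI table needs a 'cnrci' column or 'cyt_fpkm'+'nuc_fpkm'")
        df["cnrci"] = [
            compute_cnrci(c, n) for c, n in zip(df["cyt_fpkm"], df["nuc_fpkm"])
        ]
    return df


def filter_by_length(
    seqs: Sequence[NucleotideSequence], max_length: int = DEFAULT_MAX_LENGTH
) -> Tuple[List[NucleotideSequence], int]:
    """Keep sequences of length <= *max_length* (inclusive).

    Returns the kept sequences (order preserved, residues untouched) and
    the removed count.
    """
    if max_length < 1:
        raise ValueError("max_length must be >= 1")
    kept = [s for s in seqs if len(s) <= max_length]
    return kept, len(seqs) - len(kept)


def _kmer_set(residues: str, k: int) -> set:
    return {residues[i : i + k] for i in range(len(residues) - k + 1)}


def estimate_identity(a: NucleotideSequence, b: NucleotideSequence, k: int = 12) -> float:
    """k-mer containment identity estimate between two sequences.

    The shorter sequence's k-mer set is intersected with the longer one's;
    the estimate is the contained fraction.  Sequences shorter than k share
    no k-mers and score 0 unless identical.
    """
    if a.residues == b.residues:
        return 1.0
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    ks = _kmer_set(short.residues, k)
    if not ks:
        return 0.0
    kl = _kmer_set(long_.residues, k)
    return len(ks & kl) / len(ks)


def reduce_redundancy(
    seqs: Sequence[NucleotideSequence],
    identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD,
    k: int = 12,
) -> List[NucleotideSequence]:
    """Greedy longest-first clustering; returns cluster representatives.

    Sequences are visited longest-first (ties keep input order); each joins
    the first existing cluster whose founder it matches at >=
    *identity_threshold* estimated identity, else founds a new cluster.
    Founders are returned in founding order.  Deterministic and idempotent.
    """
    if not (0.0 < identity_threshold < 1.0):
        raise ValueError("identity_threshold must be in (0, 1)")
    order = sorted(range(len(seqs)), key=lambda i: (-len(seqs[i]), i))
    reps: List[NucleotideSequence] = []
    rep_kmers: List[set] = []
    for i in order:
        seq = seqs[i]
        ks = _kmer_set(seq.residues, k)
        placed = False
        for rep, rk in zip(reps, rep_kmers):
            if seq.residues == rep.residues:
                placed = True
                break
            if ks:
                # seq is never longer than rep (longest-first order), so
                # containment is measured on seq's k-mer set
                if len(ks & rk) / len(ks) >= identity_threshold:
                    placed = True
                    break
        if not placed:
            reps.append(seq)
            rep_kmers.append(ks)
    return reps


def _largest_remainder(counts: Dict[str, int], total: int) -> Dict[str, int]:
    """Allocate *total* across classes proportionally to *counts*."""
    n = sum(counts.values())
    quotas = {c: total * v / n for c, v in counts.items()}
    alloc = {c: int(math.floor(q)) for c, q in quotas.items()}
    leftover = total - sum(alloc.values())
    # largest fractional remainder first; ties by class name for determinism
    order = sorted(counts, key=lambda c: (-(quotas[c] - alloc[c]), c))
    for c in order[:leftover]:
        alloc[c] += 1
    return alloc


def stratified_split(
    labels: Dict[str, str],
    test_fraction: float = DEFAULT_TEST_FRACTION,
    seed: int = 42,
) -> Tuple[List[str], List[str]]:
    """Split ids into train/validation preserving class proportions.

    The validation size is ``ceil(test_fraction * N)``; per-class validation
    counts follow proportional allocation with largest-remainder rounding,
    so the sizes depend only on the class totals, not on the seed.  The
    seed randomizes which members fill each class quota.
    """
    if not (0.0 < test_fraction < 1.0):
        raise ValueError("test_fraction must be in (0, 1)")
    by_class: Dict[str, List[str]] = {}
    for gid, lab in labels.items():
        by_class.setdefault(lab, []).append(gid)
    for lab, members in by_class.items():
        if len(members) < 2:
            raise StratificationError(
                f"class {lab!r} has {len(members)} member(s); need at least 2"
            )
    n = len(labels)
    n_val = math.ceil(test_fraction * n)
    alloc = _largest_remainder({c: len(v) for c, v in by_class.items()}, n_val)
    rng = np.random.default_rng(seed)
    val_ids: List[str] = []
    for lab in sorted(by_class):
        members = sorted(by_class[lab])
        take = alloc[lab]
        picked = rng.permutation(len(members))[:take]
        val_ids.extend(members[i] for i in picked)
    val_set = set(val_ids)
    train_ids = [gid for gid in labels if gid not in val_set]
    return train_ids, sorted(val_ids)


def build_cell_line_dataset(
    seqs: Sequence[NucleotideSequence],
    records: Sequence[LocalizationRecord],
    cell_line: str,
    max_length: int = DEFAULT_MAX_LENGTH,
    identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD,
    test_fraction: float = DEFAULT_TEST_FRACTION,
    seed: int = 42,
) -> CellLineDataset:
    """Assemble one cell line's dataset: label join, redundancy reduction,
    length filter and stratified split."""
    label_of = {r.gene_id: r.label for r in records if r.cell_line == cell_line}
    with_label = [s for s in seqs if s.id in label_of]
    reduced = reduce_redundancy(with_label, identity_threshold)
    kept, _ = filter_by_length(reduced, max_length)
    entries = [(s, label_of[s.id]) for s in kept]
    train_ids, val_ids = stratified_split(
        {s.id: lab for s, lab in entries}, test_fraction, seed
    )
    split = {gid: TRAIN for gid in train_ids}
    split.update({gid: VALIDATION for gid in val_ids})
    return CellLineDataset(cell_line, entries, split)
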