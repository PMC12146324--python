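"""Synthetic benchmark data with planted localization signal.

Sequences are drawn from a first-order (dinucleotide) Markov chain whose
transition probabilities are tilted by latent compartment class:
cytoplasmic sequences are enriched in C residues and CpG steps, nuclear
sequences in T residues and TpG steps — the same qualitative contrast the
feature-importance analysis expects on real data (C-rich k-mers favor
cytoplasm, T-rich k-mers favor nucleus).  The CNRCI of each gene is a
noisy linear read-out of its CG-vs-TG dinucleotide content, so both the
labels and the continuous index carry the planted compositional signal.

Because class information enters through dinucleotide *transitions*, the
correlation-family descriptors (which scan dinucleotide property
profiles) carry signal as well, not only plain composition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Tuple

import numpy as np
import pandas as pd

from .dataset import CYTOPLASM, NUCLEUS
from .errors import ConfigError
from .seqio import NucleotideSequence, write_fasta

BASES = "ACGT"
_IDX = {b: i for i, b in enumerate(BASES)}


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; defaults define the package's standard benchmark."""

    n_sequences: int = 1000
    length_range: Tuple[int, int] = (200, 2000)
    effect_size: float = 3.0      # beta: CNRCI units per sd of composition signal
    noise_sd: float = 0.5         # sigma of the additive CNRCI noise (log2 units)
    cg_bias: float = 0.12         # transition tilt toward C/CpG in cytoplasmic class
    t_bias: float = 0.12          # transition tilt toward T/TpG in nuclear class
    n_cell_lines: int = 1
    flip_fraction: float = 0.0    # genes whose CNRCI sign flips in other cell lines
    class_balance: float = 0.5    # P(cytoplasm)
    seed: int = 42

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if not (200 <= lo <= hi <= 10_000):
            raise ConfigError("length_range must lie within [200, 10000]")
        if self.n_sequences < 20:
            raise ConfigError("n_sequences must be >= 20")
        if self.effect_size < 0:
            raise ConfigError("effect_size must be >= 0")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be > 0")
        if not (0 <= self.cg_bias < 0.25) or not (0 <= self.t_bias < 0.25):
            raise ConfigError("biases must lie in [0, 0.25) to keep valid probabilities")
        if not (0 < self.class_balance < 1):
            raise ConfigError("class_balance must be in (0, 1)")
        if not (0 <= self.flip_fraction <= 1):
            raise ConfigError("flip_fraction must be in [0, 1]")
        if self.n_cell_lines < 1:
            raise ConfigError("n_cell_lines must be >= 1")


def _transition_matrix(cg_bias: float, t_bias: float, cytoplasm: bool) -> np.ndarray:
    """Row-stochastic 4x4 transition matrix with class-specific tilts."""
    T = np.full((4, 4), 0.25)
    if cytoplasm:
        # enrich C everywhere and G specifically after C (CpG steps)
        T[:, _IDX["C"]] += cg_bias / 2
        T[_IDX["C"], _IDX["G"]] += cg_bias
    else:
        # enrich T everywhere and G specifically after T (TpG steps)
        T[:, _IDX["T"]] += t_bias / 2
        T[_IDX["T"], _IDX["G"]] += t_bias
    return T / T.sum(axis=1, keepdims=True)


def _sample_markov(rng: np.random.Generator, T: np.ndarray, length: int) -> str:
    cum = T.cumsum(axis=1)
    out = np.empty(length, dtype=np.int64)
    out[0] = rng.integers(4)
    u = rng.random(length)
    for i in range(1, length):
        out[i] = np.searchsorted(cum[out[i - 1]], u[i])
    return "".join(BASES[i] for i in out)


def _dinuc_freq(residues: str, dinuc: str) -> float:
    count = sum(
        1
        for i in range(len(residues) - 1)
        if residues[i] == dinuc[0] and residues[i + 1] == dinuc[1]
    )
    return count / (len(residues) - 1)


def simulate_dataset(
    config: SyntheticConfig = SyntheticConfig(),
) -> Tuple[List[NucleotideSequence], pd.DataFrame, pd.DataFrame]:
    """Generate sequences, a per-cell-line CNRCI table and the ground truth.

    CNRCI = effect_size * z(f_CG - f_TG) + Normal(0, noise_sd); whenever the
    noisy value clears the noise scale (|CNRCI| > sigma) its sign is forced
    to agree with the latent class.  Additional cell lines reuse the same
    genes; a seeded ``flip_fraction`` subset of genes gets its CNRCI sign
    inverted there, emulating genes that relocalize between cell lines.

    Returns (sequences, cnrci_table, truth_table); the CNRCI table has
    columns gene_id/cell_line/cnrci, the truth table records the latent
    class and the planted dinucleotide frequencies.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_sequences
    classes = rng.random(n) < config.class_balance  # True = cytoplasm
    lengths = rng.integers(config.length_range[0], config.length_range[1] + 1, size=n)
    T_cyt = _transition_matrix(config.cg_bias, config.t_bias, cytoplasm=True)
    T_nuc = _transition_matrix(config.cg_bias, config.t_bias, cytoplasm=False)
    width = len(str(n))
    seqs: List[NucleotideSequence] = []
    f_cg = np.empty(n)
    f_tg = np.empty(n)
    for i in range(n):
        residues = _sample_markov(rng, T_cyt if classes[i] else T_nuc, int(lengths[i]))
        seqs.append(NucleotideSequence(f"gene{i + 1:0{width}d}", residues))
        f_cg[i] = _dinuc_freq(residues, "CG")
        f_tg[i] = _dinuc_freq(residues, "TG")
    signal = f_cg - f_tg
    z = (signal - signal.mean()) / signal.std()
    cnrci = config.effect_size * z + rng.normal(0.0, config.noise_sd, size=n)
    if config.effect_size > 0:
        # force the sign to agree with the latent class whenever the value
        # clears the noise scale; under a null effect (beta = 0) the labels
        # must stay independent of composition, so no forcing is applied
        class_sign = np.where(classes, 1.0, -1.0)
        force = (np.abs(cnrci) > config.noise_sd) & (np.sign(cnrci) != class_sign)
        cnrci[force] = -cnrci[force]

    rows = []
    cell_lines = [f"CL{j + 1}" for j in range(config.n_cell_lines)]
    n_flip = int(round(config.flip_fraction * n))
    for j, cl in enumerate(cell_lines):
        values = cnrci.copy()
        if j > 0 and n_flip:
            flip_idx = rng.choice(n, size=n_flip, replace=False)
            values[flip_idx] = -values[flip_idx]
        rows.append(
            pd.DataFrame(
                {"gene_id": [s.id for s in seqs], "cell_line": cl, "cnrci": values}
            )
        )
    table = pd.concat(rows, ignore_index=True)
    truth = pd.DataFrame(
        {
            "gene_id": [s.id for s in seqs],
            "latent_class": np.where(classes, CYTOPLASM, NUCLEUS),
            "f_CG": f_cg,
            "f_TG": f_tg,
            "length": lengths,
        }
    )
    return seqs, table, truth


def make_fixture_suite(out_dir: str | Path, seed: int = 42) -> dict:
    """Write the canonical small fixtures used across the test suite.

    Produces a 3-sequence FASTA with hand-checkable descriptor values, a
    2-cell-line CNRCI table containing boundary cases (zero, negative and
    missing values), a redundancy family FASTA (5 mutated families), and a
    1,000-sequence training set with the default planted signal.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}

    tiny = [
        NucleotideSequence("tiny1", "ACGTACGTACGT"),
        NucleotideSequence("tiny2", "AAAACCCCGGGGTTTT"),
        NucleotideSequence("tiny3", "ACGT" * 10),
    ]
    paths["tiny_fasta"] = out_dir / "tiny.fasta"
    write_fasta(tiny, paths["tiny_fasta"])

    cnrci = pd.DataFrame(
        {
            "gene_id": ["tiny1", "tiny2", "tiny3", "tiny1", "tiny2", "tiny3"],
            "cell_line": ["CL1", "CL1", "CL1", "CL2", "CL2", "CL2"],
            "cnrci": [1.5, -0.3, 0.0, -2.0, float("nan"), 0.7],
        }
    )
    paths["cnrci_table"] = out_dir / "cnrci.tsv"
    cnrci.to_csv(paths["cnrci_table"], sep="\t", index=False)

    rng = np.random.default_rng(seed)
    family_seqs: List[NucleotideSequence] = []
    for fam in range(5):
        founder = "".join(rng.choice(list(BASES), size=600))
        for member in range(4):
            arr = list(founder)
            # 0.5% point mutations: with 12-mer containment identity, m
            # mutations in length L cost at most 12*m of the L-11 k-mers,
            # so 3 mutations in 600 nt keep identity >= 0.93 > 0.90
            n_mut = max(1, int(0.005 * len(arr))) if member else 0
            for pos in rng.choice(len(arr), size=n_mut, replace=False):
                arr[pos] = BASES[rng.integers(4)]
            family_seqs.append(
                NucleotideSequence(f"fam{fam + 1}_m{member + 1}", "".join(arr))
            )
    paths["redundancy_fasta"] = out_dir / "families.fasta"
    write_fasta(family_seqs, paths["redundancy_fasta"])

    seqs, table, truth = simulate_dataset(SyntheticConfig(seed=seed))
    paths["train_fasta"] = out_dir / "train.fasta"
    paths["train_cnrci"] = out_dir / "train_cnrci.tsv"
    paths["train_truth"] = out_dir / "train_truth.tsv"
    write_fasta(seqs, paths["train_fasta"])
    table.to_csv(paths["train_cnrci"], sep="\t", index=False)
    truth.to_csv(paths["train_truth"], sep="\t", index=False)
    return paths
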