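"""Reading, validating and writing nucleotide sequences.

Sequences are stored DNA-style over the {A, C, G, T} alphabet; RNA input
is accepted and U residues are mapped to T on the way in.  The FASTA id is
the first whitespace-delimited token of the header line and must be unique
within one dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import (
    DuplicateIdError,
    EmptyDatasetError,
    FastaParseError,
    InvalidAlphabetError,
)

VALID_BASES = frozenset("ACGT")

#: residue-normalization policies for `normalize_sequence`
STRICT = "strict"
DROP_AMBIGUOUS = "drop-ambiguous"

_TRANSLATE = str.maketrans("acgtu", "ACGTT")


@dataclass(frozen=True)
class NucleotideSequence:
    """A validated A/C/G/T sequence with its FASTA identifier."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.residues:
            raise InvalidAlphabetError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - VALID_BASES
        if bad:
            raise InvalidAlphabetError(
                f"sequence {self.id!r} contains non-ACGT residue(s) {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


def normalize_sequence(raw: str, policy: str = STRICT) -> str:
    """Uppercase *raw*, map U to T, and resolve ambiguous residues.

    Under the ``strict`` policy any residue outside A/C/G/T/U raises
    :class:`InvalidAlphabetError`; under ``drop-ambiguous`` such residues
    are removed.
    """
    if not raw:
        raise InvalidAlphabetError("empty sequence")
    cleaned = raw.upper().translate(_TRANSLATE).replace("U", "T")
    bad = set(cleaned) - VALID_BASES
    if not bad:
        return cleaned
    if policy == STRICT:
        sym = sorted(bad)[0]
        raise InvalidAlphabetError(
            f"invalid residue {sym!r} under strict alphabet policy"
        )
    if policy == DROP_AMBIGUOUS:
        kept = "".join(c for c in cleaned if c in VALID_BASES)
        if not kept:
            raise InvalidAlphabetError("no valid residues left after dropping ambiguous")
        return kept
    raise ValueError(f"unknown alphabet policy {policy!r}")


def read_fasta(path: str | Path, policy: str = STRICT) -> List[NucleotideSequence]:
    """Read a FASTA file into validated, normalized sequences.

    Record order is preserved.  Duplicate ids raise
    :class:`DuplicateIdError`; an empty file raises
    :class:`EmptyDatasetError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _check_fasta_shape(path)
    records: List[NucleotideSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise DuplicateIdError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(NucleotideSequence(rec.id, normalize_sequence(str(rec.seq), policy)))
    if not records:
        raise EmptyDatasetError(f"no FASTA records found in {path}")
    return records


def _check_fasta_shape(path: Path) -> None:
    """Reject files whose first non-blank line is not a FASTA header."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise FastaParseError(
                    f"{path}:{lineno}: expected '>' header, got {line.strip()[:30]!r}"
                )
            return


def write_fasta(seqs: Iterable[NucleotideSequence], path: str | Path, width: int = 70) -> None:
    """Write sequences as multi-line FASTA."""
    recs = [SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)
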