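"""Reading, validating and preprocessing protein primary sequences.

Wheat prolamin precursors carry an N-terminal signal peptide (20–23
residues for the proteins modelled here) that is cleaved during
synthesis; simulations and profiles operate on the mature chain, so
:func:`trim_signal_peptide` re-indexes cysteine positions accordingly.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Sequence, Tuple, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .scales import STANDARD_AA

PathLike = Union[str, Path]


class SequenceValidationError(ValueError):
    """Raised when a record contains non-standard residue symbols."""


@dataclass(frozen=True)
class ProteinSequence:
    """A validated protein sequence with 1-based cysteine bookkeeping."""

    id: str
    residues: str
    signal_peptide_length: int = 0

    def __post_init__(self) -> None:
        if not self.residues:
            raise SequenceValidationError(f"record {self.id!r} is empty")
        bad = [c for c in self.residues if c not in STANDARD_AA]
        if bad:
            raise SequenceValidationError(
                f"record {self.id!r} contains non-amino-acid symbol {bad[0]!r}"
            )
        if not 0 <= self.signal_peptide_length < len(self.residues):
            raise ValueError(
                "signal_peptide_length must satisfy "
                f"0 <= n < {len(self.residues)}, got {self.signal_peptide_length}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def cys_positions(self) -> Tuple[int, ...]:
        """1-based indices of cysteines, strictly increasing."""
        return tuple(i + 1 for i, c in enumerate(self.residues) if c == "C")

    def net_charge(self, scheme) -> int:
        return int(sum(scheme[c] for c in self.residues))


def _clean(raw: str, record_id: str) -> str:
    s = raw.strip().upper()
    if "*" in s:
        warnings.warn(
            f"record {record_id!r}: stripping {s.count('*')} stop symbol(s)",
            stacklevel=3,
        )
        s = s.replace("*", "")
    return s


def read_fasta(path: PathLike) -> List[ProteinSequence]:
    """Read a FASTA file into validated :class:`ProteinSequence` records.

    The header token before the first whitespace becomes the id.
    Lowercase residues are accepted and uppercased; ``*`` stop symbols
    are stripped with a warning. An empty file or a record containing a
    non-amino-acid symbol raises.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no records found in {path}")
    return [
        ProteinSequence(id=rec.id, residues=_clean(str(rec.seq), rec.id))
        for rec in records
    ]


def write_fasta(sequences: Iterable[ProteinSequence], path: PathLike) -> None:
    """Write sequences as FASTA, wrapped at 60 columns."""
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description="") for s in sequences
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(records)


def trim_signal_peptide(seq: ProteinSequence, n: int) -> ProteinSequence:
    """Remove the first ``n`` residues (the signal peptide).

    Cysteine positions of the returned mature sequence equal the
    original 1-based positions minus ``n``, restricted to positions > n.
    """
    if not 0 <= n < len(seq):
        raise ValueError(
            f"signal peptide length {n} out of range for sequence of "
            f"length {len(seq)}"
        )
    if n == 0:
        return seq
    return ProteinSequence(id=seq.id, residues=seq.residues[n:])
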