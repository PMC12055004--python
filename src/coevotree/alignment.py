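"""Aligned protein sequence container with FASTA I/O."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import InvalidAlignmentError
from .jtt import encode_sequence


@dataclass(frozen=True)
class ProteinAlignment:
    """An alignment of taxon-labeled protein sequences.

    Invariants: all sequences have equal length, taxon labels are unique,
    and there are at least two records.  Sequences are over the 20 amino
    acids plus gap/ambiguity codes.
    """

    records: tuple[tuple[str, str], ...]

    def __post_init__(self):
        recs = tuple((str(t), str(s).upper()) for t, s in self.records)
        if len(recs) < 2:
            raise InvalidAlignmentError("alignment needs at least 2 records")
        labels = [t for t, _ in recs]
        if len(set(labels)) != len(labels):
            dupes = sorted({t for t in labels if labels.count(t) > 1})
            raise InvalidAlignmentError(f"duplicate taxon labels: {dupes}")
        lengths = {len(s) for _, s in recs}
        if len(lengths) != 1:
            raise InvalidAlignmentError(f"ragged alignment, lengths {sorted(lengths)}")
        if next(iter(lengths)) < 1:
            raise InvalidAlignmentError("alignment length must be >= 1")
        object.__setattr__(self, "records", recs)

    @property
    def length(self) -> int:
        return len(self.records[0][1])

    @property
    def taxa(self) -> tuple[str, ...]:
        return tuple(t for t, _ in self.records)

    @property
    def n_taxa(self) -> int:
        return len(self.records)

    def sequence(self, taxon: str) -> str:
        for t, s in self.records:
            if t == taxon:
                return s
        raise KeyError(taxon)

    def encoded(self) -> np.ndarray:
        """(n_taxa, length) int8 matrix of state indices, -1 for gap/ambiguous."""
        return np.vstack([encode_sequence(s) for _, s in self.records])

    def subsample_columns(self, columns: Sequence[int]) -> "ProteinAlignment":
        cols = np.asarray(columns)
        return ProteinAlignment(tuple(
            (t, "".join(np.array(list(s))[cols])) for t, s in self.records))

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "ProteinAlignment":
        return cls(tuple(pairs))

    @classmethod
    def read_fasta(cls, path) -> "ProteinAlignment":
        recs = [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]
        if not recs:
            raise InvalidAlignmentError(f"no FASTA records in {path}")
        return cls(tuple(recs))

    def write_fasta(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        SeqIO.write(
            [SeqRecord(Seq(s), id=t, description="") for t, s in self.records],
            str(path), "fasta")
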