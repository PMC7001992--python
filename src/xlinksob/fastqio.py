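"""Minimal FASTQ record model and I/O.

Reads are carried through the preprocessing stages as lightweight
:class:`Read` records (name, sequence, integer Phred scores).  Disk I/O
goes through Biopython's FASTQ support (Phred+33, "fastq" format).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


@dataclass
class Read:
    """A single sequencing read.

    ``qual`` holds integer Phred scores, one per base; the invariant
    ``len(qual) == len(seq)`` is enforced on construction.
    """

    name: str
    seq: str
    qual: tuple[int, ...]

    def __post_init__(self) -> None:
        self.qual = tuple(self.qual)
        if len(self.qual) != len(self.seq):
            raise ValueError(
                f"read {self.name!r}: quality length {len(self.qual)} "
                f"!= sequence length {len(self.seq)}"
            )
        if any(q < 0 for q in self.qual):
            raise ValueError(f"read {self.name!r}: negative Phred score")

    def __len__(self) -> int:
        return len(self.seq)


def read_fastq(path: str | Path) -> Iterator[Read]:
    """Iterate over a Phred+33 FASTQ file as :class:`Read` records."""
    for rec in SeqIO.parse(str(path), "fastq"):
        yield Read(
            name=rec.description or rec.id,
            seq=str(rec.seq),
            qual=tuple(rec.letter_annotations["phred_quality"]),
        )


def write_fastq(reads: Iterable[Read], path: str | Path) -> int:
    """Write reads as Phred+33 FASTQ; returns the number written."""
    n = 0

    def _records():
        nonlocal n
        for r in reads:
            rec = SeqRecord(Seq(r.seq), id=r.name, description="")
            rec.letter_annotations["phred_quality"] = list(r.qual)
            n += 1
            yield rec

    SeqIO.write(_records(), str(path), "fastq")
    return n
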