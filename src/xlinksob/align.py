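"""Ungapped alignment of iCLIP inserts and UMI-aware duplicate collapsing.

The built-in aligner is a desk-scale exact/near-exact mapper for the
synthetic references produced by :mod:`xlinksob.simulate`: it scans both
strands of every contig for hits with at most two mismatches, never
soft-clips and reports uniqueness.  Real data aligned externally can be
ingested from SAM/BAM instead; both paths produce the same
:class:`AlignedSegment` records.

Duplicate collapsing follows the random-barcode scheme: reads whose 5'
ends map to the same genomic position are duplicate candidates; among
those, reads sharing the same random barcode are technical (PCR)
duplicates and are collapsed to one, while differing barcodes mark
independent molecules and are all kept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pysam

from .fastqio import Read
from .preprocess import parse_barcodes

_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


@dataclass
class AlignedSegment:
    name: str
    contig: str
    strand: str          # "+" or "-"
    start: int           # 0-based half-open genomic interval
    end: int
    spliced: bool = False
    unique: bool = True
    n_mismatches: int = 0

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"{self.name}: empty or inverted interval")

    @property
    def five_prime_pos(self) -> int:
        """Genomic coordinate of the read's biological 5' end (start for
        plus-strand reads, the highest aligned coordinate for minus)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def random_barcode(self) -> str:
        return parse_barcodes(self.name)[1]


def _hamming_hits(read_seq: str, contig_seq: str, max_mismatches: int):
    """All (position, mismatches) of ungapped hits with <= max_mismatches.

    Exact occurrences are enumerated with ``str.find``; the full Hamming
    scan (vectorised over windows) runs only when no exact hit exists.
    """
    hits = []
    i = contig_seq.find(read_seq)
    while i != -1:
        hits.append((i, 0))
        i = contig_seq.find(read_seq, i + 1)
    if hits:
        return hits
    L = len(read_seq)
    if L > len(contig_seq):
        return []
    g = np.frombuffer(contig_seq.encode(), dtype=np.uint8)
    r = np.frombuffer(read_seq.encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(g, L)
    mism = (windows != r).sum(axis=1)
    best = int(mism.min())
    if best > max_mismatches:
        return []
    return [(int(i), int(mism[i])) for i in np.nonzero(mism <= max_mismatches)[0]]


def align_naive(reads: Iterable[Read], contigs: dict[str, str],
                max_mismatches: int = 2) -> list[AlignedSegment]:
    """Map reads ungapped to both strands of every contig.

    For each read, all hits with <= 2 mismatches are collected; the
    single segment reported carries ``unique=True`` iff exactly one hit
    achieves the best mismatch count.  Unmappable reads are silently
    skipped (they would be removed downstream in any case).
    """
    segments = []
    rc_cache = {name: _revcomp(seq) for name, seq in contigs.items()}
    for read in reads:
        hits = []  # (mismatches, contig, strand, start)
        for contig, seq in contigs.items():
            for pos, mm in _hamming_hits(read.seq, seq, max_mismatches):
                hits.append((mm, contig, "+", pos))
            for pos, mm in _hamming_hits(read.seq, rc_cache[contig],
                                         max_mismatches):
                # position on the reverse-complement strand maps back to
                # forward coordinates from the contig's right edge
                start = len(seq) - pos - len(read.seq)
                hits.append((mm, contig, "-", start))
        if not hits:
            continue
        best = min(h[0] for h in hits)
        best_hits = [h for h in hits if h[0] == best]
        mm, contig, strand, start = best_hits[0]
        segments.append(AlignedSegment(
            name=read.name, contig=contig, strand=strand, start=start,
            end=start + len(read.seq), spliced=False,
            unique=len(best_hits) == 1, n_mismatches=mm))
    return segments


def filter_alignments(segments: Iterable[AlignedSegment]) -> list[AlignedSegment]:
    """Keep uniquely mapping, unspliced segments only."""
    return [s for s in segments if s.unique and not s.spliced]


def deduplicate(segments: Iterable[AlignedSegment]) -> list[AlignedSegment]:
    """Collapse PCR duplicates by (contig, strand, 5' position, barcode).

    Within each class exactly one segment is kept — the one with the
    lexicographically smallest name, which makes the result independent
    of input order.  Classes at the same position that differ in random
    barcode all survive (biological duplicates).
    """
    best: dict[tuple, AlignedSegment] = {}
    for seg in segments:
        try:
            barcode = seg.random_barcode
        except ValueError as exc:
            raise ValueError(f"segment {seg.name!r} lacks a random-barcode "
                             f"field in its name") from exc
        key = (seg.contig, seg.strand, seg.five_prime_pos, barcode)
        cur = best.get(key)
        if cur is None or seg.name < cur.name:
            best[key] = seg
    return sorted(best.values(),
                  key=lambda s: (s.contig, s.start, s.strand, s.name))


# ---------------------------------------------------------------------------
# SAM/BAM interchange

def write_sam(segments: Iterable[AlignedSegment], contig_lengths: dict[str, int],
              path: str | Path) -> None:
    """Serialise naive-aligner output as headered SAM."""
    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": n, "LN": ln} for n, ln in contig_lengths.items()]}
    names = list(contig_lengths)
    with pysam.AlignmentFile(str(path), "wh", header=header) as fh:
        for seg in sorted(segments, key=lambda s: (names.index(s.contig), s.start)):
            a = pysam.AlignedSegment(fh.header)
            a.query_name = seg.name
            a.reference_name = seg.contig
            a.reference_start = seg.start
            a.cigarstring = f"{seg.end - seg.start}M"
            a.flag = 16 if seg.strand == "-" else 0
            a.mapping_quality = 255 if seg.unique else 0
            a.set_tag("NH", 1 if seg.unique else 2)
            a.set_tag("NM", seg.n_mismatches)
            fh.write(a)


def load_alignments(path: str | Path, unique_tag: str = "NH",
                    mapq_min: int | None = None) -> list[AlignedSegment]:
    """Ingest SAM/BAM into :class:`AlignedSegment` records.

    A record is spliced iff its CIGAR contains a skipped-region (N)
    operator.  Uniqueness evidence is the configured tag (``NH == 1``) or,
    if ``mapq_min`` is given, ``MAPQ >= mapq_min``; records lacking both
    are dropped with a warning, since the published filter requires
    knowing uniqueness.
    """
    segments = []
    dropped = 0
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                continue
            if rec.has_tag(unique_tag):
                unique = rec.get_tag(unique_tag) == 1
            elif mapq_min is not None:
                unique = rec.mapping_quality >= mapq_min
            else:
                dropped += 1
                continue
            spliced = any(op == 3 for op, _ in (rec.cigartuples or []))
            nm = rec.get_tag("NM") if rec.has_tag("NM") else 0
            segments.append(AlignedSegment(
                name=rec.query_name, contig=rec.reference_name,
                strand="-" if rec.is_reverse else "+",
                start=rec.reference_start, end=rec.reference_end,
                spliced=spliced, unique=unique, n_mismatches=nm))
    if dropped:
        warnings.warn(f"{dropped} records lacked uniqueness evidence "
                      f"(no {unique_tag} tag and no MAPQ threshold); dropped")
    return segments
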