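"""Strand-specific single-nucleotide crosslink-event tracks.

In iCLIP, reverse transcription truncates at the protein-crosslinked
nucleotide, so the crosslink sits one nucleotide upstream — in transcript
orientation — of a read's 5' mapping position.  For a plus-strand read
starting at ``start`` that is genomic position ``start - 1``; for a
minus-strand read spanning ``[start, end)`` the biological 5' end is
``end - 1`` and the crosslink is one position 3'-ward in genome
coordinates, i.e. ``end``.  Off-by-one errors here shift every downstream
site, hence the explicit convention.

All coordinates are 0-based half-open; bedgraph output uses the format's
native 0-based half-open intervals.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .align import AlignedSegment


@dataclass
class CrosslinkTrack:
    """Sparse per-(contig, strand) map of position -> event count."""

    counts: dict[tuple[str, str], dict[int, int]] = field(
        default_factory=lambda: defaultdict(dict))
    dropped_at_boundary: int = 0

    def add(self, contig: str, strand: str, pos: int) -> None:
        d = self.counts[(contig, strand)]
        d[pos] = d.get(pos, 0) + 1

    def get(self, contig: str, strand: str, pos: int) -> int:
        return self.counts.get((contig, strand), {}).get(pos, 0)

    def total(self) -> int:
        return sum(sum(d.values()) for d in self.counts.values())

    def region_sum(self, contig: str, strand: str, start: int, end: int) -> int:
        d = self.counts.get((contig, strand), {})
        if not d:
            return 0
        if end - start < len(d):
            return sum(d.get(p, 0) for p in range(start, end))
        return sum(c for p, c in d.items() if start <= p < end)


def extract_crosslinks(segments: Iterable[AlignedSegment],
                       contig_lengths: dict[str, int] | None = None,
                       ) -> CrosslinkTrack:
    """Convert deduplicated alignments to crosslink events.

    Events that would fall outside contig bounds (5' end at a contig
    edge) are dropped and tallied in ``track.dropped_at_boundary``.
    """
    track = CrosslinkTrack()
    for seg in segments:
        pos = seg.start - 1 if seg.strand == "+" else seg.end
        if pos < 0:
            track.dropped_at_boundary += 1
            continue
        if contig_lengths is not None and pos >= contig_lengths[seg.contig]:
            track.dropped_at_boundary += 1
            continue
        track.add(seg.contig, seg.strand, pos)
    return track


def write_bedgraph(track: CrosslinkTrack, strand: str, path: str | Path) -> None:
    """Write one strand of a track as bedgraph (0-based half-open).

    Adjacent positions with equal counts are merged into one interval.
    """
    with open(path, "w") as fh:
        for (contig, s), d in sorted(track.counts.items()):
            if s != strand or not d:
                continue
            positions = sorted(d)
            run_start = prev = positions[0]
            run_count = d[run_start]
            for p in positions[1:]:
                if p == prev + 1 and d[p] == run_count:
                    prev = p
                    continue
                fh.write(f"{contig}\t{run_start}\t{prev + 1}\t{run_count}\n")
                run_start = prev = p
                run_count = d[p]
            fh.write(f"{contig}\t{run_start}\t{prev + 1}\t{run_count}\n")


def read_bedgraph(path: str | Path, strand: str) -> CrosslinkTrack:
    """Inverse of :func:`write_bedgraph` (counts must be integral)."""
    track = CrosslinkTrack()
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            contig, start, end, count = line.split()
            for pos in range(int(start), int(end)):
                d = track.counts[(contig, strand)]
                d[pos] = d.get(pos, 0) + int(count)
    return track
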