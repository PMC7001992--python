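"""Binding-site strength (signal-over-background) and sequence context.

The signal-over-background (SOB) ratio corrects crosslink-event counts
for transcript abundance: each gene's background crosslink density is
the number of events over its merged exons that fall outside binding
sites (with a 5-nt flank excluded around each site), divided by the
merged exonic length.  A site's SOB is its event count divided by that
per-nucleotide background rate, so SOB carries units of nucleotides and
is invariant under uniform rescaling of the track.  For the background,
annotated 3'UTRs are truncated to 10 nt past the gene's 3'-most binding
site, or to 500 nt when the gene has no 3'UTR site, so that unbound
3'UTR tail sequence does not dilute the background estimate.

No SOB is assigned for ribosomal genes or for genes with fewer than 10
background crosslink events; per-replicate values are averaged
arithmetically over the replicates where they are defined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

from .tracks import CrosslinkTrack

HOMOPOLYMER_DIMERS = ("AA", "CC", "GG", "TT")
ALL_DIMERS = tuple("".join(p) for p in product("ACGT", repeat=2))

_COMP = str.maketrans("ACGTN", "TGCAN")


@dataclass
class GeneModel:
    gene_id: str
    contig: str
    strand: str
    exons: list[tuple[int, int]]     # 0-based half-open
    utr3: tuple[int, int] | None = None
    ribosomal: bool = False

    def merged_exons(self) -> list[tuple[int, int]]:
        return merge_intervals(self.exons)


@dataclass(frozen=True)
class BindingSite:
    gene_id: str
    contig: str
    start: int
    end: int

    @property
    def midpoint(self) -> int:
        """Floor of the interval centre (lower-median for even widths)."""
        return (self.start + self.end - 1) // 2


@dataclass
class SOBRecord:
    site: BindingSite
    replicate_values: list[float | None] = field(default_factory=list)
    mean: float | None = None
    excluded_reason: str | None = None  # ribosomal | low_background | None


def merge_intervals(intervals):
    out = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _subtract(intervals, cut):
    """Remove interval ``cut`` from a sorted disjoint interval list."""
    cs, ce = cut
    out = []
    for s, e in intervals:
        if e <= cs or s >= ce:
            out.append((s, e))
            continue
        if s < cs:
            out.append((s, cs))
        if e > ce:
            out.append((ce, e))
    return out


def effective_gene_extent(gene: GeneModel, sites: list[BindingSite],
                          utr3_site_flank: int = 10,
                          utr3_default: int = 500):
    """Merged exonic intervals with the 3'UTR truncated for background use.

    The 3'UTR is clipped (in transcript orientation) at 10 nt past the
    3'-most binding site inside it, or at 500 nt from the 3'UTR start when
    no site falls in the 3'UTR.  Clipping never extends the annotation.
    Returns ``(intervals, total_length)``.
    """
    merged = gene.merged_exons()
    if gene.utr3 is None:
        return merged, sum(e - s for s, e in merged)
    u0, u1 = gene.utr3
    in_utr = [b for b in sites if b.start < u1 and b.end > u0]
    if gene.strand == "+":
        if in_utr:
            cut_from = min(u1, max(b.end for b in in_utr) + utr3_site_flank)
        else:
            cut_from = min(u1, u0 + utr3_default)
        removed = (cut_from, u1)
    else:
        if in_utr:
            cut_to = max(u0, min(b.start for b in in_utr) - utr3_site_flank)
        else:
            cut_to = max(u0, u1 - utr3_default)
        removed = (u0, cut_to)
    if removed[0] < removed[1]:
        merged = _subtract(merged, removed)
    return merged, sum(e - s for s, e in merged)


def compute_sob(track: CrosslinkTrack, gene: GeneModel,
                sites: list[BindingSite], flank: int = 5,
                min_background_events: int = 10,
                normalize_by_width: bool = False) -> list[SOBRecord]:
    """Per-site SOB for a single replicate's crosslink track.

    ``background = events in the effective gene extent outside every
    (site +/- flank) / merged effective exonic length``; ``SOB(site) =
    events within the site / background``.  With ``normalize_by_width``
    the site count is first divided by the site width, making SOB a
    dimensionless density ratio instead of a count-over-density.
    Sites of ribosomal genes, and of genes with fewer than
    ``min_background_events`` background events, are excluded.
    """
    if gene.ribosomal:
        return [SOBRecord(site=b, replicate_values=[None],
                          excluded_reason="ribosomal") for b in sites]
    extent, length = effective_gene_extent(gene, sites)
    if length == 0:
        raise ValueError(f"{gene.gene_id}: zero merged exonic length")

    masked = merge_intervals([(b.start - flank, b.end + flank) for b in sites])
    bg_events = 0
    for s, e in extent:
        bg_events += track.region_sum(gene.contig, gene.strand, s, e)
        for ms, me in masked:
            os_, oe = max(s, ms), min(e, me)
            if os_ < oe:
                bg_events -= track.region_sum(gene.contig, gene.strand, os_, oe)
    if bg_events < min_background_events:
        return [SOBRecord(site=b, replicate_values=[None],
                          excluded_reason="low_background") for b in sites]
    bg_rate = bg_events / length
    out = []
    for b in sites:
        signal = track.region_sum(gene.contig, gene.strand, b.start, b.end)
        if normalize_by_width:
            signal = signal / (b.end - b.start)
        out.append(SOBRecord(site=b, replicate_values=[signal / bg_rate]))
    return out


def average_sob(per_replicate: list[list[SOBRecord]]) -> list[SOBRecord]:
    """Arithmetic mean over replicates where the value is defined.

    A site with no defined replicate stays excluded (reason taken from
    the first replicate's exclusion).
    """
    if not per_replicate:
        return []
    n_sites = len(per_replicate[0])
    out = []
    for i in range(n_sites):
        records = [rep[i] for rep in per_replicate]
        values = [v for r in records for v in r.replicate_values if v is not None]
        flat = [r.replicate_values[0] if r.replicate_values else None
                for r in records]
        if values:
            out.append(SOBRecord(site=records[0].site, replicate_values=flat,
                                 mean=float(np.mean(values))))
        else:
            reason = next((r.excluded_reason for r in records
                           if r.excluded_reason), "low_background")
            out.append(SOBRecord(site=records[0].site, replicate_values=flat,
                                 excluded_reason=reason))
    return out


def sob_table(records: list[SOBRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({
            "gene": r.site.gene_id, "contig": r.site.contig,
            "start": r.site.start, "end": r.site.end,
            **{f"sob_rep{i + 1}": v for i, v in enumerate(r.replicate_values)},
            "sob_mean": r.mean, "excluded": r.excluded_reason or "",
        })
    return pd.DataFrame(rows)


def dimer_profile(sites: list[BindingSite], genes: dict[str, GeneModel],
                  contigs: dict[str, str], window: int = 100,
                  dimers: tuple[str, ...] = HOMOPOLYMER_DIMERS) -> pd.DataFrame:
    """Mean positional dinucleotide occurrence around site midpoints.

    Sites are centred at their midpoint and a symmetric window extended
    ``window`` nt up- and downstream.  For offset p and dimer d, the
    profile holds the mean over sites of the indicator that the 2-mer
    starting at (midpoint + p) on the gene's sense strand equals d.
    Windows that would run off a contig are dropped with a warning.
    Returns a DataFrame indexed by offset (-window..+window) with one
    column per dimer; entries lie in [0, 1].
    """
    offsets = np.arange(-window, window + 1)
    if not sites:
        warnings.warn("no sites supplied; empty dimer profile")
        return pd.DataFrame(index=pd.Index(offsets, name="offset"),
                            columns=list(dimers), dtype=float)
    counts = {d: np.zeros(len(offsets)) for d in dimers}
    n_used = 0
    for b in sites:
        seq = contigs[b.contig]
        mid = b.midpoint
        lo, hi = mid - window, mid + window + 2  # +2: last dimer needs 2 nt
        if lo < 0 or hi > len(seq):
            warnings.warn(f"site {b.gene_id}:{b.start}-{b.end} window "
                          f"clipped at contig edge; dropped")
            continue
        sense = seq[lo:hi]
        if genes[b.gene_id].strand == "-":
            sense = sense.translate(_COMP)[::-1]
        n_used += 1
        for j in range(len(offsets)):
            pair = sense[j:j + 2]
            if pair in counts:
                counts[pair][j] += 1
    if n_used == 0:
        warnings.warn("all site windows clipped; empty dimer profile")
        return pd.DataFrame(index=pd.Index(offsets, name="offset"),
                            columns=list(dimers), dtype=float)
    data = {d: counts[d] / n_used for d in dimers}
    return pd.DataFrame(data, index=pd.Index(offsets, name="offset"))


def call_sites(track: CrosslinkTrack, min_count: int = 2, merge_gap: int = 0,
               gene_lookup=None) -> list[BindingSite]:
    """Minimal run-based peak caller.

    Maximal runs of positions with count >= ``min_count`` become sites;
    runs separated by gaps of at most ``merge_gap`` positions are merged.
    ``gene_lookup(contig, strand, start, end)`` may map an interval to a
    gene id (defaults to the contig name).
    """
    out = []
    for (contig, strand), d in sorted(track.counts.items()):
        positions = sorted(p for p, c in d.items() if c >= min_count)
        if not positions:
            continue
        runs = []
        start = prev = positions[0]
        for p in positions[1:]:
            if p - prev - 1 <= merge_gap:
                prev = p
            else:
                runs.append((start, prev + 1))
                start = prev = p
        runs.append((start, prev + 1))
        for s, e in runs:
            gid = (gene_lookup(contig, strand, s, e) if gene_lookup
                   else contig)
            if gid is not None:
                out.append(BindingSite(gene_id=gid, contig=contig,
                                       start=s, end=e))
    return out


# ---------------------------------------------------------------------------
# BED interchange

def read_sites_bed(path) -> list[BindingSite]:
    sites = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "#")):
                continue
            f = line.split()
            sites.append(BindingSite(gene_id=f[3] if len(f) > 3 else f[0],
                                     contig=f[0], start=int(f[1]),
                                     end=int(f[2])))
    return sites


def write_sites_bed(sites: list[BindingSite], path) -> None:
    with open(path, "w") as fh:
        for b in sites:
            fh.write(f"{b.contig}\t{b.start}\t{b.end}\t{b.gene_id}\t0\t.\n")
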