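"""Synthetic references, iCLIP reads and LFQ matrices with known ground truth.

The simulator emulates the statistical structure of a multiplexed iCLIP
experiment (75-nt single-end reads carrying a 9-nt composite barcode
prefix: random-barcode bases at read positions 1-3 and 8-9, a 4-nt
experimental barcode at positions 4-7) and of a label-free proteomics
protein-groups table (replicated intensity columns with
missing-not-at-random low-abundance values and a set of spiked enriched
proteins).

Crosslinking follows a truncation-only model: cDNA synthesis stops at the
protein-contacted nucleotide, so each read's insert begins one nucleotide
downstream (in transcript orientation) of the crosslinked position.  PCR
duplicates are exact copies of a molecule and share its random barcode;
independent molecules crosslinked at the same position carry independent
random barcodes.

Every generator draws from a single :class:`numpy.random.Generator` seeded
from the config, so a fixed config reproduces byte-identical output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .fastqio import Read
from .metrics import BindingSite, GeneModel

BASES = np.array(list("ACGT"))

DEFAULT_ADAPTER = "AGATCGGAAGAGCGGTTCAG"
# one control library alongside six bait replicates, mirroring a typical
# multiplexed iCLIP design
DEFAULT_BARCODES = {
    "Mkrn1_rep1": "GGTT",
    "Mkrn1_rep2": "TTGT",
    "Mkrn1_rep3": "CAAT",
    "Mkrn1_rep4": "ACCT",
    "Mkrn1_rep5": "GTCA",
    "Mkrn1_rep6": "TGCA",
    "GFP_ctrl": "CCGG",
}


@dataclass
class LFQConfig:
    """Label-free proteomics simulation parameters.

    Intensities are generated on the log2 scale (typical MS dynamic range,
    mean ~27).  Missingness is left-censoring-like: the probability that a
    value is unobserved decreases logistically with its log2 abundance
    (midpoint ``missing_mid``, steepness ``missing_scale``; the default
    curve models a sharp protein-level detection limit, so dropout is
    mostly all-or-none within a replicate group).  Spiked enriched
    proteins emulate confidently identified interactors: they always
    carry enough peptide evidence to survive the peptide-count filter.
    """

    n_proteins: int = 500
    n_contaminants: int = 15
    n_reverse: int = 15
    n_only_site: int = 10
    n_enriched: int = 25
    true_log2fc: float = 3.0
    replicates: int = 3
    base_mean: float = 27.0
    base_sd: float = 1.5
    noise_sd: float = 0.4
    missing_mid: float = 23.5
    missing_scale: float = 0.4


@dataclass
class SimConfig:
    seed: int = 0
    n_genes: int = 20
    exon_count_range: tuple[int, int] = (1, 3)
    exon_length_range: tuple[int, int] = (300, 800)
    utr3_length: int = 400
    n_true_sites_per_gene: int = 2
    site_width: int = 9
    signal_rate: float = 1.0        # expected crosslink events per site-nt
    background_rate: float = 0.1    # expected events per exonic nt
    duplication_rate: float = 1.0   # mean extra PCR copies per molecule
    read_length: int = 75
    insert_length_range: tuple[int, int] = (25, 60)
    corruption_prob: float = 0.02   # per-base chance of a low-quality call
    barcode_map: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_BARCODES))
    adapter_seq: str = DEFAULT_ADAPTER
    lfq: LFQConfig = field(default_factory=LFQConfig)

    def validate(self) -> None:
        for name in ("signal_rate", "background_rate", "duplication_rate",
                     "corruption_prob"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        codes = list(self.barcode_map.values())
        if len(set(codes)) != len(codes):
            raise ValueError("experimental barcodes must be distinct")
        for b in codes:
            if len(b) != 4 or set(b) - set("ACGT"):
                raise ValueError(f"barcode {b!r} is not a 4-mer over ACGT")
        if self.site_width > self.exon_length_range[0]:
            raise ValueError("site_width exceeds the shortest possible exon")
        if self.read_length < 10:
            raise ValueError("read_length must leave room for the 9-nt prefix")


@dataclass
class GroundTruth:
    """Everything the simulator knows that the pipeline must recover."""

    true_sites: dict[str, list[BindingSite]] = field(default_factory=dict)
    # one row per original molecule: sample, gene, contig, strand,
    # crosslink_pos (0-based), random_barcode, insert_len, n_copies, in_site
    molecule_table: pd.DataFrame | None = None
    lfq_truth: pd.DataFrame | None = None


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=n)])


def generate_reference(config: SimConfig):
    """Build a synthetic genome with gene models and true binding sites.

    Each gene lives on its own contig, flanked by intergenic padding, with
    1 or more exons separated by short introns.  The 3'UTR occupies the
    transcript-3' end of the terminal exon.  Genes alternate strand.
    Returns ``(contigs, genes, truth)`` where ``contigs`` maps contig name
    to sequence and ``truth.true_sites`` records the planted sites.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    contigs: dict[str, str] = {}
    genes: list[GeneModel] = []
    truth = GroundTruth()

    lo, hi = config.exon_count_range
    for gi in range(config.n_genes):
        contig = f"chr{gi + 1}"
        strand = "+" if gi % 2 == 0 else "-"
        n_exons = int(rng.integers(lo, hi + 1))
        exon_lens = rng.integers(*config.exon_length_range, size=n_exons)
        # terminal exon must contain the full 3'UTR plus coding margin
        term = n_exons - 1 if strand == "+" else 0
        exon_lens[term] = max(exon_lens[term], config.utr3_length + 100)
        pos = int(rng.integers(100, 300))
        exons: list[tuple[int, int]] = []
        for L in exon_lens:
            exons.append((pos, pos + int(L)))
            pos += int(L) + int(rng.integers(100, 300))
        total_len = pos + int(rng.integers(100, 300))
        seq = _random_seq(rng, total_len)
        contigs[contig] = seq

        if strand == "+":
            ts, te = exons[-1]
            utr3 = (te - config.utr3_length, te)
        else:
            ts, te = exons[0]
            utr3 = (ts, ts + config.utr3_length)
        gene = GeneModel(gene_id=f"gene{gi + 1}", contig=contig, strand=strand,
                         exons=exons, utr3=utr3, ribosomal=False)
        genes.append(gene)

        # plant non-overlapping sites inside exons, preferring the 3'UTR
        sites: list[BindingSite] = []
        attempts = 0
        while len(sites) < config.n_true_sites_per_gene and attempts < 200:
            attempts += 1
            if rng.random() < 0.5:
                s, e = utr3
            else:
                s, e = exons[int(rng.integers(0, n_exons))]
            if e - s < config.site_width:
                continue
            start = int(rng.integers(s, e - config.site_width + 1))
            iv = (start, start + config.site_width)
            if any(iv[0] < b.end and b.start < iv[1] for b in sites):
                continue
            sites.append(BindingSite(gene_id=gene.gene_id, contig=contig,
                                     start=iv[0], end=iv[1]))
        if attempts >= 200 and len(sites) < config.n_true_sites_per_gene:
            warnings.warn(f"{gene.gene_id}: placed only {len(sites)} sites")
        truth.true_sites[gene.gene_id] = sorted(sites, key=lambda b: b.start)

    return contigs, genes, truth


def _draw_molecules(rng, config, contigs, genes, truth):
    """Poisson-sample crosslinked molecules per sample, gene and origin."""
    rows = []
    for sample in config.barcode_map:
        for gene in genes:
            sites = truth.true_sites[gene.gene_id]
            exonic = [(s, e) for s, e in gene.exons]
            # background process over every exonic nucleotide
            for s, e in exonic:
                n_bg = rng.poisson(config.background_rate * (e - s))
                for pos in rng.integers(s, e, size=n_bg):
                    rows.append((sample, gene, int(pos), False))
            # signal process concentrated on the planted sites
            for site in sites:
                n_sig = rng.poisson(config.signal_rate * (site.end - site.start))
                for pos in rng.integers(site.start, site.end, size=n_sig):
                    rows.append((sample, gene, int(pos), True))
    return rows


def simulate_iclip_reads(config: SimConfig, contigs: dict[str, str],
                         genes: list[GeneModel], truth: GroundTruth,
                         ) -> tuple[list[Read], GroundTruth]:
    """Emit multiplexed FASTQ records for every PCR copy of every molecule.

    Read layout: 3 random-barcode nt + 4 experimental-barcode nt +
    2 random-barcode nt + genomic insert starting one nucleotide
    downstream of the crosslink + adapter, padded/truncated to
    ``read_length``.  Fills ``truth.molecule_table``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1)
    gene_by_id = {g.gene_id: g for g in genes}
    molecules = _draw_molecules(rng, config, contigs, genes, truth)

    reads: list[Read] = []
    mol_rows = []
    ilo, ihi = config.insert_length_range
    max_insert = config.read_length - 9
    for mi, (sample, gene, xl, in_site) in enumerate(molecules):
        seq = contigs[gene.contig]
        insert_len = int(rng.integers(ilo, min(ihi, max_insert) + 1))
        if gene.strand == "+":
            start = xl + 1
            insert = seq[start:start + insert_len]
        else:
            end = xl  # read covers [xl - insert_len, xl), 5' end at xl - 1
            insert = _revcomp(seq[max(0, end - insert_len):end])
        if len(insert) < 15:
            continue  # crosslink too close to a contig edge to yield a read
        rand5 = _random_seq(rng, 5)
        exp4 = config.barcode_map[sample]
        prefix = rand5[:3] + exp4 + rand5[3:]
        body = prefix + insert + config.adapter_seq
        body = body[:config.read_length]
        n_copies = 1 + int(rng.poisson(config.duplication_rate))
        mol_rows.append((f"mol{mi}", sample, gene.gene_id, gene.contig,
                         gene.strand, xl, rand5, len(insert), n_copies,
                         in_site))
        for ci in range(n_copies):
            qual = _draw_quality(rng, len(body), config.corruption_prob)
            reads.append(Read(name=f"mol{mi}_c{ci}", seq=body, qual=qual))

    order = rng.permutation(len(reads))
    reads = [reads[i] for i in order]
    truth.molecule_table = pd.DataFrame(
        mol_rows, columns=["molecule_id", "sample", "gene", "contig",
                           "strand", "crosslink_pos", "random_barcode",
                           "insert_len", "n_copies", "in_site"])
    return reads, truth


def _draw_quality(rng, n, corruption_prob):
    """Two-state quality model: solid calls at Phred 38, corrupted calls
    drawn uniformly from Phred 10-19 (low enough to trip the barcode QC)."""
    qual = np.full(n, 38, dtype=int)
    bad = rng.random(n) < corruption_prob
    qual[bad] = rng.integers(10, 20, size=int(bad.sum()))
    return tuple(int(q) for q in qual)


_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def simulate_lfq_matrix(config: SimConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a protein-groups LFQ table with spiked enrichments.

    Columns follow the MaxQuant protein-groups convention: per-replicate
    intensity columns (here already log2), peptide counts, and the three
    filter flags (contaminant, reverse, only-identified-by-site).  Low
    values are masked missing with logistically decreasing probability
    (missing-not-at-random left censoring).  Enriched proteins gain
    ``true_log2fc`` in the bait condition.
    """
    config.validate()
    c = config.lfq
    if c.n_enriched > c.n_proteins:
        raise ValueError("n_enriched exceeds n_proteins")
    rng = np.random.default_rng(config.seed + 2)
    n_extra = c.n_contaminants + c.n_reverse + c.n_only_site
    n = c.n_proteins + n_extra

    base = rng.normal(c.base_mean, c.base_sd, size=n)
    enriched = np.zeros(n, dtype=bool)
    enriched[rng.choice(c.n_proteins, size=c.n_enriched, replace=False)] = True

    cols = {}
    truth_means = {}
    for cond, shift in (("ctrl", 0.0), ("bait", c.true_log2fc)):
        mean = base + np.where(enriched, shift if cond == "bait" else 0.0, 0.0)
        truth_means[cond] = mean.copy()
        for r in range(1, c.replicates + 1):
            vals = mean + rng.normal(0, c.noise_sd, size=n)
            p_miss = 1.0 / (1.0 + np.exp((vals - c.missing_mid) / c.missing_scale))
            vals = np.where(rng.random(n) < p_miss, np.nan, vals)
            cols[f"lfq_{cond}_{r}"] = vals

    flags = {"contaminant": np.zeros(n, bool), "reverse": np.zeros(n, bool),
             "only_identified_by_site": np.zeros(n, bool)}
    i = c.n_proteins
    flags["contaminant"][i:i + c.n_contaminants] = True
    i += c.n_contaminants
    flags["reverse"][i:i + c.n_reverse] = True
    i += c.n_reverse
    flags["only_identified_by_site"][i:] = True

    peptides = rng.integers(1, 30, size=n)
    unique_pep = np.minimum(peptides, rng.integers(0, 15, size=n))
    # spiked interactors are confidently identified proteins: guarantee
    # they pass the conventional peptide-evidence filter
    peptides[enriched] = np.maximum(peptides[enriched], 2)
    unique_pep[enriched] = np.maximum(unique_pep[enriched], 1)
    table = pd.DataFrame({
        "protein_id": [f"P{i:05d}" for i in range(n)],
        **flags,
        "peptides": peptides,
        "unique_peptides": unique_pep,
        "lfq_ratio_count": rng.integers(2, 10, size=n),
        **cols,
    })
    truth = GroundTruth()
    truth.lfq_truth = pd.DataFrame({
        "protein_id": table["protein_id"],
        "enriched": enriched & ~(flags["contaminant"] | flags["reverse"]
                                 | flags["only_identified_by_site"]),
        "true_mean_ctrl": truth_means["ctrl"],
        "true_mean_bait": truth_means["bait"],
    })
    return table, truth


# ---------------------------------------------------------------------------
# serialization helpers

def write_reference(contigs: dict[str, str], genes: list[GeneModel],
                    truth: GroundTruth, outdir: str | Path) -> None:
    """Write FASTA + BED12 gene models + BED6 true sites (0-based)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "reference.fa", "w") as fh:
        for name, seq in contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")
    with open(outdir / "genes.bed", "w") as fh:
        for g in genes:
            starts = ",".join(str(s - g.exons[0][0]) for s, _ in g.exons)
            sizes = ",".join(str(e - s) for s, e in g.exons)
            span = (g.exons[0][0], g.exons[-1][1])
            fh.write("\t".join(map(str, [
                g.contig, span[0], span[1], g.gene_id, 0, g.strand,
                g.utr3[0], g.utr3[1], 0, len(g.exons), sizes, starts,
            ])) + "\n")
    with open(outdir / "true_sites.bed", "w") as fh:
        for sites in truth.true_sites.values():
            for b in sites:
                fh.write(f"{b.contig}\t{b.start}\t{b.end}\t{b.gene_id}\t0\t.\n")
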