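# xlinksob

Tools for analysing protein–RNA interaction data from iCLIP
(individual-nucleotide resolution UV crosslinking and
immunoprecipitation), together with the two companion analyses such a
study needs: label-free proteomics differential abundance for the
protein interactome, and count-based statistics for organismal
phenotypes. It is aimed at analysts who want the published processing
rules — barcode-aware read filtering, UMI deduplication,
single-nucleotide crosslink calling and signal-over-background scoring —
as a tested, reusable library rather than a collection of one-off
scripts, with a synthetic-data generator so every stage can be validated
against known ground truth without downloading anything.

## What it computes

**iCLIP pipeline.** Reads carry a 9-nt composite barcode (UMI at
positions 1–3/8–9, sample barcode at 4–7). Stages: position-specific
barcode quality filtering (drop iff >1 sample-barcode position with
Phred < 20 or any UMI position < 17), exact-match demultiplexing,
3' adapter trimming (error rate ≤ 0.1, overlap ≥ 1 nt), barcode
relocation into read names, ≥15-nt length filtering, ungapped alignment
(≤2 mismatches, unique + unspliced only), UMI deduplication on the 5'
mapping position, and crosslink extraction at the nucleotide one
position upstream (transcript orientation) of each read's 5' end.

**Signal-over-background (SOB).** For a binding site *s* in gene *g*
with crosslink track *X*:

```
bg(g)   = Σ X outside ∪(sites ± 5 nt), over g's merged exons
          (3'UTR truncated 10 nt past the last 3'UTR site, else at 500 nt)
SOB(s)  = Σ_{i ∈ s} X_i / ( bg(g) / merged exonic length )
```

computed per replicate and averaged arithmetically; undefined for
ribosomal genes and genes with bg < 10 events. Also: homopolymeric
2-mer (AA/CC/GG/TT) positional profiles in ±100-nt windows around site
midpoints.

**Interactome.** MaxQuant-style protein-group tables are filtered
(contaminant/reverse/only-by-site flags, ≥2 peptides and ≥1 unique),
log2 values imputed for missingness by Beta-distributed draws in
[0.1%, 1.5%] of the lowest measured value, presence-filtered (≥2
measured replicates in ≥1 condition), and tested with an
empirical-Bayes moderated t-statistic (variance shrinkage toward a
moment-matched prior, verified numerically identical to limma), with
BH FDR ≤ 0.05 and log2FC ≥ 2 defining enrichment.

**Phenotype counts.** Exact percentages from event/total pairs
(half-up rounding), hatching tables, and one-sample t-tests for RIP
fold enrichments.

## Worked example

```python
import xlinksob as x

config = x.SimConfig(seed=1, n_genes=3, corruption_prob=0.0)
contigs, genes, truth = x.generate_reference(config)
reads, truth = x.simulate_iclip_reads(config, contigs, genes, truth)
per_sample, stats = x.run_preprocess(
    reads, x.SampleSheet(config.barcode_map), config.adapter_seq)

segs = x.filter_alignments(x.align_naive(per_sample["Mkrn1_rep1"], contigs))
molecules = x.deduplicate(segs)
track = x.extract_crosslinks(molecules)
print(len(per_sample["Mkrn1_rep1"]), len(molecules), track.total())

records = []
for gene in genes:
    records.extend(x.compute_sob(track, gene, truth.true_sites[gene.gene_id]))
print(round(records[0].replicate_values[0], 1))
```

prints

```
657 332 332
141.1
```

657 reads for this library collapse to 332 unique molecules (PCR
duplicates share UMI and 5' position), each contributing one crosslink
event; the first planted binding site scores SOB ≈ 141, i.e. its
crosslink count is ~140-fold the gene's per-nucleotide background —
consistent with the simulated tenfold per-nucleotide enrichment
concentrated on a 9-nt site. The same stages are available from the
shell via `xlinksob simulate|preprocess|align|dedup|crosslinks|sob|
dimers|interactome|counts`.

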