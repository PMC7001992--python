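# Methods

This note documents the models and procedures implemented in `xlinksob`,
the assumptions behind them, and the numerical and design choices that
were genuinely open.

## iCLIP read model and preprocessing

iCLIP libraries place a 9-nt composite barcode at the start of each
75-nt single-end read: the 5-nt random barcode (UMI) occupies read
positions 1–3 and 8–9 (1-based) and the 4-nt experimental (sample)
barcode occupies positions 4–7. Preprocessing applies, in order:

1. **Barcode-region quality filter.** A read is dropped iff more than
   one experimental-barcode position has Phred < 20, or any
   random-barcode position has Phred < 17. Reads shorter than the 9-nt
   prefix are dropped with reason `short_prefix`.
2. **Demultiplexing.** Exact match of positions 4–7 against the sample
   sheet; zero mismatches tolerated, so an `N` or miscalled base leaves
   a read unassigned. (One low-quality experimental-barcode base may
   survive the quality filter yet fail assignment; this interplay is
   inherent to the scheme and left as-is.)
3. **3' adapter trimming.** The longest read suffix matching an adapter
   prefix with mismatch fraction ≤ 0.1 and overlap ≥ 1 nt is removed.
   The search is 3'-end anchored: CLIP inserts read *into* the adapter,
   so internal occurrences are not searched.
4. **Barcode relocation.** The 9-nt prefix is stripped and both barcodes
   appended to the read name (`name_EXP_RAND`); the random barcode is
   reconstructed in positional order (1–3 then 8–9).
5. **Length filter.** Inserts shorter than 15 nt are removed; "shorter
   than" is read strictly, so 15-nt inserts are kept. The rule is
   applied to the barcode-free insert, since mapping operates on
   inserts.

## Alignment and UMI deduplication

The built-in aligner is an ungapped both-strand scanner intended for the
synthetic references: hits with ≤ 2 mismatches are collected and a read
is unique iff exactly one hit attains the best mismatch count. It never
soft-clips and does not handle indels or splicing (spliced reads are
discarded downstream in any case). External SAM/BAM can be ingested
instead; a record is spliced iff its CIGAR contains a skipped-region
(`N`) operator, and uniqueness evidence is an `NH`-style tag or a MAPQ
threshold, configurable. Only unique, unspliced alignments proceed.

Duplicates are reads whose 5' ends map to the same genomic position.
Within a (contig, strand, 5'-position, random-barcode) class exactly one
read is kept — the lexicographically smallest name, which makes the
output independent of input order; classes differing in barcode at the
same position are biological duplicates and all survive. Strand is part
of the key: opposite-strand reads sharing a coordinate are independent
molecules. For minus-strand reads the 5' end is the highest aligned
coordinate.

## Crosslink-event extraction

Reverse transcription truncates at the crosslinked nucleotide, so the
crosslink is the position one nucleotide upstream, in transcript
orientation, of the read's 5' mapping position: `start − 1` for plus
reads, `end` for minus reads (0-based half-open everywhere). This
convention is the single easiest place to introduce a silent one-off
shift, hence it is centralised in `tracks.extract_crosslinks` and pinned
by tests that recover simulated crosslink positions exactly. Events
falling outside contig bounds are dropped and counted. Bedgraph output
merges runs of equal counts and uses the format's native 0-based
half-open intervals.

## Signal-over-background (SOB)

SOB corrects a binding site's crosslink count for transcript abundance.
Per gene and replicate:

- background events = crosslink events in the gene's effective exonic
  extent, excluding every site ± 5 nt;
- background rate = background events / merged effective exonic length
  (events per nt);
- SOB(site) = events within the site / background rate.

The effective extent truncates the annotated 3'UTR at 10 nt past the
3'-most binding site in the 3'UTR, or at 500 nt from the 3'UTR start
when no site falls there, so unbound 3'UTR tail does not dilute the
background. Truncation never extends the annotation. No SOB is assigned
for ribosomal genes or genes with fewer than 10 background events; the
threshold is applied per replicate, and a site's mean is the arithmetic
mean over the replicates where its value is defined.

Numerical notes: SOB as defined is a count over a density and carries
units of nucleotides; a width-normalised variant (site count divided by
site width first) is available via `normalize_by_width=True`. The ± 5 nt
flank is excluded from the background *numerator* only — the denominator
stays the merged exonic length. SOB is invariant under uniform rescaling
of all counts. Both properties are pinned by a per-nucleotide
enumeration oracle in the tests.

## Dimer profiles and the plumbing peak caller

For sequence context around binding sites, sites are centred at their
midpoint (lower median for even widths) and a ±100-nt window extended;
for each offset the profile reports the mean indicator that the 2-mer
starting there on the gene's sense strand is AA, CC, GG or TT. Windows
clipped at contig ends are dropped with a warning. Tests extend the
alphabet to all 16 dimers as a sanity check (positional means sum to 1).

`call_sites` is deliberately minimal plumbing (maximal runs of positions
with count ≥ `min_count`, merged across gaps ≤ `merge_gap`): binding
sites are normally supplied as BED.

## Proteomics differential abundance

On a MaxQuant-style protein-groups table (log2 abundances):

1. remove contaminant, reverse and only-identified-by-site groups, and
   groups with < 2 peptides or < 1 unique peptide. The conventional AND
   requirement is the default; a literal "fails both" variant is
   available (`literal_peptide_rule=True`) because the prose rule is
   ambiguous as printed.
2. impute missing values as `m · u`, `u ~ Beta(1,1)` rescaled to
   [0.001, 0.015], with `m` the lowest measured log value (global by
   default, per-column optionally). The Beta shape is not prescribed by
   the procedure, only the interval; Beta(1,1) (uniform) is the default.
   This is an aggressive left-censoring model: imputed log2 values land
   near zero, far below the measured dynamic range, so a group measured
   in one condition and absent in the other gets a very large fold
   change — which is exactly how presence/absence interactors are
   surfaced by this scheme.
3. keep groups with ≥ 2 *originally measured* values in ≥ 1 condition;
   the measured-mask is taken before imputation so imputation cannot
   defeat the filter.
4. moderated t-test: per-group pooled variances s² (df = n₁+n₂−2) are
   shrunk toward a prior, `s²_post = (d₀s₀² + df·s²)/(d₀+df)`, with
   (d₀, s₀²) estimated by moment matching on log s²: with
   `e = log s² − ψ(df/2) + log(df/2)`, the mean of e gives s₀² and the
   excess variance of e over ψ′(df/2) gives d₀ through a Newton
   inversion of the trigamma function; d₀ = ∞ when there is no excess
   spread. The moderated t is `Δmean/(s_post·√(1/n₁+1/n₂))` on
   `d₀ + df` degrees of freedom, capped at the pooled residual df.
   These estimator details are numerically identical to the reference
   empirical-Bayes implementation (verified against limma in the test
   suite). Two-sided p-values are BH-adjusted across groups.
5. significance: FDR ≤ 0.05 and log2 fold change ≥ 2 (bait over
   control).

## Phenotype counts

Percentages are computed from raw event/total pairs and rounded half-up
to the printed precision (half-up because banker's rounding disagrees
with how such tables are typically printed at ties). Zero-total rows are
reported as 0.0% with an explicit flag rather than an error. RIP fold
enrichments are tested with a one-sample t against a null mean of 1;
zero-variance samples are undefined (flagged), except the all-values-
equal-the-null case which is reported as t = 0, p = 1. Per-transcript
"multiple t-tests" apply no correction unless requested.

## Synthetic-data generator

The generator provides ground-truthed inputs for every stage:

- **Reference/annotation**: one gene per contig (alternating strand),
  1–3 exons of 300–800 nt, a 400-nt 3'UTR at the transcript 3' end of
  the terminal exon, and 2 planted non-overlapping 9-nt binding sites
  per gene, preferentially in the 3'UTR.
- **Reads**: molecules arise from a background Poisson process over
  exonic nucleotides (0.1 events/nt per library) plus a signal process
  over site nucleotides (1.0 events/nt — tenfold enrichment); each
  molecule gets a uniform crosslink position within its origin, a
  random 5-nt UMI, an insert of 25–60 nt starting one nucleotide
  downstream of the crosslink (truncation-only model; no readthrough or
  deletion events), and 1 + Poisson(1) PCR copies that share sequence
  and UMI. Reads are 9-nt prefix + insert + adapter, cut to 75 nt.
  Qualities follow a two-state model (solid calls at Phred 38, corrupted
  calls uniform on Phred 10–19 with per-base probability 0.02), chosen
  as the simplest model able to trip both barcode-QC rules. Seven
  libraries are multiplexed (six bait replicates, one control),
  mirroring the typical experimental design.
- **LFQ matrix**: 500 protein groups plus flagged contaminant/reverse/
  only-by-site rows; log2 abundances N(27, 1.5) with replicate noise
  sd 0.4, 3 replicates × 2 conditions; 25 spiked enriched proteins at
  +3 log2 units in the bait condition. Missingness is
  missing-not-at-random: logistic in log2 abundance with midpoint 23.5
  and scale 0.4. The sharp curve models a protein-level detection limit
  and keeps dropout mostly all-or-none within a replicate group — the
  regime the near-zero imputation scheme handles well; shallower curves
  produce many single-missing-replicate rows whose imputed values
  inflate the within-group variance and mask genuine enrichments.
  Spiked proteins always carry ≥ 2 peptides and ≥ 1 unique peptide,
  emulating confidently identified spike-ins.

What the generator does **not** emulate: sequencing substitution errors
(reads are base-perfect; only qualities are corrupted), spliced reads,
chimeric or multimapping artifacts beyond exact repeats, UMI saturation
at very deep coverage, intensity-dependent variance or batch effects in
the LFQ matrix. Passing tests therefore demonstrate the correctness of
the computational procedures under their stated models, not robustness
to every artifact of real libraries.

All randomness flows from `numpy.random.default_rng` seeded from the
config (one stream per generator stage), so a fixed config reproduces
byte-identical outputs.

## Problem sizes

The test suite and the acceptance script run desk-scale instances:
3–6 genes (≈5–10 kb of genome, ~10⁴ reads) for pipeline recovery,
40 genes for SOB ranking, 500-protein matrices for the proteomics
recovery, and 200-row × 25-repetition null simulations for t-test
calibration. These sizes give stable statistics while keeping the whole
suite in the tens of seconds.

## Known limitations

- The naive aligner is exact-scan based and intended for references of
  at most a few hundred kilobases; real data should be aligned
  externally and ingested as SAM/BAM.
- Genome-scale catalogues (full binding-site lists, interactor tables)
  depend on external data and genome builds and are out of scope; the
  package reproduces the *procedures*, validated on synthetic ground
  truth and printed count tables.
- The SOB definition leaves open whether site signal is width-
  normalised; both variants are implemented, defaulting to the
  count-over-density reading.
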