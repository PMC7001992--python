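"""SOB statistic, 3'UTR truncation, dimer profiles and the peak caller."""

import numpy as np
import pytest

from xlinksob.metrics import (ALL_DIMERS, BindingSite, GeneModel,
                              average_sob, call_sites, compute_sob,
                              dimer_profile, effective_gene_extent,
                              merge_intervals, read_sites_bed,
                              write_sites_bed)
from xlinksob.tracks import CrosslinkTrack


def _gene(exons, utr3, strand="+", gene_id="g", ribosomal=False):
    return GeneModel(gene_id=gene_id, contig="c", strand=strand,
                     exons=exons, utr3=utr3, ribosomal=ribosomal)


def _site(start, end, gene_id="g"):
    return BindingSite(gene_id=gene_id, contig="c", start=start, end=end)


def _track(events):
    track = CrosslinkTrack()
    for pos, n in events.items():
        for _ in range(n):
            track.add("c", "+", pos)
    return track


class TestEffectiveExtent:
    def test_utr_clipped_10nt_past_last_site(self):
        # 800-nt 3'UTR starting at 1000; last site ends 300 nt in
        gene = _gene([(0, 1800)], (1000, 1800))
        sites = [_site(1100, 1300)]
        _, length = effective_gene_extent(gene, sites)
        assert length == 1000 + 310

    def test_utr_without_sites_clipped_at_500(self):
        gene = _gene([(0, 1800)], (1000, 1800))
        _, length = effective_gene_extent(gene, [])
        assert length == 1000 + 500

    def test_short_utr_never_extended(self):
        gene = _gene([(0, 1200)], (1000, 1200))
        _, length = effective_gene_extent(gene, [])
        assert length == 1200

    def test_minus_strand_clips_left_edge(self):
        # minus-strand gene: transcript 3' end is the lowest coordinate
        gene = _gene([(0, 1800)], (0, 800), strand="-")
        sites = [_site(500, 700)]   # 3'-most site starts at 500
        intervals, length = effective_gene_extent(gene, sites)
        assert length == 1800 - 490
        assert intervals[0][0] == 490

    def test_non_utr_sites_do_not_affect_clipping(self):
        gene = _gene([(0, 1800)], (1000, 1800))
        _, length = effective_gene_extent(gene, [_site(100, 120)])
        assert length == 1000 + 500


def _oracle_sob(track, gene, sites, flank=5, min_bg=10):
    """Per-nucleotide enumeration of the SOB definition."""
    if gene.ribosomal:
        return [None] * len(sites)
    extent, length = effective_gene_extent(gene, sites)
    exonic = [p for s, e in extent for p in range(s, e)]
    masked = set()
    for b in sites:
        masked.update(range(b.start - flank, b.end + flank))
    bg = sum(track.get(gene.contig, gene.strand, p)
             for p in exonic if p not in masked)
    if bg < min_bg:
        return [None] * len(sites)
    rate = bg / length
    return [sum(track.get(gene.contig, gene.strand, p)
                for p in range(b.start, b.end)) / rate for b in sites]


class TestComputeSOB:
    def test_hand_computed_example(self):
        # 30 events in the site, 20 background events over 2000 exonic nt
        # (site placed outside the 3'UTR so no truncation interferes)
        gene = _gene([(0, 2000)], (1990, 2000))
        site = _site(500, 510)
        events = {505: 30}
        bg_positions = list(range(0, 400, 20))  # 20 events, one per position
        for p in bg_positions:
            events[p] = 1
        # effective length: UTR contributes min(10, 500) -> full 2000
        records = compute_sob(_track(events), gene, [site])
        assert records[0].replicate_values[0] == pytest.approx(
            30 / (20 / 2000))

    def test_low_background_excluded(self):
        gene = _gene([(0, 2000)], (1990, 2000))
        events = {505: 30, **{p: 1 for p in range(0, 180, 20)}}  # 9 bg events
        records = compute_sob(_track(events), gene, [_site(500, 510)])
        assert records[0].excluded_reason == "low_background"
        assert records[0].replicate_values == [None]

    def test_ribosomal_excluded(self):
        gene = _gene([(0, 2000)], (1990, 2000), ribosomal=True)
        records = compute_sob(_track({505: 30}), gene, [_site(500, 510)])
        assert records[0].excluded_reason == "ribosomal"

    def test_flank_events_excluded_from_background_only(self):
        gene = _gene([(0, 2000)], (1990, 2000))
        events = {499: 100, **{p: 1 for p in range(0, 400, 20)}}
        # event at 499 is inside site-5 flank: not background, not signal
        records = compute_sob(_track(events), gene, [_site(500, 510)])
        assert records[0].replicate_values[0] == 0.0

    def test_zero_length_raises(self):
        gene = _gene([(0, 500)], (0, 500))
        gene.exons = []
        with pytest.raises(ValueError):
            compute_sob(_track({}), gene, [])

    def test_scale_invariance(self):
        gene = _gene([(0, 2000)], (1500, 2000))
        sites = [_site(600, 609), _site(1600, 1609)]
        events = {605: 12, 1603: 7, **{p: 1 for p in range(0, 700, 23)}}
        base = compute_sob(_track(events), gene, sites)
        scaled = compute_sob(_track({p: 3 * n for p, n in events.items()}),
                             gene, sites)
        for a, b in zip(base, scaled):
            assert b.replicate_values[0] == pytest.approx(
                a.replicate_values[0])

    def test_matches_bruteforce_oracle_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            n_exons = int(rng.integers(1, 4))
            exons, pos = [], 0
            for _ in range(n_exons):
                pos += int(rng.integers(10, 50))
                L = int(rng.integers(150, 400))
                exons.append((pos, pos + L))
                pos += L
            utr_len = int(rng.integers(50, 300))
            utr3 = (exons[-1][1] - min(utr_len, exons[-1][1] - exons[-1][0]),
                    exons[-1][1])
            gene = _gene(exons, utr3)
            sites = []
            for s, e in exons[:2]:
                if e - s > 40:
                    start = int(rng.integers(s, e - 12))
                    sites.append(_site(start, start + 9))
            events = {}
            for s, e in exons:
                for p in rng.integers(s, e, size=int(rng.integers(5, 60))):
                    events[int(p)] = events.get(int(p), 0) + 1
            got = compute_sob(_track(events), gene, sites)
            want = _oracle_sob(_track(events), gene, sites)
            for rec, expect in zip(got, want):
                if expect is None:
                    assert rec.replicate_values == [None]
                else:
                    assert rec.replicate_values[0] == pytest.approx(expect)

    def test_width_normalized_variant(self):
        gene = _gene([(0, 2000)], (1990, 2000))
        events = {505: 30, **{p: 1 for p in range(0, 400, 20)}}
        plain = compute_sob(_track(events), gene, [_site(500, 510)])
        dens = compute_sob(_track(events), gene, [_site(500, 510)],
                           normalize_by_width=True)
        assert dens[0].replicate_values[0] == pytest.approx(
            plain[0].replicate_values[0] / 10)


class TestAverageSOB:
    def _records(self, values):
        from xlinksob.metrics import SOBRecord
        return [SOBRecord(site=_site(0, 9), replicate_values=[v],
                          excluded_reason=None if v is not None
                          else "low_background") for v in values]

    def test_arithmetic_mean(self):
        avg = average_sob([self._records([2.0]), self._records([4.0])])
        assert avg[0].mean == pytest.approx(3.0)

    def test_mean_over_defined_replicates_only(self):
        avg = average_sob([self._records([5.0]), self._records([None])])
        assert avg[0].mean == pytest.approx(5.0)

    def test_all_excluded_stays_excluded(self):
        avg = average_sob([self._records([None]), self._records([None])])
        assert avg[0].mean is None
        assert avg[0].excluded_reason == "low_background"


class TestDimerProfile:
    def test_polyA_window(self):
        contigs = {"c": "A" * 400}
        genes = {"g": _gene([(0, 400)], (300, 400))}
        prof = dimer_profile([_site(190, 200)], genes, contigs)
        assert (prof["AA"] == 1.0).all()
        assert (prof[["CC", "GG", "TT"]] == 0.0).all().all()

    def test_single_site_entries_binary(self):
        rng = np.random.default_rng(0)
        contigs = {"c": "".join(rng.choice(list("ACGT"), size=500))}
        genes = {"g": _gene([(0, 500)], (400, 500))}
        prof = dimer_profile([_site(240, 250)], genes, contigs)
        assert set(np.unique(prof.to_numpy())) <= {0.0, 1.0}

    def test_full_alphabet_sums_to_one(self):
        rng = np.random.default_rng(1)
        contigs = {"c": "".join(rng.choice(list("ACGT"), size=600))}
        genes = {"g": _gene([(0, 600)], (500, 600))}
        sites = [_site(s, s + 10) for s in (150, 250, 350)]
        prof = dimer_profile(sites, genes, contigs, dimers=ALL_DIMERS)
        assert np.allclose(prof.sum(axis=1), 1.0)

    def test_minus_strand_reads_sense(self):
        # genomic polyT is sense polyA for a minus-strand gene
        contigs = {"c": "T" * 400}
        genes = {"g": _gene([(0, 400)], (0, 100), strand="-")}
        prof = dimer_profile([_site(190, 200)], genes, contigs)
        assert (prof["AA"] == 1.0).all()

    def test_clipped_windows_dropped_with_warning(self):
        contigs = {"c": "A" * 150}
        genes = {"g": _gene([(0, 150)], (100, 150))}
        with pytest.warns(UserWarning):
            prof = dimer_profile([_site(10, 20)], genes, contigs)
        assert prof.isna().all().all() or prof.empty

    def test_midpoint_is_lower_median(self):
        assert _site(10, 20).midpoint == 14
        assert _site(10, 19).midpoint == 14


class TestCallSites:
    def test_runs_and_gap_merging(self):
        track = _track({10: 5, 11: 5, 20: 5})
        sites = call_sites(track, min_count=3, merge_gap=2)
        assert [(s.start, s.end) for s in sites] == [(10, 12), (20, 21)]

    def test_threshold_above_max_no_sites(self):
        assert call_sites(_track({10: 5}), min_count=6) == []

    def test_zero_gap_splits_runs(self):
        track = _track({10: 5, 12: 5})
        sites = call_sites(track, min_count=3, merge_gap=0)
        assert [(s.start, s.end) for s in sites] == [(10, 11), (12, 13)]

    def test_gap_merging_bridges_small_gaps(self):
        track = _track({10: 5, 12: 5})
        sites = call_sites(track, min_count=3, merge_gap=1)
        assert [(s.start, s.end) for s in sites] == [(10, 13)]


class TestBedRoundtrip:
    def test_sites_roundtrip(self, tmp_path):
        sites = [_site(5, 14, "gA"), _site(100, 109, "gB")]
        path = tmp_path / "sites.bed"
        write_sites_bed(sites, path)
        assert read_sites_bed(path) == sites


def test_merge_intervals():
    assert merge_intervals([(5, 10), (0, 6), (20, 30)]) == [(0, 10), (20, 30)]
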