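import random

import pytest

from asmgaps import end_alignments, group_by_contig, overextended_contigs, report_gaps, simple_ends
from asmgaps.contig_ends import UsageError, _piece_span, _split_chunks
from conftest import make_record


class TestSimpleEnds:
    def test_single_alignment_serves_both_sides(self, t):
        rec = make_record(contig_len=150_000, qs=0, qe=30_000, ts=100_000)
        ends, skipped = simple_ends(group_by_contig([rec]), t)
        assert not skipped
        assert sorted(e.position for e in ends) == [100_000, 130_000]
        assert {e.side for e in ends} == {"left", "right"}

    def test_25kbp_floor_skips_short_terminal_alignments(self, t):
        recs = [
            make_record(qs=0, qe=10_000, ts=50_000),           # 10 kbp: below floor
            make_record(qs=15_000, qe=55_000, ts=70_000),      # 40 kbp: qualifies
            make_record(qs=60_000, qe=100_000, ts=130_000),    # 40 kbp: qualifies
            make_record(qs=105_000, qe=115_000, ts=180_000),   # 10 kbp: below floor
        ]
        ends, _ = simple_ends(group_by_contig(recs), t)
        assert sorted(e.position for e in ends) == [70_000, 170_000]

    def test_contig_without_qualifying_alignment_is_skipped(self, t):
        rec = make_record(contig_len=120_000, qs=0, qe=10_000, ts=0)
        ends, skipped = simple_ends(group_by_contig([rec]), t)
        assert ends == [] and skipped == [("s1", "h1", "ctg1")]

    def test_matches_exhaustive_per_side_scan(self, t):
        rng = random.Random(42)
        recs = []
        for i in range(20):
            q = 0
            for _ in range(rng.randrange(1, 6)):
                span = rng.randrange(5_000, 60_000)
                ts = rng.randrange(0, 50_000_000)
                recs.append(
                    make_record(contig=f"c{i}", contig_len=500_000, qs=q, qe=q + span, ts=ts)
                )
                q += span + rng.randrange(0, 5_000)
        aset = group_by_contig(recs)
        ends, skipped = simple_ends(aset, t)
        by_contig = {}
        for e in ends:
            by_contig.setdefault(e.contig, []).append(e.position)
        for key, group in aset:
            ok = [r for r in group if r.target_span >= t.min_simple_end_aln]
            if not ok:
                assert key in skipped
                continue
            first = next(r for r in group if r.target_span >= t.min_simple_end_aln)
            last = next(r for r in reversed(group) if r.target_span >= t.min_simple_end_aln)
            expected = sorted([first.target_start, last.target_end])
            assert sorted(by_contig[key[2]]) == expected


class TestEndAlignments:
    def _contig(self, right_ts):
        return [
            make_record(contig_len=1_000_000, qs=0, qe=60_000, ts=10_000_000),
            make_record(contig_len=1_000_000, qs=940_000, qe=1_000_000, ts=right_ts),
        ]

    def test_span_within_five_percent_is_one_piece(self, t):
        pieces = end_alignments(group_by_contig(self._contig(10_940_000)), t)
        assert len(pieces) == 1 and pieces[0].span == 1_000_000

    def test_overextended_contig_splits_at_largest_jump(self, t):
        pieces = end_alignments(group_by_contig(self._contig(11_060_000)), t)
        assert len(pieces) == 2
        assert [(p.ref_start, p.ref_end) for p in pieces] == [
            (10_000_000, 10_060_000),
            (11_060_000, 11_120_000),
        ]

    def test_cross_chromosome_contigs_split_at_chromosome_boundary(self, t):
        recs = [
            make_record(contig_len=200_000, qs=0, qe=100_000, ts=1_000_000, chrom="chr1"),
            make_record(contig_len=200_000, qs=100_000, qe=200_000, ts=5_000_000, chrom="chr2"),
        ]
        pieces = end_alignments(group_by_contig(recs), t)
        assert sorted(p.chrom for p in pieces) == ["chr1", "chr2"]

    def test_split_matches_exhaustive_partition_search(self, t):
        """Greedy largest-jump splitting must be minimal and feasible; the
        oracle enumerates every split subset on contigs with <=8 alignments."""
        import itertools

        rng = random.Random(11)
        for case in range(80):
            n = rng.randrange(2, 9)
            spans = [rng.randrange(50_000, 80_000) for _ in range(n)]
            contig_len = sum(spans)
            q, recs = 0, []
            for span in spans:
                ts = rng.randrange(0, 3_000_000)
                recs.append(
                    make_record(contig=f"c{case}", contig_len=contig_len, qs=q, qe=q + span, ts=ts)
                )
                q += span
            max_span = contig_len * 1.05 + 1e-6
            recs_sorted = sorted(recs, key=lambda r: r.query_start)
            chunks = _split_chunks(recs_sorted, max_span)
            # oracle: brute-force minimal feasible partition
            best = None
            for k in range(0, n):
                for cuts in itertools.combinations(range(n - 1), k):
                    prev, ok = 0, True
                    for c in list(sorted(cuts)) + [n - 1]:
                        part = recs_sorted[prev : c + 1]
                        if _piece_span(part) > max_span:
                            ok = False
                            break
                        prev = c + 1
                    if ok:
                        best = k + 1
                        break
                if best is not None:
                    break
            if best is None:
                best = n  # only singleton pieces remain
            assert len(chunks) == best
            if best < n or all(_piece_span([r]) <= max_span for r in recs_sorted):
                assert all(_piece_span(c) <= max_span for c in chunks)


class TestReportGaps:
    def _piece_set(self, t, placements):
        recs = []
        for i, (ts, te) in enumerate(placements):
            recs.append(
                make_record(contig=f"c{i}", contig_len=max(te - ts, 100_000), qs=0, qe=te - ts, ts=ts)
            )
        return end_alignments(group_by_contig(recs), t)

    def test_gap_between_subsequent_pieces(self, t):
        pieces = self._piece_set(t, [(4_900_000, 5_000_000), (5_200_000, 5_300_000)])
        (gap,) = report_gaps(pieces)
        assert (gap.chrom, gap.start, gap.end) == ("chr1", 5_000_000, 5_200_000)

    def test_overlapping_pieces_emit_nothing(self, t):
        pieces = self._piece_set(t, [(4_800_000, 5_000_000), (4_900_000, 5_100_000)])
        assert report_gaps(pieces) == []

    def test_abutting_pieces_emit_nothing(self, t):
        pieces = self._piece_set(t, [(4_900_000, 5_000_000), (5_000_000, 5_100_000)])
        assert report_gaps(pieces) == []

    def test_mixed_haplotypes_rejected(self, t):
        recs = [make_record(hap="h1"), make_record(contig="c2", hap="h2", ts=5_000_000)]
        with pytest.raises(UsageError):
            report_gaps(end_alignments(group_by_contig(recs), t))

    def test_planted_gaps_recovered_exactly(self, t, demo, demo_aset):
        _, plan, _ = demo
        pieces = end_alignments(demo_aset, t)
        found = []
        for s, h in demo_aset.haplotypes():
            mine = [p for p in pieces if (p.sample, p.haplotype) == (s, h)]
            found.extend(report_gaps(mine))
        truth = sorted((e.haplotype, e.start, e.end) for e in plan.events if e.kind == "gap")
        assert sorted((g.haplotype, g.start, g.end) for g in found) == truth


class TestOverextended:
    def test_ratio_reported(self, t):
        recs = [
            make_record(contig_len=1_000_000, qs=0, qe=60_000, ts=10_000_000),
            make_record(contig_len=1_000_000, qs=940_000, qe=1_000_000, ts=11_060_000),
        ]
        df = overextended_contigs(group_by_contig(recs), t)
        assert len(df) == 1 and df.iloc[0].ratio == pytest.approx(1.12)

    def test_exactly_five_percent_not_listed(self, t):
        recs = [
            make_record(contig_len=1_000_000, qs=0, qe=60_000, ts=10_000_000),
            make_record(contig_len=1_000_000, qs=940_000, qe=1_000_000, ts=10_990_000),
        ]
        assert overextended_contigs(group_by_contig(recs), t).empty

    def test_end_coverage_conservation_on_demo(self, t, demo_aset):
        """Per haplotype, the union of piece spans plus the gap lengths
        tiles the region between the outermost ends exactly (piece
        overlaps — embedded contigs — counted once)."""
        from asmgaps._intervals import merge

        pieces = end_alignments(demo_aset, t)
        for s, h in demo_aset.haplotypes():
            mine = [p for p in pieces if (p.sample, p.haplotype) == (s, h) and p.has_ends]
            gaps = report_gaps(mine)
            union = sum(e - st for st, e in merge([(p.ref_start, p.ref_end) for p in mine]))
            gap_sum = sum(g.length for g in gaps)
            lo = min(p.ref_start for p in mine)
            hi = max(p.ref_end for p in mine)
            assert union + gap_sum == hi - lo
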