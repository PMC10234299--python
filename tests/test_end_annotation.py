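import numpy as np
import pytest
from scipy import stats

from asmgaps.alignment_io import BedInterval
from asmgaps.contig_ends import ContigEnd, GapRegion
from asmgaps.end_annotation import (
    AnnotationConfigError,
    AnnotationTrack,
    annotate_ends,
    category_counts,
    gene_overlap,
    permutation_enrichment,
    poisson_ends,
    recurrent_gap_regions,
)


def end(pos, chrom="chr1", contig="c", sample="s1", hap="h1", side="left"):
    return ContigEnd(sample, hap, contig, side, chrom, pos, 30_000, "simple")


def track(name, intervals, priority, chrom="chr1"):
    return AnnotationTrack(name, [BedInterval(chrom, s, e) for s, e in intervals], priority)


CHROMS = {"chr1": 1_000_000}


class TestAnnotateEnds:
    def test_chromosome_end_beats_sd(self, t):
        tracks = [track("SD", [(40_000, 60_000)], 2)]
        (a,) = annotate_ends([end(50_000)], tracks, CHROMS, t)
        assert a.label == "chromosome_end"

    def test_proximity_assignment(self, t):
        tracks = [track("SD", [(495_000, 498_000)], 2)]
        (a,) = annotate_ends([end(500_000)], tracks, CHROMS, t)
        assert a.label == "SD" and a.distance == 2_001  # 500,000 vs last base 497,999

    def test_composite_sd_gatc_label(self, t):
        tracks = [track("SD", [(495_000, 498_000)], 2), track("GA/TC", [(499_000, 501_000)], 4)]
        (a,) = annotate_ends([end(500_000)], tracks, CHROMS, t)
        assert a.label == "SD+GA/TC" and a.distance == 0

    def test_equal_priorities_rejected(self, t):
        tracks = [track("SD", [(0, 10)], 2), track("SAT", [(20, 30)], 2)]
        with pytest.raises(AnnotationConfigError):
            annotate_ends([end(500_000)], tracks, CHROMS, t)

    def test_labels_match_bruteforce_and_counts_sum(self, t):
        rng = np.random.default_rng(3)
        tracks = [
            track("SD", [(s, s + 5_000) for s in rng.integers(120_000, 880_000, 8)], 2),
            track("SAT", [(s, s + 3_000) for s in rng.integers(120_000, 880_000, 5)], 3),
            track("GA/TC", [(s, s + 1_000) for s in rng.integers(120_000, 880_000, 6)], 4),
            track("AT", [(s, s + 1_000) for s in rng.integers(120_000, 880_000, 4)], 5),
        ]
        ends = [
            end(int(p), contig=f"c{i}", hap="h1" if i % 2 else "h2")
            for i, p in enumerate(rng.integers(0, 1_000_000, 200))
        ]
        annotated = annotate_ends(ends, tracks, CHROMS, t)
        poisson = set(poisson_ends(ends, t=t))
        for a in annotated:
            e = a.end
            terminus = min(e.position, 1_000_000 - e.position)
            if terminus <= t.chrom_end_window:
                assert a.label == "chromosome_end"
                continue
            near = {}
            for trk in tracks:
                d = min(
                    (abs(e.position - s) if e.position < s else (0 if e.position < en else e.position - en + 1))
                    for s, en in [(iv.start, iv.end) for iv in trk.intervals]
                )
                if d <= t.proximity:
                    near[trk.name] = d
            if "SD" in near and "GA/TC" in near:
                assert a.label == "SD+GA/TC"
            elif near:
                expected = min(near, key=lambda n: [trk.priority for trk in tracks if trk.name == n][0])
                best = sorted(near, key=lambda n: next(trk.priority for trk in tracks if trk.name == n))[0]
                assert a.label == best
            elif e in poisson:
                assert a.label == "poisson_end"
            else:
                assert a.label == "other"
        counts = category_counts(annotated)
        assert counts["count"].sum() == len(ends)  # nonredundant accounting


class TestPoissonEnds:
    def test_single_haplotype_all_poisson(self, t):
        ends = [end(200_000 + 50_000 * i) for i in range(4)]
        assert len(poisson_ends(ends, t=t)) == 4

    def test_coincident_ends_across_haplotypes_not_poisson(self, t):
        pair = [end(300_000, hap="h1"), end(302_000, hap="h2")]
        assert poisson_ends(pair, t=t) == []

    def test_private_vs_shared_breaks(self, t):
        ends = []
        for h in range(6):
            ends.append(end(200_000 + 40_000 * h, hap=f"h{h}", contig=f"p{h}"))  # private
        for h in range(6):
            ends.append(end(700_000, hap=f"h{h}", contig=f"s{h}"))  # shared
        assert len(poisson_ends(ends, t=t)) == 6


class TestEnrichment:
    def test_saturating_track_gives_fold_one(self, t):
        trk = track("ALL", [(0, 1_000_000)], 1)
        ends = [end(int(p)) for p in np.linspace(10_000, 990_000, 20)]
        r = permutation_enrichment(ends, trk, CHROMS, t, seed=1, n_permutations=200)
        assert r.observed == 20 and r.random_median == 20 and r.fold == 1.0 and r.pvalue == 1.0

    def test_depletion_direction(self, t):
        trk = track("FAR", [(900_000, 950_000)], 1)
        ends = [end(int(p)) for p in np.linspace(150_000, 400_000, 30)]
        r = permutation_enrichment(ends, trk, CHROMS, t, seed=2, n_permutations=1_000)
        assert r.observed == 0 and r.fold <= 1.0

    def test_planted_enrichment_matches_binomial_expectation(self, t):
        """100 ends inside a 100-kbp track on a 1-Mbp reference: the padded
        track covers 120 kbp, so random counts are Binomial(100, 0.12) with
        median 12 and the expected fold is ~8.33."""
        trk = track("SD", [(400_000, 500_000)], 1)
        ends = [end(int(p), contig=f"c{i}") for i, p in enumerate(np.linspace(401_000, 499_000, 100))]
        r = permutation_enrichment(ends, trk, CHROMS, t, seed=3, n_permutations=10_000)
        assert r.observed == 100
        expected_fold = 100 / (100 * 0.12)
        # 3 Monte-Carlo standard errors of the median, delta-method on fold
        se_median = 1.2533 * np.sqrt(100 * 0.12 * 0.88) / np.sqrt(10_000)
        se_fold = expected_fold / 12 * se_median * 3 + 0.5  # half-count median discreteness
        assert abs(r.fold - expected_fold) <= se_fold

    def test_seed_reproducibility(self, t):
        trk = track("SD", [(100_000, 200_000)], 1)
        ends = [end(int(p)) for p in np.linspace(150_000, 800_000, 40)]
        a = permutation_enrichment(ends, trk, CHROMS, t, seed=9, n_permutations=500)
        b = permutation_enrichment(ends, trk, CHROMS, t, seed=9, n_permutations=500)
        assert a == b

    def test_exclusion_mask_shifts_null(self, t):
        # masking everything except the padded track forces every random
        # end inside it: random median == n ends, fold == observed/n
        trk = track("SD", [(400_000, 500_000)], 1)
        mask = track("EXCL", [(0, 390_000), (510_000, 1_000_000)], 9)
        ends = [end(int(p), contig=f"c{i}") for i, p in enumerate(np.linspace(401_000, 499_000, 50))]
        r = permutation_enrichment(ends, trk, CHROMS, t, seed=4, n_permutations=200, exclude=mask)
        assert r.random_median == 50 and r.fold == 1.0

    def test_zero_ends_is_an_error(self, t):
        with pytest.raises(ValueError):
            permutation_enrichment([], track("SD", [(0, 10)], 1), CHROMS, t, seed=1)

    def test_null_calibration(self, t):
        """Uniformly placed ends vs a fixed track: mean fold ~1 and
        empirical p approximately uniform over 200 seeded replicates."""
        rng = np.random.default_rng(12345)
        trk = track("SD", [(int(s), int(s) + 8_000) for s in rng.integers(0, 990_000, 25)], 1)
        folds, pvals = [], []
        for rep in range(200):
            ends = [end(int(p), contig=f"c{i}") for i, p in enumerate(rng.integers(0, 1_000_000, 100))]
            r = permutation_enrichment(ends, trk, CHROMS, t, seed=50_000 + rep, n_permutations=1_000)
            folds.append(r.fold)
            pvals.append(r.pvalue)
        assert 0.9 <= float(np.mean(folds)) <= 1.1
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01


def gap(s, e, sample="s1", hap="h1", chrom="chr1"):
    return GapRegion(chrom, s, e, "a", "b", sample, hap)


class TestRecurrence:
    def test_identical_gap_in_five_assemblies(self):
        gaps = [gap(100_000, 120_000, sample=f"s{i}") for i in range(5)]
        (r,) = recurrent_gap_regions(gaps, min_count=5)
        assert (r.start, r.end, r.n_assemblies) == (100_000, 120_000, 5)

    def test_four_assemblies_dropped(self):
        gaps = [gap(100_000, 120_000, sample=f"s{i}") for i in range(4)]
        assert recurrent_gap_regions(gaps, min_count=5) == []

    def test_matches_naive_sweep(self):
        rng = np.random.default_rng(8)
        gaps = []
        for a in range(20):
            for _ in range(rng.integers(1, 5)):
                s = int(rng.integers(0, 900_000))
                gaps.append(gap(s, s + int(rng.integers(5_000, 60_000)), sample=f"s{a}"))
        regions = recurrent_gap_regions(gaps, min_count=1)
        # naive oracle: per-base union and per-region distinct-assembly count
        cover = np.zeros(1_000_000, dtype=bool)
        for g in gaps:
            cover[g.start : g.end] = True
        blocks, s = [], None
        for i in range(len(cover)):
            if cover[i] and s is None:
                s = i
            elif not cover[i] and s is not None:
                blocks.append((s, i))
                s = None
        if s is not None:
            blocks.append((s, len(cover)))
        assert [(r.start, r.end) for r in regions] == blocks
        for r in regions:
            expected = len({g.sample for g in gaps if g.start < r.end and r.start < g.end})
            assert r.n_assemblies == expected

    def test_satellite_exclusion(self):
        gaps = [gap(100_000, 120_000, sample=f"s{i}") for i in range(6)]
        sat = track("SAT", [(110_000, 130_000)], 3)
        assert recurrent_gap_regions(gaps, 5, satellite_track=sat) == []


class TestGeneOverlap:
    def test_gap_in_seven_assemblies(self):
        gaps = [gap(100_000, 200_000, sample=f"s{i}") for i in range(7)]
        genes = [BedInterval("chr1", 120_000, 140_000, "GENE1")]
        df = gene_overlap(gaps, genes)
        assert df.loc[df.gene == "GENE1", "n_assemblies"].item() == 7

    def test_split_gene_ranges_are_collapsed(self):
        # gap touches only the gap between the two exon blocks; the
        # collapsed gene range still overlaps
        genes = [
            BedInterval("chr1", 100_000, 110_000, "GENE1"),
            BedInterval("chr1", 150_000, 160_000, "GENE1"),
        ]
        gaps = [gap(120_000, 130_000)]
        df = gene_overlap(gaps, genes)
        assert df.loc[df.gene == "GENE1", "n_assemblies"].item() == 1

    def test_matches_all_pairs_overlap(self):
        rng = np.random.default_rng(5)
        genes = [
            BedInterval("chr1", int(s), int(s) + 20_000, f"G{i}")
            for i, s in enumerate(rng.integers(0, 950_000, 30))
        ]
        gaps = []
        for a in range(10):
            s = int(rng.integers(0, 900_000))
            gaps.append(gap(s, s + 50_000, sample=f"s{a}"))
        df = gene_overlap(gaps, genes).set_index("gene")
        for g in genes:
            expected = len(
                {gp.sample for gp in gaps if gp.start < g.end and g.start < gp.end}
            )
            assert df.loc[g.name, "n_assemblies"] == expected
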