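"""Multicoverage regions, embedded contigs, windowed copy number and the
four-way CNV classification.

A haploid assembly should tile the reference at single (1n) coverage;
reference intervals covered by two or more contig alignments of one
haplotype ("multicoverage") mark either real copy-number variation or
assembly/mapping artifacts.  A special artifact class is the *embedded
contig*: a contig whose entire aligned span lies inside another contig's
span in the same haplotype.

To separate real CNV from artifact, windowed read depth is converted to
diploid copy number (CN = 2 x depth / mean control depth, optional per-GC
rescaling) and compared with the reference's own k-mer-derived copy number:

* ``noCN``      — sample CN equals the diploid expectation (2) or shows no
                  difference from the reference CN;
* ``CNV``       — sample CN below 10 with at least a one-copy increase over
                  the reference;
* ``more10CN``  — a copy-number increase but sample CN above 10;
* ``none``      — everything else (including the unassigned boundary case
                  of sample CN exactly 10 with an increase);
* ``uncallable``— the region has no copy-number windows.

A loss-of-heterozygosity screen flags contig overlaps where one contig has
lost nearly all heterozygous variation while being nearly identical to the
opposite parental haplotype — the signature of a duplicated contig drawn
from the wrong parent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .alignment_io import ContigAlignmentSet
from .config import Thresholds

CATEGORY_CNV = "CNV"
CATEGORY_NOCN = "noCN"
CATEGORY_MORE10 = "more10CN"
CATEGORY_NONE = "none"
CATEGORY_UNCALLABLE = "uncallable"


@dataclass(frozen=True)
class MultiCoverageRegion:
    sample: str
    haplotype: str
    chrom: str
    start: int
    end: int
    depth: int
    contigs: tuple[str, ...]
    embedded: bool


def multicoverage_regions(aset: ContigAlignmentSet) -> list[MultiCoverageRegion]:
    """Sweep-line over one haplotype's target intervals; maximal intervals
    with alignment depth >= 2, with contributing contigs and the embedded
    flag (one contributor's whole aligned span inside another's)."""
    haps = {(k[0], k[1]) for k, _ in aset}
    out: list[MultiCoverageRegion] = []
    for sample, hap in sorted(haps):
        sub = aset.subset(sample, hap)
        per_chrom: dict[str, list[tuple[int, int, str]]] = {}
        contig_spans: dict[tuple[str, str], tuple[int, int]] = {}
        for (s, h, contig), recs in sub:
            for r in recs:
                per_chrom.setdefault(r.target_name, []).append(
                    (r.target_start, r.target_end, contig)
                )
                key = (r.target_name, contig)
                lo, hi = contig_spans.get(key, (r.target_start, r.target_end))
                contig_spans[key] = (min(lo, r.target_start), max(hi, r.target_end))
        for chrom, ivs in sorted(per_chrom.items()):
            events: list[tuple[int, int, str]] = []  # (pos, delta, contig)
            for s, e, contig in ivs:
                events.append((s, 1, contig))
                events.append((e, -1, contig))
            events.sort(key=lambda x: (x[0], x[1]))
            depth = 0
            active: dict[str, int] = {}
            prev_pos = None
            segments: list[tuple[int, int, int, set[str]]] = []
            for pos, delta, contig in events:
                if depth >= 2 and prev_pos is not None and pos > prev_pos:
                    segments.append((prev_pos, pos, depth, set(active)))
                if delta == 1:
                    active[contig] = active.get(contig, 0) + 1
                else:
                    active[contig] -= 1
                    if active[contig] == 0:
                        del active[contig]
                depth = sum(active.values())
                prev_pos = pos
            # stitch adjacent depth>=2 segments into maximal regions
            merged: list[tuple[int, int, int, set[str]]] = []
            for s, e, d, contigs in segments:
                if merged and s == merged[-1][1]:
                    ps, pe, pd_, pc = merged[-1]
                    merged[-1] = (ps, e, max(pd_, d), pc | contigs)
                else:
                    merged.append((s, e, d, set(contigs)))
            for s, e, d, contigs in merged:
                embedded = False
                spans = {c: contig_spans[(chrom, c)] for c in contigs}
                for a in contigs:
                    for b in contigs:
                        if a == b:
                            continue
                        (alo, ahi), (blo, bhi) = spans[a], spans[b]
                        if blo <= alo and ahi <= bhi and (alo, ahi) != (blo, bhi):
                            embedded = True
                out.append(
                    MultiCoverageRegion(
                        sample, hap, chrom, s, e, d, tuple(sorted(contigs)), embedded
                    )
                )
    return out


@dataclass(frozen=True)
class CopyNumberWindow:
    chrom: str
    start: int
    end: int
    copy_number: float


def depth_to_copy_number(
    windows: pd.DataFrame,
    control_regions: Sequence[tuple[str, int, int]],
    cn_diploid: int = 2,
    gc_correct: bool = False,
) -> pd.DataFrame:
    """Convert a window depth table (`chrom start end depth [gc]`) to
    diploid copy number by scaling against copy-number-stable control
    regions: CN = diploid x depth / mean(control depth).

    With ``gc_correct`` and a ``gc`` column, depth is first rescaled per GC
    decile so each decile's control mean matches the global control mean.
    """
    df = windows.copy()
    in_control = np.zeros(len(df), dtype=bool)
    for chrom, s, e in control_regions:
        in_control |= (df["chrom"] == chrom).to_numpy() & (
            (df["start"].to_numpy() < e) & (df["end"].to_numpy() > s)
        )
    if not in_control.any():
        raise ValueError("control regions cover no windows")
    depth = df["depth"].to_numpy(dtype=float)
    if gc_correct and "gc" in df.columns:
        decile = np.clip((df["gc"].to_numpy(dtype=float) * 10).astype(int), 0, 9)
        global_mean = depth[in_control].mean()
        for d in range(10):
            sel = in_control & (decile == d)
            if sel.any() and depth[sel].mean() > 0:
                depth[decile == d] *= global_mean / depth[sel].mean()
    control_mean = depth[in_control].mean()
    if control_mean <= 0:
        raise ValueError("control regions have zero depth")
    df["copy_number"] = cn_diploid * depth / control_mean
    return df


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def classify_pair(sample_cn: int, reference_cn: int, t: Thresholds) -> str:
    """Four-way category for one (sample CN, reference CN) integer pair."""
    delta = sample_cn - reference_cn
    if sample_cn == t.cn_diploid or delta == 0:
        return CATEGORY_NOCN
    if delta >= 1 and sample_cn < t.cn_high:
        return CATEGORY_CNV
    if delta >= 1 and sample_cn > t.cn_high:
        return CATEGORY_MORE10
    return CATEGORY_NONE


@dataclass(frozen=True)
class CNVCall:
    chrom: str
    start: int
    end: int
    sample_cn: float
    reference_cn: float
    delta: int
    category: str


def classify_cnv(
    region: tuple[str, int, int],
    sample_track: pd.DataFrame,
    reference_track: pd.DataFrame,
    t: Thresholds,
) -> CNVCall:
    """Classify a region from the mean sample and reference copy number of
    the windows it covers (means rounded half-up to integers first)."""
    chrom, start, end = region

    def region_mean(track: pd.DataFrame) -> float | None:
        sel = (track["chrom"] == chrom) & (track["start"] < end) & (track["end"] > start)
        if not sel.any():
            return None
        return float(track.loc[sel, "copy_number"].mean())

    s_mean = region_mean(sample_track)
    r_mean = region_mean(reference_track)
    if s_mean is None or r_mean is None:
        return CNVCall(chrom, start, end, float("nan"), float("nan"), 0, CATEGORY_UNCALLABLE)
    s_int, r_int = _round_half_up(s_mean), _round_half_up(r_mean)
    return CNVCall(
        chrom, start, end, s_mean, r_mean, s_int - r_int, classify_pair(s_int, r_int, t)
    )


@dataclass
class LohResult:
    region: tuple[str, int, int]
    densities: dict[str, list[float]]   # contig -> per-window het density (per bp)
    flagged: tuple[str, ...]            # contigs with the LOH-like signature
    callable: bool

    @property
    def is_loh(self) -> bool:
        return bool(self.flagged)


def loh_screen(
    region: tuple[str, int, int],
    contig_hets: Mapping[str, Sequence[int]],
    opposite_diffs: Mapping[str, Sequence[int]],
    assembly_median_density: float,
    expected_het_rate: float,
    window: int = 100_000,
    low_frac: float = 0.10,
) -> LohResult:
    """Screen a contig-overlap region for loss of heterozygosity.

    ``contig_hets`` maps each overlapping contig to its heterozygous
    variant positions inside the region; ``opposite_diffs`` maps each to
    the positions where it differs from the opposite-haplotype contig over
    the same interval.  A contig is flagged when its het density falls
    below ``low_frac`` of the assembly-wide median density while it is
    nearly identical to the opposite haplotype (differences below
    ``low_frac`` of the expected het rate).
    """
    chrom, start, end = region
    if not contig_hets:
        return LohResult(region, {}, (), callable=False)
    length = end - start
    densities: dict[str, list[float]] = {}
    flagged: list[str] = []
    for contig, positions in contig_hets.items():
        pos = np.asarray([p for p in positions if start <= p < end])
        per_window = []
        for ws in range(start, end, window):
            we = min(ws + window, end)
            per_window.append(float(((pos >= ws) & (pos < we)).sum()) / (we - ws))
        densities[contig] = per_window
        overall = len(pos) / length
        near_identical = (
            len([p for p in opposite_diffs.get(contig, []) if start <= p < end]) / length
            < low_frac * expected_het_rate
        )
        if overall < low_frac * assembly_median_density and near_identical:
            flagged.append(contig)
    return LohResult(region, densities, tuple(sorted(flagged)), callable=True)
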