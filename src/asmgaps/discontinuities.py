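"""Intra-contig alignment discontinuities: putative structural variation.

A discontinuity is the gap between two query-adjacent alignments of one
contig on one chromosome.  The gap has a size on the reference (target)
axis and a size within the contig (query) axis — the unaligned bases.  A
*contraction* has a larger target gap than query gap (reference sequence
missing from the contig); an *expansion* has a larger query gap than target
gap (contig sequence absent from the reference); the predicted event size
is the absolute difference of the two gaps.  Only discontinuities with a
target gap below 1 Mbp are reported — larger jumps were already split into
separate contig pieces upstream.  Events within +/-1 Mbp of centromeric
satellite annotation are flagged CENSAT, since alignment there is dominated
by satellite turnover rather than discrete structural events.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .alignment_io import AlignmentRecord, ContigAlignmentSet
from .config import Thresholds
from .end_annotation import AnnotationTrack
from ._intervals import merge

log = logging.getLogger(__name__)

CONTRACTION = "contraction"
EXPANSION = "expansion"
NEUTRAL = "neutral"


@dataclass
class Discontinuity:
    sample: str
    haplotype: str
    contig: str
    chrom: str
    start: int                 # target gap interval (start == end for point insertions)
    end: int
    target_gap: int
    query_gap: int             # unaligned bases
    klass: str
    event_size: int
    strand_switch: bool
    censat_flag: bool = False


def _classify(target_gap: int, query_gap: int) -> str:
    if target_gap > query_gap:
        return CONTRACTION
    if target_gap < query_gap:
        return EXPANSION
    return NEUTRAL


def find_discontinuities(aset: ContigAlignmentSet, t: Thresholds) -> list[Discontinuity]:
    """Walk query-adjacent alignment pairs of each contig on each
    chromosome and emit classified discontinuities.

    Pairs with overlapping query intervals are skipped with a warning
    (split/supplementary artifacts); pairs whose target intervals overlap
    (multicoverage signature) and pairs with both gaps zero emit nothing;
    target gaps at or above ``max_discontinuity`` are not discontinuities.
    Strand-switch pairs (inversion breakpoints) are evaluated and labelled.
    """
    out: list[Discontinuity] = []
    for key, recs in aset:
        sample, hap, contig = key
        for prev, nxt in zip(recs, recs[1:]):
            if prev.target_name != nxt.target_name:
                continue  # cross-chromosome adjacency is a piece boundary, not a discontinuity
            query_gap = nxt.query_start - prev.query_end
            if query_gap < 0:
                log.warning(
                    "%s: overlapping query intervals at %d, skipping pair", contig, nxt.query_start
                )
                continue
            # target gap on the reference axis, strand-aware: for a reverse-
            # oriented pair the downstream query block lies upstream on the
            # reference, so order the two intervals by reference coordinate
            lo, hi = sorted([prev, nxt], key=lambda r: (r.target_start, r.target_end))
            target_gap = hi.target_start - lo.target_end
            if target_gap < 0:
                continue  # overlapping target alignments: multicoverage, not a gap
            if target_gap == 0 and query_gap == 0:
                continue
            if target_gap >= t.max_discontinuity:
                continue
            klass = _classify(target_gap, query_gap)
            out.append(
                Discontinuity(
                    sample=sample, haplotype=hap, contig=contig,
                    chrom=prev.target_name, start=lo.target_end,
                    end=lo.target_end + target_gap,
                    target_gap=target_gap, query_gap=query_gap, klass=klass,
                    event_size=abs(target_gap - query_gap),
                    strand_switch=prev.strand != nxt.strand,
                )
            )
    return out


def censat_flagging(
    discs: Sequence[Discontinuity], censat: AnnotationTrack, t: Thresholds
) -> list[Discontinuity]:
    """Set ``censat_flag`` on discontinuities within ``censat_pad``
    (+/-1 Mbp) of any centromeric satellite interval; returns the same
    objects for chaining."""
    for d in discs:
        d.censat_flag = censat.overlaps_interval(
            d.chrom, d.start - t.censat_pad, d.end + t.censat_pad
        )
    return list(discs)


def summarize_unaligned(
    discs: Sequence[Discontinuity],
    assembly_lengths: dict[tuple[str, str], int],
) -> pd.DataFrame:
    """Per-assembly totals of unaligned (query-gap) bases split by CENSAT
    flag, as base pairs and as percentages of the total assembly length."""
    rows = []
    for (sample, hap), total_len in sorted(assembly_lengths.items()):
        mine = [d for d in discs if (d.sample, d.haplotype) == (sample, hap)]
        inside = sum(d.query_gap for d in mine if d.censat_flag)
        outside = sum(d.query_gap for d in mine if not d.censat_flag)
        rows.append(
            {
                "sample": sample,
                "hap": hap,
                "assembly_len": total_len,
                "unaligned_censat_bp": inside,
                "unaligned_other_bp": outside,
                "unaligned_censat_pct": 100.0 * inside / total_len,
                "unaligned_other_pct": 100.0 * outside / total_len,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "sample", "hap", "assembly_len", "unaligned_censat_bp", "unaligned_other_bp",
            "unaligned_censat_pct", "unaligned_other_pct",
        ],
    )


@dataclass(frozen=True)
class RecurrentSVRegion:
    chrom: str
    start: int
    end: int
    klass: str
    n_assemblies: int
    event_sizes: tuple[int, ...]


def recurrent_sv_regions(discs: Sequence[Discontinuity], t: Thresholds) -> list[RecurrentSVRegion]:
    """Merge same-class events of size >= ``recur_min_event`` that overlap
    on the reference, and keep merged regions supported by at least
    ``recur_min_assemblies`` distinct assemblies (haplotypes).  Point
    insertions participate as 1-bp intervals; neutral events are excluded."""
    out: list[RecurrentSVRegion] = []
    for klass in (CONTRACTION, EXPANSION):
        pool = [d for d in discs if d.klass == klass and d.event_size >= t.recur_min_event]
        by_chrom: dict[str, list[Discontinuity]] = {}
        for d in pool:
            by_chrom.setdefault(d.chrom, []).append(d)
        for chrom, events in sorted(by_chrom.items()):
            ivs = [(d.start, max(d.end, d.start + 1)) for d in events]
            for start, end in merge(ivs, join_adjacent=False):
                hits = [
                    d for d, iv in zip(events, ivs) if iv[0] < end and start < iv[1]
                ]
                support = {(d.sample, d.haplotype) for d in hits}
                if len(support) >= t.recur_min_assemblies:
                    out.append(
                        RecurrentSVRegion(
                            chrom, start, end, klass, len(support),
                            tuple(sorted(d.event_size for d in hits)),
                        )
                    )
    out.sort(key=lambda r: (r.chrom, r.start, r.klass))
    return out


def inverted_segments(aset: ContigAlignmentSet) -> list[tuple[str, int, int, str, str]]:
    """Maximal runs of reverse-strand alignments flanked by forward
    alignments within one contig — the split-alignment signature of a
    misoriented (inverted) assembly segment.  Returns
    ``(chrom, start, end, contig, haplotype)`` tuples."""
    out = []
    for key, recs in aset:
        _, hap, contig = key
        runs: list[list[AlignmentRecord]] = []
        for r in recs:
            if r.strand == "-":
                if runs and runs[-1] and runs[-1][-1].target_name == r.target_name:
                    runs[-1].append(r)
                else:
                    runs.append([r])
            elif runs and runs[-1]:
                runs.append([])
        for run in runs:
            if not run:
                continue
            has_forward = any(r.strand == "+" for r in recs)
            if has_forward:
                start = min(r.target_start for r in run)
                end = max(r.target_end for r in run)
                out.append((run[0].target_name, start, end, contig, hap))
    return sorted(out)
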