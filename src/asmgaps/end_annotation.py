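"""Annotation of contig ends against feature tracks and enrichment testing.

Each contig end receives exactly one label: the highest-priority annotation
within ``proximity`` (10 kbp) of the end.  Ends near a reference chromosome
terminus are always "chromosome_end"; ends near both a segmental duplication
and a GA/TC window take the composite "SD+GA/TC" label when configured;
remaining unlabeled ends that occur in only one haplotype across the cohort
are "poisson_end" (nonrecurrent, presumed random); everything else is
"other".  Because the labels are nonredundant, category counts sum exactly
to the number of ends.

Enrichment of ends near a track is measured against uniformly random end
placement: the same number of ends is dropped uniformly over the reference
``n_permutations`` times, fold enrichment is observed / median(random) and
the empirical p-value is ``(1 + #{random >= observed}) / (1 + n)``.  Unlike
the nonredundant labelling above, enrichment counts an end toward every
track it is near.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._intervals import merge
from .alignment_io import BedInterval
from .config import Thresholds
from .contig_ends import ContigEnd, GapRegion

CHROMOSOME_END = "chromosome_end"
POISSON_END = "poisson_end"
OTHER = "other"


class AnnotationConfigError(ValueError):
    pass


@dataclass
class AnnotationTrack:
    """A named feature track with a priority rank (lower = higher priority)."""

    name: str
    intervals: list[BedInterval]
    priority: int

    def __post_init__(self) -> None:
        self.intervals = sorted(self.intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
        tmp: dict[str, tuple[list[int], list[int]]] = {}
        for iv in self.intervals:
            starts, ends = tmp.setdefault(iv.chrom, ([], []))
            starts.append(iv.start)
            ends.append(iv.end)
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {
            c: (np.asarray(s), np.asarray(e)) for c, (s, e) in tmp.items()
        }

    def overlaps_interval(self, chrom: str, start: int, end: int) -> bool:
        if chrom not in self._by_chrom:
            return False
        starts, ends = self._by_chrom[chrom]
        return bool(((starts < end) & (ends > start)).any())

    @property
    def is_empty(self) -> bool:
        return not self.intervals

    def distance(self, chrom: str, pos: int) -> int | None:
        """Distance from a point to the nearest interval on ``chrom``
        (0 when inside); None when the track has nothing there."""
        if chrom not in self._by_chrom:
            return None
        starts, ends = self._by_chrom[chrom]
        i = int(np.searchsorted(starts, pos, side="right"))
        best = None
        if i > 0:
            if pos < ends[i - 1]:
                return 0
            best = pos - int(ends[i - 1]) + 1
        if i < len(starts):
            d = int(starts[i]) - pos
            best = d if best is None else min(best, d)
        return best


@dataclass(frozen=True)
class AnnotatedEnd:
    end: ContigEnd
    label: str
    distance: int


@dataclass(frozen=True)
class EnrichmentResult:
    track: str
    observed: int
    random_median: float
    fold: float
    pvalue: float
    n_permutations: int
    seed: int
    fold_defined: bool = True


def poisson_ends(
    ends: Sequence[ContigEnd], cluster_distance: int | None = None, t: Thresholds | None = None
) -> list[ContigEnd]:
    """Ends with no end from any *other* haplotype within
    ``cluster_distance`` (default: the proximity threshold) on the same
    chromosome — nonrecurrent, therefore likely random breaks."""
    if cluster_distance is None:
        cluster_distance = (t or Thresholds()).proximity
    by_chrom: dict[str, list[ContigEnd]] = {}
    for e in ends:
        by_chrom.setdefault(e.chrom, []).append(e)
    out: list[ContigEnd] = []
    for chrom, chrom_ends in by_chrom.items():
        chrom_ends.sort(key=lambda e: e.position)
        positions = [e.position for e in chrom_ends]
        for i, e in enumerate(chrom_ends):
            lo = bisect_left(positions, e.position - cluster_distance)
            recurrent = False
            for j in range(lo, len(chrom_ends)):
                other = chrom_ends[j]
                if other.position > e.position + cluster_distance:
                    break
                if (other.sample, other.haplotype) != (e.sample, e.haplotype):
                    recurrent = True
                    break
            if not recurrent:
                out.append(e)
    return out


def annotate_ends(
    ends: Sequence[ContigEnd],
    tracks: Sequence[AnnotationTrack],
    chrom_lengths: Mapping[str, int],
    t: Thresholds,
    composite: tuple[str, str, str] | None = ("SD", "GA/TC", "SD+GA/TC"),
    composite_priority: float = 0.5,
    poisson: Iterable[ContigEnd] | None = None,
) -> list[AnnotatedEnd]:
    """Assign exactly one label per end.

    Priority: chromosome end (implicit rank 0) beats everything; then the
    composite label (when both its parts are within proximity); then tracks
    by ascending priority rank; unlabeled ends present in ``poisson``
    (defaults to :func:`poisson_ends` over the input) become "poisson_end";
    the rest are "other".
    """
    priorities = [trk.priority for trk in tracks]
    if len(set(priorities)) != len(priorities):
        raise AnnotationConfigError(f"duplicate track priorities: {priorities}")
    by_name = {trk.name: trk for trk in tracks}
    if composite is not None and not (composite[0] in by_name and composite[1] in by_name):
        composite = None
    if poisson is None:
        poisson = poisson_ends(ends, t=t)
    poisson_set = set(poisson)

    ordered = sorted(tracks, key=lambda trk: trk.priority)
    out: list[AnnotatedEnd] = []
    for e in ends:
        chrom_len = chrom_lengths[e.chrom]
        terminus = min(e.position, chrom_len - e.position)
        if terminus <= t.chrom_end_window:
            out.append(AnnotatedEnd(e, CHROMOSOME_END, terminus))
            continue
        dists = {
            trk.name: d
            for trk in ordered
            if (d := trk.distance(e.chrom, e.position)) is not None and d <= t.proximity
        }
        if composite is not None and composite[0] in dists and composite[1] in dists:
            out.append(AnnotatedEnd(e, composite[2], min(dists[composite[0]], dists[composite[1]])))
            continue
        assigned = next((trk for trk in ordered if trk.name in dists), None)
        if assigned is not None:
            out.append(AnnotatedEnd(e, assigned.name, dists[assigned.name]))
        elif e in poisson_set:
            out.append(AnnotatedEnd(e, POISSON_END, 0))
        else:
            out.append(AnnotatedEnd(e, OTHER, 0))
    return out


def category_counts(annotated: Sequence[AnnotatedEnd]) -> pd.DataFrame:
    df = pd.DataFrame({"label": [a.label for a in annotated]})
    counts = df.value_counts("label").rename("count").reset_index()
    return counts.sort_values("count", ascending=False).reset_index(drop=True)


def _padded_linear_intervals(
    track: AnnotationTrack, chrom_lengths: Mapping[str, int], proximity: int
) -> tuple[np.ndarray, int]:
    """Track intervals padded by ``proximity``, clipped to chromosomes and
    mapped into one concatenated coordinate axis; returns the merged
    boundary array (flattened starts/ends) and the total genome length."""
    offset = 0
    bounds: list[tuple[int, int]] = []
    for chrom in sorted(chrom_lengths):
        length = chrom_lengths[chrom]
        if chrom in track._by_chrom:
            starts, ends = track._by_chrom[chrom]
            padded = [
                (offset + max(0, int(s) - proximity), offset + min(length, int(e) + proximity))
                for s, e in zip(starts, ends)
            ]
            bounds.extend(merge(padded))
        offset += length
    flat = np.asarray([x for iv in merge(bounds) for x in iv], dtype=np.int64)
    return flat, offset


def permutation_enrichment(
    ends: Sequence[ContigEnd],
    track: AnnotationTrack,
    chrom_lengths: Mapping[str, int],
    t: Thresholds,
    seed: int,
    n_permutations: int | None = None,
    exclude: AnnotationTrack | None = None,
) -> EnrichmentResult:
    """Fold enrichment of ends within ``proximity`` of a track versus
    uniformly random placement of the same number of ends.

    ``exclude`` optionally removes regions (e.g. unassemblable sequence)
    from the random placement space; by default nothing is masked.
    """
    if not ends:
        raise ValueError("permutation_enrichment needs at least one end")
    n_perm = t.n_permutations if n_permutations is None else n_permutations
    observed = sum(
        1
        for e in ends
        if (d := track.distance(e.chrom, e.position)) is not None and d <= t.proximity
    )
    if track.is_empty:
        return EnrichmentResult(track.name, observed, 0.0, float(observed), 1.0, n_perm, seed, False)

    flat, total = _padded_linear_intervals(track, chrom_lengths, t.proximity)
    rng = np.random.default_rng(seed)
    if exclude is None:
        draws = rng.integers(0, total, size=(n_perm, len(ends)))
    else:
        excl, _ = _padded_linear_intervals(exclude, chrom_lengths, 0)
        allowed: list[tuple[int, int]] = []
        cursor = 0
        for s, e in zip(excl[::2], excl[1::2]):
            if int(s) > cursor:
                allowed.append((cursor, int(s)))
            cursor = max(cursor, int(e))
        if cursor < total:
            allowed.append((cursor, total))
        lengths = np.asarray([e - s for s, e in allowed])
        offsets = np.concatenate([[0], np.cumsum(lengths)])
        u = rng.integers(0, int(offsets[-1]), size=(n_perm, len(ends)))
        block = np.searchsorted(offsets, u.ravel(), side="right") - 1
        starts = np.asarray([s for s, _ in allowed])
        draws = (starts[block] + (u.ravel() - offsets[block])).reshape(u.shape)
    inside = (np.searchsorted(flat, draws.ravel(), side="right") % 2 == 1).reshape(draws.shape)
    random_counts = inside.sum(axis=1)
    med = float(np.median(random_counts))
    if med > 0:
        fold, defined = observed / med, True
    else:
        fold, defined = float(observed), False
    p = (1 + int((random_counts >= observed).sum())) / (1 + n_perm)
    return EnrichmentResult(track.name, observed, med, fold, p, n_perm, seed, defined)


@dataclass(frozen=True)
class RecurrentRegion:
    chrom: str
    start: int
    end: int
    n_assemblies: int


def recurrent_gap_regions(
    gaps: Sequence[GapRegion],
    min_count: int,
    satellite_track: AnnotationTrack | None = None,
) -> list[RecurrentRegion]:
    """Merge per-haplotype gaps pooled across assemblies into maximal
    nonredundant regions, count the distinct assemblies (haplotypes)
    contributing to each, and keep regions with count >= ``min_count``;
    regions overlapping ``satellite_track`` are optionally excluded."""
    by_chrom: dict[str, list[GapRegion]] = {}
    for g in gaps:
        by_chrom.setdefault(g.chrom, []).append(g)
    out: list[RecurrentRegion] = []
    for chrom, chrom_gaps in sorted(by_chrom.items()):
        for start, end in merge([(g.start, g.end) for g in chrom_gaps], join_adjacent=False):
            support = {
                (g.sample, g.haplotype)
                for g in chrom_gaps
                if g.start < end and start < g.end
            }
            if len(support) < min_count:
                continue
            if satellite_track is not None and satellite_track.overlaps_interval(chrom, start, end):
                continue
            out.append(RecurrentRegion(chrom, start, end, len(support)))
    return out


def gene_overlap(gaps: Sequence[GapRegion], genes: Sequence[BedInterval]) -> pd.DataFrame:
    """Per-gene count of distinct assemblies whose gaps overlap the gene.

    Multiple ranges of the same gene are collapsed to one spanning range per
    chromosome before the overlap test; any >=1 bp overlap counts.
    """
    collapsed: dict[tuple[str, str], tuple[int, int]] = {}
    for g in genes:
        key = (g.name, g.chrom)
        if key in collapsed:
            s, e = collapsed[key]
            collapsed[key] = (min(s, g.start), max(e, g.end))
        else:
            collapsed[key] = (g.start, g.end)
    rows = []
    for (name, chrom), (s, e) in sorted(collapsed.items(), key=lambda kv: (kv[0][1], kv[1][0])):
        support = {
            (g.sample, g.haplotype)
            for g in gaps
            if g.chrom == chrom and g.start < e and s < g.end
        }
        rows.append(
            {"gene": name, "chrom": chrom, "start": s, "end": e, "n_assemblies": len(support)}
        )
    return pd.DataFrame(rows, columns=["gene", "chrom", "start", "end", "n_assemblies"])
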