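"""Contig ends, contig-end alignments and assembly gaps.

Three related views of where an assembly terminates against the reference:

* *simple contig ends* — per contig, the first and last alignment with at
  least ``min_simple_end_aln`` (default 25 kbp) aligned; a point position on
  the reference used for feature-enrichment accounting.
* *contig-end alignments* — terminal alignments of at least
  ``min_ctg_end_aln`` (default 50 kbp).  When the reference span between a
  contig's terminal alignments exceeds its length by more than
  ``overextension_frac`` (5%), the contig is partitioned into pieces, split
  at the largest inter-alignment reference jumps, each piece carrying its
  own pair of ends.
* *assembly gaps* — reference intervals between subsequent contig pieces of
  one haploid assembly; the pipeline's primary product.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from ._intervals import gap_distance
from .alignment_io import AlignmentRecord, ContigAlignmentSet
from .config import Thresholds

#: contigs with more alignments than this fall back to greedy largest-jump
#: splitting instead of exhaustive subset search
_EXACT_SPLIT_LIMIT = 16


@dataclass(frozen=True)
class ContigEnd:
    sample: str
    haplotype: str
    contig: str
    side: str            # 'left'/'right' in reference orientation
    chrom: str
    position: int        # 0-based reference point
    support: int         # aligned bp of the qualifying alignment
    kind: str            # 'simple' or 'end_alignment'


@dataclass
class ContigPiece:
    sample: str
    haplotype: str
    contig: str
    piece_index: int
    chrom: str
    alignments: list[AlignmentRecord]
    left_end: ContigEnd | None
    right_end: ContigEnd | None

    @property
    def has_ends(self) -> bool:
        return self.left_end is not None and self.right_end is not None

    @property
    def ref_start(self) -> int:
        assert self.left_end is not None
        return self.left_end.position

    @property
    def ref_end(self) -> int:
        assert self.right_end is not None
        return self.right_end.position

    @property
    def span(self) -> int:
        """Reference span between this piece's outermost end alignments."""
        return self.ref_end - self.ref_start


@dataclass(frozen=True)
class GapRegion:
    chrom: str
    start: int
    end: int
    left_piece: str
    right_piece: str
    sample: str
    haplotype: str

    @property
    def length(self) -> int:
        return self.end - self.start


class UsageError(ValueError):
    pass


def _outer_position(rec: AlignmentRecord, contig_side: str) -> int:
    """Reference coordinate of the contig-side extremity of an alignment."""
    if contig_side == "left":
        return rec.target_start if rec.strand == "+" else rec.target_end
    return rec.target_end if rec.strand == "+" else rec.target_start


def simple_ends(
    aset: ContigAlignmentSet, t: Thresholds
) -> tuple[list[ContigEnd], list[tuple[str, str, str]]]:
    """First/last qualifying (>= ``min_simple_end_aln`` aligned) alignment
    of each contig; returns ``(ends, skipped_contigs)``.  One alignment may
    anchor both sides of a single-alignment contig."""
    ends: list[ContigEnd] = []
    skipped: list[tuple[str, str, str]] = []
    for key, recs in aset:
        sample, hap, contig = key
        qualifying_left = next((r for r in recs if r.target_span >= t.min_simple_end_aln), None)
        qualifying_right = next(
            (r for r in reversed(recs) if r.target_span >= t.min_simple_end_aln), None
        )
        if qualifying_left is None or qualifying_right is None:
            skipped.append(key)
            continue
        p_left = _outer_position(qualifying_left, "left")
        p_right = _outer_position(qualifying_right, "right")
        # report in reference orientation so downstream gap logic is uniform
        (pos_lo, rec_lo), (pos_hi, rec_hi) = sorted(
            [(p_left, qualifying_left), (p_right, qualifying_right)], key=lambda x: x[0]
        )
        ends.append(ContigEnd(sample, hap, contig, "left", rec_lo.target_name, pos_lo,
                              rec_lo.target_span, "simple"))
        ends.append(ContigEnd(sample, hap, contig, "right", rec_hi.target_name, pos_hi,
                              rec_hi.target_span, "simple"))
    return ends, skipped


def _piece_span(chunk: Sequence[AlignmentRecord]) -> int:
    return max(r.target_end for r in chunk) - min(r.target_start for r in chunk)


def _split_chunks(
    recs: Sequence[AlignmentRecord], max_span: float
) -> list[list[AlignmentRecord]]:
    """Partition a query-ordered alignment run into the minimal number of
    pieces, cut at the largest reference jumps, so each piece's reference
    span stays within ``max_span``."""
    if _piece_span(recs) <= max_span or len(recs) == 1:
        return [list(recs)]
    jumps = [
        gap_distance((a.target_start, a.target_end), (b.target_start, b.target_end))
        for a, b in zip(recs, recs[1:])
    ]
    n = len(jumps)

    def pieces_for(cuts: tuple[int, ...]) -> list[list[AlignmentRecord]]:
        out, prev = [], 0
        for c in sorted(cuts):
            out.append(list(recs[prev : c + 1]))
            prev = c + 1
        out.append(list(recs[prev:]))
        return out

    order = sorted(range(n), key=lambda i: (-jumps[i], i))
    for k in range(1, n + 1):
        greedy = tuple(sorted(order[:k]))
        chunks = pieces_for(greedy)
        if all(_piece_span(c) <= max_span for c in chunks):
            return chunks
        if n <= _EXACT_SPLIT_LIMIT:
            candidates = sorted(
                itertools.combinations(range(n), k),
                key=lambda cuts: (-sum(jumps[c] for c in cuts), cuts),
            )
            for cuts in candidates:
                chunks = pieces_for(cuts)
                if all(_piece_span(c) <= max_span for c in chunks):
                    return chunks
    return pieces_for(tuple(range(n)))  # every boundary cut: nothing better exists


def end_alignments(aset: ContigAlignmentSet, t: Thresholds) -> list[ContigPiece]:
    """Contig-end alignments with the >5% overextension split rule.

    Cross-chromosome contigs are first split at chromosome boundaries (a
    reference span is undefined across chromosomes); each resulting run is
    then tested against ``contig_length * (1 + overextension_frac)`` and
    recursively split at the largest reference jumps when it fails.  Pieces
    whose terminal alignments never reach ``min_ctg_end_aln`` are reported
    with ``left_end``/``right_end`` of ``None``.
    """
    pieces: list[ContigPiece] = []
    for key, recs in aset:
        sample, hap, contig = key
        contig_len = recs[0].query_len
        # +epsilon: a span of exactly (1 + frac) x length is within bounds
        max_span = contig_len * (1.0 + t.overextension_frac) + 1e-6
        by_chrom: dict[str, list[AlignmentRecord]] = {}
        for r in recs:
            by_chrom.setdefault(r.target_name, []).append(r)
        index = 0
        for chrom in sorted(by_chrom):
            for chunk in _split_chunks(by_chrom[chrom], max_span):
                index += 1
                left = next((r for r in chunk if r.target_span >= t.min_ctg_end_aln), None)
                right = next(
                    (r for r in reversed(chunk) if r.target_span >= t.min_ctg_end_aln), None
                )
                if left is None or right is None:
                    pieces.append(ContigPiece(sample, hap, contig, index, chrom, chunk, None, None))
                    continue
                p_left = _outer_position(left, "left")
                p_right = _outer_position(right, "right")
                (lo, lo_rec), (hi, hi_rec) = sorted(
                    [(p_left, left), (p_right, right)], key=lambda x: x[0]
                )
                name = f"{contig}.{index}"
                le = ContigEnd(sample, hap, name, "left", chrom, lo, lo_rec.target_span, "end_alignment")
                re_ = ContigEnd(sample, hap, name, "right", chrom, hi, hi_rec.target_span, "end_alignment")
                pieces.append(ContigPiece(sample, hap, contig, index, chrom, chunk, le, re_))
    return pieces


def report_gaps(pieces: Sequence[ContigPiece]) -> list[GapRegion]:
    """Reference intervals between subsequent contig pieces of one haploid
    assembly.  Pieces are sorted per chromosome by left end; a gap is
    emitted whenever the running rightmost end lies strictly left of the
    next piece's left end (overlapping or abutting pieces emit nothing)."""
    usable = [p for p in pieces if p.has_ends]
    haps = {(p.sample, p.haplotype) for p in usable}
    if len(haps) > 1:
        raise UsageError(f"report_gaps expects one (sample, haplotype), got {sorted(haps)}")
    gaps: list[GapRegion] = []
    by_chrom: dict[str, list[ContigPiece]] = {}
    for p in usable:
        by_chrom.setdefault(p.chrom, []).append(p)
    for chrom, chrom_pieces in sorted(by_chrom.items()):
        chrom_pieces.sort(key=lambda p: (p.ref_start, p.ref_end))
        right_most = chrom_pieces[0]
        for nxt in chrom_pieces[1:]:
            if right_most.ref_end < nxt.ref_start:
                gaps.append(
                    GapRegion(
                        chrom, right_most.ref_end, nxt.ref_start,
                        f"{right_most.contig}.{right_most.piece_index}",
                        f"{nxt.contig}.{nxt.piece_index}",
                        nxt.sample, nxt.haplotype,
                    )
                )
            if nxt.ref_end > right_most.ref_end:
                right_most = nxt
    return gaps


def overextended_contigs(aset: ContigAlignmentSet, t: Thresholds) -> pd.DataFrame:
    """Contigs whose per-chromosome reference span strictly exceeds the
    contig length by more than ``overextension_frac``; one row per offending
    contig and chromosome with the span/length ratio."""
    rows = []
    for key, recs in aset:
        sample, hap, contig = key
        contig_len = recs[0].query_len
        by_chrom: dict[str, list[AlignmentRecord]] = {}
        for r in recs:
            by_chrom.setdefault(r.target_name, []).append(r)
        for chrom, chunk in sorted(by_chrom.items()):
            span = _piece_span(chunk)
            ratio = span / contig_len
            if span - contig_len > contig_len * t.overextension_frac + 1e-6:  # strict >

                rows.append(
                    {
                        "sample": sample, "hap": hap, "contig": contig,
                        "chrom": chrom, "contig_len": contig_len,
                        "span": span, "ratio": round(ratio, 4),
                    }
                )
    return pd.DataFrame(rows, columns=["sample", "hap", "contig", "chrom", "contig_len", "span", "ratio"])
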