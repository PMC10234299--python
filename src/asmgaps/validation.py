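"""Orthogonal validation: long-read gap spanning and phasing concordance.

*Gap spanning* asks whether an assembly gap could be closed with the
long-read data at hand: a read spans a gap when its alignment interval
strictly contains the gap (and the read maps with quality >= ``min_mapq``);
a gap with >= ``span_min_reads`` (default 10) spanning reads is considered
closable.

*Phasing concordance* compares a phased test assembly against truth-phased
variants: the genome is cut into ``phase_block`` (1-Mbp) blocks, each block
is assigned to truth haplotype 1 or 2 by majority vote of the test-H1
alleles it contains (ties and empty blocks stay unassigned), and
concordance is the fraction of assigned blocks whose assignment matches the
expectation.  Maximal runs of consecutive discordant blocks expose
large-scale switch errors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import Thresholds
from .contig_ends import GapRegion


@dataclass(frozen=True)
class SpanResult:
    gap: GapRegion
    n_spanning: int
    spanned: bool


def gap_spanning(
    gaps: Sequence[GapRegion],
    reads: pd.DataFrame,
    t: Thresholds,
    require_containment: bool = True,
) -> list[SpanResult]:
    """Count reads spanning each gap.

    ``reads`` is a BED-like table (`chrom start end [name] mapq`).  A read
    spans a gap when it fully contains it (``start < gap.start`` and
    ``end > gap.end``); with ``require_containment=False`` any overlap
    counts instead.  Reads below ``min_mapq`` are ignored.
    """
    kept = reads[reads["mapq"] >= t.min_mapq]
    chrom_arr = kept["chrom"].to_numpy()
    starts = kept["start"].to_numpy()
    ends = kept["end"].to_numpy()
    out = []
    for gap in gaps:
        on_chrom = chrom_arr == gap.chrom
        if require_containment:
            hits = on_chrom & (starts < gap.start) & (ends > gap.end)
        else:
            hits = on_chrom & (starts < gap.end) & (ends > gap.start)
        n = int(hits.sum())
        out.append(SpanResult(gap, n, n >= t.span_min_reads))
    return out


@dataclass(frozen=True)
class PhaseBlock:
    chrom: str
    start: int
    end: int
    assigned: str            # 'H1', 'H2' or 'unassigned'
    n_match_h1: int
    n_match_h2: int
    concordant: bool | None  # None when unassigned


@dataclass
class PhaseConcordance:
    blocks: list[PhaseBlock]
    per_chromosome: pd.DataFrame   # chrom, n_blocks, n_assigned, concordance_pct
    concordance_pct: float
    switch_runs: list[tuple[str, int, int]]  # maximal runs of discordant blocks


def phase_concordance(
    truth: pd.DataFrame,
    test: pd.DataFrame,
    chrom_lengths: Mapping[str, int],
    t: Thresholds,
    expected: str = "H1",
) -> PhaseConcordance:
    """Block-wise haplotype assignment of a test assembly against truth.

    ``truth`` columns: `chrom pos h1 h2` (alleles of truth haplotypes);
    ``test`` columns: `chrom pos allele` (the test assembly's haplotype-1
    allele at that position).  Positions missing from either table are
    ignored.  Each ``phase_block``-sized block is assigned to the truth
    haplotype matching the majority of its informative sites; concordance
    is the fraction of assigned blocks equal to ``expected``.
    """
    merged = truth.merge(test, on=["chrom", "pos"], how="inner")
    if merged.empty:
        raise ValueError("no overlapping variant positions between truth and test")
    merged["match_h1"] = merged["allele"] == merged["h1"]
    merged["match_h2"] = merged["allele"] == merged["h2"]

    blocks: list[PhaseBlock] = []
    for chrom in sorted(chrom_lengths):
        length = chrom_lengths[chrom]
        sub = merged[merged["chrom"] == chrom]
        for start in range(0, length, t.phase_block):
            end = min(start + t.phase_block, length)
            in_block = sub[(sub["pos"] >= start) & (sub["pos"] < end)]
            n1 = int(in_block["match_h1"].sum())
            n2 = int(in_block["match_h2"].sum())
            if n1 == n2:  # covers the zero-informative-site case too
                blocks.append(PhaseBlock(chrom, start, end, "unassigned", n1, n2, None))
                continue
            assigned = "H1" if n1 > n2 else "H2"
            blocks.append(
                PhaseBlock(chrom, start, end, assigned, n1, n2, assigned == expected)
            )

    rows = []
    for chrom in sorted(chrom_lengths):
        mine = [b for b in blocks if b.chrom == chrom]
        assigned = [b for b in mine if b.concordant is not None]
        good = sum(1 for b in assigned if b.concordant)
        rows.append(
            {
                "chrom": chrom,
                "n_blocks": len(mine),
                "n_assigned": len(assigned),
                "concordance_pct": 100.0 * good / len(assigned) if assigned else float("nan"),
            }
        )
    per_chrom = pd.DataFrame(rows, columns=["chrom", "n_blocks", "n_assigned", "concordance_pct"])
    assigned_all = [b for b in blocks if b.concordant is not None]
    overall = (
        100.0 * sum(1 for b in assigned_all if b.concordant) / len(assigned_all)
        if assigned_all
        else float("nan")
    )

    switch_runs: list[tuple[str, int, int]] = []
    for chrom in sorted(chrom_lengths):
        run_start = None
        run_end = None
        for b in [b for b in blocks if b.chrom == chrom]:
            if b.concordant is False:
                if run_start is None:
                    run_start = b.start
                run_end = b.end
            elif b.concordant is True and run_start is not None:
                switch_runs.append((chrom, run_start, run_end))
                run_start = run_end = None
        if run_start is not None:
            switch_runs.append((chrom, run_start, run_end))

    return PhaseConcordance(blocks, per_chrom, overall, switch_runs)
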