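"""Dinucleotide low-complexity tract detection and GA/TC window flagging.

Long tandem tracts of GA/TC (and AT-rich) dinucleotides deplete HiFi read
coverage and are a major cause of assembly breaks.  Two detectors:

* tract sizing — overlapping occurrences of the tracked dinucleotides (TA,
  TC, GA) are counted in non-overlapping 100-bp bins; per-dinucleotide
  Z-scores over a sequence's bins mark enriched bins (Z >= 1.96), and
  maximal runs of enriched bins become tracts sized run-length x bin size.
* window flagging — 1-kbp sliding windows (100-bp step) where at least 80%
  of bases are covered by GA or TC dinucleotide occurrences; overlapping
  flagged windows are merged into one interval.  The same machinery with
  the AT/TA pair flags AT-rich windows.

"GA/TC content" is measured as the fraction of bases covered by GA- or
TC-dinucleotide occurrences: 1.0 on a pure tract, ~0.23 on random sequence,
so the 80% threshold separates them cleanly.  Occurrences straddling a bin
boundary are counted in neither bin; the straddle count is recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment_io import BedInterval
from .config import Thresholds

TRACKED = ("TA", "TC", "GA")
AT_PAIRS = ("AT", "TA")
GATC_PAIRS = ("GA", "TC")


@dataclass(frozen=True)
class Tract:
    start: int
    end: int
    size: int
    dinucleotide: str


@dataclass
class DinucleotideProfile:
    sequence_id: str
    bin_size: int
    n_bins: int
    last_bin_length: int
    counts: dict[str, np.ndarray]           # dinucleotide -> per-bin counts
    straddled: dict[str, int]               # occurrences lost at bin boundaries
    zscores: dict[str, np.ndarray] = field(default_factory=dict)
    enriched: dict[str, np.ndarray] = field(default_factory=dict)
    degenerate: dict[str, bool] = field(default_factory=dict)  # sd == 0
    tracts: list[Tract] = field(default_factory=list)


def _pair_mask(seq: np.ndarray, dinuc: str) -> np.ndarray:
    """Boolean array over positions i marking seq[i:i+2] == dinuc."""
    a, b = dinuc.encode()
    return (seq[:-1] == a) & (seq[1:] == b)


def dinucleotide_profile(
    seq: str, t: Thresholds, sequence_id: str = "seq", tracked: tuple[str, ...] = TRACKED
) -> DinucleotideProfile:
    """Count overlapping occurrences of each tracked dinucleotide per
    non-overlapping ``dinuc_bin``-sized bin (both bases inside the bin);
    the final partial bin is kept and its length recorded."""
    if len(seq) < 2:
        raise ValueError("sequence must be at least 2 bp")
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    bin_size = t.dinuc_bin
    n_bins = (len(seq) + bin_size - 1) // bin_size
    last_len = len(seq) - (n_bins - 1) * bin_size
    counts: dict[str, np.ndarray] = {}
    straddled: dict[str, int] = {}
    boundary = np.arange(1, n_bins) * bin_size - 1  # pair positions straddling bins
    for dinuc in tracked:
        mask = _pair_mask(arr, dinuc)
        on_boundary = boundary[boundary < mask.size]
        straddled[dinuc] = int(mask[on_boundary].sum()) if on_boundary.size else 0
        kept = mask.copy()
        kept[on_boundary[on_boundary < kept.size]] = False
        per_bin = np.zeros(n_bins, dtype=np.int64)
        idx = np.flatnonzero(kept) // bin_size
        np.add.at(per_bin, idx, 1)
        counts[dinuc] = per_bin
    return DinucleotideProfile(
        sequence_id=sequence_id,
        bin_size=bin_size,
        n_bins=n_bins,
        last_bin_length=last_len,
        counts=counts,
        straddled=straddled,
    )


def enriched_tracts(profile: DinucleotideProfile, t: Thresholds) -> list[Tract]:
    """Mark bins with per-dinucleotide Z >= ``z_cutoff`` as enriched and
    collapse maximal runs of enriched bins into tracts (size = run length x
    bin size).  A dinucleotide with zero variance across bins yields no
    tracts and is flagged degenerate."""
    if profile.n_bins < 2:
        raise ValueError("need at least 2 bins for Z-scores")
    tracts: list[Tract] = []
    for dinuc, per_bin in profile.counts.items():
        mean = per_bin.mean()
        sd = per_bin.std()
        if sd == 0:
            profile.degenerate[dinuc] = True
            profile.zscores[dinuc] = np.zeros_like(per_bin, dtype=float)
            profile.enriched[dinuc] = np.zeros_like(per_bin, dtype=bool)
            continue
        profile.degenerate[dinuc] = False
        z = (per_bin - mean) / sd
        flags = z >= t.z_cutoff
        profile.zscores[dinuc] = z
        profile.enriched[dinuc] = flags
        run_start = None
        for i, on in enumerate(list(flags) + [False]):
            if on and run_start is None:
                run_start = i
            elif not on and run_start is not None:
                n_run = i - run_start
                tracts.append(
                    Tract(
                        start=run_start * profile.bin_size,
                        end=i * profile.bin_size,
                        size=n_run * profile.bin_size,
                        dinucleotide=dinuc,
                    )
                )
                run_start = None
    tracts.sort(key=lambda tr: (tr.start, tr.dinucleotide))
    profile.tracts = tracts
    return tracts


def _coverage_mask(seq: np.ndarray, pairs: tuple[str, ...]) -> np.ndarray:
    """Per-base boolean: covered by an occurrence of any of ``pairs``."""
    covered = np.zeros(seq.size, dtype=bool)
    for dinuc in pairs:
        hits = _pair_mask(seq, dinuc)
        covered[:-1] |= hits
        covered[1:] |= hits
    return covered


def _flag_windows(
    seq: str,
    chrom: str,
    pairs: tuple[str, ...],
    window: int,
    frac: float,
    step: int,
    label: str,
) -> list[BedInterval]:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    if arr.size < window:
        return []
    covered = _coverage_mask(arr, pairs)
    cum = np.concatenate([[0], np.cumsum(covered)])
    starts = np.arange(0, arr.size - window + 1, step)
    content = (cum[starts + window] - cum[starts]) / window
    flagged = content >= frac
    out: list[tuple[int, int]] = []
    for s in starts[flagged]:
        s = int(s)
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], s + window)
        else:
            out.append((s, s + window))
    return [BedInterval(chrom, s, e, label, ".", ".") for s, e in out]


def gatc_windows(
    sequences: dict[str, str] | str, t: Thresholds, step: int = 100, chrom: str = "seq"
) -> list[BedInterval]:
    """Merged intervals of ``gatc_window``-sized windows (default 1 kbp,
    100-bp step) whose GA/TC dinucleotide content is >= ``gatc_frac``."""
    if isinstance(sequences, str):
        sequences = {chrom: sequences}
    out: list[BedInterval] = []
    for name, seq in sequences.items():
        out.extend(_flag_windows(seq, name, GATC_PAIRS, t.gatc_window, t.gatc_frac, step, "GA/TC"))
    return out


def at_windows(
    sequences: dict[str, str] | str, t: Thresholds, step: int = 100, chrom: str = "seq"
) -> list[BedInterval]:
    """Same machinery as :func:`gatc_windows` with the AT/TA pair."""
    if isinstance(sequences, str):
        sequences = {chrom: sequences}
    out: list[BedInterval] = []
    for name, seq in sequences.items():
        out.extend(_flag_windows(seq, name, AT_PAIRS, t.gatc_window, t.gatc_frac, step, "AT"))
    return out
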