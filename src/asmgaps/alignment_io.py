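"""Reading, filtering and grouping of contig-to-reference alignments.

Alignments arrive as minimap2-style PAF (12 mandatory tab-separated columns,
0-based half-open intervals on both axes). :func:`read_paf` applies the three
record-level filters used throughout the pipeline — mapping quality, minimum
alignment width on the reference, and minimum total contig size — and
:func:`group_by_contig` organizes the survivors per contig, sorted along the
contig (query) axis, which is the order every downstream stage walks them in.

Sample and haplotype identity is file provenance: one PAF per haploid
assembly, names supplied by the caller, never parsed out of contig names.

Shared BED/FASTA/TSV helpers for the rest of the package also live here.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, NamedTuple, Sequence

import pandas as pd

from .config import Thresholds

log = logging.getLogger(__name__)


class PafParseError(ValueError):
    """Malformed PAF row (wrong column count, bad coordinate, start >= end)."""


@dataclass(frozen=True)
class AlignmentRecord:
    """One filtered PAF row."""

    query_name: str
    query_len: int
    query_start: int
    query_end: int
    strand: str  # '+' or '-'
    target_name: str
    target_len: int
    target_start: int
    target_end: int
    residue_matches: int
    block_len: int
    mapq: int
    sample: str = ""
    haplotype: str = ""

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise PafParseError(f"bad strand {self.strand!r}")
        for axis, start, end, length in (
            ("query", self.query_start, self.query_end, self.query_len),
            ("target", self.target_start, self.target_end, self.target_len),
        ):
            if not (0 <= start < end <= length):
                raise PafParseError(
                    f"bad {axis} interval [{start}, {end}) for length {length}"
                )

    @property
    def target_span(self) -> int:
        return self.target_end - self.target_start

    @property
    def query_span(self) -> int:
        return self.query_end - self.query_start

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.sample, self.haplotype, self.query_name)


def parse_paf_line(line: str, lineno: int = 0, sample: str = "", haplotype: str = "") -> AlignmentRecord | None:
    """Parse a single PAF row; returns ``None`` for secondary alignments
    (``tp:A:S`` tag), which are dropped with a warning."""
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 12:
        raise PafParseError(f"line {lineno}: expected >=12 columns, got {len(fields)}")
    for tag in fields[12:]:
        if tag == "tp:A:S":
            log.warning("line %d: dropping secondary alignment of %s", lineno, fields[0])
            return None
    try:
        rec = AlignmentRecord(
            query_name=fields[0],
            query_len=int(fields[1]),
            query_start=int(fields[2]),
            query_end=int(fields[3]),
            strand=fields[4],
            target_name=fields[5],
            target_len=int(fields[6]),
            target_start=int(fields[7]),
            target_end=int(fields[8]),
            residue_matches=int(fields[9]),
            block_len=int(fields[10]),
            mapq=int(fields[11]),
            sample=sample,
            haplotype=haplotype,
        )
    except (ValueError, PafParseError) as exc:
        raise PafParseError(f"line {lineno}: {exc}") from exc
    return rec


def filter_records(records: Iterable[AlignmentRecord], t: Thresholds) -> list[AlignmentRecord]:
    """Keep records with mapq >= ``min_mapq``, reference width >=
    ``min_aln_width`` and contig size >= ``min_ctg_size``; order preserved.
    Idempotent by construction."""
    return [
        r
        for r in records
        if r.mapq >= t.min_mapq
        and r.target_span >= t.min_aln_width
        and r.query_len >= t.min_ctg_size
    ]


def read_paf(
    path,
    t: Thresholds,
    sample: str = "",
    haplotype: str = "",
) -> list[AlignmentRecord]:
    """Read and filter a PAF file into :class:`AlignmentRecord` objects,
    preserving input order."""
    records: list[AlignmentRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            rec = parse_paf_line(line, lineno, sample=sample, haplotype=haplotype)
            if rec is not None:
                records.append(rec)
    return filter_records(records, t)


class DataError(ValueError):
    """Inconsistent input data (e.g. conflicting contig lengths)."""


@dataclass
class ContigAlignmentSet:
    """Filtered alignments grouped per (sample, haplotype, contig), each
    group sorted by query_start (ties: target_start, then target_name)."""

    groups: dict[tuple[str, str, str], list[AlignmentRecord]] = field(default_factory=dict)

    def __iter__(self) -> Iterator[tuple[tuple[str, str, str], list[AlignmentRecord]]]:
        return iter(self.groups.items())

    def __len__(self) -> int:
        return len(self.groups)

    def contig_length(self, key: tuple[str, str, str]) -> int:
        return self.groups[key][0].query_len

    def haplotypes(self) -> list[tuple[str, str]]:
        return sorted({(s, h) for (s, h, _) in self.groups})

    def subset(self, sample: str, haplotype: str) -> "ContigAlignmentSet":
        return ContigAlignmentSet(
            {k: v for k, v in self.groups.items() if k[0] == sample and k[1] == haplotype}
        )


def group_by_contig(records: Sequence[AlignmentRecord]) -> ContigAlignmentSet:
    """Bucket records by (sample, haplotype, contig) and sort each bucket
    along the contig."""
    groups: dict[tuple[str, str, str], list[AlignmentRecord]] = {}
    for rec in records:
        groups.setdefault(rec.key, []).append(rec)
    for key, recs in groups.items():
        lengths = {r.query_len for r in recs}
        if len(lengths) > 1:
            raise DataError(f"contig {key}: inconsistent query_len values {sorted(lengths)}")
        recs.sort(key=lambda r: (r.query_start, r.target_start, r.target_name))
    return ContigAlignmentSet(groups)


# ---------------------------------------------------------------------------
# Shared BED / TSV / FASTA helpers
# ---------------------------------------------------------------------------


class BedInterval(NamedTuple):
    chrom: str
    start: int
    end: int
    name: str = "."
    score: str = "."
    strand: str = "."


def read_bed(path) -> list[BedInterval]:
    """Read a BED3+ file (0-based half-open); `#`/track lines skipped."""
    out: list[BedInterval] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            out.append(
                BedInterval(
                    f[0],
                    int(f[1]),
                    int(f[2]),
                    f[3] if len(f) > 3 else ".",
                    f[4] if len(f) > 4 else ".",
                    f[5] if len(f) > 5 else ".",
                )
            )
    return out


def write_bed(path, intervals: Iterable[BedInterval], t: Thresholds | None = None, extra_header: Sequence[str] = ()) -> None:
    with open(path, "w") as fh:
        if t is not None:
            fh.write(t.header() + "\n")
        for line in extra_header:
            fh.write(line.rstrip("\n") + "\n")
        for iv in intervals:
            fh.write("\t".join(str(x) for x in iv) + "\n")


def write_table(path, df: pd.DataFrame, t: Thresholds | None = None, extra_header: Sequence[str] = ()) -> None:
    """TSV writer; thresholds echoed as a leading `## thresholds:` line."""
    with open(path, "w") as fh:
        if t is not None:
            fh.write(t.header() + "\n")
        for line in extra_header:
            fh.write(line.rstrip("\n") + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def read_fasta(path) -> dict[str, str]:
    """Load a FASTA file into an id -> uppercase sequence dict."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, sequences: dict[str, str], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def records_to_frame(records: Sequence[AlignmentRecord]) -> pd.DataFrame:
    """Normalized alignments as a BED-like table
    (`chrom start end contig contig_start contig_end strand mapq sample hap`)."""
    return pd.DataFrame(
        {
            "chrom": [r.target_name for r in records],
            "start": [r.target_start for r in records],
            "end": [r.target_end for r in records],
            "contig": [r.query_name for r in records],
            "contig_start": [r.query_start for r in records],
            "contig_end": [r.query_end for r in records],
            "strand": [r.strand for r in records],
            "mapq": [r.mapq for r in records],
            "sample": [r.sample for r in records],
            "hap": [r.haplotype for r in records],
        }
    )
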