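"""Synthetic annotated reference and fragmented diploid assembly.

Real evaluations of phased human assemblies need ~100 GB of consortium data;
this module builds, from a seed, a small reference carrying the feature
classes that matter at assembly breaks (segmental-duplication blocks with a
controlled identity, satellite arrays, low-complexity dinucleotide tracts,
gene intervals) and a diploid assembly derived from it with planted,
ground-truthed events: inter-contig gaps, inversions, expansions (novel
sequence in the contig), contractions (reference sequence missing from the
contig), embedded duplicate contigs and tandem copy-number gains.

The truth alignment (PAF) is constructed analytically, one row per maximal
co-linear segment, rather than by running an aligner, so every downstream
stage can be tested against exact expected coordinates. Background sequence
is uniform-random ACGT from ``numpy.random.default_rng(seed)``; identical
spec + plan + seed give byte-identical FASTA/PAF/BED output.

No read-level simulation (no HiFi/ONT error models) is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from ._intervals import overlaps
from .alignment_io import AlignmentRecord, BedInterval, write_bed, write_fasta

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

EVENT_KINDS = ("gap", "inversion", "expansion", "contraction", "embedded_contig", "cn_gain")


class SpecificationError(ValueError):
    """A planted feature or event violates the generator invariants."""


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Substitute each base independently with probability ``rate`` (always
    to a different base), emulating diverged duplication copies."""
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.flatnonzero(rng.random(arr.size) < rate)
    for i in hits:
        choices = [b for b in (b"A", b"C", b"G", b"T") if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return arr.tobytes().decode()


# ---------------------------------------------------------------------------
# Reference
# ---------------------------------------------------------------------------


@dataclass
class ReferenceSpec:
    """Recipe for the synthetic reference.

    ``sd_blocks`` entries are ``(length, identity, copies)``;
    ``satellite_arrays`` are ``(length, monomer)``; ``gatc_tracts`` are
    ``(length, dinucleotide)`` with dinucleotide in {GA, TC, AT, TA};
    ``gene_intervals`` are explicit ``(chrom_index, start, end)`` triples.
    """

    n_chromosomes: int = 1
    chrom_length: int = 1_000_000
    sd_blocks: list[tuple[int, float, int]] = field(default_factory=list)
    satellite_arrays: list[tuple[int, str]] = field(default_factory=list)
    gatc_tracts: list[tuple[int, str]] = field(default_factory=list)
    gene_intervals: list[tuple[int, int, int]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1 or self.chrom_length < 1:
            raise SpecificationError("need >=1 chromosome of positive length")
        for _, dinuc in self.gatc_tracts:
            if dinuc not in {"GA", "TC", "AT", "TA"}:
                raise SpecificationError(f"unsupported tract dinucleotide {dinuc!r}")
        total = sum(l * c for l, _, c in self.sd_blocks)
        total += sum(l for l, _ in self.satellite_arrays)
        total += sum(l for l, _ in self.gatc_tracts)
        if total >= self.n_chromosomes * self.chrom_length:
            raise SpecificationError("total feature length must be < total reference length")


@dataclass
class Reference:
    sequences: dict[str, str]
    tracks: dict[str, list[BedInterval]]
    seed: int

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(outdir / "reference.fa", self.sequences)
        header = [f"## seed: {self.seed}"]
        for name, ivs in self.tracks.items():
            fname = name.lower().replace("/", "").replace("+", "") + ".bed"
            write_bed(outdir / fname, ivs, extra_header=header)


def _place_features(
    rng: np.random.Generator,
    spec: ReferenceSpec,
    features: list[tuple[str, int, object]],
    margin: int = 2_000,
) -> list[tuple[int, int, int, str, object]]:
    """Place ``(kind, length, payload)`` features at seeded random
    non-overlapping positions; returns ``(chrom_idx, start, end, kind,
    payload)``.  Overcrowding that defeats placement is a specification
    error."""
    placed: list[tuple[int, int, int, str, object]] = []
    occupied: dict[int, list[tuple[int, int]]] = {i: [] for i in range(spec.n_chromosomes)}
    for ci, s, e in spec.gene_intervals:
        # genes may overlap other annotation classes, only repeats must not
        if not (0 <= s < e <= spec.chrom_length) or ci >= spec.n_chromosomes:
            raise SpecificationError(f"gene interval ({ci},{s},{e}) outside reference")
    for kind, length, payload in features:
        for _ in range(2_000):
            ci = int(rng.integers(0, spec.n_chromosomes))
            start = int(rng.integers(0, spec.chrom_length - length + 1))
            candidate = (start - margin, start + length + margin)
            if all(not overlaps(candidate, iv) for iv in occupied[ci]):
                occupied[ci].append((start, start + length))
                placed.append((ci, start, start + length, kind, payload))
                break
        else:
            raise SpecificationError(f"cannot place feature {kind} of length {length}; reference too crowded")
    return placed


def build_reference(spec: ReferenceSpec) -> Reference:
    """Generate the reference FASTA plus one annotation track per feature
    class (SD with identity in the score column, satellite, GA/TC tract,
    AT tract, gene)."""
    rng = np.random.default_rng(spec.seed)
    chrom_names = [f"chr{i + 1}" for i in range(spec.n_chromosomes)]
    seqs = [
        np.frombuffer(random_sequence(rng, spec.chrom_length).encode(), dtype="S1").copy()
        for _ in chrom_names
    ]

    features: list[tuple[str, int, object]] = []
    for bi, (length, identity, copies) in enumerate(spec.sd_blocks):
        base = random_sequence(rng, length)
        for copy in range(copies):
            copy_seq = base if copy == 0 else mutate(rng, base, 1.0 - identity)
            features.append(("sd", length, (f"SD{bi}", identity, copy_seq)))
    for ai, (length, monomer) in enumerate(spec.satellite_arrays):
        seq = (monomer * (length // len(monomer) + 1))[:length]
        features.append(("satellite", length, (f"SAT{ai}", seq)))
    for ti, (length, dinuc) in enumerate(spec.gatc_tracts):
        seq = (dinuc * (length // 2 + 1))[:length]
        track = "at" if dinuc in {"AT", "TA"} else "gatc"
        features.append((track, length, (f"{dinuc}{ti}", dinuc, seq)))

    placed = _place_features(rng, spec, features)
    tracks: dict[str, list[BedInterval]] = {"SD": [], "SAT": [], "GA/TC": [], "AT": [], "GENE": []}
    for ci, start, end, kind, payload in placed:
        chrom = chrom_names[ci]
        if kind == "sd":
            name, identity, seq = payload
            tracks["SD"].append(BedInterval(chrom, start, end, name, f"{identity:.4f}", "+"))
        elif kind == "satellite":
            name, seq = payload
            tracks["SAT"].append(BedInterval(chrom, start, end, name, ".", "+"))
        else:
            name, dinuc, seq = payload
            track = "AT" if kind == "at" else "GA/TC"
            tracks[track].append(BedInterval(chrom, start, end, name, dinuc, "+"))
        seqs[ci][start:end] = np.frombuffer(seq.encode(), dtype="S1")
    for gi, (ci, s, e) in enumerate(spec.gene_intervals):
        tracks["GENE"].append(BedInterval(chrom_names[ci], s, e, f"gene{gi + 1}", ".", "+"))
    for name in tracks:
        tracks[name].sort(key=lambda iv: (iv.chrom, iv.start, iv.end))

    sequences = {name: arr.tobytes().decode() for name, arr in zip(chrom_names, seqs)}
    return Reference(sequences=sequences, tracks=tracks, seed=spec.seed)


# ---------------------------------------------------------------------------
# Assembly simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TruthEvent:
    """One planted event.

    ``(chrom, start, end)`` is the affected reference interval; expansions
    use a zero-length interval (``start == end``) marking the insertion
    point, with ``size`` novel bases inserted into the contig.
    """

    kind: str
    chrom: str
    start: int
    end: int
    size: int
    haplotype: str

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise SpecificationError(f"unknown event kind {self.kind!r}")
        if self.kind == "expansion":
            if self.start != self.end or self.size <= 0:
                raise SpecificationError("expansion needs start == end and size > 0")
        else:
            if not self.start < self.end:
                raise SpecificationError(f"{self.kind} needs start < end")
            if self.size != self.end - self.start:
                raise SpecificationError(f"{self.kind} size must equal end - start")


@dataclass
class AssemblyPlan:
    events: list[TruthEvent] = field(default_factory=list)
    haplotypes: tuple[str, str] = ("h1", "h2")

    def __post_init__(self) -> None:
        for hap in {e.haplotype for e in self.events}:
            per = sorted(
                (e for e in self.events if e.haplotype == hap and e.kind != "embedded_contig"),
                key=lambda e: (e.chrom, e.start),
            )
            for a, b in zip(per, per[1:]):
                if a.chrom == b.chrom and b.start < a.end:
                    raise SpecificationError(f"overlapping events on {hap}: {a} / {b}")

    def for_haplotype(self, hap: str) -> list[TruthEvent]:
        return sorted(
            (e for e in self.events if e.haplotype == hap),
            key=lambda e: (e.chrom, e.start, e.end),
        )


@dataclass
class SyntheticAssembly:
    contigs: dict[str, dict[str, str]]          # haplotype -> contig name -> sequence
    alignments: list[AlignmentRecord]           # truth PAF rows, mapq 60
    events: list[TruthEvent]
    seed: int

    def paf_lines(self) -> list[str]:
        lines = []
        for r in self.alignments:
            lines.append(
                "\t".join(
                    str(x)
                    for x in (
                        r.query_name, r.query_len, r.query_start, r.query_end, r.strand,
                        r.target_name, r.target_len, r.target_start, r.target_end,
                        r.residue_matches, r.block_len, r.mapq,
                    )
                )
            )
        return lines

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for hap, contigs in self.contigs.items():
            write_fasta(outdir / f"assembly_{hap}.fa", contigs)
        for hap in self.contigs:
            with open(outdir / f"truth_{hap}.paf", "w") as fh:
                for r, line in zip(self.alignments, self.paf_lines()):
                    if r.haplotype == hap:
                        fh.write(line + "\n")
        truth = [
            BedInterval(e.chrom, e.start, e.end, f"{e.kind}:{e.haplotype}", str(e.size), ".")
            for e in self.events
        ]
        write_bed(outdir / "truth_events.bed", truth, extra_header=[f"## seed: {self.seed}"])


def _close_contig(
    parts: list[tuple],
    chrom: str,
    chrom_len: int,
    name: str,
    hap: str,
    sample: str,
    ref_seq: str,
    rng: np.random.Generator,
) -> tuple[str, list[AlignmentRecord]]:
    """Materialize one contig from its part list and emit its truth PAF rows."""
    # merge query- and target-adjacent forward blocks into maximal co-linear segments
    merged: list[tuple] = []
    for part in parts:
        if (
            merged
            and part[0] == "ref"
            and merged[-1][0] == "ref"
            and part[3] == "+"
            and merged[-1][3] == "+"
            and merged[-1][2] == part[1]
        ):
            merged[-1] = ("ref", merged[-1][1], part[2], "+")
        else:
            merged.append(part)
    merged = [p for p in merged if p[0] == "novel" or p[2] > p[1]]

    seq_parts: list[str] = []
    rows: list[tuple] = []  # (qstart, qend, strand, tstart, tend)
    offset = 0
    for part in merged:
        if part[0] == "novel":
            novel = part[1]
            seq_parts.append(novel)
            offset += len(novel)
            continue
        _, s, e, strand = part
        segment = ref_seq[s:e]
        if strand == "-":
            segment = reverse_complement(segment)
        seq_parts.append(segment)
        rows.append((offset, offset + (e - s), strand, s, e))
        offset += e - s
    seq = "".join(seq_parts)
    records = [
        AlignmentRecord(
            query_name=name, query_len=len(seq), query_start=qs, query_end=qe,
            strand=strand, target_name=chrom, target_len=chrom_len,
            target_start=ts, target_end=te, residue_matches=te - ts,
            block_len=te - ts, mapq=60, sample=sample, haplotype=hap,
        )
        for qs, qe, strand, ts, te in rows
    ]
    return seq, records


def simulate_assembly(
    reference: Reference,
    plan: AssemblyPlan,
    sample: str = "sample1",
    seed: int | None = None,
    inject_low_mapq: int = 0,
) -> SyntheticAssembly:
    """Derive per-haplotype contigs from the reference and the planted
    events, together with the analytic truth PAF (one row per maximal
    co-linear segment, synthetic mapq 60).

    ``inject_low_mapq`` appends that many duplicated alignment rows with
    mapq 5 (and no contig sequence) to exercise mapping-quality filtering.
    """
    seed = reference.seed if seed is None else seed
    rng = np.random.default_rng(seed + 1)
    contigs: dict[str, dict[str, str]] = {}
    alignments: list[AlignmentRecord] = []

    for hap in plan.haplotypes:
        contigs[hap] = {}
        events = plan.for_haplotype(hap)
        for chrom, ref_seq in reference.sequences.items():
            chrom_len = len(ref_seq)
            chrom_events = [e for e in events if e.chrom == chrom]
            for e in chrom_events:
                if e.end > chrom_len:
                    raise SpecificationError(f"event {e} outside reference bounds")
            parts: list[tuple] = []
            finished: list[list[tuple]] = []
            embedded: list[TruthEvent] = []
            cur = 0
            for e in chrom_events:
                if e.kind == "embedded_contig":
                    embedded.append(e)
                    continue
                if e.start > cur:
                    parts.append(("ref", cur, e.start, "+"))
                if e.kind == "gap":
                    finished.append(parts)
                    parts = []
                elif e.kind == "inversion":
                    parts.append(("ref", e.start, e.end, "-"))
                elif e.kind == "contraction":
                    pass  # reference segment absent from the contig
                elif e.kind == "expansion":
                    parts.append(("novel", random_sequence(rng, e.size)))
                elif e.kind == "cn_gain":
                    parts.append(("ref", e.start, e.end, "+"))
                    parts.append(("ref", e.start, e.end, "+"))
                cur = e.end
            if cur < chrom_len:
                parts.append(("ref", cur, chrom_len, "+"))
            if parts:
                finished.append(parts)

            for idx, contig_parts in enumerate(p for p in finished if p):
                name = f"{hap}_{chrom}_ctg{idx + 1}"
                seq, rows = _close_contig(
                    contig_parts, chrom, chrom_len, name, hap, sample, ref_seq, rng
                )
                if seq:
                    contigs[hap][name] = seq
                    alignments.extend(rows)
            for ei, e in enumerate(embedded):
                name = f"{hap}_{chrom}_emb{ei + 1}"
                seq = ref_seq[e.start:e.end]
                contigs[hap][name] = seq
                alignments.append(
                    AlignmentRecord(
                        query_name=name, query_len=len(seq), query_start=0,
                        query_end=len(seq), strand="+", target_name=chrom,
                        target_len=chrom_len, target_start=e.start, target_end=e.end,
                        residue_matches=len(seq), block_len=len(seq), mapq=60,
                        sample=sample, haplotype=hap,
                    )
                )

    if inject_low_mapq:
        pool = [r for r in alignments if r.target_span > 2_000]
        for i in range(inject_low_mapq):
            src = pool[int(rng.integers(0, len(pool)))]
            alignments.append(
                AlignmentRecord(
                    query_name=src.query_name, query_len=src.query_len,
                    query_start=src.query_start, query_end=src.query_start + 1_500,
                    strand=src.strand, target_name=src.target_name,
                    target_len=src.target_len, target_start=src.target_start,
                    target_end=src.target_start + 1_500, residue_matches=1_400,
                    block_len=1_500, mapq=5, sample=src.sample, haplotype=src.haplotype,
                )
            )

    return SyntheticAssembly(contigs=contigs, alignments=alignments, events=plan.events, seed=seed)


def verify_truth(reference: Reference, assembly: SyntheticAssembly) -> None:
    """Self-consistency: every truth PAF row's query slice must reproduce the
    reference slice (strand-aware). Raises AssertionError on mismatch."""
    for r in assembly.alignments:
        if r.mapq < 60:
            continue  # injected low-quality rows are deliberately bogus
        contig = assembly.contigs[r.haplotype][r.query_name]
        q = contig[r.query_start:r.query_end]
        t = reference.sequences[r.target_name][r.target_start:r.target_end]
        if r.strand == "-":
            q = reverse_complement(q)
        assert q == t, f"truth mismatch for {r.query_name} [{r.query_start},{r.query_end})"


# ---------------------------------------------------------------------------
# Canonical demo dataset: a 10-Mbp annotated chromosome, diploid assembly
# with 12 gaps, 6 contractions, 6 expansions, 2 inversions, 3 embedded
# contigs — enough planted structure to exercise every stage in seconds.
# ---------------------------------------------------------------------------


def demo_reference_spec(seed: int = 0) -> ReferenceSpec:
    return ReferenceSpec(
        n_chromosomes=1,
        chrom_length=10_000_000,
        sd_blocks=[(60_000, 0.99, 2), (40_000, 0.98, 2)],
        satellite_arrays=[(120_000, "AATGG"), (80_000, "TTCCA")],
        gatc_tracts=[(3_000, "GA"), (1_600, "TC"), (2_400, "AT")],
        gene_intervals=[(0, 1_200_000, 1_260_000), (0, 4_500_000, 4_580_000), (0, 8_200_000, 8_230_000)],
        seed=seed,
    )


def demo_assembly_plan(reference: Reference, seed: int = 0) -> AssemblyPlan:
    """Plant the canonical event set at seeded random positions, keeping
    events >=250 kbp apart so each flanking contig piece stays alignable."""
    rng = np.random.default_rng(seed + 17)
    chrom = next(iter(reference.sequences))
    chrom_len = len(reference.sequences[chrom])
    wanted = (
        [("gap", h, int(rng.integers(20_000, 100_000))) for h in ("h1",) * 6 + ("h2",) * 6]
        + [("contraction", h, int(rng.integers(5_000, 50_000))) for h in ("h1",) * 3 + ("h2",) * 3]
        + [("expansion", h, int(rng.integers(5_000, 50_000))) for h in ("h1",) * 3 + ("h2",) * 3]
        + [("inversion", h, int(rng.integers(120_000, 250_000))) for h in ("h1", "h2")]
        + [("embedded_contig", h, int(rng.integers(150_000, 350_000))) for h in ("h1", "h1", "h2")]
    )
    events: list[TruthEvent] = []
    occupied: dict[str, list[tuple[int, int]]] = {"h1": [], "h2": []}
    margin = 250_000
    for kind, hap, size in wanted:
        span = 0 if kind == "expansion" else size
        for _ in range(10_000):
            start = int(rng.integers(margin, chrom_len - margin - span))
            cand = (start - margin, start + span + margin)
            if all(not overlaps(cand, iv) for iv in occupied[hap]):
                occupied[hap].append((start, start + max(span, 1)))
                events.append(TruthEvent(kind, chrom, start, start + span, size, hap))
                break
        else:  # pragma: no cover - demo scale never triggers this
            raise SpecificationError("demo plan placement failed")
    return AssemblyPlan(events=events)


def simulate_demo(seed: int = 0, sample: str = "sample1") -> tuple[Reference, AssemblyPlan, SyntheticAssembly]:
    spec = demo_reference_spec(seed)
    reference = build_reference(spec)
    plan = demo_assembly_plan(reference, seed)
    assembly = simulate_assembly(reference, plan, sample=sample, seed=seed)
    return reference, plan, assembly
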