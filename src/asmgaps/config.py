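"""Run-wide thresholds.

Every numeric cutoff used by the pipeline lives in a single immutable
:class:`Thresholds` object so that all stages share one source of truth and
every output file can echo the exact parameterization it was produced under.

Defaults are the values used for evaluating human phased assemblies against a
complete (T2T) reference: alignments are kept at mapping quality >= 10 and
width >= 1 kbp from contigs >= 100 kbp; contig-end alignments must cover
>= 50 kbp (>= 25 kbp for "simple" ends); a contig is split into pieces when
its reference span exceeds its length by more than 5%; feature proximity for
end annotation is 10 kbp; and so on.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Mapping


class ConfigError(ValueError):
    """A threshold key is unknown or a value violates an invariant."""


# field name -> (kind, meaning); kind drives parsing and validation
_INT_SIZE = "size"      # positive integer number of base pairs / copies / counts
_NONNEG_INT = "nonneg"  # integer >= 0
_FRACTION = "fraction"  # real in (0, 1]
_POS_REAL = "posreal"   # real > 0


@dataclass(frozen=True)
class Thresholds:
    """Immutable bundle of every numeric threshold used by the pipeline."""

    #: minimum alignment mapping quality (0 disables the filter)
    min_mapq: int = 10
    #: minimum alignment width on the reference axis, bp
    min_aln_width: int = 1_000
    #: minimum total contig size, bp
    min_ctg_size: int = 100_000
    #: minimum size of a terminal alignment anchoring a contig-end alignment, bp
    min_ctg_end_aln: int = 50_000
    #: minimum aligned size for a simple contig end, bp
    min_simple_end_aln: int = 25_000
    #: reference span may exceed contig length by at most this fraction
    overextension_frac: float = 0.05
    #: distance within which a contig end is "near" an annotation, bp
    proximity: int = 10_000
    #: distance from a chromosome terminus counted as a chromosome end, bp
    chrom_end_window: int = 100_000
    #: intra-contig alignment gaps at or above this size are not discontinuities, bp
    max_discontinuity: int = 1_000_000
    #: padding around centromeric satellite annotation for CENSAT flagging, bp
    censat_pad: int = 1_000_000
    #: minimum number of distinct assemblies for a recurrent region
    recur_min_assemblies: int = 5
    #: minimum predicted event size for recurrence analysis, bp
    recur_min_event: int = 100
    #: dinucleotide counting bin, bp
    dinuc_bin: int = 100
    #: Z-score at or above which a bin is dinucleotide enriched
    z_cutoff: float = 1.96
    #: window size for GA/TC-content flagging, bp
    gatc_window: int = 1_000
    #: minimum GA/TC dinucleotide content of a flagged window
    gatc_frac: float = 0.80
    #: minimum number of long reads spanning a gap to call it spanned
    span_min_reads: int = 10
    #: block size for phasing-concordance evaluation, bp
    phase_block: int = 1_000_000
    #: expected diploid copy number
    cn_diploid: int = 2
    #: copy number above which a region is "more10CN"
    cn_high: int = 10
    #: permutations for enrichment testing
    n_permutations: int = 10_000
    #: unmasked base pairs per read-depth window
    depth_window_unmasked: int = 500

    def __post_init__(self) -> None:
        kinds = _field_kinds()
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            kind = kinds[f.name]
            if kind == _INT_SIZE and (not isinstance(v, int) or v <= 0):
                raise ConfigError(f"{f.name} must be a positive integer, got {v!r}")
            if kind == _NONNEG_INT and (not isinstance(v, int) or v < 0):
                raise ConfigError(f"{f.name} must be a non-negative integer, got {v!r}")
            if kind == _FRACTION and not (0 < float(v) <= 1):
                raise ConfigError(f"{f.name} must be in (0, 1], got {v!r}")
            if kind == _POS_REAL and not float(v) > 0:
                raise ConfigError(f"{f.name} must be > 0, got {v!r}")

    def header(self) -> str:
        """One-line ``## thresholds:`` header echoed into every output file."""
        body = " ".join(
            f"{f.name}={getattr(self, f.name)!r}" for f in dataclasses.fields(self)
        )
        return f"## thresholds: {body}"

    @classmethod
    def from_header(cls, line: str) -> "Thresholds":
        """Re-parse a header produced by :meth:`header` (exact round trip)."""
        prefix = "## thresholds:"
        if not line.strip().startswith(prefix):
            raise ConfigError(f"not a thresholds header: {line!r}")
        payload = line.strip()[len(prefix):].strip()
        pairs: dict[str, str] = {}
        for token in payload.split():
            key, _, raw = token.partition("=")
            pairs[key] = raw
        return cls(**_parse_values(pairs))

    def replace(self, **overrides) -> "Thresholds":
        return dataclasses.replace(self, **overrides)


def _field_kinds() -> dict[str, str]:
    fractions = {"overextension_frac", "gatc_frac"}
    posreal = {"z_cutoff"}
    nonneg = {"min_mapq"}
    kinds = {}
    for f in dataclasses.fields(Thresholds):
        if f.name in fractions:
            kinds[f.name] = _FRACTION
        elif f.name in posreal:
            kinds[f.name] = _POS_REAL
        elif f.name in nonneg:
            kinds[f.name] = _NONNEG_INT
        else:
            kinds[f.name] = _INT_SIZE
    return kinds


def _parse_values(pairs: Mapping[str, str]) -> dict[str, object]:
    """Parse raw string values into ints/floats according to the field kinds."""
    kinds = _field_kinds()
    out: dict[str, object] = {}
    for key, raw in pairs.items():
        if key not in kinds:
            raise ConfigError(f"unknown threshold key: {key!r}")
        raw = str(raw).strip()
        try:
            if kinds[key] in (_FRACTION, _POS_REAL):
                out[key] = float(raw)
            else:
                out[key] = int(raw.replace(",", "").replace("_", ""))
        except ValueError as exc:
            raise ConfigError(f"cannot parse value for {key!r}: {raw!r}") from exc
    return out


def load_config(path=None, overrides: Mapping[str, object] | None = None) -> Thresholds:
    """Build a :class:`Thresholds` from defaults, an optional flat key=value
    file, and optional programmatic/CLI overrides (overrides win over the
    file, the file wins over defaults).

    The file format is one ``key = value`` per line; blank lines and ``#``
    comments are ignored. Unknown keys are rejected.
    """
    values: dict[str, object] = {}
    if path is not None:
        file_pairs: dict[str, str] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ConfigError(f"{path}:{lineno}: expected key=value, got {line!r}")
                key, _, raw = line.partition("=")
                file_pairs[key.strip()] = raw.strip()
        values.update(_parse_values(file_pairs))
    if overrides:
        for key, v in overrides.items():
            if key not in _field_kinds():
                raise ConfigError(f"unknown threshold key: {key!r}")
            values[key] = _parse_values({key: str(v)})[key] if isinstance(v, str) else v
    return Thresholds(**values)
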