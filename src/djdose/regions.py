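"""Target-region handling: BED-style interval sets, reference masking,
PAF-based target transfer between assemblies, and sex-chromosome inference.

All coordinates are 0-based half-open (BED/PAF semantics). Strand is carried
along but never enters any dosage arithmetic.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import ConfigurationError, CoordinateError

Interval = tuple[str, int, int, str]  # (sequence, start, end, strand)

#: sequence names excluded from the autosomal background by default
NON_AUTOSOME_NAMES = frozenset(
    {"chrX", "chrY", "chrM", "chrMT", "X", "Y", "M", "MT", "*"}
)


def merge_intervals(
    intervals: Iterable[tuple[str, int, int] | Interval],
    gap_tolerance: int = 0,
) -> list[Interval]:
    """Merge overlapping/adjacent intervals per sequence.

    Intervals separated by at most ``gap_tolerance`` bases are joined.
    Strand of a merged interval is kept only when all inputs agree,
    otherwise it degrades to ``"."``.
    """
    norm: list[Interval] = []
    for iv in intervals:
        chrom, start, end = iv[0], int(iv[1]), int(iv[2])
        strand = iv[3] if len(iv) > 3 else "."  # type: ignore[misc]
        if start < 0 or end <= start:
            raise CoordinateError(f"invalid interval {chrom}:{start}-{end}")
        norm.append((chrom, start, end, strand))
    norm.sort(key=lambda iv: (iv[0], iv[1], iv[2]))
    merged: list[Interval] = []
    for chrom, start, end, strand in norm:
        if merged and merged[-1][0] == chrom and start <= merged[-1][2] + gap_tolerance:
            prev = merged[-1]
            merged[-1] = (
                chrom,
                prev[1],
                max(prev[2], end),
                prev[3] if prev[3] == strand else ".",
            )
        else:
            merged.append((chrom, start, end, strand))
    return merged


@dataclass
class TargetRegionSet:
    """A named set of genomic intervals on one reference build.

    ``canonical_length`` overrides the summed interval length when the
    dosage formulas must be normalized by the target length on the build
    the target was originally defined on (e.g. a lifted-over target keeps
    the donor build's length).
    """

    name: str
    intervals: list[Interval]
    reference_label: str = ""
    canonical_length: int | None = None
    background: str | list[Interval] | None = None
    autosome_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        norm: list[Interval] = []
        for iv in self.intervals:
            chrom, start, end = iv[0], int(iv[1]), int(iv[2])
            strand = iv[3] if len(iv) > 3 and iv[3] else "."
            if start < 0 or end <= start:
                raise CoordinateError(
                    f"{self.name}: invalid interval {chrom}:{start}-{end}"
                )
            norm.append((chrom, start, end, strand))
        self.intervals = norm

    @property
    def span(self) -> int:
        """Total covered bases after merging (overlaps counted once)."""
        return sum(e - s for _, s, e, _ in merge_intervals(self.intervals))

    @property
    def target_length(self) -> int:
        """Len_T: the canonical length if supplied, else the merged span."""
        return self.canonical_length if self.canonical_length else self.span

    @property
    def total_autosome_length(self) -> int:
        """Len_A: summed autosome lengths (requires ``autosome_lengths``)."""
        if not self.autosome_lengths:
            raise ConfigurationError(f"{self.name}: no autosome lengths supplied")
        return sum(self.autosome_lengths.values())

    def merged(self, gap_tolerance: int = 0) -> "TargetRegionSet":
        return TargetRegionSet(
            name=self.name,
            intervals=merge_intervals(self.intervals, gap_tolerance),
            reference_label=self.reference_label,
            canonical_length=self.canonical_length,
            background=self.background,
            autosome_lengths=dict(self.autosome_lengths),
        )

    def validate(self, sequence_lengths: Mapping[str, int]) -> None:
        """Check every interval against declared sequence lengths."""
        for chrom, start, end, _ in self.intervals:
            if chrom not in sequence_lengths:
                raise CoordinateError(f"{self.name}: unknown sequence {chrom!r}")
            if end > sequence_lengths[chrom]:
                raise CoordinateError(
                    f"{self.name}: interval {chrom}:{start}-{end} exceeds "
                    f"sequence length {sequence_lengths[chrom]}"
                )

    # ---- BED I/O -------------------------------------------------------

    @classmethod
    def from_bed(cls, path: str | Path, name: str | None = None, **kwargs) -> "TargetRegionSet":
        intervals: list[Interval] = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                strand = parts[5] if len(parts) > 5 else "."
                intervals.append((parts[0], int(parts[1]), int(parts[2]), strand))
        return cls(name=name or Path(path).stem, intervals=intervals, **kwargs)

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom, start, end, strand in self.intervals:
                fh.write(f"{chrom}\t{start}\t{end}\t{self.name}\t0\t{strand}\n")


# ---------------------------------------------------------------------------
# Reference masking
# ---------------------------------------------------------------------------


def mask_reference(
    sequences: Mapping[str, str], mask: TargetRegionSet
) -> dict[str, str]:
    """Replace bases inside ``mask`` intervals with ``N``.

    Lengths and all bases outside the mask are unchanged; sequences not
    named in the mask pass through untouched. Raises ``CoordinateError``
    when an interval extends beyond its sequence.
    """
    out = dict(sequences)
    for chrom, start, end, _ in mask.intervals:
        if chrom not in out:
            raise CoordinateError(f"mask names unknown sequence {chrom!r}")
        seq = out[chrom]
        if end > len(seq):
            raise CoordinateError(
                f"mask interval {chrom}:{start}-{end} exceeds sequence "
                f"length {len(seq)}"
            )
        out[chrom] = seq[:start] + "N" * (end - start) + seq[end:]
    return out


def mask_fasta(
    in_fasta: str | Path, out_fasta: str | Path, mask: TargetRegionSet, width: int = 60
) -> None:
    """File-level masking: read a FASTA, mask, write a FASTA."""
    from pyfaidx import Fasta

    fa = Fasta(str(in_fasta))
    seqs = {name: str(fa[name][:]) for name in fa.keys()}
    masked = mask_reference(seqs, mask)
    with open(out_fasta, "w") as fh:
        for name, seq in masked.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# PAF-based target transfer
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PafRecord:
    """One PAF alignment line (minimal 12 mandatory columns)."""

    query_name: str
    query_length: int
    query_start: int
    query_end: int
    strand: str
    target_name: str
    target_length: int
    target_start: int
    target_end: int
    matching_bases: int
    alignment_block_length: int
    mapping_quality: int

    def __post_init__(self) -> None:
        if not (0 <= self.query_start < self.query_end <= self.query_length):
            raise CoordinateError(f"bad query coordinates in PAF record {self}")
        if not (0 <= self.target_start < self.target_end <= self.target_length):
            raise CoordinateError(f"bad target coordinates in PAF record {self}")
        if self.matching_bases > self.alignment_block_length:
            raise CoordinateError("matching bases exceed alignment block length")

    @classmethod
    def from_line(cls, line: str) -> "PafRecord":
        f = line.rstrip("\n").split("\t")
        return cls(
            query_name=f[0],
            query_length=int(f[1]),
            query_start=int(f[2]),
            query_end=int(f[3]),
            strand=f[4],
            target_name=f[5],
            target_length=int(f[6]),
            target_start=int(f[7]),
            target_end=int(f[8]),
            matching_bases=int(f[9]),
            alignment_block_length=int(f[10]),
            mapping_quality=int(f[11]) if len(f) > 11 else 255,
        )

    @property
    def identity_pct(self) -> float:
        """Percent identity: 100 x matching bases / alignment block length."""
        return 100.0 * self.matching_bases / self.alignment_block_length

    @property
    def target_coverage_pct(self) -> float:
        """Percent of the target (donor) sequence spanned by this block."""
        return 100.0 * (self.target_end - self.target_start) / self.target_length


def read_paf(path: str | Path) -> list[PafRecord]:
    with open(path) as fh:
        return [PafRecord.from_line(ln) for ln in fh if ln.strip()]


def filter_target_alignments(
    records: Sequence[PafRecord],
    min_length_bp: int = 10_000,
    min_identity_pct: float = 0.0,
    min_coverage_pct: float = 0.0,
    name: str = "target",
    reference_label: str = "",
    gap_tolerance: int = 0,
    return_rejected: bool = False,
):
    """Build a target region set on a new reference from PAF alignments.

    A record survives when its alignment block length is >= ``min_length_bp``
    (blocks strictly shorter than the cutoff are dropped), its identity
    (100 x matches / block length) is >= ``min_identity_pct``, and its
    coverage of the donor target is >= ``min_coverage_pct``. Surviving
    query intervals are merged. With ``return_rejected`` the second return
    value lists ``(record, reason)`` pairs.
    """
    kept: list[Interval] = []
    rejected: list[tuple[PafRecord, str]] = []
    for rec in records:
        if rec.alignment_block_length < min_length_bp:
            rejected.append((rec, f"block length {rec.alignment_block_length} < {min_length_bp}"))
            continue
        if rec.identity_pct < min_identity_pct:
            rejected.append((rec, f"identity {rec.identity_pct:.2f}% < {min_identity_pct}%"))
            continue
        if rec.target_coverage_pct < min_coverage_pct:
            rejected.append((rec, f"coverage {rec.target_coverage_pct:.2f}% < {min_coverage_pct}%"))
            continue
        kept.append((rec.query_name, rec.query_start, rec.query_end, rec.strand))
    if not kept:
        warnings.warn(f"no PAF records survive filtering for {name!r}", stacklevel=2)
    region = TargetRegionSet(
        name=name,
        intervals=merge_intervals(kept, gap_tolerance) if kept else [],
        reference_label=reference_label,
    )
    if return_rejected:
        return region, rejected
    return region


# ---------------------------------------------------------------------------
# Sex-chromosome complement inference
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SexCall:
    """Sex-chromosome complement inferred from X/Y read coverage.

    The call selects the matched masked reference for downstream
    alignment: Y-masked for XX, PAR-masked-Y for XY.
    """

    cov_x: float
    cov_y: float
    ratio: float
    call: str  # "XX" | "XY"


def infer_sex(summary, threshold: float = 4.0, x_name: str | None = None, y_name: str | None = None) -> SexCall:
    """Call XX/XY from per-chromosome mapped-read coverage.

    Coverage per chromosome is mapped reads / chromosome length; a
    covX/covY ratio above ``threshold`` (or zero Y coverage) calls XX,
    otherwise XY.

    ``summary`` is an :class:`~djdose.coverage.AlignmentSummary` (or any
    object with ``sequence_stats(name) -> (length, mapped)``).
    """

    def _resolve(preferred: str | None, candidates: tuple[str, ...]) -> str:
        names = candidates if preferred is None else (preferred,)
        for n in names:
            if summary.has_sequence(n):
                return n
        raise ConfigurationError(f"no sex chromosome among {names} in alignment summary")

    xn = _resolve(x_name, ("chrX", "X"))
    yn = _resolve(y_name, ("chrY", "Y"))
    x_len, x_mapped = summary.sequence_stats(xn)
    y_len, y_mapped = summary.sequence_stats(yn)
    cov_x = x_mapped / x_len
    cov_y = y_mapped / y_len
    ratio = math.inf if cov_y == 0 else cov_x / cov_y
    call = "XX" if (cov_y == 0 or ratio > threshold) else "XY"
    return SexCall(cov_x=cov_x, cov_y=cov_y, ratio=ratio, call=call)
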