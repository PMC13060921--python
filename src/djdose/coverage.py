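"""Alignment-based diploid copy-number estimation of a target region.

Five normalization modes are provided, all of the form
``CN = 2 x (target coverage) / (background coverage)``:

============  ======================================  =============================
mode          target coverage                         background coverage
============  ======================================  =============================
chm13_highres median per-base depth over target       median per-base depth over a
                                                      supplied background BED
pilot_fast    sum RC_T / Len_T (raw counts)           (sum RC_A - RU_A) / Len_A
fast          sum RC_T / Len_T (raw counts)           median over autosomes of
                                                      RC_C / Len_C
fast_precise  sum FRC_T / Len_T (flag-filtered)       FRC_A / Len_A
fast_refine   sum FRC_T / Len_T (flag-filtered)       median over autosomes of
                                                      FRC_C / Len_C
grch38_highres sum Depth_T / Len_T (per-base)         median over autosomes of
                                                      mean per-base coverage
============  ======================================  =============================

``RC`` are raw record counts, ``FRC`` counts after excluding reads whose SAM
flag intersects the filter mask (default 3332: unmapped + secondary +
duplicate + supplementary). A diploid single-copy region yields CN = 2.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, UndefinedEstimateError
from .regions import NON_AUTOSOME_NAMES, TargetRegionSet

#: unmapped (4) + secondary (256) + duplicate (1024) + supplementary (2048)
DEFAULT_FLAG_MASK = 0x4 | 0x100 | 0x400 | 0x800  # == 3332

MODES = (
    "chm13_highres",
    "pilot_fast",
    "fast",
    "fast_precise",
    "fast_refine",
    "grch38_highres",
    "kmer",
)


@dataclass(frozen=True)
class ReadFilterSpec:
    """Which alignment records count toward filtered totals.

    ``excluded_flag_mask`` drops any record whose flag shares a bit with
    the mask. ``count_policy`` controls multi-interval targets:
    ``"per-interval"`` counts a read once per overlapped interval
    (region-query semantics), ``"unique"`` counts each read name once.
    """

    excluded_flag_mask: int = DEFAULT_FLAG_MASK
    count_policy: str = "per-interval"


def weighted_median(pairs: Iterable[tuple[float, float]]) -> float:
    """Median of a multiplicity-weighted sample under the strict-``>`` rule.

    Returns the smallest value whose cumulative count strictly exceeds
    half of the total count. This matches histogram-median semantics used
    for k-mer multiplicity spectra (not the conventional mid-point
    average; interval depth medians use :func:`numpy.median` instead).
    """
    items = sorted((float(v), float(c)) for v, c in pairs if c > 0)
    if not items:
        raise ValueError("weighted_median of empty input")
    half = sum(c for _, c in items) / 2.0
    cum = 0.0
    for value, count in items:
        cum += count
        if cum > half:
            return value
    return items[-1][0]  # only reachable through float round-off


# ---------------------------------------------------------------------------
# Alignment summary
# ---------------------------------------------------------------------------


class AlignmentSummary:
    """Per-reference read statistics plus depth access for one sample.

    Backed either by an indexed BAM/SAM/CRAM (``from_bam``) or by explicit
    tables (``from_tables``) when only the normalization arithmetic is
    exercised. ``stats`` is a DataFrame with columns
    ``name, length, mapped, unmapped, filtered_mapped``.
    """

    def __init__(
        self,
        stats: pd.DataFrame,
        bam_path: str | Path | None = None,
        autosomes: Sequence[str] | None = None,
        filter_mask: int = DEFAULT_FLAG_MASK,
        depths: dict[str, np.ndarray] | None = None,
        target_counts: dict[tuple[str, bool], int] | None = None,
        n_duplicate_flagged: int | None = None,
        reference_fasta: str | Path | None = None,
    ):
        required = {"name", "length", "mapped", "unmapped", "filtered_mapped"}
        if not required.issubset(stats.columns):
            raise ConfigurationError(f"stats table must have columns {sorted(required)}")
        self.stats = stats.set_index("name", drop=False)
        self.bam_path = str(bam_path) if bam_path else None
        self.filter_mask = filter_mask
        self._depths = depths or {}
        self._target_counts = target_counts or {}
        self.n_duplicate_flagged = n_duplicate_flagged
        self.reference_fasta = str(reference_fasta) if reference_fasta else None
        if autosomes is None:
            autosomes = [
                n for n in self.stats.index if n not in NON_AUTOSOME_NAMES
            ]
        self.autosomes = list(autosomes)

    # ---- construction --------------------------------------------------

    @classmethod
    def from_bam(
        cls,
        path: str | Path,
        autosomes: Sequence[str] | None = None,
        filter_mask: int = DEFAULT_FLAG_MASK,
        reference_fasta: str | Path | None = None,
    ) -> "AlignmentSummary":
        """Scan an alignment file once, collecting per-reference counts."""
        import pysam

        mode_kwargs = {}
        if reference_fasta:
            mode_kwargs["reference_filename"] = str(reference_fasta)
        with pysam.AlignmentFile(str(path), **mode_kwargs) as af:
            names = list(af.references)
            lengths = dict(zip(names, af.lengths))
            mapped = dict.fromkeys(names, 0)
            unmapped = dict.fromkeys(names, 0)
            filtered = dict.fromkeys(names, 0)
            n_dup = 0
            for read in af.fetch(until_eof=True):
                ref = read.reference_name
                if read.is_duplicate:
                    n_dup += 1
                if read.is_unmapped:
                    if ref is not None:
                        unmapped[ref] += 1
                    continue
                mapped[ref] += 1
                if not (read.flag & filter_mask):
                    filtered[ref] += 1
        stats = pd.DataFrame(
            {
                "name": names,
                "length": [lengths[n] for n in names],
                "mapped": [mapped[n] for n in names],
                "unmapped": [unmapped[n] for n in names],
                "filtered_mapped": [filtered[n] for n in names],
            }
        )
        return cls(
            stats,
            bam_path=path,
            autosomes=autosomes,
            filter_mask=filter_mask,
            n_duplicate_flagged=n_dup,
            reference_fasta=reference_fasta,
        )

    @classmethod
    def from_tables(
        cls,
        stats: pd.DataFrame,
        depths: dict[str, np.ndarray] | None = None,
        target_counts: dict[tuple[str, bool], int] | None = None,
        autosomes: Sequence[str] | None = None,
        **kwargs,
    ) -> "AlignmentSummary":
        """Table-backed summary (no alignment file behind it)."""
        return cls(
            stats, depths=depths, target_counts=target_counts, autosomes=autosomes, **kwargs
        )

    # ---- basic accessors -----------------------------------------------

    def has_sequence(self, name: str) -> bool:
        return name in self.stats.index

    def sequence_stats(self, name: str) -> tuple[int, int]:
        """(length, mapped read count) for one reference sequence."""
        if name not in self.stats.index:
            raise ConfigurationError(f"sequence {name!r} not in alignment summary")
        row = self.stats.loc[name]
        return int(row["length"]), int(row["mapped"])

    @property
    def autosome_table(self) -> pd.DataFrame:
        return self.stats.loc[self.autosomes]

    @property
    def len_a(self) -> int:
        """Len_A: total autosomal length."""
        return int(self.autosome_table["length"].sum())

    @property
    def rc_a(self) -> int:
        """RC_A: raw mapped records on autosomes."""
        return int(self.autosome_table["mapped"].sum())

    @property
    def ru_a(self) -> int:
        """RU_A: unmapped records assigned to autosomes."""
        return int(self.autosome_table["unmapped"].sum())

    @property
    def frc_a(self) -> int:
        """FRC_A: flag-filtered mapped records on autosomes."""
        return int(self.autosome_table["filtered_mapped"].sum())

    # ---- target-restricted counting -------------------------------------

    def count_in(
        self, target: TargetRegionSet, filtered: bool = False, policy: str = "per-interval"
    ) -> int:
        """Reads overlapping the target intervals (RC_T / FRC_T).

        Default policy counts a read once per overlapped interval, matching
        region-query counting; ``"unique"`` counts each read name once.
        """
        key = (target.name, filtered)
        if key in self._target_counts:
            return int(self._target_counts[key])
        if self.bam_path is None:
            raise ConfigurationError(
                "no alignment file attached and no precomputed target counts"
            )
        import pysam

        kwargs = {}
        if self.reference_fasta:
            kwargs["reference_filename"] = self.reference_fasta
        total = 0
        seen: set[tuple[str, int]] = set()
        with pysam.AlignmentFile(self.bam_path, **kwargs) as af:
            for chrom, start, end, _ in target.intervals:
                for read in af.fetch(chrom, start, end):
                    if filtered and (read.flag & self.filter_mask):
                        continue
                    if policy == "unique":
                        seen.add((read.query_name, read.flag))
                    else:
                        total += 1
        return len(seen) if policy == "unique" else total

    # ---- per-base depth --------------------------------------------------

    def depth_array(self, target: TargetRegionSet, filtered: bool = True) -> np.ndarray:
        """Concatenated per-base depth over the target intervals.

        With ``filtered`` (default) records matching the flag mask are
        excluded, mirroring default depth-tool behaviour.
        """
        if self._depths:
            chunks = []
            for chrom, start, end, _ in target.intervals:
                if chrom not in self._depths:
                    raise ConfigurationError(f"no depth track for {chrom!r}")
                chunks.append(np.asarray(self._depths[chrom][start:end], dtype=float))
            return np.concatenate(chunks) if chunks else np.array([])
        if self.bam_path is None:
            raise ConfigurationError("no alignment file attached and no depth tracks")
        import pysam

        kwargs = {}
        if self.reference_fasta:
            kwargs["reference_filename"] = self.reference_fasta
        chunks = []
        with pysam.AlignmentFile(self.bam_path, **kwargs) as af:
            for chrom, start, end, _ in target.intervals:
                diff = np.zeros(end - start + 1, dtype=np.int64)
                for read in af.fetch(chrom, start, end):
                    if filtered and (read.flag & self.filter_mask):
                        continue
                    s = max(read.reference_start, start)
                    e = min(read.reference_end or read.reference_start, end)
                    if e > s:
                        diff[s - start] += 1
                        diff[e - start] -= 1
                chunks.append(np.cumsum(diff[:-1]).astype(float))
        return np.concatenate(chunks) if chunks else np.array([])

    def median_depth(
        self,
        target: TargetRegionSet,
        include_zero: bool = False,
        filtered: bool = True,
    ) -> float:
        """Conventional median of per-base depth over the target.

        By default positions with zero depth are excluded, matching a
        depth stream that only emits covered positions; ``include_zero``
        switches to the all-positions median.
        """
        depth = self.depth_array(target, filtered=filtered)
        if not include_zero:
            depth = depth[depth > 0]
        if depth.size == 0:
            return 0.0
        return float(np.median(depth))

    def mean_coverage(self, name: str, filtered: bool = True) -> float:
        """Cov_C: mean per-base depth of one whole reference sequence."""
        length, _ = self.sequence_stats(name)
        region = TargetRegionSet(name=f"__cov_{name}", intervals=[(name, 0, length, ".")])
        depth = self.depth_array(region, filtered=filtered)
        return float(depth.sum() / length)


# ---------------------------------------------------------------------------
# Copy-number estimates
# ---------------------------------------------------------------------------


@dataclass
class CopyNumberEstimate:
    """A continuous diploid copy-number estimate and its discrete bin."""

    sample: str
    target: str
    mode: str
    value: float
    bin: int | str | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("copy number cannot be negative")


def bin_copy_number(value: float, rule: str = "nearest") -> int:
    """Discretize a continuous copy-number estimate.

    ``"nearest"`` rounds to the nearest integer with .5 ties rounding up.
    ``"dj_threshold"`` is identical except that the 10/11 boundary sits at
    10.4 instead of 10.5 (values in [10.4, 10.5) bin to 11), reflecting the
    empirical gap between the 10-copy bulk and DJ-gain samples.
    """
    if not math.isfinite(value):
        raise ValueError(f"cannot bin non-finite value {value}")
    if rule == "dj_threshold" and 10.4 <= value < 10.5:
        return 11
    if rule not in ("nearest", "dj_threshold"):
        raise ValueError(f"unknown binning rule {rule!r}")
    return int(math.floor(value + 0.5))


def _estimate(sample, target, mode, num, den, provenance, bin_rule):
    if den == 0:
        raise UndefinedEstimateError(f"{mode}: zero background coverage")
    value = 2.0 * num / den
    return CopyNumberEstimate(
        sample=sample,
        target=target.name,
        mode=mode,
        value=value,
        bin=bin_copy_number(value, bin_rule),
        provenance=provenance,
    )


def cn_highres_chm13(
    summary: AlignmentSummary,
    target: TargetRegionSet,
    background: TargetRegionSet,
    sample: str = "sample",
    include_zero: bool = False,
    bin_rule: str = "nearest",
) -> CopyNumberEstimate:
    """CN = 2 x MedianDepth_T / MedianDepth_B (per-base depth medians).

    The background region set should exclude the masked repeat copies and
    other copy-number-variable sequence.
    """
    med_t = summary.median_depth(target, include_zero=include_zero)
    med_b = summary.median_depth(background, include_zero=include_zero)
    return _estimate(
        sample,
        target,
        "chm13_highres",
        med_t,
        med_b,
        {"median_depth_target": med_t, "median_depth_background": med_b},
        bin_rule,
    )


def cn_pilot_fast(
    summary: AlignmentSummary,
    target: TargetRegionSet,
    sample: str = "sample",
    bin_rule: str = "nearest",
) -> CopyNumberEstimate:
    """CN = 2 x (sum RC_T / Len_T) / ((sum RC_A - RU_A) / Len_A), unfiltered."""
    len_t = target.target_length
    if len_t == 0:
        raise UndefinedEstimateError("target length is zero")
    rc_t = summary.count_in(target, filtered=False)
    num = rc_t / len_t
    den = (summary.rc_a - summary.ru_a) / summary.len_a
    return _estimate(
        sample,
        target,
        "pilot_fast",
        num,
        den,
        {"rc_t": rc_t, "len_t": len_t, "rc_a": summary.rc_a, "ru_a": summary.ru_a,
         "len_a": summary.len_a},
        bin_rule,
    )


def _median_autosome_coverage(summary: AlignmentSummary, column: str) -> float:
    tab = summary.autosome_table
    tab = tab[tab["length"] > 0]
    if len(tab) == 0:
        raise UndefinedEstimateError("no autosome with nonzero length")
    return float(np.median(tab[column] / tab["length"]))


def cn_fast(
    summary: AlignmentSummary,
    target: TargetRegionSet,
    sample: str = "sample",
    bin_rule: str = "nearest",
) -> CopyNumberEstimate:
    """CN = 2 x (sum RC_T / Len_T) / median_C(RC_C / Len_C), unfiltered.

    ``Len_T`` is the canonical target length on the build the target was
    defined on (``TargetRegionSet.canonical_length`` when set).
    """
    len_t = target.target_length
    if len_t == 0:
        raise UndefinedEstimateError("target length is zero")
    rc_t = summary.count_in(target, filtered=False)
    den = _median_autosome_coverage(summary, "mapped")
    return _estimate(
        sample, target, "fast", rc_t / len_t, den,
        {"rc_t": rc_t, "len_t": len_t, "median_autosome_coverage": den}, bin_rule,
    )


def cn_fast_precise(
    summary: AlignmentSummary,
    target: TargetRegionSet,
    filter_spec: ReadFilterSpec | None = None,
    sample: str = "sample",
    bin_rule: str = "nearest",
) -> CopyNumberEstimate:
    """CN = 2 x (sum FRC_T / Len_T) / (FRC_A / Len_A).

    Duplicates must be marked upstream; a warning is emitted when no
    duplicate-flagged read was seen anywhere (possible unmarked input).
    """
    spec = filter_spec or ReadFilterSpec()
    if summary.n_duplicate_flagged == 0:
        warnings.warn(
            "no duplicate-flagged reads anywhere in the alignment; duplicates "
            "may be unmarked", stacklevel=2,
        )
    len_t = target.target_length
    if len_t == 0:
        raise UndefinedEstimateError("target length is zero")
    frc_t = summary.count_in(target, filtered=True, policy=spec.count_policy)
    den = summary.frc_a / summary.len_a
    return _estimate(
        sample, target, "fast_precise", frc_t / len_t, den,
        {"frc_t": frc_t, "len_t": len_t, "frc_a": summary.frc_a,
         "len_a": summary.len_a, "flag_mask": spec.excluded_flag_mask}, bin_rule,
    )


def cn_fast_refine(
    summary: AlignmentSummary,
    target: TargetRegionSet,
    filter_spec: ReadFilterSpec | None = None,
    sample: str = "sample",
    bin_rule: str = "nearest",
) -> CopyNumberEstimate:
    """CN = 2 x (sum FRC_T / Len_T) / median_C(FRC_C / Len_C)."""
    spec = filter_spec or ReadFilterSpec()
    len_t = target.target_length
    if len_t == 0:
        raise UndefinedEstimateError("target length is zero")
    frc_t = summary.count_in(target, filtered=True, policy=spec.count_policy)
    den = _median_autosome_coverage(summary, "filtered_mapped")
    return _estimate(
        sample, target, "fast_refine", frc_t / len_t, den,
        {"frc_t": frc_t, "len_t": len_t, "median_autosome_filtered_coverage": den},
        bin_rule,
    )


def cn_highres_grch38(
    summary: AlignmentSummary,
    target: TargetRegionSet,
    sample: str = "sample",
    bin_rule: str = "nearest",
) -> CopyNumberEstimate:
    """CN = 2 x (sum Depth_T / Len_T) / median_C(Cov_C) (per-base depth)."""
    len_t = target.target_length
    if len_t == 0:
        raise UndefinedEstimateError("target length is zero")
    depth = summary.depth_array(target, filtered=True)
    num = float(depth.sum()) / len_t
    covs = [summary.mean_coverage(n) for n in summary.autosomes]
    if not covs:
        raise UndefinedEstimateError("no autosomes for background coverage")
    den = float(np.median(covs))
    return _estimate(
        sample, target, "grch38_highres", num, den,
        {"sum_depth_t": float(depth.sum()), "len_t": len_t,
         "median_autosome_mean_coverage": den}, bin_rule,
    )


#: dispatch used by the CLI; chm13_highres needs an explicit background
MODE_FUNCTIONS = {
    "pilot_fast": cn_pilot_fast,
    "fast": cn_fast,
    "fast_precise": cn_fast_precise,
    "fast_refine": cn_fast_refine,
    "grch38_highres": cn_highres_grch38,
}
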