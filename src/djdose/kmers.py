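"""Reference-free DJ dosage from k-mer multiplicities.

The estimator works in three stages:

1. marker selection — canonical 31-mers present exactly once in *every*
   DJ unit sequence (so each marker occurs ``c`` times in a genome with
   ``c`` DJ copies);
2. calibration — locate the diploid ("2-copy") peak of the whole-read
   k-mer multiplicity spectrum, optionally band-filtering markers around
   ``kcov x expected_copies``;
3. estimation — ``CN = 2 x median(marker multiplicities) / 2-copy peak``,
   with the median taken under the strict-``>`` cumulative rule.
"""

from __future__ import annotations

import json
import warnings
from collections import Counter
from dataclasses import dataclass, field
from math import ceil, floor
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from scipy.signal import find_peaks

from .coverage import CopyNumberEstimate, bin_copy_number, weighted_median
from .errors import CalibrationError
from .regions import TargetRegionSet  # noqa: F401  (re-exported for CLI typing)

_RC = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def canonical_kmer(kmer: str) -> str:
    """Lexicographic minimum of a k-mer and its reverse complement."""
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc


def count_canonical_kmers(seq: str, k: int = 31) -> Counter:
    """Multiset of canonical k-mers in one sequence; k-mers touching a
    non-ACGT base are skipped."""
    seq = seq.upper()
    counts: Counter = Counter()
    valid = set("ACGT")
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if set(kmer) <= valid:
            counts[canonical_kmer(kmer)] += 1
    return counts


def select_shared_single_copy_kmers(unit_sequences: Iterable[str], k: int = 31) -> set[str]:
    """Canonical k-mers occurring exactly once in each unit sequence.

    These are the marker k-mers whose read multiplicity tracks the number
    of unit copies in a genome. An empty result triggers a warning (units
    too divergent, or k too small).
    """
    units = list(unit_sequences)
    if len(units) < 2:
        raise ValueError("need at least two unit sequences")
    marker: set[str] | None = None
    for seq in units:
        singles = {km for km, n in count_canonical_kmers(seq, k).items() if n == 1}
        marker = singles if marker is None else marker & singles
    assert marker is not None
    if not marker:
        warnings.warn("no shared single-copy k-mers found", stacklevel=2)
    return marker


# ---------------------------------------------------------------------------
# Histograms
# ---------------------------------------------------------------------------


@dataclass
class KmerHistogram:
    """k-mer multiplicity spectrum: multiplicity -> count of distinct k-mers."""

    counts: dict[int, int]
    k: int = 31

    def __post_init__(self) -> None:
        clean = {}
        for mult, n in self.counts.items():
            if int(mult) < 1:
                raise ValueError("multiplicities must be >= 1")
            if n < 0:
                raise ValueError("counts must be >= 0")
            if n:
                clean[int(mult)] = int(n)
        self.counts = clean

    @property
    def total_distinct(self) -> int:
        return sum(self.counts.values())

    def items(self) -> list[tuple[int, int]]:
        return sorted(self.counts.items())

    def restrict(self, lo: int, hi: int) -> "KmerHistogram":
        return KmerHistogram(
            {m: n for m, n in self.counts.items() if lo <= m <= hi}, k=self.k
        )

    def median_multiplicity(self) -> float:
        """Histogram median under the strict-``>`` cumulative rule."""
        return weighted_median(self.items())

    @classmethod
    def from_multiplicities(cls, multiplicities: Iterable[int], k: int = 31) -> "KmerHistogram":
        return cls(dict(Counter(int(m) for m in multiplicities)), k=k)

    @classmethod
    def from_tsv(cls, path: str | Path, k: int = 31) -> "KmerHistogram":
        """Two-column TSV: multiplicity <TAB> count (comments with #)."""
        counts: dict[int, int] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                mult, n = line.split("\t")[:2]
                counts[int(mult)] = counts.get(int(mult), 0) + int(n)
        return cls(counts, k=k)

    def to_tsv(self, path: str | Path, header: str | None = None) -> None:
        with open(path, "w") as fh:
            if header:
                fh.write(header if header.endswith("\n") else header + "\n")
            for mult, n in self.items():
                fh.write(f"{mult}\t{n}\n")


def count_read_kmers(reads: Iterable[str], k: int = 31) -> Counter:
    """Streamed canonical k-mer counting over read sequences (small inputs;
    genome-scale spectra are expected as precomputed histograms)."""
    counts: Counter = Counter()
    for read in reads:
        counts.update(count_canonical_kmers(read, k))
    return counts


# ---------------------------------------------------------------------------
# Target band filtering
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KmerTargetSpec:
    """Marker set plus the multiplicity band used to refine it.

    The band is ``[kcov x (copies - half_width), kcov x (copies + half_width)]``
    with floor/ceil rounding (``round_multiple`` snaps both edges to the
    nearest multiple instead, a convenience for hand-set presets).
    """

    k: int = 31
    markers: frozenset[str] = field(default_factory=frozenset)
    kcov: float | None = None
    expected_copies: float = 10.0
    half_width: float = 0.5
    round_multiple: int | None = None

    @property
    def band(self) -> tuple[int, int]:
        if self.kcov is None:
            raise CalibrationError("kcov not set; cannot derive multiplicity band")
        return multiplicity_band(
            self.kcov, self.expected_copies, self.half_width, self.round_multiple
        )


def multiplicity_band(
    kcov: float,
    copies: float = 10.0,
    half_width: float = 0.5,
    round_multiple: int | None = None,
) -> tuple[int, int]:
    """Expected marker multiplicity band from haploid k-mer coverage."""
    lo = kcov * (copies - half_width)
    hi = kcov * (copies + half_width)
    if round_multiple:
        lo = round(lo / round_multiple) * round_multiple
        hi = round(hi / round_multiple) * round_multiple
    else:
        lo, hi = floor(lo), ceil(hi)
    lo, hi = int(lo), int(hi)
    if lo >= hi:
        raise CalibrationError(f"degenerate multiplicity band [{lo}, {hi}]")
    return lo, hi


def band_filter_markers(
    marker_multiplicities: Mapping[str, int] | KmerHistogram,
    kcov: float,
    copies: float = 10.0,
    half_width: float = 0.5,
    round_multiple: int | None = None,
):
    """Retain markers whose read multiplicity falls inside the expected band.

    Accepts either a marker -> multiplicity mapping (returns the surviving
    marker set) or a marker histogram (returns the restricted histogram).
    Raises :class:`CalibrationError` when nothing survives — usually a
    mis-estimated ``kcov``.
    """
    lo, hi = multiplicity_band(kcov, copies, half_width, round_multiple)
    if isinstance(marker_multiplicities, KmerHistogram):
        out = marker_multiplicities.restrict(lo, hi)
        if out.total_distinct == 0:
            raise CalibrationError(
                f"no markers in band [{lo}, {hi}]; check the kcov estimate"
            )
        return out
    kept = {m for m, mult in marker_multiplicities.items() if lo <= mult <= hi}
    if not kept:
        raise CalibrationError(f"no markers in band [{lo}, {hi}]; check the kcov estimate")
    return kept


# ---------------------------------------------------------------------------
# Peak calibration
# ---------------------------------------------------------------------------


@dataclass
class PeakCalibration:
    """Diploid-peak calibration of a read k-mer spectrum."""

    two_copy_peak: int
    one_copy_peak: int | None = None
    boundaries: dict[str, tuple[int, int]] = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.one_copy_peak is not None and self.two_copy_peak <= self.one_copy_peak:
            raise CalibrationError("2-copy peak must exceed 1-copy peak")

    @property
    def kcov(self) -> float:
        """Fallback haploid coverage estimate: half the diploid peak."""
        return self.two_copy_peak / 2.0

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "two_copy_peak": self.two_copy_peak,
                    "one_copy_peak": self.one_copy_peak,
                    "boundaries": {k: list(v) for k, v in self.boundaries.items()},
                    "diagnostics": self.diagnostics,
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path: str | Path) -> "PeakCalibration":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            two_copy_peak=d["two_copy_peak"],
            one_copy_peak=d.get("one_copy_peak"),
            boundaries={k: tuple(v) for k, v in d.get("boundaries", {}).items()},
            diagnostics=d.get("diagnostics", {}),
        )


def _moving_average(y: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return y.astype(float)
    if window % 2 == 0:
        raise ValueError("smoothing window must be odd")
    kernel = np.ones(window) / window
    pad = window // 2
    padded = np.pad(y.astype(float), pad, mode="edge")
    return np.convolve(padded, kernel, mode="valid")


def detect_copy_peaks(
    hist: KmerHistogram,
    smooth_window: int = 3,
    error_floor: int = 5,
    prominence: float | None = None,
    min_peak_height_fraction: float = 0.05,
) -> PeakCalibration:
    """Locate the diploid peak of a k-mer multiplicity spectrum.

    The low-multiplicity sequencing-error region (up to the first local
    minimum, and at least up to ``error_floor``) is excluded; local maxima
    of the lightly smoothed counts are collected. Maxima below
    ``min_peak_height_fraction`` of the tallest one are not copy peaks
    (high-multiplicity repeat bumps hold orders of magnitude fewer
    distinct k-mers than the genome-wide diploid peak). With a single
    surviving peak it is taken as the 2-copy peak (homozygous-like
    spectrum); with several, the tallest peak at or beyond the
    second-lowest position is the 2-copy peak and any peak left of it is
    the 1-copy peak. Boundaries are the flanking local minima.
    """
    if len(hist.counts) < 10:
        raise CalibrationError("histogram too sparse (< 10 multiplicity bins)")
    max_mult = max(hist.counts)
    y = np.zeros(max_mult + 1)
    for m, n in hist.counts.items():
        y[m] = n
    ys = _moving_average(y, smooth_window)

    # end of the decreasing error run, scanning from multiplicity 1
    trough = 1
    while trough < max_mult and ys[trough + 1] <= ys[trough]:
        trough += 1
    start = max(trough, error_floor)
    if start >= max_mult:
        raise CalibrationError("no local maximum beyond the error trough")

    segment = ys[start:]
    if prominence is None:
        prominence = 0.01 * float(segment.max())
    idx, props = find_peaks(segment, prominence=prominence)
    all_positions = [int(i + start) for i in idx]
    if not all_positions:
        raise CalibrationError("no local maximum beyond the error trough")
    tallest = max(ys[p] for p in all_positions)
    positions = [
        p for p in all_positions if ys[p] >= min_peak_height_fraction * tallest
    ]

    if len(positions) == 1:
        two_copy = positions[0]
        one_copy = None
    else:
        second_lowest = sorted(positions)[1]
        candidates = [p for p in positions if p >= second_lowest]
        two_copy = max(candidates, key=lambda p: ys[p])
        left = [p for p in positions if p < two_copy]
        one_copy = min(left) if left else None

    def _bounds(peak: int) -> tuple[int, int]:
        lo = peak
        while lo > start and ys[lo - 1] <= ys[lo]:
            lo -= 1
        hi = peak
        while hi < max_mult and ys[hi + 1] <= ys[hi]:
            hi += 1
        return lo, hi

    boundaries = {"two_copy": _bounds(two_copy)}
    if one_copy is not None:
        boundaries["one_copy"] = _bounds(one_copy)
    return PeakCalibration(
        two_copy_peak=two_copy,
        one_copy_peak=one_copy,
        boundaries=boundaries,
        diagnostics={
            "error_trough": trough,
            "scan_start": start,
            "all_peaks": all_positions,
            "copy_peak_candidates": positions,
            "smooth_window": smooth_window,
            "prominence": prominence,
        },
    )


def cn_from_kmers(
    marker_hist: KmerHistogram,
    calibration: PeakCalibration,
    sample: str = "sample",
    target: str = "DJ",
    bin_rule: str = "nearest",
) -> CopyNumberEstimate:
    """CN = 2 x median(marker multiplicities) / 2-copy peak."""
    if marker_hist.total_distinct == 0:
        raise CalibrationError("empty marker histogram")
    if calibration.two_copy_peak <= 0:
        raise CalibrationError("2-copy peak must be positive")
    med = marker_hist.median_multiplicity()
    value = 2.0 * med / calibration.two_copy_peak
    return CopyNumberEstimate(
        sample=sample,
        target=target,
        mode="kmer",
        value=value,
        bin=bin_copy_number(value, bin_rule),
        provenance={
            "median_marker_multiplicity": med,
            "two_copy_peak": calibration.two_copy_peak,
            "n_markers": marker_hist.total_distinct,
        },
    )


def write_marker_set(markers: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for km in sorted(markers):
            fh.write(km + "\n")


def read_marker_set(path: str | Path) -> set[str]:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}
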