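"""Synthetic fixtures with known ground truth for every pipeline stage.

Three generators, all deterministic under a fixed seed:

* :func:`simulate_alignment_fixture` — a coordinate-sorted, indexed BAM
  over a toy diploid genome in which target intervals carry a configurable
  diploid copy number (read density scaled by ``copy/2``). Duplicate
  flags are injected on *target* reads (emulating the PCR-duplicate-like
  pile-ups seen over collapsed repeats, which is what separates filtered
  from unfiltered estimator modes); secondary/supplementary flags are
  injected genome-wide.
* :func:`simulate_kmer_spectrum` — a k-mer multiplicity histogram with a
  geometric sequencing-error spike plus Gaussian-discretized 1-copy,
  2-copy and marker bumps, and the matching marker sub-histogram.
* :func:`simulate_cohort` — per-sample continuous copy numbers drawn from
  a Gaussian mixture with known weights and component labels retained.

Reads are fixed-length single-end placements: pairing adds nothing to
aggregate dosage arithmetic. No base-level errors or GC bias are modeled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .coverage import AlignmentSummary
from .kmers import KmerHistogram
from .mixture import DEFAULT_MEANS


@dataclass(frozen=True)
class TargetSpec:
    """One target interval with its true diploid copy number."""

    chrom: str
    start: int
    end: int
    copy_number: float = 10.0


@dataclass
class SimulationConfig:
    """Study conditions for all three generators.

    Alignment defaults give three 3.2 Mb "autosomes" and a 20 kb target —
    proportions chosen so that read-length edge effects on the target and
    target-derived reads inside whole-autosome totals each perturb the
    estimators by well under 0.1 copies even at 13 copies, as in a real
    genome, while keeping simulation to seconds. Cohort defaults mirror a
    screening population: n = 2,402 with ~85% 10-copy samples, a rare
    8-copy ROB class, and sigma 0.15 at the consistent component means.
    """

    seed: int = 0
    # --- alignment fixture ---
    chromosomes: tuple[tuple[str, int], ...] = (
        ("chr1", 3_200_000),
        ("chr2", 3_200_000),
        ("chr3", 3_200_000),
        ("chrX", 120_000),
        ("chrY", 40_000),
    )
    targets: tuple[TargetSpec, ...] = (TargetSpec("chr1", 100_000, 120_000, 10.0),)
    depth: float = 30.0
    read_length: int = 150
    duplicate_fraction: float = 0.0
    secondary_fraction: float = 0.0
    supplementary_fraction: float = 0.0
    sex: str = "XX"  # controls chrY read density (0 for XX, haploid for XY)
    # --- k-mer spectrum ---
    error_spike_count: float = 2e6
    error_spike_decay: float = 0.4
    one_copy_peak: tuple[float, float | None, int] | None = None  # (center, sd, n)
    two_copy_peak: tuple[float, float | None, int] = (50.0, None, 1_000_000)
    marker_peak: tuple[float, float | None, int] = (250.0, None, 50_000)
    # --- cohort ---
    cohort_n: int = 2402
    mixture_means: tuple[float, ...] = DEFAULT_MEANS
    mixture_weights: tuple[float, ...] = (0.001, 0.03, 0.85, 0.02, 0.08, 0.015, 0.004)
    mixture_sigmas: float | tuple[float, ...] = 0.15

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        for frac in (
            self.duplicate_fraction,
            self.secondary_fraction,
            self.supplementary_fraction,
        ):
            if not 0 <= frac <= 1:
                raise ValueError("flag fractions must be in [0, 1]")
        w = np.asarray(self.mixture_weights, dtype=float)
        if abs(w.sum() - 1) > 1e-9 or np.any(w < 0):
            raise ValueError("mixture weights must be nonnegative and sum to 1")


# ---------------------------------------------------------------------------
# Alignment fixture
# ---------------------------------------------------------------------------


@dataclass
class AlignmentFixture:
    sam_path: Path
    bam_path: Path
    summary: AlignmentSummary
    truth: dict


def _poisson_starts(rng, n_expected: float, lo: int, hi: int) -> np.ndarray:
    """Poisson-many uniform read starts on [lo, hi)."""
    n = rng.poisson(n_expected)
    if n <= 0 or hi <= lo:
        return np.empty(0, dtype=np.int64)
    return rng.integers(lo, hi, size=n, dtype=np.int64)


def simulate_alignment_fixture(
    cfg: SimulationConfig, out_dir: str | Path, name: str = "fixture"
) -> AlignmentFixture:
    """Write ``<name>.sam`` / sorted+indexed ``<name>.bam`` plus truth JSON.

    Per-base depth is Poisson around ``cfg.depth``; inside each target
    interval the read density is multiplied by ``copy_number / 2``. chrX
    carries diploid density for XX and haploid for XY; chrY carries haploid
    density for XY only.
    """
    import pysam

    rng = np.random.default_rng(cfg.seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rl = cfg.read_length
    rate = cfg.depth / rl  # reads per base at diploid dosage

    targets_by_chrom: dict[str, list[TargetSpec]] = {}
    for t in cfg.targets:
        targets_by_chrom.setdefault(t.chrom, []).append(t)

    records: list[tuple[int, int, int, int]] = []  # (ref_idx, pos, flag, serial)
    serial = 0
    chrom_names = [c for c, _ in cfg.chromosomes]
    for ref_idx, (chrom, length) in enumerate(cfg.chromosomes):
        base_rate = rate
        if chrom in ("chrX", "X"):
            base_rate = rate if cfg.sex == "XX" else rate / 2
        elif chrom in ("chrY", "Y"):
            base_rate = 0.0 if cfg.sex == "XX" else rate / 2
        span = max(length - rl, 1)
        starts = _poisson_starts(rng, base_rate * span, 0, span)
        extra_target: list[np.ndarray] = []
        for t in targets_by_chrom.get(chrom, []):
            t_span = max(t.end - rl - t.start, 1)
            boost = t.copy_number / 2.0 - 1.0
            if boost > 0:
                extra = _poisson_starts(rng, base_rate * boost * t_span, t.start, t.start + t_span)
                extra_target.append(extra)
            elif boost < 0:
                # thin base reads inside the interval down to copy/2
                inside = (starts >= t.start) & (starts < t.end)
                keep = rng.random(starts.size) < (t.copy_number / 2.0)
                starts = starts[~inside | keep]
        if extra_target:
            starts = np.concatenate([starts] + extra_target)
        target_mask = np.zeros(starts.size, dtype=bool)
        for t in targets_by_chrom.get(chrom, []):
            target_mask |= (starts >= t.start) & (starts < t.end)

        flags = np.zeros(starts.size, dtype=np.int64)
        chrom_records = [starts, flags]

        # duplicate-flagged copies of target reads (repeat-pile-up artifact)
        if cfg.duplicate_fraction > 0 and target_mask.any():
            t_idx = np.flatnonzero(target_mask)
            pick = t_idx[rng.random(t_idx.size) < cfg.duplicate_fraction]
            chrom_records[0] = np.concatenate([starts, starts[pick]])
            chrom_records[1] = np.concatenate(
                [flags, np.full(pick.size, 0x400, dtype=np.int64)]
            )
        starts, flags = chrom_records
        # genome-wide secondary / supplementary extra records
        for frac, bit in (
            (cfg.secondary_fraction, 0x100),
            (cfg.supplementary_fraction, 0x800),
        ):
            if frac > 0 and starts.size:
                pick = np.flatnonzero(rng.random(starts.size) < frac)
                starts = np.concatenate([starts, starts[pick]])
                flags = np.concatenate([flags, np.full(pick.size, bit, dtype=np.int64)])

        order = np.argsort(starts, kind="stable")
        for pos, flag in zip(starts[order], flags[order]):
            records.append((ref_idx, int(pos), int(flag), serial))
            serial += 1

    sam_path = out_dir / f"{name}.sam"
    with open(sam_path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        for chrom, length in cfg.chromosomes:
            fh.write(f"@SQ\tSN:{chrom}\tLN:{length}\n")
        cigar = f"{rl}M"
        for ref_idx, pos, flag, ser in records:
            fh.write(
                f"r{ser:08d}\t{flag}\t{chrom_names[ref_idx]}\t{pos + 1}\t60\t"
                f"{cigar}\t*\t0\t0\t*\t*\n"
            )

    bam_path = out_dir / f"{name}.bam"
    pysam.sort("-o", str(bam_path), "-O", "bam", str(sam_path))
    pysam.index(str(bam_path))

    truth = {
        "seed": cfg.seed,
        "depth": cfg.depth,
        "read_length": rl,
        "sex": cfg.sex,
        "duplicate_fraction": cfg.duplicate_fraction,
        "secondary_fraction": cfg.secondary_fraction,
        "supplementary_fraction": cfg.supplementary_fraction,
        "targets": [asdict(t) for t in cfg.targets],
    }
    (out_dir / f"{name}.truth.json").write_text(json.dumps(truth, indent=2) + "\n")

    summary = AlignmentSummary.from_bam(bam_path)
    return AlignmentFixture(sam_path=sam_path, bam_path=bam_path, summary=summary, truth=truth)


# ---------------------------------------------------------------------------
# k-mer spectrum
# ---------------------------------------------------------------------------


def _bump(rng, center: float, sd: float | None, n: int) -> np.ndarray:
    """Rounded-Gaussian multiplicities (sd defaults to sqrt(center), the
    Poisson-like width of a coverage peak)."""
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    sd = np.sqrt(center) if sd is None else sd
    draws = np.rint(rng.normal(center, sd, size=n)).astype(np.int64)
    return draws[draws >= 1]


def simulate_kmer_spectrum(
    cfg: SimulationConfig,
) -> tuple[KmerHistogram, KmerHistogram, dict]:
    """(full spectrum, marker sub-histogram, truth record).

    The full spectrum is the error spike (counts decaying geometrically
    from multiplicity 1, Poisson-sampled) plus the configured 1-copy,
    2-copy and marker bumps. Truth holds the bump centers.
    """
    rng = np.random.default_rng(cfg.seed)
    counts: dict[int, int] = {}
    m = 1
    expected = cfg.error_spike_count
    while expected >= 0.5 and m < 1000:
        n = int(rng.poisson(expected))
        if n:
            counts[m] = counts.get(m, 0) + n
        expected *= cfg.error_spike_decay
        m += 1

    bumps = []
    if cfg.one_copy_peak is not None:
        bumps.append(cfg.one_copy_peak)
    bumps.append(cfg.two_copy_peak)
    marker_mults = _bump(rng, *cfg.marker_peak)
    for center, sd, n in bumps:
        for mult in _bump(rng, center, sd, n):
            counts[int(mult)] = counts.get(int(mult), 0) + 1
    # marker k-mers are part of the read spectrum too
    for mult in marker_mults:
        counts[int(mult)] = counts.get(int(mult), 0) + 1

    full = KmerHistogram(counts)
    marker_hist = KmerHistogram.from_multiplicities(marker_mults)
    truth = {
        "seed": cfg.seed,
        "one_copy_peak": cfg.one_copy_peak[0] if cfg.one_copy_peak else None,
        "two_copy_peak": cfg.two_copy_peak[0],
        "marker_peak": cfg.marker_peak[0],
        "true_copy_number": 2.0 * cfg.marker_peak[0] / cfg.two_copy_peak[0],
    }
    return full, marker_hist, truth


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------


def simulate_cohort(cfg: SimulationConfig, path: str | Path | None = None) -> pd.DataFrame:
    """Cohort of continuous copy-number draws from a Gaussian mixture.

    Returns a DataFrame with columns ``sample, cn, component`` (the true
    component index is the ground-truth label); optionally written as TSV.
    """
    rng = np.random.default_rng(cfg.seed)
    means = np.asarray(cfg.mixture_means, dtype=float)
    weights = np.asarray(cfg.mixture_weights, dtype=float)
    sigmas = (
        np.full(means.size, cfg.mixture_sigmas)
        if np.isscalar(cfg.mixture_sigmas)
        else np.asarray(cfg.mixture_sigmas, dtype=float)
    )
    comp = rng.choice(means.size, size=cfg.cohort_n, p=weights)
    values = rng.normal(means[comp], sigmas[comp])
    df = pd.DataFrame(
        {
            "sample": [f"s{i:05d}" for i in range(cfg.cohort_n)],
            "cn": values,
            "component": comp,
        }
    )
    if path is not None:
        df.to_csv(path, sep="\t", index=False, float_format="%.6f")
    return df
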