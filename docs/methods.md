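# Methods

## Problem and model

A diploid human genome carries ten rDNA distal junctions (DJ), one per
acrocentric haplotype. A Robertsonian fusion removes two, so the copy
number of the DJ — estimated from nothing more than read dosage — is a
carrier screen. The package estimates that dosage three ways (per-base
depth, read counts, k-mer multiplicities), harmonizes estimates across
reference builds, discretizes them with a constrained mixture model, and
bounds the misclassification rates analytically.

All estimators share one identity: a sequence present in ``c`` copies per
diploid genome attracts ``c/2`` times the read dosage of single-copy
(2-copy diploid) background, hence ``CN = 2 × target/background``
coverage. The modes differ only in how "coverage" is measured and which
reads are admitted, trading accuracy against the cost of touching every
read (per-base depth) versus index-level counters (the fast modes). The
filtered modes exclude reads whose SAM flag intersects 3332 (unmapped,
secondary, duplicate, supplementary); this matters on references where
the target is collapsed or mis-assembled and attracts duplicate-like
pile-ups that inflate unfiltered counts.

## Conventions and numerical choices

- **Coordinates** are 0-based half-open everywhere (BED and PAF native).
- **Histogram medians** (k-mer multiplicities) use the strict-``>``
  cumulative rule: the smallest value whose running count exceeds half
  the total. **Interval depth medians** use the conventional
  average-of-central-values median, over positions with depth ≥ 1 by
  default (an ``include_zero`` switch covers depth streams that emit all
  positions). The two conventions are deliberately separate and tested
  separately, matching the distinct toolchains each mimics.
- **Read counting** over multi-interval targets counts a read once per
  overlapped interval (region-query semantics); a ``unique`` policy
  de-duplicates by read name.
- **Zero denominators** raise immediately (`UndefinedEstimateError`);
  NaNs never propagate.
- **Binning** rounds to the nearest integer with .5 rounding up. The
  alternative ``dj_threshold`` rule moves only the 10/11 boundary down to
  10.4, reflecting the empirical gap between the 10-copy bulk and gain
  samples; the two rules agree everywhere else and on every reference
  family-trio value.
- **Target transfer** between builds filters PAF records by alignment
  block length (strictly shorter than 10 kb dropped; exactly 10 kb kept),
  identity (100 × matches / block length) and donor-target coverage, then
  merges surviving query intervals with 0 bp gap tolerance.
- **Sex inference** calls XX when covX/covY > 4 (or covY = 0), else XY;
  the call selects the sex-chromosome-complement-matched masked
  reference downstream.

## k-mer estimator

Marker k-mers (default k = 31, canonical = lexicographic min of the
strand pair) must occur exactly once in every DJ unit, so their read
multiplicity is proportional to DJ copy number. The diploid scale factor
is the 2-copy peak of the whole-read spectrum, found after excluding the
sequencing-error region (everything up to the first local minimum, and at
least multiplicity 5) and lightly smoothing (centered moving average,
window 3). Candidate copy peaks must reach 5% of the tallest peak's
distinct-k-mer count: high-multiplicity repeat or marker bumps hold
orders of magnitude fewer distinct k-mers than the genome-wide diploid
peak, and without this floor a homozygous-like spectrum (no 1-copy bump)
would hand the marker bump itself to the calibrator. With one surviving
peak it is the 2-copy peak; with several, the tallest at or beyond the
second-lowest position wins and anything left of it is the 1-copy peak.

Marker refinement against calibration reads keeps multiplicities inside
``kcov × (c ± 0.5)`` with floor/ceil rounding; ``kcov`` (haploid k-mer
coverage) is an input fitted externally from the spectrum, with
``2-copy peak / 2`` as fallback. A round-to-multiple-of-25 preset
reproduces hand-set calibration bands (e.g. 475–525 at kcov 49.9).

## Mixture classification

Free-mean mixtures collapse on a screening cohort that is ~85–90%
ten-copy: rare components wander or vanish. Means are therefore fixed at
`[8, 9.1, 10.1, 10.7, 11.1, 11.9, 13]` (peak locations consistent across
cohorts; `find_consistent_peaks` re-derives them from ≥ 100-sample
cohorts), and EM updates only weights and sigmas, with σ projected into
[0.1, 0.2] after each M-step. Initialization: uniform weights, σ at the
bounds midpoint. Convergence: relative log-likelihood change < 1e-10
(an absolute mode exists), max 500 iterations. Log-likelihood is
guaranteed non-decreasing only across unclamped iterations (projected
EM); trajectories record both the value and whether clamping fired.

Bootstrap aggregation resamples the cohort with replacement B times
(default 1000), fits each replicate, and averages weights and sigmas;
weights are renormalized after averaging (the sum is already 1 to float
error). Replicates that fail to fit are dropped with a warning, > 10%
failures abort.

Classification evaluates ``ψ_k N(x; u_k, σ_k)`` in log space —
mandatory, so far-tail samples never underflow to an all-zero
posterior — and assigns the maximum a posteriori component.
Log-posteriors within 1e-9 of the maximum are treated as tied and
resolved toward the lower mean (a value at exactly 10.4 between the 10.1
and 10.7 components bins as 10). The 10.7 component is an intermediate
partial-duplication class; only bin 8 (or lower) flags a ROB candidate.

A known geometric limit: values drawn with σ = 0.1 *around* 10.7 or 11.1
cannot be recovered at 99% — their neighbors sit 0.4 copies away, so even
an equal-weight midpoint boundary is only 2σ out. Well-separated
components (nearest neighbor ≥ 0.6) and cohort-weighted accuracy do reach
99%, and exact component means always classify to their own bin.

## Rate model

The FP/FN model assumes the ten acrocentric haplotypes are independent
and exchangeable, and attributes the whole 9-DJ cohort frequency to
single-haplotype deletion (measurement noise contributing to that
frequency is not modeled — the rates are therefore conservative upper
bounds on the deletion process). Small probabilities go through
``log1p``/``expm1``. The end-to-end report also expresses the FP rate as
a share of an observed 8-DJ frequency, capped at 1 with a warning. Note
the binomial point mass is increasing in p only up to p = k/n; it is not
monotone on all of [0, 1].

## Synthetic fixtures

The generators produce every input the pipeline consumes, with known
truth, deterministically per seed (byte-identical text outputs).

*Alignments*: fixed-length (150 bp) single-end placements, Poisson read
starts at per-base rate depth/150, multiplied by ``copy/2`` inside target
intervals; three 3.2 Mb autosomes and a 20 kb target. These proportions
keep the two geometric artifacts of a toy genome — read-length edge
effects at target boundaries, and target-derived reads inflating
whole-autosome totals — below ~0.1 copies at CN 13 (measured recovery
bias ≤ 0.2 per mode at 30×). Duplicate flags are injected on target
reads only, emulating the repeat-pile-up artifact the filtered modes
exist to remove (and making the `fast` vs `fast_precise` contrast
testable: with duplicate fraction d, their ratio is ≈ 1 + d);
secondary/supplementary flags are injected genome-wide. chrX/chrY read
density follows the configured sex (diploid/zero for XX, haploid/haploid
for XY). Not emulated: base-level sequencing error, GC bias, read
pairing, mapping ambiguity — so passing recovery tests demonstrates the
normalization arithmetic and filtering logic, not robustness to
alignment artifacts on real genomes.

*k-mer spectra*: a geometric error spike from multiplicity 1 plus
rounded-Gaussian bumps (sd defaults to √center, the Poisson width of a
coverage peak) for the 1-copy, 2-copy and marker peaks, Poisson/Gaussian
sampled per seed. Real spectra additionally carry heterozygosity
structure and contamination modes.

*Cohorts*: n draws from the 7-component mixture at the default means,
weights (0.001, 0.03, 0.85, 0.02, 0.08, 0.015, 0.004) and σ = 0.15 —
the composition of a large screening population — with true component
labels retained.

## Problem sizes used in tests and the acceptance script

Alignment recovery runs at 30× over the ~9.8 Mb toy genome (≈ 2 M reads
per fixture) for true CN ∈ {8, 10, 13} plus a 30%-duplicate fixture;
k-mer recovery uses 100 seeded spectra per condition; the mixture re-fit
uses n = 2,402 with B = 200 bootstrap replicates (a scaled-down B — the
aggregate is an average, so its bias does not depend on B and its Monte
Carlo error at B = 200 is already far below the ±0.02 recovery check);
harmonization uses 92-sample designs. These sizes make the full suite
run in a few minutes while leaving each check's noise floor well below
its tolerance.

## Known limitations

- Aggregate dosage only: the method counts DJs, it cannot say *which*
  acrocentric lost one, and cannot distinguish a true fusion from two
  coincident deletions (hence the FP model; confirmation needs FISH,
  karyotype or Hi-C).
- Canonical target coordinates on real references are user-supplied
  inputs (shipped BEDs / supplementary tables), not computed here.
- The k-mer counter is streamed pure Python, intended for unit sequences
  and small read sets; genome-scale spectra should arrive as precomputed
  two-column histograms.
- ``kcov`` is taken as input; the built-in fallback (half the 2-copy
  peak) ignores heterozygosity.
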