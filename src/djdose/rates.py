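"""Analytic false-positive / false-negative rates for ROB calling.

A Robertsonian-translocation (ROB) carrier loses two of the ten acrocentric
DJ copies, so 8 DJs is the screening signature. Treating the ten acrocentric
haplotypes as independent and exchangeable:

* a cohort frequency ``f_loss`` of 9-DJ samples implies a per-haplotype
  DJ-deletion probability ``p_del = 1 - (1 - f_loss)^(1/10)``;
* two independent deletions mimic the 8-DJ signature without any fusion,
  so ``P(FP) = C(10,2) p_del^2 (1 - p_del)^8``;
* a true carrier with a duplicated DJ on one of its 8 unaffected
  haplotypes climbs back to >8 copies, so with per-haplotype duplication
  probability ``p_dup`` (from the >=11-DJ frequency ``f_gain``),
  ``P(FN | ROB) = 1 - (1 - p_dup)^8``.

Small probabilities are computed through ``log1p``/``expm1`` forms.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path


def per_haplotype_rate(f: float, n: int = 10) -> float:
    """Per-haplotype event probability from a cohort frequency.

    Inverts ``f = 1 - (1 - p)^n`` under haplotype independence:
    ``p = 1 - (1 - f)^(1/n)``.
    """
    if not 0 <= f < 1:
        raise ValueError(f"cohort frequency must be in [0, 1), got {f}")
    if n < 1:
        raise ValueError("haplotype count must be >= 1")
    return -math.expm1(math.log1p(-f) / n)


def fp_rate(p: float, n: int = 10, k: int = 2) -> float:
    """Binomial point mass: exactly ``k`` of ``n`` haplotypes lack a DJ.

    With ``k = 2`` this is the probability that independent deletions
    mimic the 8-DJ carrier signature without a fusion.
    """
    if not 0 <= p <= 1:
        raise ValueError(f"probability must be in [0, 1], got {p}")
    if k > n or k < 0:
        raise ValueError(f"k={k} out of range for n={n}")
    if p == 0:
        return 0.0 if k > 0 else 1.0
    if p == 1:
        return 1.0 if k == n else 0.0
    log_mass = (
        math.log(math.comb(n, k)) + k * math.log(p) + (n - k) * math.log1p(-p)
    )
    return math.exp(log_mass)


def fn_rate(p_dup: float, m: int = 8) -> float:
    """Probability a true carrier exceeds 8 DJs via >=1 duplication.

    ``1 - (1 - p_dup)^m`` over the carrier's ``m`` non-fused acrocentric
    haplotypes.
    """
    if not 0 <= p_dup <= 1:
        raise ValueError(f"probability must be in [0, 1], got {p_dup}")
    if m < 0:
        raise ValueError("haplotype count must be >= 0")
    if m == 0:
        return 0.0
    return -math.expm1(m * math.log1p(-p_dup))


@dataclass
class RateModel:
    """End-to-end rate report from cohort frequencies."""

    f_loss: float
    f_gain: float
    n_haplotypes: int
    m_unaffected: int
    p_del: float
    p_dup: float
    fp_rate: float
    fn_rate: float
    observed_8dj_frequency: float | None = None
    fp_fraction_of_observed: float | None = None

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def rate_report(
    f_loss: float,
    f_gain: float,
    observed_8dj_frequency: float | None = None,
    n_haplotypes: int = 10,
    n_deleted: int = 2,
    m_unaffected: int = 8,
) -> RateModel:
    """Cohort frequencies in, per-haplotype rates and FP/FN out.

    ``observed_8dj_frequency`` (the cohort's empirical 8-DJ fraction), when
    given, yields the share of observed 8-DJ calls the deletion model alone
    can explain; shares above 1 are capped with a warning.
    """
    p_del = per_haplotype_rate(f_loss, n_haplotypes)
    p_dup = per_haplotype_rate(f_gain, n_haplotypes)
    fp = fp_rate(p_del, n_haplotypes, n_deleted)
    fn = fn_rate(p_dup, m_unaffected)
    fraction = None
    if observed_8dj_frequency is not None:
        if observed_8dj_frequency <= 0:
            raise ValueError("observed 8-DJ frequency must be positive")
        fraction = fp / observed_8dj_frequency
        if fraction > 1:
            warnings.warn(
                "modeled FP rate exceeds the observed 8-DJ frequency; capping at 1",
                stacklevel=2,
            )
            fraction = 1.0
    return RateModel(
        f_loss=f_loss,
        f_gain=f_gain,
        n_haplotypes=n_haplotypes,
        m_unaffected=m_unaffected,
        p_del=p_del,
        p_dup=p_dup,
        fp_rate=fp,
        fn_rate=fn,
        observed_8dj_frequency=observed_8dj_frequency,
        fp_fraction_of_observed=fraction,
    )
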