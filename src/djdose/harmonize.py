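"""Cross-reference calibration of copy-number estimates.

Copy numbers estimated against different reference builds sit on slightly
different scales (reference bias, collapsed copies). A simple ordinary
least squares model ``y = b0 + b1 x + e`` maps source-scale estimates onto
the target scale; among several candidate source modes the one with the
lowest residual sum of squares is preferred. A rank-sum test with the
rank-biserial correlation as effect size checks whether two cohorts of
estimates are distributionally comparable.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import statsmodels.api as sm
from scipy.stats import mannwhitneyu

from .errors import DegenerateDesignError


@dataclass
class LinearTransform:
    """Fitted OLS map from one copy-number scale to another."""

    beta0: float
    beta1: float
    residual_variance: float
    rss: float
    n: int
    source_mode: str = ""
    target_scale: str = ""

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2)

    @classmethod
    def from_json(cls, path: str | Path) -> "LinearTransform":
        with open(path) as fh:
            return cls(**json.load(fh))


def fit_linear_transform(
    x: Sequence[float],
    y: Sequence[float],
    source_mode: str = "",
    target_scale: str = "",
) -> LinearTransform:
    """OLS fit of ``y = b0 + b1 x``; reports RSS and residual variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d sequences")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 paired estimates")
    if np.ptp(x) == 0:
        raise DegenerateDesignError("constant predictor: slope is unidentifiable")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    dof = max(n - 2, 1)
    return LinearTransform(
        beta0=float(res.params[0]),
        beta1=float(res.params[1]),
        residual_variance=float(res.ssr / dof),
        rss=float(res.ssr),
        n=int(n),
        source_mode=source_mode,
        target_scale=target_scale,
    )


def apply_transform(t: LinearTransform, values: Sequence[float]) -> np.ndarray:
    """Map source-scale values onto the target scale: ``b0 + b1 x``."""
    return t.beta0 + t.beta1 * np.asarray(values, dtype=float)


def select_mode_by_rss(candidates: Mapping[str, LinearTransform]) -> str:
    """Mode whose transform has minimal RSS; name-order tie-break with warning."""
    if not candidates:
        raise ValueError("no candidate transforms")
    best = min(sorted(candidates), key=lambda m: candidates[m].rss)
    ties = [m for m in candidates if candidates[m].rss == candidates[best].rss]
    if len(ties) > 1:
        warnings.warn(f"RSS tie among modes {sorted(ties)}; keeping {best!r}", stacklevel=2)
    return best


@dataclass
class ComparisonReport:
    """Two-sided rank-sum comparison of two cohorts of estimates."""

    statistic: float  # Mann-Whitney U of the first sample
    p_value: float
    rank_biserial: float
    alpha: float
    indistinguishable: bool


def compare_distributions(
    a: Sequence[float], b: Sequence[float], alpha: float = 0.05
) -> ComparisonReport:
    """Mann-Whitney U test with rank-biserial correlation effect size.

    ``RBC = 1 - 2U/(n_a n_b)``: +1 when every ``a`` is below every ``b``,
    -1 for the reverse, 0 for fully interleaved samples. The cohorts are
    flagged ``indistinguishable`` when p exceeds ``alpha``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples need at least 2 observations")
    res = mannwhitneyu(a, b, alternative="two-sided")
    u = float(res.statistic)
    rbc = 1.0 - 2.0 * u / (a.size * b.size)
    return ComparisonReport(
        statistic=u,
        p_value=float(res.pvalue),
        rank_biserial=rbc,
        alpha=alpha,
        indistinguishable=bool(res.pvalue > alpha),
    )


def train_test_split(
    values: Sequence[float], train_fraction: float = 0.75, seed: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded random split of a cohort (default 0.75/0.25)."""
    values = np.asarray(values, dtype=float)
    rng = np.random.default_rng(seed)
    idx = rng.permutation(values.size)
    n_train = int(round(train_fraction * values.size))
    return values[idx[:n_train]], values[idx[n_train:]]
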