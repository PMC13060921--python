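"""One-dimensional Gaussian mixture classification of DJ copy numbers.

A free-mean mixture collapses on sparsely populated classes (a screening
cohort is ~85-90% ten-copy samples), so component means are *fixed* at
empirically consistent peak locations and only the weights and standard
deviations are fitted, with the standard deviations constrained to a
narrow band (default [0.1, 0.2]) by projection after each M-step.
Uncertainty is quantified by a nonparametric bootstrap whose per-replicate
weights and sigmas are averaged into the final model. Classification is
maximum a posteriori over the fitted components, evaluated in log space.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks
from scipy.special import logsumexp
from scipy.stats import norm

from .errors import MixtureFitError

#: component means consistent across screening cohorts (diploid DJ copies)
DEFAULT_MEANS: tuple[float, ...] = (8.0, 9.1, 10.1, 10.7, 11.1, 11.9, 13.0)
#: bin labels; the 10.7 component is an intermediate partial-duplication class
DEFAULT_LABELS: tuple[int | str, ...] = (8, 9, 10, "10-11", 11, 12, 13)
DEFAULT_SIGMA_BOUNDS: tuple[float, float] = (0.1, 0.2)


@dataclass
class BootstrapSummary:
    B: int
    seed: int | None
    weight_replicates: np.ndarray  # (B_ok, K)
    sigma_replicates: np.ndarray  # (B_ok, K)
    n_failed: int
    weights_renormalized: bool = True


@dataclass
class MixtureModel:
    """Gaussian mixture with fixed, strictly increasing component means."""

    means: np.ndarray
    weights: np.ndarray
    sigmas: np.ndarray
    sigma_bounds: tuple[float, float] = DEFAULT_SIGMA_BOUNDS
    labels: tuple[int | str, ...] | None = None
    converged: bool = False
    n_iter: int = 0
    log_likelihood: float = float("nan")
    trajectory: list[tuple[float, bool]] = field(default_factory=list)
    bootstrap: BootstrapSummary | None = None

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        self.sigmas = np.asarray(self.sigmas, dtype=float)
        if not np.all(np.diff(self.means) > 0):
            raise ValueError("component means must be strictly increasing")
        if np.any(self.weights < 0) or abs(self.weights.sum() - 1) > 1e-8:
            raise ValueError("weights must be nonnegative and sum to 1")
        lo, hi = self.sigma_bounds
        if np.any(self.sigmas < lo - 1e-12) or np.any(self.sigmas > hi + 1e-12):
            raise ValueError("sigmas outside declared bounds")
        if self.labels is None:
            self.labels = tuple(
                int(m) if float(m).is_integer() else f"{m:g}" for m in self.means
            )
        if len(self.labels) != self.means.size:
            raise ValueError("one label per component required")

    @property
    def n_components(self) -> int:
        return int(self.means.size)

    def to_json(self, path: str | Path) -> None:
        d = {
            "means": self.means.tolist(),
            "weights": self.weights.tolist(),
            "sigmas": self.sigmas.tolist(),
            "sigma_bounds": list(self.sigma_bounds),
            "labels": list(self.labels),
            "converged": self.converged,
            "n_iter": self.n_iter,
            "log_likelihood": self.log_likelihood,
        }
        if self.bootstrap is not None:
            d["bootstrap"] = {
                "B": self.bootstrap.B,
                "seed": self.bootstrap.seed,
                "n_failed": self.bootstrap.n_failed,
                "weights_renormalized": self.bootstrap.weights_renormalized,
            }
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)

    @classmethod
    def from_json(cls, path: str | Path) -> "MixtureModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            means=np.array(d["means"]),
            weights=np.array(d["weights"]),
            sigmas=np.array(d["sigmas"]),
            sigma_bounds=tuple(d.get("sigma_bounds", DEFAULT_SIGMA_BOUNDS)),
            labels=tuple(d["labels"]) if "labels" in d else None,
            converged=d.get("converged", False),
            n_iter=d.get("n_iter", 0),
            log_likelihood=d.get("log_likelihood", float("nan")),
        )


# ---------------------------------------------------------------------------
# Peak consistency across cohorts
# ---------------------------------------------------------------------------


def find_consistent_peaks(
    cohorts: Sequence[Sequence[float]],
    tolerance: float = 0.1,
    bin_width: float = 0.1,
    prominence: float | None = None,
) -> list[float]:
    """Density-peak locations present (within ``tolerance``) in every cohort.

    Each cohort is binned at ``bin_width`` and local maxima are collected
    with :func:`scipy.signal.find_peaks` (default prominence: 0.5% of the
    cohort size). Peaks from the first cohort that have a match in every
    other cohort are returned as the across-cohort mean location, sorted
    ascending. Intended for cohorts of >= 100 samples; smaller cohorts
    trigger a warning.
    """
    if not cohorts:
        raise ValueError("need at least one cohort")
    per_cohort: list[list[float]] = []
    for data in cohorts:
        data = np.asarray(data, dtype=float)
        if data.size < 100:
            warnings.warn(
                f"cohort of {data.size} samples is small for peak detection",
                stacklevel=2,
            )
        lo = np.floor(data.min() / bin_width) * bin_width
        hi = np.ceil(data.max() / bin_width) * bin_width + bin_width
        edges = np.arange(lo, hi + bin_width / 2, bin_width)
        counts, edges = np.histogram(data, bins=edges)
        prom = prominence if prominence is not None else max(1.0, 0.005 * data.size)
        # pad so that boundary maxima are still detectable
        idx, _ = find_peaks(np.concatenate([[0.0], counts, [0.0]]), prominence=prom)
        centers = (edges[:-1] + edges[1:]) / 2.0
        per_cohort.append([float(centers[i - 1]) for i in idx])

    consistent: list[float] = []
    for p in per_cohort[0]:
        matches = [p]
        ok = True
        for peaks in per_cohort[1:]:
            close = [q for q in peaks if abs(q - p) <= tolerance]
            if not close:
                ok = False
                break
            matches.append(min(close, key=lambda q: abs(q - p)))
        if ok:
            consistent.append(float(np.mean(matches)))
    if not consistent:
        raise MixtureFitError(
            "no peaks consistent across cohorts; consider the fixed default means"
        )
    return sorted(consistent)


# ---------------------------------------------------------------------------
# EM with fixed means
# ---------------------------------------------------------------------------


def _log_component_densities(x: np.ndarray, model_w, model_u, model_s) -> np.ndarray:
    with np.errstate(divide="ignore"):
        log_w = np.log(model_w)
    return log_w[None, :] + norm.logpdf(x[:, None], loc=model_u[None, :], scale=model_s[None, :])


def em_fit_fixed_means(
    data: Sequence[float],
    means: Sequence[float] | None = None,
    sigma_bounds: tuple[float, float] = DEFAULT_SIGMA_BOUNDS,
    labels: tuple[int | str, ...] | None = None,
    max_iter: int = 500,
    tol: float = 1e-10,
    tol_mode: str = "relative",
    init_weights: Sequence[float] | None = None,
    init_sigma: float | None = None,
) -> MixtureModel:
    """Projected EM for a Gaussian mixture with fixed component means.

    E-step responsibilities r_ik ∝ w_k N(x_i; u_k, s_k); M-step updates
    ``w_k = mean_i r_ik`` and ``s_k^2 = sum_i r_ik (x_i - u_k)^2 / sum_i r_ik``
    with each ``s_k`` clamped into ``sigma_bounds`` (the means never move).
    Convergence: change in log-likelihood below ``tol`` (relative change by
    default; ``tol_mode="absolute"`` compares the raw difference). The
    iteration trajectory records ``(log_likelihood, clamped)`` pairs —
    log-likelihood is guaranteed non-decreasing only across unclamped
    iterations.
    """
    x = np.asarray(data, dtype=float)
    u = np.asarray(DEFAULT_MEANS if means is None else means, dtype=float)
    if means is None and labels is None:
        labels = DEFAULT_LABELS
    k = u.size
    if x.size < k:
        raise ValueError(f"need at least {k} observations for {k} components")
    if not np.all(np.isfinite(x)):
        raise ValueError("data must be finite")
    lo, hi = sigma_bounds
    w = (
        np.full(k, 1.0 / k)
        if init_weights is None
        else np.asarray(init_weights, dtype=float)
    )
    s = np.full(k, (lo + hi) / 2.0 if init_sigma is None else init_sigma)

    trajectory: list[tuple[float, bool]] = []
    ll_prev = -np.inf
    converged = False
    n_iter = 0
    tiny = np.finfo(float).tiny
    for n_iter in range(1, max_iter + 1):
        log_dens = _log_component_densities(x, w, u, s)
        log_norm = logsumexp(log_dens, axis=1)
        ll = float(log_norm.sum())
        if not np.isfinite(ll):
            raise MixtureFitError(f"non-finite log-likelihood at iteration {n_iter}")
        resp = np.exp(log_dens - log_norm[:, None])

        nk = resp.sum(axis=0)
        w_new = nk / x.size
        var = np.empty(k)
        for j in range(k):
            if nk[j] > tiny:
                var[j] = float(resp[:, j] @ (x - u[j]) ** 2 / nk[j])
            else:
                var[j] = s[j] ** 2  # empty component: keep its sigma
        s_new = np.sqrt(np.maximum(var, tiny))
        s_clamped = np.clip(s_new, lo, hi)
        clamped = bool(np.any(s_clamped != s_new))
        w, s = w_new, s_clamped
        trajectory.append((ll, clamped))

        delta = abs(ll - ll_prev)
        ref = abs(ll_prev) if tol_mode == "relative" else 1.0
        if np.isfinite(ll_prev) and delta < tol * max(ref, tiny):
            converged = True
            break
        ll_prev = ll

    return MixtureModel(
        means=u,
        weights=w / w.sum(),
        sigmas=s,
        sigma_bounds=sigma_bounds,
        labels=labels,
        converged=converged,
        n_iter=n_iter,
        log_likelihood=trajectory[-1][0],
        trajectory=trajectory,
    )


def bootstrap_fit(
    data: Sequence[float],
    B: int = 1000,
    seed: int | None = None,
    means: Sequence[float] | None = None,
    sigma_bounds: tuple[float, float] = DEFAULT_SIGMA_BOUNDS,
    labels: tuple[int | str, ...] | None = None,
    max_failure_fraction: float = 0.1,
    **em_kwargs,
) -> MixtureModel:
    """Bootstrap-aggregated mixture fit.

    Draws ``B`` resamples with replacement, fits each with
    :func:`em_fit_fixed_means`, and averages the per-replicate weights and
    sigmas (weights renormalized after averaging). Replicates that fail to
    fit are dropped with a warning; more than ``max_failure_fraction``
    failures aborts.
    """
    x = np.asarray(data, dtype=float)
    rng = np.random.default_rng(seed)
    w_reps, s_reps = [], []
    n_failed = 0
    for _ in range(B):
        sample = x[rng.integers(0, x.size, size=x.size)]
        try:
            fit = em_fit_fixed_means(
                sample, means=means, sigma_bounds=sigma_bounds, labels=labels, **em_kwargs
            )
        except MixtureFitError as exc:  # pragma: no cover - rare numeric failure
            n_failed += 1
            warnings.warn(f"bootstrap replicate failed: {exc}", stacklevel=2)
            continue
        w_reps.append(fit.weights)
        s_reps.append(fit.sigmas)
    if n_failed > max_failure_fraction * B:
        raise MixtureFitError(f"{n_failed}/{B} bootstrap replicates failed")
    w_mat = np.vstack(w_reps)
    s_mat = np.vstack(s_reps)
    w_mean = w_mat.mean(axis=0)
    model = MixtureModel(
        means=np.asarray(DEFAULT_MEANS if means is None else means, dtype=float),
        weights=w_mean / w_mean.sum(),
        sigmas=np.clip(s_mat.mean(axis=0), *sigma_bounds),
        sigma_bounds=sigma_bounds,
        labels=DEFAULT_LABELS if (means is None and labels is None) else labels,
        converged=True,
        n_iter=0,
        log_likelihood=float("nan"),
        bootstrap=BootstrapSummary(
            B=B,
            seed=seed,
            weight_replicates=w_mat,
            sigma_replicates=s_mat,
            n_failed=n_failed,
        ),
    )
    return model


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

#: log-posterior gap treated as a tie (resolved toward the lower mean)
_TIE_TOL = 1e-9


@dataclass
class Classification:
    """MAP assignment of one copy-number value to a mixture component."""

    value: float
    posterior: np.ndarray
    component: int
    bin: int | str
    map_probability: float

    def __post_init__(self) -> None:
        if abs(self.posterior.sum() - 1) > 1e-9:
            raise ValueError("posterior must be normalized")


def classify_sample(x: float, model: MixtureModel) -> Classification:
    """Posterior membership probabilities and the MAP bin for one value.

    The unnormalized posterior is ``w_k N(x; u_k, s_k)``, evaluated and
    normalized in log space so extreme tails never underflow to an
    all-zero posterior. Log-posteriors within a small tolerance of the
    maximum are treated as tied and resolved toward the lower mean.
    """
    xa = np.asarray([float(x)])
    log_dens = _log_component_densities(xa, model.weights, model.means, model.sigmas)[0]
    log_post = log_dens - logsumexp(log_dens)
    best = float(log_post.max())
    tol = _TIE_TOL * max(1.0, abs(best))
    component = int(np.flatnonzero(log_post >= best - tol)[0])
    posterior = np.exp(log_post)
    posterior /= posterior.sum()
    return Classification(
        value=float(x),
        posterior=posterior,
        component=component,
        bin=model.labels[component],
        map_probability=float(posterior[component]),
    )


def classify_cohort(values: Sequence[float], model: MixtureModel):
    """Classify many values; returns a tidy DataFrame (one row per sample)."""
    import pandas as pd

    rows = []
    for i, v in enumerate(values):
        c = classify_sample(v, model)
        row = {"sample": f"s{i}", "cn": c.value, "bin": c.bin, "map_prob": c.map_probability}
        for j in range(model.n_components):
            row[f"posterior_{model.labels[j]}"] = c.posterior[j]
        rows.append(row)
    return pd.DataFrame(rows)
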