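import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from djdose.errors import MixtureFitError
from djdose.mixture import (
    DEFAULT_LABELS,
    DEFAULT_MEANS,
    MixtureModel,
    bootstrap_fit,
    classify_sample,
    em_fit_fixed_means,
    find_consistent_peaks,
)

WEIGHTS_TRUTH = (0.001, 0.03, 0.85, 0.02, 0.08, 0.015, 0.004)


def _draw(n=2000, weights=WEIGHTS_TRUTH, sigma=0.15, seed=0):
    rng = np.random.default_rng(seed)
    comp = rng.choice(len(DEFAULT_MEANS), size=n, p=weights)
    return np.asarray(DEFAULT_MEANS)[comp] + rng.normal(0, sigma, n), comp


def _equal_model(sigma=0.15):
    k = len(DEFAULT_MEANS)
    return MixtureModel(
        means=np.array(DEFAULT_MEANS),
        weights=np.full(k, 1 / k),
        sigmas=np.full(k, sigma),
        labels=DEFAULT_LABELS,
    )


# ---------------------------------------------------------------------------
# EM fitting
# ---------------------------------------------------------------------------


def test_point_mass_at_first_mean_clamps_sigma_to_floor():
    fit = em_fit_fixed_means(np.full(200, 8.0))
    assert fit.weights[0] == pytest.approx(1.0, abs=1e-6)
    assert fit.sigmas[0] == pytest.approx(0.1)


def test_single_component_recovery_from_seeded_draws():
    rng = np.random.default_rng(42)
    data = rng.normal(10.1, 0.15, 2000)
    fit = em_fit_fixed_means(data)
    assert fit.weights[2] >= 0.95
    assert 0.13 <= fit.sigmas[2] <= 0.17


def test_one_component_model_is_trivial():
    rng = np.random.default_rng(1)
    data = rng.normal(10.0, 0.15, 500)
    fit = em_fit_fixed_means(data, means=[10.0])
    assert fit.weights == pytest.approx([1.0])
    assert 0.1 <= fit.sigmas[0] <= 0.2


def test_full_mixture_weight_recovery_single_fit():
    data, _ = _draw(n=2402, seed=3)
    fit = em_fit_fixed_means(data)
    assert np.abs(fit.weights - np.array(WEIGHTS_TRUTH)).max() < 0.02
    assert np.all(fit.sigmas >= 0.1) and np.all(fit.sigmas <= 0.2)
    assert fit.converged and fit.n_iter <= 500


def test_log_likelihood_non_decreasing_across_unclamped_iterations():
    data, _ = _draw(n=1500, seed=9)
    fit = em_fit_fixed_means(data)
    lls = [ll for ll, _ in fit.trajectory]
    clamped = [c for _, c in fit.trajectory]
    for i in range(len(lls) - 1):
        if not clamped[i]:
            assert lls[i + 1] >= lls[i] - 1e-8


def test_non_finite_data_rejected():
    with pytest.raises(ValueError):
        em_fit_fixed_means([8.0, np.nan] + [10.0] * 10)


# ---------------------------------------------------------------------------
# bootstrap aggregation
# ---------------------------------------------------------------------------


def test_bootstrap_b1_equals_single_fit_on_the_resample():
    data, _ = _draw(n=400, seed=5)
    boot = bootstrap_fit(data, B=1, seed=123)
    rng = np.random.default_rng(123)
    resample = data[rng.integers(0, data.size, size=data.size)]
    single = em_fit_fixed_means(resample)
    np.testing.assert_allclose(boot.weights, single.weights, atol=1e-12)
    np.testing.assert_allclose(boot.sigmas, single.sigmas, atol=1e-12)


def test_degenerate_data_any_b_gives_point_mass():
    boot = bootstrap_fit(np.full(100, 8.0), B=5, seed=0)
    assert boot.weights[0] == pytest.approx(1.0, abs=1e-6)
    assert boot.sigmas[0] == pytest.approx(0.1)


def test_bootstrap_stable_across_seeds():
    data, _ = _draw(n=800, seed=21)
    b1 = bootstrap_fit(data, B=30, seed=1)
    b2 = bootstrap_fit(data, B=30, seed=2)
    assert np.abs(b1.weights - b2.weights).max() < 0.02


def test_bootstrap_metadata_and_json(tmp_path):
    data, _ = _draw(n=300, seed=2)
    boot = bootstrap_fit(data, B=8, seed=4)
    assert boot.bootstrap.B == 8
    assert boot.bootstrap.weight_replicates.shape == (8, 7)
    path = tmp_path / "model.json"
    boot.to_json(path)
    loaded = MixtureModel.from_json(path)
    np.testing.assert_allclose(loaded.weights, boot.weights)
    assert loaded.labels == boot.labels


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


def test_value_at_a_component_mean_maps_to_that_bin():
    c = classify_sample(8.0, _equal_model())
    assert c.bin == 8
    assert c.map_probability == c.posterior.max()


def test_midpoint_tie_resolves_to_the_lower_mean():
    c = classify_sample(10.4, _equal_model())
    assert c.bin == 10  # tie between means 10.1 and 10.7


def test_far_tail_classifies_via_log_space():
    c = classify_sample(20.0, _equal_model(sigma=0.1))
    assert c.bin == 13
    assert np.isfinite(c.posterior).all()


@given(st.floats(min_value=-50, max_value=80, allow_nan=False))
def test_posterior_always_normalized(x):
    c = classify_sample(x, _equal_model(sigma=0.1))
    assert c.posterior.sum() == pytest.approx(1.0, abs=1e-12)
    assert c.map_probability >= 1.0 / 7 - 1e-12


def test_draws_at_well_separated_means_classify_consistently():
    """Values drawn N(u_k, 0.1) at components whose nearest neighbor is
    >= 0.6 copies away come back as that component >= 99% of the time."""
    data, comp = _draw(n=2402, seed=13)
    model = em_fit_fixed_means(data)
    means = np.asarray(DEFAULT_MEANS)
    gaps = np.minimum(
        np.r_[np.diff(means), np.inf], np.r_[np.inf, np.diff(means)]
    )
    rng = np.random.default_rng(99)
    for j in np.flatnonzero(gaps >= 0.6):
        draws = rng.normal(means[j], 0.1, 500)
        hits = sum(classify_sample(x, model).component == j for x in draws)
        assert hits / 500 >= 0.99, f"component {j} ({means[j]})"


# ---------------------------------------------------------------------------
# consistent peaks
# ---------------------------------------------------------------------------


def test_consistent_peaks_found_across_two_cohorts():
    rng = np.random.default_rng(3)
    def cohort(seed):
        r = np.random.default_rng(seed)
        return np.concatenate(
            [r.normal(10.1, 0.12, 900), r.normal(11.1, 0.12, 100)]
        )
    peaks = find_consistent_peaks([cohort(1), cohort(2)])
    assert len(peaks) == 2
    assert abs(peaks[0] - 10.1) <= 0.1
    assert abs(peaks[1] - 11.1) <= 0.1


def test_single_cohort_peaks_are_trivially_consistent():
    rng = np.random.default_rng(8)
    data = rng.normal(10.1, 0.1, 1000)
    peaks = find_consistent_peaks([data])
    assert len(peaks) >= 1 and abs(peaks[0] - 10.1) <= 0.1


def test_disjoint_cohort_peaks_raise():
    rng = np.random.default_rng(4)
    a = rng.normal(9.0, 0.1, 500)
    b = rng.normal(12.0, 0.1, 500)
    with pytest.raises(MixtureFitError, match="default means"):
        find_consistent_peaks([a, b], tolerance=0.1)
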