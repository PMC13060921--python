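import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from djdose.coverage import (
    AlignmentSummary,
    bin_copy_number,
    cn_fast,
    cn_fast_precise,
    cn_fast_refine,
    cn_highres_chm13,
    cn_highres_grch38,
    cn_pilot_fast,
    weighted_median,
)
from djdose.errors import UndefinedEstimateError
from djdose.regions import TargetRegionSet

from conftest import make_uniform_summary

# ---------------------------------------------------------------------------
# weighted median (strict-">" histogram rule)
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "pairs, expected",
    [
        ([(5, 3), (10, 4), (20, 3)], 10),
        ([(7, 1)], 7),
        ([(1, 5), (9, 5)], 9),
    ],
)
def test_weighted_median_examples(pairs, expected):
    assert weighted_median(pairs) == expected


def test_weighted_median_empty_input_raises():
    with pytest.raises(ValueError):
        weighted_median([])


@given(st.lists(st.tuples(st.integers(1, 50), st.integers(1, 8)), min_size=1, max_size=12))
def test_weighted_median_matches_expanded_cumulative_walk(pairs):
    """Independent oracle: expand multiplicities into a flat sorted list
    and take the first element whose 1-based index exceeds half the size."""
    flat = sorted(v for v, c in pairs for _ in range(c))
    half = len(flat) / 2
    expected = next(v for i, v in enumerate(flat, start=1) if i > half)
    assert weighted_median(pairs) == expected


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "value, expected",
    [(8.16, 8), (8.88, 9), (10.09, 10), (9.5, 10), (10.2, 10), (8.04, 8), (9.15, 9)],
)
def test_bin_nearest_integer_with_half_up_ties(value, expected):
    assert bin_copy_number(value) == expected


def test_threshold_rule_moves_only_the_10_11_boundary():
    assert bin_copy_number(10.45, rule="dj_threshold") == 11
    assert bin_copy_number(10.39, rule="dj_threshold") == 10
    # everywhere else the rules agree
    for v in (8.16, 8.88, 10.09, 9.5, 11.4, 12.6):
        assert bin_copy_number(v, rule="dj_threshold") == bin_copy_number(v)


def test_bin_rejects_non_finite():
    with pytest.raises(ValueError):
        bin_copy_number(float("nan"))


# ---------------------------------------------------------------------------
# formula arithmetic on table-backed summaries
# ---------------------------------------------------------------------------


def _summary(autosomes, target_raw, target_filtered=None, depths=None, unmapped=None, filtered=None):
    """autosomes: list of (name, length, mapped)."""
    names = [a[0] for a in autosomes]
    mapped = [a[2] for a in autosomes]
    stats = pd.DataFrame(
        {
            "name": names,
            "length": [a[1] for a in autosomes],
            "mapped": mapped,
            "unmapped": unmapped or [0] * len(names),
            "filtered_mapped": filtered or mapped,
        }
    )
    counts = {("T", False): target_raw, ("T", True): target_filtered if target_filtered is not None else target_raw}
    return AlignmentSummary.from_tables(
        stats, depths=depths, target_counts=counts, n_duplicate_flagged=1
    )


TARGET = TargetRegionSet("T", [("chr1", 0, 10_000, "+")])


def test_pilot_fast_formula():
    # RC_T 500 over 10 kb vs (1,010,000 - 10,000) / 100 Mb = 0.01 -> CN 10
    s = _summary(
        [("chr1", 50_000_000, 505_000), ("chr2", 50_000_000, 505_000)],
        target_raw=500,
        unmapped=[5_000, 5_000],
    )
    assert cn_pilot_fast(s, TARGET).value == pytest.approx(10.0)


def test_pilot_fast_zero_target_reads():
    s = _summary([("chr1", 1_000_000, 10_000)], target_raw=0)
    assert cn_pilot_fast(s, TARGET).value == 0.0


def test_fast_formula_uses_median_autosome_coverage():
    s = _summary(
        [
            ("chr1", 1_000_000, 9_000),
            ("chr2", 1_000_000, 10_000),
            ("chr3", 1_000_000, 11_000),
        ],
        target_raw=500,  # 0.05 per bp vs median 0.01
    )
    assert cn_fast(s, TARGET).value == pytest.approx(10.0)


def test_fast_median_is_robust_to_one_outlier_autosome():
    autosomes = [(f"chr{i}", 1_000_000, 10_000) for i in range(1, 22)]
    base = cn_fast(_summary(autosomes, target_raw=500), TARGET).value
    autosomes[0] = ("chr1", 1_000_000, 500_000)  # 50x outlier
    spiked = cn_fast(_summary(autosomes, target_raw=500), TARGET).value
    assert spiked == pytest.approx(base)


def test_fast_precise_formula_and_flag_invariance():
    s = _summary(
        [("chr1", 40_000_000, 400_000), ("chr2", 40_000_000, 400_000)],
        target_raw=1_000,
        target_filtered=400,  # FRC_T 400 / 10 kb = 0.04 vs 8e5/8e7 = 0.01
    )
    assert cn_fast_precise(s, TARGET).value == pytest.approx(8.0)
    # adding secondary-flagged reads changes raw counts only
    s2 = _summary(
        [("chr1", 40_000_000, 600_000), ("chr2", 40_000_000, 500_000)],
        target_raw=5_000,
        target_filtered=400,
        filtered=[400_000, 400_000],
    )
    assert cn_fast_precise(s2, TARGET).value == pytest.approx(8.0)


def test_fast_precise_warns_on_unmarked_duplicates():
    s = _summary([("chr1", 1_000_000, 10_000)], target_raw=100)
    s.n_duplicate_flagged = 0
    with pytest.warns(UserWarning, match="duplicate"):
        cn_fast_precise(s, TARGET)


def test_fast_refine_formula():
    s = _summary(
        [
            ("chr1", 1_000_000, 10_000),
            ("chr2", 1_000_000, 11_000),
            ("chr3", 1_000_000, 12_000),
        ],
        target_raw=900,
        target_filtered=550,  # 0.055 vs median filtered 0.011
    )
    assert cn_fast_refine(s, TARGET).value == pytest.approx(10.0)


def test_fast_equals_fast_refine_without_flagged_reads():
    s = _summary(
        [("chr1", 1_000_000, 9_500), ("chr2", 1_000_000, 10_500), ("chr3", 1_000_000, 10_000)],
        target_raw=480,
    )
    assert cn_fast(s, TARGET).value == pytest.approx(cn_fast_refine(s, TARGET).value)


def test_highres_grch38_formula():
    depths = {
        "chr1": np.full(1_000_000, 10.0),
        "chr2": np.full(1_000_000, 10.0),
        "chr3": np.full(1_000_000, 10.0),
    }
    depths["chr1"][:10_000] = 50.0  # sum Depth_T / Len_T = 50, median Cov_C = 10
    s = _summary(
        [("chr1", 1_000_000, 0), ("chr2", 1_000_000, 0), ("chr3", 1_000_000, 0)],
        target_raw=0,
        depths=depths,
    )
    est = cn_highres_grch38(s, TARGET)
    assert est.value == pytest.approx(10.0)


def test_highres_chm13_formula_and_zero_background():
    depths = {"chr1": np.full(20_000, 150.0), "chr2": np.full(100_000, 30.0)}
    s = _summary([("chr1", 20_000, 0), ("chr2", 100_000, 0)], target_raw=0, depths=depths)
    background = TargetRegionSet("B", [("chr2", 0, 100_000, ".")])
    assert cn_highres_chm13(s, TARGET, background).value == pytest.approx(10.0)
    empty_bg_depths = {"chr1": np.full(20_000, 150.0), "chr2": np.zeros(100_000)}
    s0 = _summary([("chr1", 20_000, 0), ("chr2", 100_000, 0)], target_raw=0, depths=empty_bg_depths)
    with pytest.raises(UndefinedEstimateError):
        cn_highres_chm13(s0, TARGET, background)


# ---------------------------------------------------------------------------
# shared invariants
# ---------------------------------------------------------------------------

ALL_MODES = [cn_pilot_fast, cn_fast, cn_fast_precise, cn_fast_refine, cn_highres_grch38]


@pytest.mark.parametrize("mode_fn", ALL_MODES)
def test_uniform_dataset_gives_exactly_two(mode_fn):
    summary, target = make_uniform_summary()
    assert mode_fn(summary, target).value == pytest.approx(2.0, abs=1e-12)


def test_uniform_dataset_chm13_highres_gives_exactly_two():
    summary, target = make_uniform_summary()
    background = TargetRegionSet("B", [("chr2", 0, 1_000_000, "."), ("chr3", 0, 1_000_000, ".")])
    assert cn_highres_chm13(summary, target, background).value == pytest.approx(2.0, abs=1e-12)


@pytest.mark.parametrize("mode_fn", ALL_MODES)
def test_scale_invariance(mode_fn):
    base, target = make_uniform_summary(scale=1.0)
    scaled, _ = make_uniform_summary(scale=7.5)
    assert mode_fn(base, target).value == pytest.approx(mode_fn(scaled, target).value)


def test_zero_length_target_is_an_error():
    summary, _ = make_uniform_summary()
    with pytest.raises(UndefinedEstimateError):
        cn_fast(summary, TargetRegionSet("empty", []))
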