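import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from djdose.coverage import AlignmentSummary
from djdose.regions import TargetRegionSet
from djdose.simulate import SimulationConfig, TargetSpec, simulate_alignment_fixture

settings.register_profile("suite", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("suite")

#: target/background geometry shared by the alignment recovery fixtures
TARGET_IVS = [("chr1", 100_000, 120_000, "+")]
BACKGROUND_IVS = [("chr2", 0, 3_200_000, "."), ("chr3", 0, 3_200_000, ".")]


@pytest.fixture(scope="session")
def dj_target() -> TargetRegionSet:
    return TargetRegionSet("DJ", list(TARGET_IVS))


@pytest.fixture(scope="session")
def background_regions() -> TargetRegionSet:
    return TargetRegionSet("background", list(BACKGROUND_IVS))


def make_uniform_summary(
    depth: float = 30.0,
    read_length: int = 150,
    autosome_lengths=(1_000_000, 1_000_000, 1_000_000),
    target_len: int = 20_000,
    scale: float = 1.0,
) -> tuple[AlignmentSummary, TargetRegionSet]:
    """Table-backed summary for a perfectly uniform diploid genome.

    Every base is covered at exactly ``depth * scale`` and no read carries
    an excluded flag, so every estimator mode must return CN = 2 exactly.
    """
    per_base_reads = depth * scale / read_length
    names = [f"chr{i + 1}" for i in range(len(autosome_lengths))]
    stats = pd.DataFrame(
        {
            "name": names,
            "length": list(autosome_lengths),
            "mapped": [length * per_base_reads for length in autosome_lengths],
            "unmapped": [0] * len(names),
            "filtered_mapped": [length * per_base_reads for length in autosome_lengths],
        }
    )
    depths = {
        n: np.full(length, depth * scale)
        for n, length in zip(names, autosome_lengths)
    }
    target = TargetRegionSet("T", [("chr1", 0, target_len, "+")])
    counts = {
        ("T", False): target_len * per_base_reads,
        ("T", True): target_len * per_base_reads,
    }
    summary = AlignmentSummary.from_tables(
        stats, depths=depths, target_counts=counts, n_duplicate_flagged=1
    )
    return summary, target


@pytest.fixture(scope="session")
def recovery_fixtures(tmp_path_factory):
    """Simulated alignments at true DJ copy number 2, 8, 10 and 13 (30x),
    plus an 8-copy fixture with 30% duplicate-flagged reads on the target.

    Generated once per session; the dict maps label -> AlignmentFixture.
    """
    root = tmp_path_factory.mktemp("alignment_fixtures")
    out = {}
    for label, copy, dup in [
        ("c2", 2.0, 0.0),
        ("c8", 8.0, 0.0),
        ("c10", 10.0, 0.0),
        ("c13", 13.0, 0.0),
        ("dup", 8.0, 0.3),
    ]:
        cfg = SimulationConfig(
            seed=101 + int(copy) + int(100 * dup),
            targets=(TargetSpec("chr1", 100_000, 120_000, copy),),
            duplicate_fraction=dup,
        )
        out[label] = simulate_alignment_fixture(cfg, root / label)
    return out


@pytest.fixture(scope="session")
def recovery_estimates(recovery_fixtures, dj_target, background_regions):
    """All six estimator modes evaluated on every recovery fixture."""
    import warnings

    from djdose.coverage import (
        cn_fast,
        cn_fast_precise,
        cn_fast_refine,
        cn_highres_chm13,
        cn_highres_grch38,
        cn_pilot_fast,
    )

    values: dict[str, dict[str, float]] = {}
    for label, fx in recovery_fixtures.items():
        s = fx.summary
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            values[label] = {
                "pilot_fast": cn_pilot_fast(s, dj_target).value,
                "fast": cn_fast(s, dj_target).value,
                "fast_precise": cn_fast_precise(s, dj_target).value,
                "fast_refine": cn_fast_refine(s, dj_target).value,
                "grch38_highres": cn_highres_grch38(s, dj_target).value,
                "chm13_highres": cn_highres_chm13(
                    s, dj_target, background_regions
                ).value,
            }
    return values
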