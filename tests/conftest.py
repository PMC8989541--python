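import numpy as np
import pytest

from bescreen.outcomes import pool_samples, RateMatrix, SUBSTITUTION_INDEX, position_to_column
from bescreen.recombination import MatchStats
from bescreen.simulate import (
    GuideTarget,
    SimTruth,
    generate_guide_library,
    simulate_screen,
)
from bescreen.recombination import correct_profile


@pytest.fixture(scope="session")
def small_library():
    return generate_guide_library(60, seed=7)


@pytest.fixture(scope="session")
def cbe_truth():
    return SimTruth.default("CBE")


@pytest.fixture(scope="session")
def quiet_truth():
    """Noise channels off: sampling noise only (for recovery checks)."""
    return SimTruth.default(
        "CBE",
        latent_dispersion=0.0,
        position_noise_sd=0.0,
        read_depth_dispersion=None,
    )


def make_guide(
    spacer: str,
    guide_id: str = "g0",
    up: str = "A" * 10,
    pam: str = "AGG",
    down: str | None = None,
    editor_label: str = "CBE",
) -> GuideTarget:
    """Construct a GuideTarget with controlled flanking context."""
    if down is None:
        down = "T" * (79 - len(up) - 20 - 3)
    return GuideTarget(
        guide_id=guide_id,
        spacer=spacer,
        target_construct=up + spacer + pam + down,
        protospacer_offset=len(up),
        editor_label=editor_label,
    )


def make_rate_matrix(
    guide_id: str,
    cells: dict[tuple[int, str, str], float],
    offset: int = 10,
    effective_total: float = 1000.0,
) -> RateMatrix:
    """RateMatrix with explicit (position, ref, alt) -> rate cells."""
    rates = np.zeros((12, 79))
    for (pos, ref, alt), r in cells.items():
        rates[SUBSTITUTION_INDEX[(ref, alt)], position_to_column(pos, offset)] = r
    return RateMatrix(
        guide_id=guide_id,
        rates=rates,
        effective_total_reads=effective_total,
        protospacer_offset=offset,
    )


def corrected_matrices(library, result):
    """Pool samples and correct every guide using the simulator's own
    recombination bookkeeping (exact empirical match rates)."""
    by_guide = {}
    for p in result.profiles:
        by_guide.setdefault(p.guide_id, []).append(p)
    out = {}
    for g in library:
        pooled = pool_samples(by_guide[g.guide_id])
        stats = MatchStats(
            g.guide_id,
            result.assigned_reads[g.guide_id],
            result.matched_reads[g.guide_id],
        )
        out[g.guide_id] = correct_profile(pooled, stats)
    return out


@pytest.fixture(scope="session")
def small_screen(small_library, cbe_truth):
    result = simulate_screen(small_library, cbe_truth, n_samples=2, seed=3)
    return small_library, cbe_truth, result
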