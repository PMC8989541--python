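"""Per-guide editing-outcome containers and their processing.

A self-targeting screen yields, for each guide and sample, the number of
reads carrying each base substitution at each position of the guide's
79-nt target construct.  This module turns those raw per-sample outcome
profiles into filtered, pooled, per-guide editing-rate matrices.

Coordinate convention
---------------------
Protospacer positions are 1-based: position 1 is the first spacer base and
the PAM occupies positions 21-23.  All I/O uses protospacer-relative
coordinates, so upstream context positions are zero or negative.  A
construct column index ``i`` (0-based, 0..78) maps to protospacer position
``p = i - offset + 1`` where ``offset`` is the 0-based construct index of
protospacer position 1 (default 10).

Substitution rows are ordered lexicographically over ref -> alt pairs:
A>C, A>G, A>T, C>A, C>G, C>T, G>A, G>C, G>T, T>A, T>C, T>G.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

BASES = ("A", "C", "G", "T")

#: the 12 ordered ref->alt substitution pairs, lexicographic
SUBSTITUTIONS: tuple[tuple[str, str], ...] = tuple(
    (r, a) for r in BASES for a in BASES if r != a
)

SUBSTITUTION_INDEX: dict[tuple[str, str], int] = {
    sub: i for i, sub in enumerate(SUBSTITUTIONS)
}

CONSTRUCT_LENGTH = 79
DEFAULT_PROTOSPACER_OFFSET = 10


def position_to_column(position: int, offset: int = DEFAULT_PROTOSPACER_OFFSET) -> int:
    """Map a 1-based protospacer position to a 0-based construct column."""
    col = offset + position - 1
    if not 0 <= col < CONSTRUCT_LENGTH:
        raise ValueError(
            f"protospacer position {position} falls outside the construct "
            f"(offset {offset})"
        )
    return col


def column_to_position(column: int, offset: int = DEFAULT_PROTOSPACER_OFFSET) -> int:
    """Map a 0-based construct column to a 1-based protospacer position."""
    if not 0 <= column < CONSTRUCT_LENGTH:
        raise ValueError(f"column {column} outside construct")
    return column - offset + 1


@dataclass
class OutcomeProfile:
    """Read counts of each (position, ref, alt) substitution for one guide/sample.

    ``counts`` is keyed by (protospacer position, ref base, alt base);
    ``total_reads`` is the number of reads assigned to the guide in this
    sample, which is the denominator before any recombination correction.
    """

    guide_id: str
    sample_id: str
    total_reads: int
    counts: dict[tuple[int, str, str], int] = field(default_factory=dict)

    def validate(self) -> None:
        if self.total_reads < 0:
            raise ValueError("total_reads must be non-negative")
        for (pos, ref, alt), n in self.counts.items():
            if ref == alt:
                raise ValueError(f"ref == alt at position {pos}")
            if ref not in BASES or alt not in BASES:
                raise ValueError(f"invalid substitution {ref}>{alt}")
            if n < 0 or n > self.total_reads:
                raise ValueError(
                    f"count {n} for {ref}>{alt}@{pos} exceeds total {self.total_reads}"
                )


@dataclass
class RateMatrix:
    """Editing rates for one guide: 12 substitution types x 79 construct positions.

    ``rates[s, i]`` is the fraction of (effective) reads carrying
    substitution ``SUBSTITUTIONS[s]`` at construct column ``i``.
    ``effective_total_reads`` is the post-correction denominator.
    """

    guide_id: str
    rates: np.ndarray
    effective_total_reads: float
    protospacer_offset: int = DEFAULT_PROTOSPACER_OFFSET

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        if self.rates.shape != (len(SUBSTITUTIONS), CONSTRUCT_LENGTH):
            raise ValueError(
                f"rate matrix must be {len(SUBSTITUTIONS)}x{CONSTRUCT_LENGTH}, "
                f"got {self.rates.shape}"
            )

    def rate(self, position: int, ref: str, alt: str) -> float:
        """Rate of ``ref>alt`` at a 1-based protospacer position."""
        col = position_to_column(position, self.protospacer_offset)
        return float(self.rates[SUBSTITUTION_INDEX[(ref, alt)], col])


def pool_samples(profiles: list[OutcomeProfile], sample_id: str = "pooled") -> OutcomeProfile:
    """Pool outcome profiles of one guide across samples by summing counts.

    Timepoints and replicates of a screen are combined by adding the reads
    assigned to the guide in each sample and treating the union as a single
    screen.  Summation is associative and order-independent.
    """
    if not profiles:
        raise ValueError("no profiles to pool")
    guide_ids = {p.guide_id for p in profiles}
    if len(guide_ids) != 1:
        raise ValueError(f"cannot pool profiles of different guides: {sorted(guide_ids)}")
    counts: dict[tuple[int, str, str], int] = {}
    total = 0
    for p in profiles:
        total += p.total_reads
        for key, n in p.counts.items():
            counts[key] = counts.get(key, 0) + n
    return OutcomeProfile(
        guide_id=profiles[0].guide_id,
        sample_id=sample_id,
        total_reads=total,
        counts=counts,
    )


def filter_low_coverage(
    profiles: list[OutcomeProfile], min_reads: int = 100
) -> set[str]:
    """Guides with at least ``min_reads`` reads in *every* sample.

    A guide with fewer than ``min_reads`` reads in any one sample is
    dropped entirely; exactly ``min_reads`` reads is retained.
    """
    if not profiles:
        raise ValueError("no profiles supplied")
    guides: dict[str, list[int]] = {}
    for p in profiles:
        guides.setdefault(p.guide_id, []).append(p.total_reads)
    return {g for g, totals in guides.items() if min(totals) >= min_reads}


def profile_to_rates(
    profile: OutcomeProfile,
    effective_total: float | None = None,
    protospacer_offset: int = DEFAULT_PROTOSPACER_OFFSET,
) -> RateMatrix:
    """Convert a count profile to an editing-rate matrix.

    Rates are counts divided by ``effective_total`` (defaults to the
    profile's own total), clipped to 1.  Clipping can occur after
    recombination correction shrinks the denominator below an observed
    count; it is logged because it signals an inconsistent match rate.
    """
    if effective_total is None:
        effective_total = profile.total_reads
    if effective_total <= 0:
        raise ValueError("effective_total must be positive")
    rates = np.zeros((len(SUBSTITUTIONS), CONSTRUCT_LENGTH))
    clipped = False
    for (pos, ref, alt), n in profile.counts.items():
        col = position_to_column(pos, protospacer_offset)
        r = n / effective_total
        if r > 1.0:
            clipped = True
            r = 1.0
        rates[SUBSTITUTION_INDEX[(ref, alt)], col] = r
    if clipped:
        logger.warning(
            "guide %s: some counts exceed effective total %s; rates clipped to 1",
            profile.guide_id,
            effective_total,
        )
        warnings.warn(
            f"guide {profile.guide_id}: rates clipped to 1 "
            f"(counts exceed effective total {effective_total})",
            stacklevel=2,
        )
    return RateMatrix(
        guide_id=profile.guide_id,
        rates=rates,
        effective_total_reads=float(effective_total),
        protospacer_offset=protospacer_offset,
    )


# ---------------------------------------------------------------------------
# TSV interchange

PROFILE_COLUMNS = ["guide_id", "sample_id", "position", "ref", "alt", "count", "total_reads"]


def profiles_to_frame(profiles: list[OutcomeProfile]) -> pd.DataFrame:
    """Long-form table of outcome profiles (one row per substitution cell)."""
    rows = []
    for p in profiles:
        if not p.counts:
            rows.append((p.guide_id, p.sample_id, 0, ".", ".", 0, p.total_reads))
        for (pos, ref, alt), n in sorted(p.counts.items()):
            rows.append((p.guide_id, p.sample_id, pos, ref, alt, n, p.total_reads))
    return pd.DataFrame(rows, columns=PROFILE_COLUMNS)


def frame_to_profiles(df: pd.DataFrame) -> list[OutcomeProfile]:
    """Inverse of :func:`profiles_to_frame`."""
    profiles = []
    for (gid, sid), grp in df.groupby(["guide_id", "sample_id"], sort=True):
        totals = grp["total_reads"].unique()
        if len(totals) != 1:
            raise ValueError(f"inconsistent total_reads for {gid}/{sid}")
        counts = {}
        for _, row in grp.iterrows():
            if row["ref"] == ".":
                continue
            counts[(int(row["position"]), row["ref"], row["alt"])] = int(row["count"])
        profiles.append(
            OutcomeProfile(
                guide_id=str(gid),
                sample_id=str(sid),
                total_reads=int(totals[0]),
                counts=counts,
            )
        )
    return profiles


def rates_to_frame(matrices: list[RateMatrix], drop_zero: bool = True) -> pd.DataFrame:
    """Long-form rate table (guide_id, position, ref, alt, rate)."""
    rows = []
    for m in matrices:
        sub_idx, cols = np.nonzero(m.rates) if drop_zero else np.meshgrid(
            np.arange(len(SUBSTITUTIONS)), np.arange(CONSTRUCT_LENGTH), indexing="ij"
        )
        if not drop_zero:
            sub_idx = sub_idx.ravel()
            cols = cols.ravel()
        for s, c in zip(sub_idx, cols):
            ref, alt = SUBSTITUTIONS[s]
            rows.append(
                (
                    m.guide_id,
                    column_to_position(int(c), m.protospacer_offset),
                    ref,
                    alt,
                    m.rates[s, c],
                    m.effective_total_reads,
                )
            )
    return pd.DataFrame(
        rows, columns=["guide_id", "position", "ref", "alt", "rate", "effective_total_reads"]
    )
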