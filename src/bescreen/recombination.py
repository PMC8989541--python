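"""Guide-target recombination: read assignment, alignment, rate correction.

Lentiviral delivery of a self-targeting library suffers template switching
("recombination") that pairs a guide with the wrong target construct in
some cells.  Reads from such cells dilute the apparent editing rate of the
guide because their target never carried the guide's edit sites.  The
remedy: measure, per guide, the fraction of reads whose target matches the
expected construct (the guide-target match rate) and scale each guide's
read total by it, leaving edited-read counts unchanged.

Read assignment uses the forward read over the guide region: an exact
20-nt spacer match wins; otherwise a unique match of the middle 10 spacer
bases (positions 6-15); otherwise the read is unassigned.  Target
integrity is scored by global alignment of the reverse read against the
expected 79-nt construct with match +1, mismatch 0 and affine gaps (-1 to
open, -0.1 per additional column); scores of at least 50 call a match
(random construct pairs score well below this).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from Bio import Align

from .outcomes import OutcomeProfile, RateMatrix, profile_to_rates

logger = logging.getLogger(__name__)

MIDDLE10_START = 5  # 0-based start of spacer positions 6-15
MIDDLE10_LENGTH = 10

DEFAULT_MATCH_THRESHOLD = 50.0


@dataclass
class MatchStats:
    """Per-guide guide-target integrity from the mismatch assay."""

    guide_id: str
    assigned_reads: int
    matched_reads: int

    def __post_init__(self) -> None:
        if self.matched_reads > self.assigned_reads:
            raise ValueError("matched_reads cannot exceed assigned_reads")

    @property
    def match_rate(self) -> float:
        if self.assigned_reads == 0:
            return float("nan")
        return self.matched_reads / self.assigned_reads


def build_guide_indexes(
    spacers: dict[str, str], middle_offset: int = MIDDLE10_START
) -> tuple[dict[str, str], dict[str, str | None]]:
    """Build spacer and middle-10 lookup indexes from guide_id -> spacer.

    The middle-10 index maps a 10-mer to its guide only when unique;
    10-mers shared by several guides map to ``None`` (ambiguous).
    """
    spacer_index: dict[str, str] = {}
    for gid, sp in spacers.items():
        spacer_index[sp] = gid
    middle_index: dict[str, str | None] = {}
    for gid, sp in spacers.items():
        mid = sp[middle_offset : middle_offset + MIDDLE10_LENGTH]
        if mid in middle_index:
            middle_index[mid] = None
        else:
            middle_index[mid] = gid
    return spacer_index, middle_index


def assign_read(
    forward_read: str,
    spacer_index: dict[str, str],
    middle_index: dict[str, str | None],
    middle_offset: int = MIDDLE10_START,
) -> str | None:
    """Assign a forward read to a guide, or None if unassignable.

    An exact full-spacer hit anywhere in the read wins; failing that, a
    middle-10 hit that identifies a unique guide; ambiguous or absent
    hits leave the read unassigned.
    """
    L = 20
    for i in range(len(forward_read) - L + 1):
        gid = spacer_index.get(forward_read[i : i + L])
        if gid is not None:
            return gid
    L = MIDDLE10_LENGTH
    hit: str | None = None
    seen = False
    for i in range(len(forward_read) - L + 1):
        kmer = forward_read[i : i + L]
        if kmer in middle_index:
            gid = middle_index[kmer]
            if gid is None:
                return None  # ambiguous 10-mer
            if seen and gid != hit:
                return None  # read matches two different guides
            hit, seen = gid, True
    return hit


_aligner: Align.PairwiseAligner | None = None


def _get_aligner(gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    global _aligner
    if (
        _aligner is None
        or _aligner.open_gap_score != gap_open
        or _aligner.extend_gap_score != gap_extend
    ):
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = 1.0
        aligner.mismatch_score = 0.0
        aligner.open_gap_score = gap_open
        aligner.extend_gap_score = gap_extend
        _aligner = aligner
    return _aligner


def alignment_score(
    seq_a: str,
    seq_b: str,
    gap_open: float = -1.0,
    gap_extend: float = -0.1,
) -> float:
    """Global alignment score: match +1, mismatch 0, affine gaps.

    A gap of length L costs ``gap_open + gap_extend*(L-1)`` (default
    -1 - 0.1*(L-1)); end gaps are penalized.  Symmetric in its arguments.
    """
    if not seq_a or not seq_b:
        raise ValueError("cannot align empty sequence")
    return float(_get_aligner(gap_open, gap_extend).score(seq_a, seq_b))


def classify_target_read(
    expected_target: str,
    reverse_read: str,
    threshold: float = DEFAULT_MATCH_THRESHOLD,
    gap_open: float = -1.0,
    gap_extend: float = -0.1,
) -> bool:
    """True when the reverse read aligns to the expected target at >= threshold."""
    return alignment_score(expected_target, reverse_read, gap_open, gap_extend) >= threshold


def match_stats_from_reads(
    reads: pd.DataFrame,
    spacers: dict[str, str],
    targets: dict[str, str],
    threshold: float = DEFAULT_MATCH_THRESHOLD,
    middle_offset: int = MIDDLE10_START,
) -> dict[str, MatchStats]:
    """Run the full assignment + alignment pipeline over raw read pairs.

    ``reads`` needs columns forward_seq and reverse_seq.  Unassigned reads
    are dropped; each assigned read is classified matched/mismatched by
    aligning the reverse read to the assigned guide's expected target.
    """
    spacer_index, middle_index = build_guide_indexes(spacers, middle_offset)
    assigned: dict[str, int] = {}
    matched: dict[str, int] = {}
    n_unassigned = 0
    for fwd, rev in zip(reads["forward_seq"], reads["reverse_seq"]):
        gid = assign_read(fwd, spacer_index, middle_index, middle_offset)
        if gid is None:
            n_unassigned += 1
            continue
        assigned[gid] = assigned.get(gid, 0) + 1
        if classify_target_read(targets[gid], rev, threshold):
            matched[gid] = matched.get(gid, 0) + 1
    if n_unassigned:
        logger.info("%d reads unassigned", n_unassigned)
    return {
        gid: MatchStats(gid, assigned[gid], matched.get(gid, 0)) for gid in assigned
    }


def correct_profile(
    profile: OutcomeProfile,
    stats: MatchStats,
    round_total: bool = True,
    protospacer_offset: int | None = None,
) -> RateMatrix:
    """Recombination-corrected rate matrix for one guide.

    The read total is scaled by the guide-target match rate (edited-read
    counts are left unchanged, on the assumption that an edited read's
    guide and target matched), and rates are computed against the scaled
    denominator.  Rates exceeding 1 after scaling are clipped with a
    warning.  Guides with zero match rate cannot be corrected.
    """
    if stats.guide_id != profile.guide_id:
        raise ValueError("match stats and profile refer to different guides")
    rate = stats.match_rate
    if not rate > 0:
        raise ValueError(
            f"guide {profile.guide_id} has match rate {rate}; excluded from correction"
        )
    effective = profile.total_reads * rate
    if round_total:
        effective = round(effective)
    if effective <= 0:
        raise ValueError(f"guide {profile.guide_id}: zero effective reads")
    kwargs = {}
    if protospacer_offset is not None:
        kwargs["protospacer_offset"] = protospacer_offset
    return profile_to_rates(profile, effective_total=effective, **kwargs)


def match_stats_to_frame(stats: dict[str, MatchStats]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "guide_id": list(stats),
            "assigned": [s.assigned_reads for s in stats.values()],
            "matched": [s.matched_reads for s in stats.values()],
            "match_rate": [s.match_rate for s in stats.values()],
        }
    )


def frame_to_match_stats(df: pd.DataFrame) -> dict[str, MatchStats]:
    return {
        str(r.guide_id): MatchStats(str(r.guide_id), int(r.assigned), int(r.matched))
        for r in df.itertuples(index=False)
    }
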