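"""Position- and context-stratified editing statistics.

Quantifies the phenomena that drive base-editing outcome variability:
the peaked per-position editing profile with bootstrap confidence
intervals, percent changes in editing from flanking bases (stratified by
position), 20%-of-maximum editing windows per preceding-base stratum,
per-base rates as a function of editable-base count, inter-position rate
correlations, and excess editing over control cells.

All statistics operate across guides on per-guide rate matrices; the
flanking context of an edited position is read from each guide's target
construct, so context exists even for protospacer position 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .outcomes import RateMatrix, position_to_column, SUBSTITUTION_INDEX
from .simulate import GuideTarget, intended_substitution

DEFAULT_WINDOW = (4, 5, 6, 7, 8)
DEFAULT_MIN_STRATUM = 20


def median_with_bootstrap(
    rates: np.ndarray, n_boot: int = 1000, seed: int = 0
) -> dict[str, float]:
    """Sample median with a 95% bootstrap percentile CI.

    The CI is the 2.5/97.5 percentile of ``n_boot`` resampled medians;
    deterministic under the seed.
    """
    rates = np.asarray(rates, dtype=float)
    if rates.size == 0:
        raise ValueError("empty input")
    med = float(np.median(rates))
    if rates.size < 2:
        raise ValueError("need >= 2 observations for a bootstrap CI")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, rates.size, size=(n_boot, rates.size))
    boots = np.median(rates[idx], axis=1)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return {"median": med, "ci_low": float(lo), "ci_high": float(hi)}


def _guide_rates_at(
    matrices: dict[str, RateMatrix],
    library: dict[str, GuideTarget],
    substitution: tuple[str, str],
    position: int,
) -> tuple[list[str], np.ndarray]:
    """Per-guide rates of a substitution at a position, over guides whose
    construct carries the ref base there."""
    ref, alt = substitution
    gids, vals = [], []
    for gid, m in matrices.items():
        guide = library[gid]
        try:
            if guide.base_at(position) != ref:
                continue
        except ValueError:
            continue
        gids.append(gid)
        vals.append(m.rate(position, ref, alt))
    return gids, np.asarray(vals)


def context_effect(
    matrices: dict[str, RateMatrix],
    library: dict[str, GuideTarget],
    substitution: tuple[str, str],
    position: int,
    side: str,
    base: str,
    min_stratum: int = DEFAULT_MIN_STRATUM,
) -> float | None:
    """Percent change in median editing from a flanking base.

    100 * (median over guides whose ``side`` ("preceding"/"following")
    neighbour of the edited position is ``base``, minus the pooled median
    over guides with any other neighbour base) / (the other-base median).
    Returns None when either stratum has fewer than ``min_stratum``
    guides or the other-base median is zero.
    """
    if side not in ("preceding", "following"):
        raise ValueError("side must be 'preceding' or 'following'")
    ctx_pos = position - 1 if side == "preceding" else position + 1
    gids, vals = _guide_rates_at(matrices, library, substitution, position)
    in_stratum, out_stratum = [], []
    for gid, v in zip(gids, vals):
        try:
            ctx = library[gid].base_at(ctx_pos)
        except ValueError:
            continue
        (in_stratum if ctx == base else out_stratum).append(v)
    if len(in_stratum) < min_stratum or len(out_stratum) < min_stratum:
        return None
    med_in = float(np.median(in_stratum))
    med_out = float(np.median(out_stratum))
    if med_out == 0:
        return None
    return 100.0 * (med_in - med_out) / med_out


def editing_window(
    profile: dict[int, float], threshold_frac: float = 0.2
) -> dict[str, object]:
    """Positions whose value reaches ``threshold_frac`` of the profile max.

    Returns the set of above-threshold positions and the contiguous span
    containing the maximum.
    """
    if not profile:
        raise ValueError("empty profile")
    vals = np.array(list(profile.values()), dtype=float)
    if np.any(vals < 0):
        raise ValueError("profile must be non-negative")
    vmax = vals.max()
    if vmax == 0:
        raise ValueError("all-zero profile")
    cut = threshold_frac * vmax
    positions = {p for p, v in profile.items() if v >= cut}
    peak = max(profile, key=lambda p: profile[p])
    lo = hi = peak
    while lo - 1 in positions:
        lo -= 1
    while hi + 1 in positions:
        hi += 1
    return {"positions": positions, "span": (lo, hi)}


def median_position_profile(
    matrices: dict[str, RateMatrix],
    library: dict[str, GuideTarget],
    substitution: tuple[str, str],
    positions: list[int],
    preceding_base: str | None = None,
    min_stratum: int = 2,
) -> dict[int, float]:
    """Median per-guide rate at each position, optionally restricted to
    guides with a given preceding base."""
    out: dict[int, float] = {}
    for p in positions:
        gids, vals = _guide_rates_at(matrices, library, substitution, p)
        if preceding_base is not None:
            keep = []
            for gid, v in zip(gids, vals):
                try:
                    if library[gid].base_at(p - 1) == preceding_base:
                        keep.append(v)
                except ValueError:
                    pass
            vals = np.asarray(keep)
        if vals.size >= min_stratum:
            out[p] = float(np.median(vals))
    return out


def per_base_rate_by_count(
    matrices: dict[str, RateMatrix],
    library: dict[str, GuideTarget],
    editor: str = "CBE",
    window: tuple[int, ...] = DEFAULT_WINDOW,
) -> dict[int, float]:
    """Mean per-base intended-edit rate, stratified by editable-base count.

    Guides are grouped by how many editable (ref) bases fall in the
    window; within each group the per-guide value is the mean intended
    rate across its editable window bases, and the stratum value is the
    mean over guides.
    """
    ref, alt = intended_substitution(editor)
    per_n: dict[int, list[float]] = {}
    for gid, m in matrices.items():
        guide = library[gid]
        rates = [
            m.rate(p, ref, alt) for p in window if guide.base_at(p) == ref
        ]
        if not rates:
            continue
        per_n.setdefault(len(rates), []).append(float(np.mean(rates)))
    return {n: float(np.mean(v)) for n, v in sorted(per_n.items())}


def interposition_correlation(
    matrices: dict[str, RateMatrix],
    library: dict[str, GuideTarget],
    pos_i: int,
    pos_j: int,
    editor: str = "CBE",
) -> float | None:
    """Pearson correlation across guides of intended-edit rates at two positions.

    Uses guides with an editable base at both positions; None with fewer
    than 3 such guides or zero variance at either position.
    """
    ref, alt = intended_substitution(editor)
    xs, ys = [], []
    for gid, m in matrices.items():
        guide = library[gid]
        try:
            if guide.base_at(pos_i) != ref or guide.base_at(pos_j) != ref:
                continue
        except ValueError:
            continue
        xs.append(m.rate(pos_i, ref, alt))
        ys.append(m.rate(pos_j, ref, alt))
    if len(xs) < 3:
        return None
    xs, ys = np.asarray(xs), np.asarray(ys)
    if xs.std() == 0 or ys.std() == 0:
        return None
    return float(sps.pearsonr(xs, ys).statistic)


def compare_to_control(
    editor_rates: np.ndarray,
    control_rates: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
) -> dict[str, float]:
    """Difference of medians (editor - control) with a bootstrap 95% CI."""
    editor_rates = np.asarray(editor_rates, dtype=float)
    control_rates = np.asarray(control_rates, dtype=float)
    if editor_rates.size == 0 or control_rates.size == 0:
        raise ValueError("both cohorts must be non-empty")
    diff = float(np.median(editor_rates) - np.median(control_rates))
    rng = np.random.default_rng(seed)
    ei = rng.integers(0, editor_rates.size, size=(n_boot, editor_rates.size))
    ci = rng.integers(0, control_rates.size, size=(n_boot, control_rates.size))
    boots = np.median(editor_rates[ei], axis=1) - np.median(control_rates[ci], axis=1)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return {"excess": diff, "ci_low": float(lo), "ci_high": float(hi)}


@dataclass
class BiasReport:
    """Nested report of the bias statistics for one cohort of guides."""

    median_by_position: dict = field(default_factory=dict)
    context_effects: dict = field(default_factory=dict)
    windows: dict = field(default_factory=dict)
    per_base_count_rates: dict = field(default_factory=dict)
    interposition_r: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        def keyfmt(k):
            return "|".join(str(x) for x in k) if isinstance(k, tuple) else str(k)

        return {
            "median_by_position": {
                keyfmt(k): v for k, v in self.median_by_position.items()
            },
            "context_effects": {keyfmt(k): v for k, v in self.context_effects.items()},
            "windows": {
                keyfmt(k): {
                    "positions": sorted(v["positions"]),
                    "span": list(v["span"]),
                }
                for k, v in self.windows.items()
            },
            "per_base_count_rates": {
                str(k): v for k, v in self.per_base_count_rates.items()
            },
            "interposition_r": {
                keyfmt(k): v for k, v in self.interposition_r.items()
            },
        }


def build_bias_report(
    matrices: dict[str, RateMatrix],
    library: dict[str, GuideTarget],
    editor: str = "CBE",
    positions: list[int] | None = None,
    n_boot: int = 1000,
    seed: int = 0,
    min_stratum: int = DEFAULT_MIN_STRATUM,
) -> BiasReport:
    """Full bias report for one editor cohort.

    Covers the intended transition: per-position medians with bootstrap
    CIs, preceding/following-base percent effects per position, marginal
    and per-preceding-base 20%-of-max windows, per-base rates by editable-
    base count, and window inter-position correlations.
    """
    if positions is None:
        positions = list(range(-5, 18))
    sub = intended_substitution(editor)
    report = BiasReport()

    for p in positions:
        _, vals = _guide_rates_at(matrices, library, sub, p)
        if vals.size >= 2:
            report.median_by_position[(f"{sub[0]}>{sub[1]}", p)] = median_with_bootstrap(
                vals, n_boot=n_boot, seed=seed + p + 100
            )

    for side in ("preceding", "following"):
        for base in "ACGT":
            for p in positions:
                eff = context_effect(
                    matrices, library, sub, p, side, base, min_stratum=min_stratum
                )
                if eff is not None:
                    report.context_effects[(side, base, p)] = eff

    marginal = {
        p: v["median"]
        for (s, p), v in report.median_by_position.items()
    }
    if marginal and max(marginal.values()) > 0:
        report.windows["marginal"] = editing_window(marginal)
    for base in "ACGT":
        prof = median_position_profile(
            matrices, library, sub, positions, preceding_base=base,
            min_stratum=min_stratum,
        )
        if prof and max(prof.values()) > 0:
            report.windows[("preceding", base)] = editing_window(prof)

    report.per_base_count_rates = per_base_rate_by_count(
        matrices, library, editor=editor
    )

    window = DEFAULT_WINDOW
    for i, pi in enumerate(window):
        for pj in window[i + 1 :]:
            r = interposition_correlation(matrices, library, pi, pj, editor=editor)
            if r is not None:
                report.interposition_r[(pi, pj)] = r
    return report


def context_effect_table(report: BiasReport) -> pd.DataFrame:
    rows = [
        (side, base, pos, eff)
        for (side, base, pos), eff in sorted(report.context_effects.items())
    ]
    return pd.DataFrame(rows, columns=["side", "base", "position", "percent_change"])
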