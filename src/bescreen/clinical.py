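"""From standardized predictions to absolute rates, purity and guide scoring.

Standardized model outputs are mapped back to absolute editing rates with
per-position means and SDs; when a dataset's own statistics are not
reliable, an anchored scaling derives them from a fixed position-6 anchor
(e.g. mean 0.5 for a clinical scenario) times a per-position scaling
vector shaped like the marginal position profile.

A guide's purity at a position is its intended-edit rate there divided by
the summed intended-edit rate across all its editable positions; a
disease-SNP guide is scored by its correction efficiency (rate at the SNP
position), its bystander sum (intended-type editing at the other modeled
positions) and purity.  Editors with a shifted window (e.g. Target-AID,
3 nt downstream) are handled by shifting the guide frame before
prediction and mapping results back to original coordinates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import GuideFeaturizer
from .models import PositionEditingModel

logger = logging.getLogger(__name__)

MODELED_RANGE = (3, 4, 5, 6, 7, 8, 9, 10)
ANCHOR_POSITION = 6


def _default_scaling() -> dict[int, float]:
    # marginal position-profile shape relative to position 6
    return {
        3: 0.30, 4: 0.55, 5: 0.85, 6: 1.0, 7: 0.85, 8: 0.55, 9: 0.30, 10: 0.15,
    }


@dataclass
class AnchoredScaling:
    """Per-position (mean, SD) derived from a position-6 anchor.

    mu_p = anchor_mean * scaling[p]; sigma_p = anchor_sd * scaling[p].
    The default scaling vector follows the marginal position profile; it
    is an assumption and is logged when used unmodified.
    """

    anchor_mean: float = 0.5
    anchor_sd: float = 0.2
    scaling: dict[int, float] = field(default_factory=_default_scaling)

    def params_at(self, position: int) -> tuple[float, float]:
        if position not in self.scaling:
            raise ValueError(f"no scaling value for position {position}")
        s = self.scaling[position]
        if s <= 0:
            raise ValueError(f"scaling at position {position} must be positive")
        return self.anchor_mean * s, self.anchor_sd * s


def destandardize(
    z: float | np.ndarray,
    mean: float,
    std: float,
    clip: bool = True,
) -> float | np.ndarray:
    """Absolute rate r = mean + z * std, clipped to [0, 1] by default."""
    if std <= 0:
        raise ValueError("std must be positive")
    r = np.asarray(z, dtype=float) * std + mean
    if clip:
        if np.any((r < 0) | (r > 1)):
            warnings.warn("destandardized rates clipped to [0, 1]", stacklevel=2)
        r = np.clip(r, 0.0, 1.0)
    if np.ndim(z) == 0:
        return float(r)
    return r


def destandardize_anchored(
    z: float, position: int, scaling: AnchoredScaling, clip: bool = True
) -> float:
    """Anchored-mode destandardization (position-6 anchor times scaling)."""
    mean, std = scaling.params_at(position)
    return destandardize(z, mean, std, clip=clip)


def purity(rates: dict[int, float]) -> dict[int, float]:
    """Per-position purity: rate divided by the summed rate over positions.

    Applied identically to measured and predicted absolute intended-edit
    rates; purities over positions with nonzero rates sum to 1.  All-zero
    input is undefined.
    """
    if not rates:
        raise ValueError("no rates supplied")
    if any(r < 0 for r in rates.values()):
        raise ValueError("rates must be non-negative")
    total = sum(rates.values())
    if total == 0:
        raise ValueError("all rates are zero; purity undefined")
    return {p: r / total for p, r in rates.items()}


def shift_guide_frame(
    spacer: str, upstream_flank: str, shift: int = 3
) -> tuple[str, dict[int, int]]:
    """Shift a guide's coordinate frame downstream by ``shift`` nt.

    For editors whose window sits earlier in the protospacer (Target-AID),
    the guide sequence is shifted forward so that original position 1
    becomes position 1 + shift; the vacated 5' slots are filled from the
    genomic upstream flank.  Returns the shifted spacer and the map from
    shifted-frame positions back to original coordinates.
    """
    if shift < 0:
        raise ValueError("shift must be >= 0")
    if shift == 0:
        return spacer, {p: p for p in range(1, len(spacer) + 1)}
    if len(upstream_flank) < shift:
        raise ValueError(
            f"need >= {shift} nt of upstream flank, got {len(upstream_flank)}"
        )
    shifted = upstream_flank[-shift:] + spacer[: len(spacer) - shift]
    mapping = {p: p - shift for p in range(1, len(spacer) + 1)}
    return shifted, mapping


def predict_absolute_rates(
    model: PositionEditingModel,
    spacers: list[str],
    scaling: AnchoredScaling,
    positions: tuple[int, ...] = MODELED_RANGE,
) -> pd.DataFrame:
    """Predicted absolute intended-edit rates per position for each spacer."""
    X = GuideFeaturizer().fit(spacers).transform(spacers)
    zpred = model.predict(X)
    out = {}
    for p in positions:
        if p not in model.positions_:
            continue
        mean, std = scaling.params_at(p)
        out[p] = destandardize(zpred[p].to_numpy(), mean, std)
    return pd.DataFrame(out, index=spacers)


@dataclass
class GuideEvaluation:
    """Purity/efficiency scores of one disease-correction guide."""

    guide_id: str
    snp_position: int
    correction_efficiency: float
    bystander_sum: float
    purity: float
    rates: dict[int, float]


def evaluate_disease_guides(
    guides: pd.DataFrame,
    model: PositionEditingModel,
    scaling: AnchoredScaling,
    editable_base: str = "C",
    purity_threshold: float = 0.8,
    efficiency_quantile: float = 0.9,
) -> pd.DataFrame:
    """Score SNP-correcting guides and shortlist the promising ones.

    ``guides`` needs columns guide_id, spacer, snp_position.  Per guide:
    correction efficiency = predicted intended-edit rate at the SNP
    position; bystander sum = summed intended-type editing at the other
    editable positions in the modeled 3-10 range; purity = efficiency /
    (efficiency + bystander sum).  The shortlist flag marks guides with
    purity above ``purity_threshold`` that are also in the top decile of
    correction efficiencies within the evaluated cohort.  Guides whose
    SNP position falls outside 3-10 are excluded with a reason.
    """
    kept = guides[
        guides["snp_position"].between(MODELED_RANGE[0], MODELED_RANGE[-1])
    ].copy()
    dropped = len(guides) - len(kept)
    if dropped:
        logger.info("%d guides excluded: SNP position outside %s", dropped, MODELED_RANGE)
    if kept.empty:
        return pd.DataFrame(
            columns=[
                "guide_id", "snp_position", "correction_efficiency",
                "bystander_sum", "purity", "shortlisted",
            ]
        )
    spacers = kept["spacer"].tolist()
    abs_rates = predict_absolute_rates(model, spacers, scaling)
    rows = []
    for (_, g), (_, rates) in zip(kept.iterrows(), abs_rates.iterrows()):
        snp_pos = int(g["snp_position"])
        editable = {
            p: float(rates[p])
            for p in abs_rates.columns
            if g["spacer"][p - 1] == editable_base or p == snp_pos
        }
        eff = editable.get(snp_pos, float(rates.get(snp_pos, 0.0)))
        bystander = sum(r for p, r in editable.items() if p != snp_pos)
        total = eff + bystander
        pur = eff / total if total > 0 else float("nan")
        rows.append((g["guide_id"], snp_pos, eff, bystander, pur))
    out = pd.DataFrame(
        rows,
        columns=[
            "guide_id", "snp_position", "correction_efficiency",
            "bystander_sum", "purity",
        ],
    )
    cutoff = out["correction_efficiency"].quantile(efficiency_quantile)
    out["shortlisted"] = (out["purity"] > purity_threshold) & (
        out["correction_efficiency"] >= cutoff
    )
    out["more_bystander_than_target"] = out["bystander_sum"] > out["correction_efficiency"]
    return out
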