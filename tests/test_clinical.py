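"""Destandardization, purity, frame shifting and disease-guide scoring."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from bescreen.clinical import (
    AnchoredScaling,
    destandardize,
    destandardize_anchored,
    evaluate_disease_guides,
    purity,
    shift_guide_frame,
)
from bescreen.features import standardize


class TestDestandardize:
    def test_zero_z_gives_mean(self):
        assert destandardize(0.0, mean=0.31, std=0.1) == pytest.approx(0.31)

    def test_anchored_position_six(self):
        scaling = AnchoredScaling(anchor_mean=0.5, anchor_sd=0.2)
        assert destandardize_anchored(0.0, 6, scaling) == pytest.approx(0.5)

    def test_large_negative_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clipped"):
            assert destandardize(-50.0, mean=0.3, std=0.1) == 0.0

    def test_roundtrip_identity_on_unclipped(self):
        rng = np.random.default_rng(2)
        r = rng.uniform(0.05, 0.6, 200)
        z = standardize(r, 0.3, 0.1)
        back = destandardize(z, 0.3, 0.1)
        assert np.max(np.abs(back - r)) < 1e-12

    def test_anchored_requires_scaling_entry(self):
        scaling = AnchoredScaling(scaling={6: 1.0})
        with pytest.raises(ValueError, match="scaling"):
            destandardize_anchored(0.0, 5, scaling)


class TestPurity:
    def test_formula_arithmetic(self):
        p = purity({6: 0.3, 5: 0.2})
        assert p[6] == pytest.approx(0.6)
        assert p[5] == pytest.approx(0.4)

    def test_single_position_is_one(self):
        assert purity({6: 0.12}) == {6: 1.0}

    def test_sums_to_one(self):
        rng = np.random.default_rng(1)
        rates = {p: float(r) for p, r in zip(range(3, 11), rng.random(8))}
        assert sum(purity(rates).values()) == pytest.approx(1.0)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.floats(min_value=0.01, max_value=100.0),
           st.integers(min_value=0, max_value=2**31 - 1))
    def test_scale_invariance(self, c, seed):
        rng = np.random.default_rng(seed)
        rates = {p: float(r) + 1e-6 for p, r in zip(range(3, 11), rng.random(8))}
        base = purity(rates)
        scaled = purity({p: c * r for p, r in rates.items()})
        for p in rates:
            assert scaled[p] == pytest.approx(base[p], rel=1e-9)

    def test_all_zero_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            purity({5: 0.0, 6: 0.0})


class TestFrameShift:
    def test_original_position_one_becomes_four(self):
        spacer = "GACGTACGTACGTACGTACG"
        shifted, mapping = shift_guide_frame(spacer, upstream_flank="TTTAAA", shift=3)
        assert len(shifted) == 20
        assert shifted == "AAA" + spacer[:17]
        assert mapping[4] == 1  # shifted-frame position 4 is original position 1

    def test_zero_shift_identity(self):
        spacer = "GACGTACGTACGTACGTACG"
        shifted, mapping = shift_guide_frame(spacer, upstream_flank="", shift=0)
        assert shifted == spacer
        assert all(mapping[p] == p for p in range(1, 21))

    def test_roundtrip_to_original_coordinates(self):
        spacer = "GACGTACGTACGTACGTACG"
        _, mapping = shift_guide_frame(spacer, "ACGTAC", shift=3)
        # a prediction at shifted position q reports at original q - 3
        assert [mapping[q] + 3 for q in (4, 5, 6)] == [4, 5, 6]

    def test_insufficient_flank_rejected(self):
        with pytest.raises(ValueError, match="flank"):
            shift_guide_frame("G" * 20, upstream_flank="AC", shift=3)


class _StubModel:
    """Fixed standardized predictions per position for scoring tests."""

    def __init__(self, zmap):
        self.zmap = zmap
        self.positions_ = list(zmap)

    def predict(self, X):
        n = len(np.atleast_2d(X))
        return pd.DataFrame({p: np.full(n, z) for p, z in self.zmap.items()})


class TestDiseaseGuides:
    @staticmethod
    def _scaling():
        # unit scaling everywhere: absolute rate = 0.5 + 0.2 * z
        return AnchoredScaling(
            anchor_mean=0.5, anchor_sd=0.2, scaling={p: 1.0 for p in range(3, 11)}
        )

    def test_efficiency_bystander_purity_arithmetic(self):
        # SNP at 6 -> 0.5; single bystander C at 4 -> 0.3; purity 0.625
        model = _StubModel({4: -1.0, 6: 0.0})
        guides = pd.DataFrame(
            {
                "guide_id": ["g1"],
                "spacer": ["GAACAC" + "A" * 14],  # C at 4 and 6 only
                "snp_position": [6],
            }
        )
        out = evaluate_disease_guides(guides, model, self._scaling())
        row = out.iloc[0]
        assert row["correction_efficiency"] == pytest.approx(0.5)
        assert row["bystander_sum"] == pytest.approx(0.3)
        assert row["purity"] == pytest.approx(0.625)
        assert not row["more_bystander_than_target"]

    def test_single_editable_base_pure(self):
        model = _StubModel({p: 0.0 for p in range(3, 11)})
        guides = pd.DataFrame(
            {
                "guide_id": ["g1"],
                "spacer": ["GAAAACA" + "A" * 13],  # only C is at position 6
                "snp_position": [6],
            }
        )
        out = evaluate_disease_guides(guides, model, self._scaling())
        assert out.iloc[0]["purity"] == pytest.approx(1.0)
        assert out.iloc[0]["bystander_sum"] == 0.0

    def test_out_of_range_snp_excluded(self):
        model = _StubModel({6: 0.0})
        guides = pd.DataFrame(
            {
                "guide_id": ["g1", "g2"],
                "spacer": ["GAAAACA" + "A" * 13] * 2,
                "snp_position": [6, 15],
            }
        )
        out = evaluate_disease_guides(guides, model, self._scaling())
        assert list(out["guide_id"]) == ["g1"]

    def test_shortlist_requires_purity_and_top_decile(self):
        model = _StubModel({p: 0.0 for p in range(3, 11)})
        spacer_pure = "GAAAACA" + "A" * 13       # C at 6 only -> purity 1
        spacer_impure = "GAACCCC" + "A" * 13     # C at 4,5,6,7 -> purity 0.25
        guides = pd.DataFrame(
            {
                "guide_id": [f"g{i}" for i in range(20)],
                "spacer": [spacer_pure] * 10 + [spacer_impure] * 10,
                "snp_position": [6] * 20,
            }
        )
        out = evaluate_disease_guides(guides, model, self._scaling())
        pure_ids = [f"g{i}" for i in range(10)]
        assert (out[out["guide_id"].isin(pure_ids)]["purity"] == 1).all()
        short = out[out["shortlisted"]]
        assert (short["purity"] > 0.8).all()
        cutoff = out["correction_efficiency"].quantile(0.9)
        assert (short["correction_efficiency"] >= cutoff).all()
        # impure guides never pass the purity filter
        assert not short["guide_id"].isin([f"g{i}" for i in range(10, 20)]).any()

    def test_more_editable_bases_more_bystanders(self):
        model = _StubModel({p: 0.0 for p in range(3, 11)})
        cohort = [
            ("g_one", "GAAAACA" + "A" * 13),   # C at 6 only
            ("g_two", "GAACAC" + "A" * 14),    # C at 4 and 6
            ("g_four", "GCCCACC" + "A" * 13),  # C at 3, 4, 6, 7
        ]
        out = evaluate_disease_guides(
            pd.DataFrame(
                [(gid, sp, 6) for gid, sp in cohort],
                columns=["guide_id", "spacer", "snp_position"],
            ),
            model,
            self._scaling(),
        )
        by = out.set_index("guide_id")["bystander_sum"]
        assert by["g_one"] < by["g_two"] < by["g_four"]
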