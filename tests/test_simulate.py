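"""Generative model: library layout, rate oracle, screen sampling."""

import numpy as np
import pytest

from bescreen.outcomes import CONSTRUCT_LENGTH
from bescreen.simulate import (
    SimTruth,
    generate_guide_library,
    library_to_frame,
    simulate_screen,
    simulate_match_assay,
    true_rate,
)

from conftest import make_guide


class TestLibrary:
    def test_layout_and_forced_g(self):
        lib = generate_guide_library(1, seed=7, force_g=True)
        (g,) = lib
        g.validate()
        assert len(g.target_construct) == CONSTRUCT_LENGTH
        assert g.spacer[0] == "G"
        assert len(g.pam) == 3 and g.pam[1:] == "GG"
        # spacer embedded at the protospacer offset (19-nt match with forced G)
        emb = g.target_construct[g.protospacer_offset : g.protospacer_offset + 20]
        assert emb[1:] == g.spacer[1:]

    def test_deterministic_under_seed(self):
        a = library_to_frame(generate_guide_library(100, seed=7))
        b = library_to_frame(generate_guide_library(100, seed=7))
        assert a.equals(b)

    def test_different_seeds_differ(self):
        a = library_to_frame(generate_guide_library(100, seed=7))
        b = library_to_frame(generate_guide_library(100, seed=8))
        assert not a.equals(b)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            generate_guide_library(0, seed=1)
        with pytest.raises(ValueError):
            generate_guide_library(1, seed=1, pam="NGG")


class TestTrueRate:
    def test_product_formula(self):
        # pi_6 = 0.3, preceding T multiplier 1.5 (gradient exponent 1 at the
        # center), neutral following base -> 0.3 * 1.5 = 0.45
        g = make_guide("G" + "A" * 3 + "TCA" + "A" * 13)  # C at position 6, T before, A after
        truth = SimTruth(
            position_profile={6: 0.3},
            preceding_mult={"A": 1.0, "C": 1.0, "G": 1.0, "T": 1.5},
            following_mult={"A": 1.0, "C": 1.0, "G": 1.0, "T": 1.0},
            substitution_weights={"intended": 1.0, "background": 0.0},
        )
        assert true_rate(g, 6, ("C", "T"), truth) == pytest.approx(0.45)

    def test_zero_weight_gives_zero(self):
        g = make_guide("G" + "A" * 3 + "TCA" + "A" * 13)
        truth = SimTruth(
            position_profile={6: 0.3},
            substitution_weights={"intended": 0.0, "background": 0.0},
        )
        assert true_rate(g, 6, ("C", "T"), truth) == 0.0

    def test_clipped_at_one(self):
        g = make_guide("G" + "A" * 3 + "TCA" + "A" * 13)
        truth = SimTruth(
            position_profile={6: 0.9},
            preceding_mult={"A": 1.0, "C": 1.0, "G": 1.0, "T": 5.0},
            substitution_weights={"intended": 1.0, "background": 0.0},
        )
        assert true_rate(g, 6, ("C", "T"), truth) == 1.0

    def test_ref_mismatch_rejected(self, cbe_truth):
        g = make_guide("G" + "A" * 19)
        with pytest.raises(ValueError):
            true_rate(g, 6, ("C", "T"), cbe_truth)  # construct has A at 6

    def test_background_for_out_of_window(self, cbe_truth):
        g = make_guide("G" + "A" * 3 + "TCA" + "A" * 13, down="C" + "T" * 45)
        # position 24 (first downstream base) is outside the modeled profile
        assert true_rate(g, 24, ("C", "T"), cbe_truth) == pytest.approx(
            cbe_truth.substitution_weights["background"]
        )


class TestScreen:
    def test_no_edits_when_rates_zero(self):
        lib = generate_guide_library(5, seed=1)
        truth = SimTruth(
            substitution_weights={"intended": 0.0, "background": 0.0},
            recombination_rate=0.0,
            read_depth=200,
        )
        res = simulate_screen(lib, truth, n_samples=2, seed=2)
        assert all(not p.counts for p in res.profiles)
        assert all(p.total_reads > 0 for p in res.profiles)

    def test_recombination_fraction_matches_rho(self):
        lib = generate_guide_library(20, seed=1)
        truth = SimTruth.default("CBE", recombination_rate=0.3, read_depth=10_000)
        res = simulate_screen(lib, truth, n_samples=1, seed=5)
        n = sum(res.assigned_reads.values())
        mis = n - sum(res.matched_reads.values())
        se = np.sqrt(0.3 * 0.7 / n)
        assert abs(mis / n - 0.3) < 3 * se

    def test_rates_converge_to_truth_at_depth(self, quiet_truth):
        lib = generate_guide_library(30, seed=2)
        truth = SimTruth.default(
            "CBE",
            recombination_rate=0.0,
            read_depth=10_000,
            latent_dispersion=0.0,
            position_noise_sd=0.0,
        )
        res = simulate_screen(lib, truth, n_samples=1, seed=9)
        ok = tot = 0
        for g in lib:
            prof = next(p for p in res.profiles if p.guide_id == g.guide_id)
            n = prof.total_reads
            for p in range(1, 21):
                if g.base_at(p) != "C":
                    continue
                r = true_rate(g, p, ("C", "T"), truth)
                if r < 0.01:
                    continue
                obs = prof.counts.get((p, "C", "T"), 0) / n
                tot += 1
                ok += abs(obs - r) <= 3 * np.sqrt(r * (1 - r) / n)
        assert tot > 50
        assert ok / tot > 0.95

    def test_positions_independent_without_latent(self):
        # with the per-read latent and position noise off, per-sample rates
        # at two distinct editable positions are uncorrelated across samples
        g = make_guide("G" + "A" * 3 + "CCC" + "A" * 13, guide_id="gx")
        truth = SimTruth.default(
            "CBE",
            recombination_rate=0.0,
            read_depth=500,
            latent_dispersion=0.0,
            position_noise_sd=0.0,
            read_depth_dispersion=None,
        )
        res = simulate_screen([g], truth, n_samples=200, seed=4)
        r5 = np.array([p.counts.get((5, "C", "T"), 0) / p.total_reads for p in res.profiles])
        r6 = np.array([p.counts.get((6, "C", "T"), 0) / p.total_reads for p in res.profiles])
        r = np.corrcoef(r5, r6)[0, 1]
        assert abs(r) < 3 / np.sqrt(len(res.profiles))

    def test_latent_induces_positive_correlation(self):
        g = make_guide("G" + "A" * 3 + "CCC" + "A" * 13, guide_id="gx")
        truth = SimTruth.default(
            "CBE",
            recombination_rate=0.0,
            read_depth=500,
            latent_dispersion=0.6,
            position_noise_sd=0.0,
            read_depth_dispersion=None,
        )
        res = simulate_screen([g], truth, n_samples=200, seed=4)
        r5 = np.array([p.counts.get((5, "C", "T"), 0) / p.total_reads for p in res.profiles])
        r6 = np.array([p.counts.get((6, "C", "T"), 0) / p.total_reads for p in res.profiles])
        assert np.corrcoef(r5, r6)[0, 1] > 3 / np.sqrt(len(res.profiles))

    def test_seed_fixes_emitted_bytes(self, small_library, cbe_truth):
        from bescreen.outcomes import profiles_to_frame
        import copy

        a = simulate_screen(small_library, copy.deepcopy(cbe_truth), n_samples=2, seed=3)
        b = simulate_screen(small_library, copy.deepcopy(cbe_truth), n_samples=2, seed=3)
        fa = profiles_to_frame(a.profiles).to_csv(sep="\t")
        fb = profiles_to_frame(b.profiles).to_csv(sep="\t")
        assert fa == fb

    def test_match_assay_carries_recombined_targets(self):
        lib = generate_guide_library(10, seed=3)
        truth = SimTruth.default("CBE", recombination_rate=0.4)
        reads = simulate_match_assay(lib, truth, reads_per_guide=100, seed=6)
        assert len(reads) == 1000
        own = {g.guide_id: g.target_construct for g in lib}
        frac_mis = float(
            (reads["reverse_seq"] != reads["guide_id"].map(own)).mean()
        )
        assert abs(frac_mis - 0.4) < 3 * np.sqrt(0.4 * 0.6 / len(reads))


class TestTruthValidation:
    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            SimTruth(recombination_rate=1.0).validate()
        with pytest.raises(ValueError):
            SimTruth(read_depth=0).validate()
        with pytest.raises(ValueError):
            SimTruth(editor="XBE").validate()

    def test_roundtrip_through_dict(self, cbe_truth):
        d = cbe_truth.to_dict()
        back = SimTruth.from_dict(d)
        assert back.position_profile == cbe_truth.position_profile
        assert back.preceding_mult == cbe_truth.preceding_mult
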