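"""Synthetic self-targeting base-editing screens with known ground truth.

The generator emulates the statistical structure of a pooled self-targeting
library screen: each lentiviral construct carries a 20-nt gRNA spacer and a
79-nt target (spacer + PAM embedded in randomized context), cells carrying a
construct edit their own target, and amplicon sequencing reads out per-
position substitution counts.

The generative model for the probability that a read of guide ``g`` carries
substitution ``s`` at protospacer position ``p`` is

    r(g, p, s) = min(1, e_g * pi(p) * mu_prev(b_{p-1}, p) * nu_next(b_{p+1}) * kappa_s)

where ``pi`` is a peaked position profile (maximal at protospacer position
6, canonical window 4-8), ``mu_prev``/``nu_next`` are multiplicative
flanking-base effects, ``kappa_s`` weights the substitution channel
(intended transition, C>A / C>G transversions, opposite-strand G>A), and
``e_g`` is a per-guide efficacy latent partially explained by spacer
melting temperature.  The preceding-base effect grows away from the window
center, ``mu_prev(b, p) = mu_b ** (1 + gamma * |p - 6|)``, which is what
makes the effective editing window broaden after a T and shrink after a G.
A flat background channel (rate ``kappa_background`` per alt base at every
position, context-free) models sequencing/PCR noise and control cells.

Guide-target recombination during lentiviral delivery is modeled by a
fraction ``rho`` of each guide's reads carrying a different guide's target;
those reads contribute to the read total but show no edits at the guide's
sites, which is exactly the dilution that downstream match-rate correction
removes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .outcomes import (
    BASES,
    CONSTRUCT_LENGTH,
    DEFAULT_PROTOSPACER_OFFSET,
    OutcomeProfile,
    position_to_column,
)

logger = logging.getLogger(__name__)

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

SPACER_LENGTH = 20
PAM_LENGTH = 3

#: protospacer positions at which the generative position profile is defined
MODELED_POSITIONS = tuple(range(-5, 18))

WINDOW_CENTER = 6


@dataclass
class GuideTarget:
    """One self-targeting construct: spacer, 79-nt target, and anchors."""

    guide_id: str
    spacer: str
    target_construct: str
    protospacer_offset: int = DEFAULT_PROTOSPACER_OFFSET
    editor_label: str = "CBE"

    @property
    def pam(self) -> str:
        start = self.protospacer_offset + SPACER_LENGTH
        return self.target_construct[start : start + PAM_LENGTH]

    def base_at(self, position: int) -> str:
        """Construct base at a 1-based protospacer position (can be <= 0)."""
        idx = self.protospacer_offset + position - 1
        if not 0 <= idx < len(self.target_construct):
            raise ValueError(f"position {position} outside construct")
        return self.target_construct[idx]

    def validate(self) -> None:
        if len(self.spacer) != SPACER_LENGTH:
            raise ValueError("spacer must be 20 nt")
        if len(self.target_construct) != CONSTRUCT_LENGTH:
            raise ValueError("target construct must be 79 nt")
        if set(self.spacer) - set(BASES) or set(self.target_construct) - set(BASES):
            raise ValueError("invalid alphabet")
        embedded = self.target_construct[
            self.protospacer_offset : self.protospacer_offset + SPACER_LENGTH
        ]
        # first spacer base may be a forced G that mismatches the target
        if embedded[1:] != self.spacer[1:]:
            raise ValueError("spacer does not match construct at protospacer")


def gaussian_position_profile(
    peak_rate: float = 0.3,
    center: int = WINDOW_CENTER,
    width: float = 1.3,
    positions: tuple[int, ...] = MODELED_POSITIONS,
) -> dict[int, float]:
    """Peaked baseline editing profile; default yields window 4-8 at 20% of max."""
    return {
        p: peak_rate * float(np.exp(-((p - center) ** 2) / (2.0 * width**2)))
        for p in positions
    }


def _default_profile() -> dict[int, float]:
    return gaussian_position_profile()


def _default_preceding() -> dict[str, float]:
    return {"A": 1.0, "C": 1.0, "G": 0.3, "T": 1.5}


def _default_following() -> dict[str, float]:
    return {"A": 0.85, "C": 1.2, "G": 1.0, "T": 1.0}


def _default_weights() -> dict[str, float]:
    return {
        "intended": 1.0,
        "C>A": 0.05,
        "C>G": 0.05,
        "opposite_G>A": 0.12,
        "background": 0.001,
    }


@dataclass
class SimTruth:
    """Generative parameters of a synthetic screen (ground truth).

    Parameters
    ----------
    editor:
        "CBE" (intended C>T) or "ABE" (intended A>G).  Guides labeled
        "control" get only the background channel.
    position_profile:
        Baseline rate pi(p) per protospacer position; default a Gaussian
        peaked at position 6 (rate 0.3, width 1.3) over positions -5..17.
    preceding_mult, following_mult:
        Multiplicative flanking-base effects at the window center.
    context_position_gradient:
        gamma in mu_prev(b, p) = mu_b ** (1 + gamma*|p-6|); the preceding-
        base effect strengthens away from the center, broadening the
        effective window after T and narrowing it after G.
    substitution_weights:
        Relative channel weights; "background" is a flat context-free
        per-alt rate.
    guide_efficacy:
        Per-guide positive scalars; drawn lazily (lognormal, median 1,
        partially explained by spacer melting temperature) if empty.
    recombination_rate:
        Fraction rho of reads carrying a mismatched (recombined) target.
    read_depth / read_depth_dispersion:
        Mean reads per guide per sample; negative-binomial spread
        (dispersion = NB shape; larger is tighter; None for Poisson).
    latent_dispersion:
        Variance of the per-read Beta multiplier on all edit
        probabilities (0 disables; induces within-read correlation).
    position_noise_sd / position_noise_scale:
        Per-guide log-normal rate perturbation correlated along the
        construct (exponential kernel with this length scale); produces
        the distance-decaying inter-position rate correlations seen
        across guides.  0 disables.
    """

    editor: str = "CBE"
    position_profile: dict[int, float] = field(default_factory=_default_profile)
    preceding_mult: dict[str, float] = field(default_factory=_default_preceding)
    following_mult: dict[str, float] = field(default_factory=_default_following)
    context_position_gradient: float = 1.0
    substitution_weights: dict[str, float] = field(default_factory=_default_weights)
    guide_efficacy: dict[str, float] = field(default_factory=dict)
    efficacy_sd: float = 0.4
    efficacy_tm_corr: float = 0.5
    recombination_rate: float = 0.2
    read_depth: float = 800.0
    read_depth_dispersion: float | None = 10.0
    latent_dispersion: float = 0.2
    position_noise_sd: float = 0.25
    position_noise_scale: float = 3.0
    seed: int = 0

    @classmethod
    def default(cls, editor: str = "CBE", **overrides) -> "SimTruth":
        kw = {}
        if editor == "ABE":
            kw["preceding_mult"] = {"A": 0.6, "C": 1.0, "G": 1.0, "T": 1.25}
            kw["substitution_weights"] = {
                "intended": 1.0,
                "opposite_G>A": 0.10,
                "background": 0.001,
            }
        kw.update(overrides)
        return cls(editor=editor, **kw)

    def validate(self) -> None:
        if self.editor not in ("CBE", "ABE"):
            raise ValueError(f"unknown editor {self.editor}")
        if any(v < 0 for v in self.position_profile.values()):
            raise ValueError("position profile rates must be >= 0")
        if any(v < 0 for v in self.preceding_mult.values()) or any(
            v < 0 for v in self.following_mult.values()
        ):
            raise ValueError("context multipliers must be >= 0")
        if any(v < 0 for v in self.substitution_weights.values()):
            raise ValueError("substitution weights must be >= 0")
        if not 0 <= self.recombination_rate < 1:
            raise ValueError("recombination rate must be in [0, 1)")
        if self.read_depth <= 0:
            raise ValueError("read depth must be positive")
        if not 0 <= self.latent_dispersion < 1:
            raise ValueError("latent dispersion must be in [0, 1)")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["position_profile"] = {str(k): v for k, v in self.position_profile.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimTruth":
        d = dict(d)
        if "position_profile" in d:
            d["position_profile"] = {
                int(k): float(v) for k, v in d["position_profile"].items()
            }
        return cls(**d)


def intended_substitution(editor: str) -> tuple[str, str]:
    """The editor's intended transition: C>T for CBEs, A>G for ABEs."""
    if editor == "CBE":
        return ("C", "T")
    if editor == "ABE":
        return ("A", "G")
    raise ValueError(f"unknown editor {editor}")


# ---------------------------------------------------------------------------
# Library generation


def generate_guide_library(
    n_guides: int,
    seed: int,
    force_g: bool = True,
    upstream_context: int = DEFAULT_PROTOSPACER_OFFSET,
    editor_label: str = "CBE",
    pam: str | None = None,
    id_prefix: str = "g",
) -> list[GuideTarget]:
    """Generate a random guide-target library.

    Each construct is 79 nt: ``upstream_context`` random bases, the 20-nt
    spacer, a 3-nt NGG PAM, and random downstream context filling the
    remainder.  When ``force_g`` is set the first spacer base is a G (for
    expression from a U6 promoter) regardless of the embedded target base,
    leaving a 19-nt guide-target match.
    """
    if n_guides < 1:
        raise ValueError("n_guides must be >= 1")
    if pam is not None and (len(pam) != PAM_LENGTH or set(pam) - set(BASES)):
        raise ValueError(f"invalid PAM {pam!r}")
    downstream = CONSTRUCT_LENGTH - upstream_context - SPACER_LENGTH - PAM_LENGTH
    if downstream < 0:
        raise ValueError("upstream context too long for 79-nt construct")
    rng = np.random.default_rng(seed)
    bases = np.array(list(BASES))
    library = []
    width = max(5, len(str(n_guides)))
    for i in range(n_guides):
        target_spacer = "".join(rng.choice(bases, SPACER_LENGTH))
        spacer = ("G" + target_spacer[1:]) if force_g else target_spacer
        this_pam = pam if pam is not None else str(rng.choice(bases)) + "GG"
        up = "".join(rng.choice(bases, upstream_context))
        down = "".join(rng.choice(bases, downstream))
        construct = up + spacer + this_pam + down
        gt = GuideTarget(
            guide_id=f"{id_prefix}{i:0{width}d}",
            spacer=spacer,
            target_construct=construct,
            protospacer_offset=upstream_context,
            editor_label=editor_label,
        )
        library.append(gt)
    return library


def library_to_frame(library: list[GuideTarget]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "guide_id": [g.guide_id for g in library],
            "spacer": [g.spacer for g in library],
            "construct": [g.target_construct for g in library],
            "offset": [g.protospacer_offset for g in library],
            "pam": [g.pam for g in library],
            "editor_label": [g.editor_label for g in library],
        }
    )


def frame_to_library(df: pd.DataFrame) -> list[GuideTarget]:
    return [
        GuideTarget(
            guide_id=str(r.guide_id),
            spacer=str(r.spacer),
            target_construct=str(r.construct),
            protospacer_offset=int(r.offset),
            editor_label=str(getattr(r, "editor_label", "CBE")),
        )
        for r in df.itertuples(index=False)
    ]


def library_to_fasta(library: list[GuideTarget]) -> str:
    """FASTA of target constructs (one record per guide)."""
    return "".join(f">{g.guide_id}\n{g.target_construct}\n" for g in library)


# ---------------------------------------------------------------------------
# Closed-form rate oracle


def _channels_for_site(
    guide: GuideTarget, base: str, truth: SimTruth
) -> list[tuple[str, str, str]]:
    """Editor channels (ref, alt, class) active at a site with this ref base."""
    if guide.editor_label == "control":
        return []
    w = truth.substitution_weights
    intended = intended_substitution(truth.editor)
    channels = []
    if base == intended[0]:
        channels.append((intended[0], intended[1], "intended"))
        if truth.editor == "CBE":
            if "C>A" in w:
                channels.append(("C", "A", "C>A"))
            if "C>G" in w:
                channels.append(("C", "G", "C>G"))
    if base == "G" and "opposite_G>A" in w:
        channels.append(("G", "A", "opposite_G>A"))
    return channels


def _context_multiplier(
    guide: GuideTarget, position: int, channel_class: str, truth: SimTruth
) -> float:
    """Flanking-base multiplier for a channel at a position.

    The opposite-strand G>A channel is deamination of the C paired with
    the G, so its context is read on the reverse complement: the
    preceding base there is the complement of the sense base at p+1.
    """
    try:
        if channel_class == "opposite_G>A":
            prev = COMPLEMENT[guide.base_at(position + 1)]
            nxt = COMPLEMENT[guide.base_at(position - 1)]
        else:
            prev = guide.base_at(position - 1)
            nxt = guide.base_at(position + 1)
    except ValueError:
        return 1.0  # context beyond construct edge: neutral
    gamma = truth.context_position_gradient
    exponent = 1.0 + gamma * abs(position - WINDOW_CENTER)
    mu = truth.preceding_mult.get(prev, 1.0) ** exponent
    nu = truth.following_mult.get(nxt, 1.0)
    return mu * nu


def true_rate(
    guide: GuideTarget,
    position: int,
    substitution: tuple[str, str],
    truth: SimTruth,
) -> float:
    """Expected per-read rate of ``substitution`` at ``position`` for ``guide``.

    Editor channels follow the product model
    ``min(1, e_g * pi(p) * mu_prev * nu_next * kappa)``; any substitution
    not generated by an active channel falls back to the flat background
    rate.  The ref base must match the construct.
    """
    ref, alt = substitution
    if ref == alt or ref not in BASES or alt not in BASES:
        raise ValueError(f"invalid substitution {ref}>{alt}")
    if guide.base_at(position) != ref:
        raise ValueError(
            f"ref base {ref} does not match construct base "
            f"{guide.base_at(position)} at position {position}"
        )
    background = truth.substitution_weights.get("background", 0.0)
    if position not in truth.position_profile:
        return background
    for cref, calt, cls in _channels_for_site(guide, ref, truth):
        if (cref, calt) == (ref, alt):
            e = truth.guide_efficacy.get(guide.guide_id, 1.0)
            pi = truth.position_profile[position]
            ctx = _context_multiplier(guide, position, cls, truth)
            kappa = truth.substitution_weights[cls]
            return min(1.0, e * pi * ctx * kappa)
    return background


def editable_sites(guide: GuideTarget, truth: SimTruth) -> list[tuple[int, list]]:
    """Modeled positions of a guide with their active editor channels."""
    sites = []
    for p in sorted(truth.position_profile):
        try:
            base = guide.base_at(p)
        except ValueError:
            continue
        channels = _channels_for_site(guide, base, truth)
        if channels:
            sites.append((p, channels))
    return sites


def true_rate_matrix(guide: GuideTarget, truth: SimTruth):
    """Noise-free expected RateMatrix for a guide (editor channels only)."""
    from .outcomes import SUBSTITUTION_INDEX, SUBSTITUTIONS, RateMatrix

    rates = np.zeros((len(SUBSTITUTIONS), CONSTRUCT_LENGTH))
    for p, channels in editable_sites(guide, truth):
        col = position_to_column(p, guide.protospacer_offset)
        for ref, alt, _cls in channels:
            rates[SUBSTITUTION_INDEX[(ref, alt)], col] = true_rate(
                guide, p, (ref, alt), truth
            )
    return RateMatrix(
        guide_id=guide.guide_id,
        rates=rates,
        effective_total_reads=0.0,
        protospacer_offset=guide.protospacer_offset,
    )


# ---------------------------------------------------------------------------
# Latent draws


def draw_guide_efficacies(
    library: list[GuideTarget], truth: SimTruth, seed: int
) -> dict[str, float]:
    """Lognormal per-guide efficacies, median 1, correlated with spacer Tm."""
    from .features import melting_temperature

    rng = np.random.default_rng(seed)
    tm = np.array([melting_temperature(g.spacer) for g in library])
    z = (tm - tm.mean()) / tm.std() if tm.std() > 0 else np.zeros(len(tm))
    rho = truth.efficacy_tm_corr
    eps = rng.standard_normal(len(library))
    log_e = truth.efficacy_sd * (rho * z + np.sqrt(max(0.0, 1 - rho**2)) * eps)
    return {g.guide_id: float(np.exp(le)) for g, le in zip(library, log_e)}


def _position_noise(
    n_positions: int, sd: float, length_scale: float, rng: np.random.Generator
) -> np.ndarray:
    """Multiplicative lognormal noise correlated along positions (mean 1)."""
    if sd <= 0:
        return np.ones(n_positions)
    idx = np.arange(n_positions)
    cov = sd**2 * np.exp(-np.abs(idx[:, None] - idx[None, :]) / length_scale)
    # nugget for numerical PD
    cov += 1e-10 * np.eye(n_positions)
    eta = rng.multivariate_normal(np.zeros(n_positions), cov, method="cholesky")
    return np.exp(eta - sd**2 / 2.0)


# ---------------------------------------------------------------------------
# Screen simulation


@dataclass
class ScreenResult:
    """Output of :func:`simulate_screen`.

    ``profiles`` holds one OutcomeProfile per guide per sample;
    ``assigned_reads``/``matched_reads`` record the simulator's own
    bookkeeping of recombination (matched = reads carrying the guide's own
    target), pooled across samples; ``true_match_rate`` is the generative
    1 - rho per guide.
    """

    profiles: list[OutcomeProfile]
    assigned_reads: dict[str, int]
    matched_reads: dict[str, int]
    true_match_rate: dict[str, float]
    guide_efficacy: dict[str, float]

    @property
    def empirical_match_rate(self) -> dict[str, float]:
        return {
            g: (self.matched_reads[g] / self.assigned_reads[g])
            if self.assigned_reads[g] > 0
            else float("nan")
            for g in self.assigned_reads
        }


def _site_probs(
    guide: GuideTarget, truth: SimTruth
) -> list[tuple[int, list[tuple[str, str]], np.ndarray]]:
    """Per editable site: (position, [(ref, alt)...], channel probabilities)."""
    out = []
    for p, channels in editable_sites(guide, truth):
        subs = [(ref, alt) for ref, alt, _ in channels]
        probs = np.array([true_rate(guide, p, s, truth) for s in subs])
        out.append((p, subs, probs))
    return out


def _draw_read_count(truth: SimTruth, rng: np.random.Generator) -> int:
    if truth.read_depth_dispersion is None:
        return int(rng.poisson(truth.read_depth))
    k = truth.read_depth_dispersion
    p = k / (k + truth.read_depth)
    return int(rng.negative_binomial(k, p))


def simulate_screen(
    library: list[GuideTarget],
    truth: SimTruth,
    n_samples: int = 2,
    seed: int | None = None,
) -> ScreenResult:
    """Simulate per-sample outcome profiles for a guide-target library.

    Per guide and sample: a read count is drawn around ``read_depth``
    (negative binomial); a Binomial(n, rho) subset of reads is recombined
    (mismatched target, no edits); the remaining reads edit each editable
    site independently with probability ``true_rate`` scaled by the
    per-read Beta latent and the per-guide correlated position noise;
    channel competition within a site is multinomial.  Background
    substitutions occur at a flat rate at every construct position.
    Deterministic under a fixed seed.
    """
    truth.validate()
    if seed is None:
        seed = truth.seed
    rng = np.random.default_rng(seed)
    if not truth.guide_efficacy:
        truth.guide_efficacy = draw_guide_efficacies(
            library, truth, seed=int(rng.integers(2**31))
        )
    bg = truth.substitution_weights.get("background", 0.0)
    rho = truth.recombination_rate

    profiles: list[OutcomeProfile] = []
    assigned: dict[str, int] = {g.guide_id: 0 for g in library}
    matched: dict[str, int] = {g.guide_id: 0 for g in library}

    for guide in library:
        sites = _site_probs(guide, truth)
        noise = _position_noise(
            len(sites), truth.position_noise_sd, truth.position_noise_scale, rng
        )
        site_probs = [
            (p, subs, np.minimum(1.0, probs * w))
            for (p, subs, probs), w in zip(sites, noise)
        ]
        for si in range(n_samples):
            n = _draw_read_count(truth, rng)
            n_mis = int(rng.binomial(n, rho)) if rho > 0 and n > 0 else 0
            n_gen = n - n_mis
            assigned[guide.guide_id] += n
            matched[guide.guide_id] += n_gen
            counts: dict[tuple[int, str, str], int] = {}

            if n_gen > 0:
                if truth.latent_dispersion > 0:
                    a = (1.0 / truth.latent_dispersion - 1.0) / 2.0
                    m = 2.0 * rng.beta(a, a, size=n_gen)
                else:
                    m = None
                for p, subs, probs in site_probs:
                    total_p = probs.sum()
                    if total_p <= 0:
                        continue
                    if m is None:
                        if total_p >= 1.0:
                            pvals = np.append(probs / total_p, 0.0)
                        else:
                            pvals = np.append(probs, 1.0 - total_p)
                        cell = rng.multinomial(n_gen, pvals)[: len(subs)]
                    else:
                        tot_r = np.minimum(1.0, total_p * m)
                        n_edit = int((rng.random(n_gen) < tot_r).sum())
                        cell = rng.multinomial(n_edit, probs / total_p)
                    for (ref, alt), c in zip(subs, cell):
                        if c > 0:
                            counts[(p, ref, alt)] = counts.get((p, ref, alt), 0) + int(c)
                if bg > 0:
                    bg_counts = rng.binomial(
                        n_gen, bg, size=(CONSTRUCT_LENGTH, len(BASES) - 1)
                    )
                    nz = np.argwhere(bg_counts > 0)
                    for col, alt_i in nz:
                        ref = guide.target_construct[col]
                        alts = [b for b in BASES if b != ref]
                        pos = int(col) - guide.protospacer_offset + 1
                        key = (pos, ref, alts[alt_i])
                        counts[key] = min(
                            n, counts.get(key, 0) + int(bg_counts[col, alt_i])
                        )
            profiles.append(
                OutcomeProfile(
                    guide_id=guide.guide_id,
                    sample_id=f"s{si + 1}",
                    total_reads=n,
                    counts=counts,
                )
            )
    return ScreenResult(
        profiles=profiles,
        assigned_reads=assigned,
        matched_reads=matched,
        true_match_rate={g.guide_id: 1.0 - rho for g in library},
        guide_efficacy=dict(truth.guide_efficacy),
    )


def simulate_match_assay(
    library: list[GuideTarget],
    truth: SimTruth,
    reads_per_guide: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Raw read pairs from the guide-target mismatch assay.

    Emulates the long-range PCR on an early, pre-editing timepoint: the
    forward read covers the guide (spacer) region and the reverse read the
    79-nt target.  A fraction ``rho`` of each guide's reverse reads carry a
    different, uniformly chosen guide's target (recombination).
    Returns a table (read_id, guide_id, forward_seq, reverse_seq) where
    guide_id is the true template guide for reference only.
    """
    rng = np.random.default_rng(seed)
    rho = truth.recombination_rate
    rows = []
    n_lib = len(library)
    rid = 0
    for i, guide in enumerate(library):
        n_mis = rng.binomial(reads_per_guide, rho) if rho > 0 else 0
        donors = rng.integers(0, n_lib, size=n_mis)
        for r in range(reads_per_guide):
            if r < n_mis:
                j = int(donors[r])
                if j == i:
                    j = (j + 1) % n_lib
                reverse = library[j].target_construct
            else:
                reverse = guide.target_construct
            rows.append((f"r{rid:08d}", guide.guide_id, guide.spacer, reverse))
            rid += 1
    return pd.DataFrame(
        rows, columns=["read_id", "guide_id", "forward_seq", "reverse_seq"]
    )
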