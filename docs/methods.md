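# Methods

## Scope and data model

`bescreen` analyses pooled self-targeting base-editing screens. Each
library member is a single lentiviral cassette encoding a 20-nt gRNA
spacer and its own 79-nt target construct: the 23-nt protospacer + PAM
embedded in randomized flanking context. After delivery and editing,
amplicon sequencing of the target region yields, per guide and sample,
read counts for every base substitution at every construct position.
The package covers the full path from those counts (or from simulated
raw reads) to recombination-corrected editing rates, position-stratified
sequence-bias statistics, per-position predictive models, and
purity/efficiency scoring of SNP-correcting guides.

Coordinates are protospacer-relative and 1-based: position 1 is the
first spacer base, the PAM occupies 21–23, and upstream context
positions are ≤ 0. By default the construct places 10 nt of context
upstream of the protospacer and 46 nt downstream, so the construct spans
protospacer positions −9..69 and the generative model covers −5..17.
The upstream/downstream split of the 56-nt randomized context is a
package choice (it is configurable); 10 nt upstream is the minimum that
leaves the full −5..17 analysis range inside the construct with margin
for context lookups. Editing-rate matrices are 12 ordered substitutions
(A>C, A>G, … T>G) × 79 construct positions.

## Generative model of the synthetic screen

The simulator is first-class, tested code with a closed-form rate oracle
(`true_rate`). The probability that a read of guide *g* carries
substitution *s* at position *p* is

    r(g, p, s) = min(1, e_g · π(p) · μ_prev(b_{p−1}, p) · ν_next(b_{p+1}) · κ_s)

with the following components and defaults.

**Position profile π(p).** Gaussian over positions −5..17, peak rate 0.3
at position 6, width 1.3. At the 20%-of-maximum threshold this yields
the canonical editing window, positions 4–8.

**Preceding-base effect μ_prev(b, p).** Center multipliers are T = 1.5,
G = 0.3 (A, C = 1) for cytosine editors, and A = 0.6, T = 1.25 for
adenine editors. The effect strengthens away from the window center:
μ_prev(b, p) = μ_b^(1 + γ·|p − 6|) with γ = 1 by default. This
position-dependence is essential, not cosmetic: a position-independent
multiplicative effect rescales a stratum's profile without changing its
shape, so every preceding-base stratum would have the same
20%-of-its-own-max window. With the gradient, a preceding T flattens the
profile and broadens the window to 3–9 while a preceding G sharpens it
to 5–7, the behaviour screens actually show.

**Following-base effect ν_next(b).** C = 1.2, A = 0.85, position-
independent.

**Substitution channels κ_s.** For CBEs: intended C>T (weight 1), C>A
and C>G transversions (0.05 each), and an opposite-strand G>A channel
(0.12) whose flanking context is read on the reverse complement (its
preceding base is the complement of the sense base at p+1). For ABEs:
intended A>G (1) and opposite-strand G>A (0.10). A flat background
channel (rate 0.001 per alternative base at every position, context- and
position-free) models sequencing/PCR noise and is the only channel
active in control guides; it deliberately falls outside the product
formula so that out-of-window rates match control-cell background
instead of vanishing with π.

**Guide efficacy e_g.** Lognormal with median 1 and log-SD 0.4, with
correlation 0.5 between log e_g and the z-scored spacer melting
temperature — an efficacy latent that is only partially explained by the
model's Tm feature, as in real screens.

**Read sampling.** Read counts per guide per sample are negative
binomial around `read_depth` (default 800, NB shape 10; Poisson
optional), so the ≥100-reads-per-sample filter removes a realistic tail.
Within a read, editable sites compete channels multinomially and
distinct sites are independent unless the per-read latent is on.

**Correlation structure.** Two latents: (i) a per-read Beta multiplier
on all edit probabilities (variance `latent_dispersion`, default 0.2),
which induces within-read co-editing; and (ii) a per-guide lognormal
perturbation of site rates with an exponential spatial kernel
(`position_noise_sd` 0.25, length scale 3 positions), which produces the
distance-decaying inter-position rate correlations observed across
guides (neighbouring positions correlate much more strongly than
distant ones). A single shared per-read multiplier cannot produce
distance decay — it correlates all position pairs equally and its
per-guide average is ~1 at realistic depth — hence the second latent.

**Recombination.** A fraction ρ (default 0.2) of each guide's reads
carry a different, uniformly drawn guide's target. Such reads inflate
the read total but contribute no edits at the guide's sites, which is
exactly the dilution the downstream match-rate correction removes. The
simulator also emits the separate guide–target mismatch assay: read
pairs whose forward read covers the spacer and whose reverse read covers
the (possibly recombined, pre-editing) target.

**What the generator does not emulate.** No per-base quality scores, no
PCR duplicates, no indels (sub-0.5% in this assay class), no positional
sequencing-error profile beyond the flat background, and no guide
dropout from fitness effects. Passing recovery tests therefore show the
statistical machinery is correct under the stated model, not that real
screens are free of these additional effects.

## Outcome processing

Samples (timepoints, replicates) of one guide are pooled by summing
counts; pooling then rating equals the read-weighted average of
per-sample rates. Guides with fewer than 100 reads in *any* sample are
dropped (exactly 100 is kept). Rates are counts over an effective read
total, clipped to 1 with a warning if the denominator falls below an
observed count (possible after correction with an inconsistent match
rate).

## Recombination correction

Reads of the mismatch assay are assigned to guides by exact 20-nt spacer
match anywhere in the forward read, falling back to a unique match of
the middle 10 spacer bases (positions 6–15, the symmetric center;
configurable). Ambiguous 10-mers — shared by several guides, or hitting
two different guides within one read — leave the read unassigned, since
uniqueness is what makes the 10-mer informative.

Target integrity is scored by global alignment of the reverse read
against the assigned guide's expected construct: match +1, mismatch 0,
affine gaps costing −1 for the first column and −0.1 for each further
column, end gaps penalized (Biopython `PairwiseAligner`). A score ≥ 50
calls a match; random 79-mer construct pairs score below ~41 under this
scheme (confirmed empirically in the acceptance run), while a correctly
paired read with a handful of edits scores near 79, so the threshold
separates the two populations with a wide margin.

The guide-target match rate is the matched fraction of a guide's
assigned reads. Correction scales each guide's read total by its match
rate (rounded to the nearest integer by default; configurable to stay
fractional) and leaves edited-read counts unchanged, on the assumption
that a read must have carried the matching target to acquire the edit.
Corrected rates are therefore ≥ uncorrected ones, with equality at match
rate 1. Guides with zero match rate cannot be corrected and are excluded
with a logged reason.

## Bias statistics

All statistics operate across guides on per-guide rate matrices, with
flanking context read from each guide's construct (so position 1 has a
preceding base in the upstream context).

- **Medians with bootstrap CIs.** Per-position medians carry 95%
  percentile CIs from 1000 bootstrap resamples, deterministic under a
  seed. The percentile method mildly undercovers for sample medians
  (the bootstrap distribution of an order statistic is lumpy); observed
  coverage in simulation is a few points below the nominal 95%.
- **Context effects.** The percent change from a flanking base is
  100 × (median of the base's stratum − pooled median of all other
  bases' guides) / (pooled other median). Pooling the three other bases
  into one stratum (rather than averaging three per-base medians) is
  the package's reading of "compared to all other bases"; medians are
  used throughout because the per-position summaries are medians.
  Strata under 20 guides are reported missing — bootstrap medians are
  unstable below that.
- **Editing windows.** Positions whose median reaches 20% of the
  profile's maximum, reported as a set plus the contiguous span around
  the peak. Applied marginally and per preceding-base stratum, each
  stratum thresholded at 20% of its own maximum.
- **Per-base rates by editable-base count, inter-position Pearson
  correlations** (≥3 guides, defined variance), and **excess over
  control** (difference of medians with a bootstrap CI) complete the
  report. t-tests between strata are deliberately not used as
  gatekeepers; they would be descriptive annotations only.

## Features, standardization, splitting

Model inputs are 81 features per guide: position-major one-hot encoding
of the 20-nt spacer (channel order A, C, G, T; exactly one hot bit per
slot; N is rejected at ingestion) plus the spacer's nearest-neighbour
melting temperature. Tm uses Biopython `MeltingTemp.Tm_NN` defaults —
the SantaLucia (1998) unified DNA/DNA table with terminal corrections,
25 nM strand concentrations, 50 mM Na⁺, and the 0.368·(N−1)·ln[Na⁺]
entropy salt correction. Any fixed, documented, GC/stacking-correlated
parameter set would serve equally; determinism and documentation are the
requirements, and the unit suite pins the computation against a
hand-summed thermodynamic oracle.

Targets are per-position intended-transition rates (NaN where the guide
lacks an editable base) plus an "overall" target: the summed
substitution rate across modeled positions, clipped to 1 — an any-edit
approximation that counts multi-edit reads once per edit. Each dataset
is standardized independently per position with the population (ddof=0)
mean and SD of its training portion; z-scores are never re-standardized
after datasets are combined. Train/test splits are 90/10 per dataset
before combination, with the test size floored (95 guides → 86/9), and
test rows are never mixed into training.

## Per-position models

One squared-error `GradientBoostingRegressor` per position 3–10 plus the
overall model: 100 trees, depth 4, minimum 2 samples per leaf, learning
rate 0.1, no stochastic subsampling, so fits and predictions are
deterministic under a fixed seed. These hyperparameters are the
defaults; an optional 5-fold CV grid search over wider ranges
(10–1000 trees, depth 1–10, leaf 1–50, rate 0.001–1) is provided for
re-selection. Each position's model trains only on guides with an
editable base at that position (minimum 50 rows). Evaluation reports
Pearson R and MSE per position, averaged across positions, and broken
down by provenance dataset. Downsampling experiments refit on random
subsets (80/50/25/10% by default, 100 repetitions) and always evaluate
on the full test set. Impurity-based feature importances are normalized
to sum 1 per model. Fitted model sets persist as a joblib bundle with a
JSON sidecar (schema width, hyperparameters, seed, training provenance);
loading refuses a bundle whose metadata disagrees with the fitted
schema.

## Absolute rates, purity, guide scoring

Standardized predictions map back to absolute rates via r = μ_p + z·σ_p,
clipped to [0, 1]. When a dataset's own per-position statistics are
unreliable, anchored scaling derives (μ_p, σ_p) from a position-6 anchor
(e.g. mean 0.5 for a clinical scenario, SD 0.2) times a per-position
scaling vector; the default vector follows the marginal position-profile
shape and is an explicit assumption users should replace with their own
calibration. Purity at a position is its intended-edit rate divided by
the summed intended-edit rate over the guide's modeled positions —
scale-invariant, so the anchor choice does not affect it. Editors with a
shifted window (e.g. Target-AID) are handled by shifting the guide frame
3 nt downstream (original position 1 becomes position 4), filling the
vacated 5′ slots from the genomic flank, and mapping predictions back to
original coordinates.

Disease-guide evaluation restricts to SNPs at positions 3–10 (the
modeled range): correction efficiency is the predicted intended-edit
rate at the SNP position, the bystander sum is the summed intended-type
editing at the other editable positions in 3–10, and the shortlist keeps
guides with purity > 0.8 that are also in the top decile of correction
efficiencies *within the evaluated cohort* (a relative, not absolute,
cutoff).

## Numerical and design choices

- Population (ddof=0) SDs everywhere in standardization; SD ≤ 1e−12 is
  treated as degenerate and rejected.
- The scaled read total is rounded to the nearest integer by default
  (integer denominators keep counts interpretable); unrounded
  denominators are available by flag.
- The spec-level split rule floors the test-set size; an epsilon guards
  the floating-point floor (100 × (1−0.9) must give 10, not 9).
- Multi-substitution reads increment every affected cell independently;
  the profile container does not attempt joint-outcome bookkeeping.
- Pipeline runs derive every stage seed from the single config seed, and
  every output file embeds the config hash; readers refuse mixed hashes.
  Reruns under one config reproduce metric tables byte for byte.

## Problem sizes used in verification

The test suite and acceptance script size their simulations to what the
checks need: 500 guides at read depth 10⁴ with ρ = 0.3 for correction
recovery (noise latents off, so the 3-binomial-SE band is the exact
sampling distribution); 2000 guides at depth 800 for context-effect and
window recovery; 1200 guides for model training runs; 10 repetitions per
fraction for the learning-curve property. The context-effect recovery
oracle is the same estimator applied to noise-free rate matrices built
from `true_rate`, i.e. the infinite-depth limit of the screen.

## Known limitations

- The generator's channel weights and context multipliers are shared
  across guides; real deaminases show additional motif effects (e.g.
  TCT-specific transversion boosts) that are not separately modeled.
- The overall-editing target over-counts multi-edit reads; it is an
  upper bound on the fraction of reads with any edit.
- Anchored destandardization inherits whatever error is in the supplied
  scaling vector; the built-in default is a modeling assumption, not a
  calibration.
- The match-rate correction assumes recombined reads are unedited at the
  guide's sites; templates recombined with a target that happens to
  share edit sites violate this mildly.
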