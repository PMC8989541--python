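# bescreen

Analysis of pooled **self-targeting base-editing screens**: from screen
read counts through recombination-corrected per-position editing rates
and position-stratified sequence-bias statistics, to per-position
predictive models of editing activity and purity/efficiency scoring of
disease-SNP-correcting guides. A fully tested synthetic-screen generator
with known ground truth makes the entire pipeline runnable and
verifiable without any external data.

## The problem

CRISPR base editors (cytosine editors converting C→T, adenine editors
converting A→G) act within an editing window of the protospacer —
canonically positions 4–8, PAM at 21–23 — but their activity varies
strongly with the position of the target base and its flanking sequence,
and unintended *bystander* edits of nearby editable bases are common.
Self-targeting screens measure editing outcomes at thousands of
guide–target pairs at once: each lentiviral construct carries a 20-nt
gRNA and its own 79-nt target (protospacer + PAM in randomized context),
so sequencing the target region reads out, per guide, the fraction of
reads carrying every substitution at every position (a 12 × 79 rate
matrix).

Two analysis problems make this non-trivial:

1. **Guide–target recombination.** Lentiviral template switching pairs
   some guides with the wrong target, diluting apparent editing. The fix
   is to measure each guide's *match rate* (fraction of reads whose
   target aligns to the expected construct at score ≥ 50 under
   match +1 / mismatch 0 / affine gaps −1, −0.1) and scale the guide's
   read total by it, leaving edited-read counts unchanged.
2. **Position-specific sequence bias.** The effect of the flanking base
   depends on the edited position — a preceding T broadens the effective
   editing window, a preceding G narrows it — so editing is modeled
   *per position*: one gradient-boosted tree regressor for each
   protospacer position 3–10 (plus an overall-editing model), with the
   one-hot spacer sequence and its melting temperature as the 81
   features and per-dataset z-scored rates as targets
   (z = (r − μ_p)/σ_p).

Predicted standardized rates are mapped back to absolute efficiencies
(r = μ_p + z·σ_p, optionally anchored at a position-6 mean such as 50%
for clinical scenarios) and summarized per guide as **correction
efficiency** (intended-edit rate at the SNP position), **bystander sum**
(intended-type editing at the other modeled positions), and **purity**
(efficiency / total intended editing), which is scale-invariant.

## Worked example

```python
import bescreen as bs

# 1. simulate an 800-guide CBE screen with 30% guide-target recombination
library = bs.generate_guide_library(800, seed=7)
truth = bs.SimTruth.default("CBE", recombination_rate=0.3)
screen = bs.simulate_screen(library, truth, n_samples=2, seed=8)

# 2. estimate per-guide match rates from the mismatch assay (alignment)
assay = bs.simulate_match_assay(library, truth, reads_per_guide=100, seed=9)
stats = bs.match_stats_from_reads(
    assay,
    spacers={g.guide_id: g.spacer for g in library},
    targets={g.guide_id: g.target_construct for g in library},
)

# 3. filter (>= 100 reads in every sample), pool samples, correct rates
retained = bs.filter_low_coverage(screen.profiles, min_reads=100)
by_guide = {}
for p in screen.profiles:
    if p.guide_id in retained:
        by_guide.setdefault(p.guide_id, []).append(p)
matrices = {
    gid: bs.correct_profile(bs.pool_samples(profs), stats[gid])
    for gid, profs in by_guide.items()
}
print(f"retained {len(matrices)}/{len(library)} guides; "
      f"mean match rate {sum(s.match_rate for s in stats.values())/len(stats):.3f}")

# 4. position profile, editing window, context effects
from bescreen.bias import median_position_profile
lib_index = {g.guide_id: g for g in library}
positions = list(range(-5, 18))
profile = median_position_profile(matrices, lib_index, ("C", "T"), positions)
window = bs.editing_window(profile)
print(f"median C>T rate at position 6: {profile[6]:.3f}")
print(f"editing window (20% of max): {sorted(window['positions'])}")
eff_T = bs.context_effect(matrices, lib_index, ("C", "T"), 6, "preceding", "T")
eff_G = bs.context_effect(matrices, lib_index, ("C", "T"), 6, "preceding", "G")
print(f"preceding-base effect at position 6: T {eff_T:+.0f}%, G {eff_G:+.0f}%")
```

Output:

```
retained 800/800 guides; mean match rate 0.701
median C>T rate at position 6: 0.301
editing window (20% of max): [4, 5, 6, 7, 8]
preceding-base effect at position 6: T +55%, G -74%
```

The estimated match rate recovers the simulated 70% (1 − ρ); the
corrected rates peak at ~0.30 at position 6 with the canonical 4–8
window; and the flanking-base effects recover the planted biases
(editing up after a T, strongly down after a G).

The full pipeline — simulate → correct → bias report → featurize →
train → evaluate → downsample → disease-guide scoring — runs from one
YAML config:

```bash
bescreen run-all --seed 1 --outdir out/
bescreen predict --model out/model.joblib --spacers my_spacers.txt --out pred.tsv
bescreen disease --model out/model.joblib --guides snps.tsv --out scored.tsv
```

Every output file embeds the config hash, and reruns under the same
config reproduce the metric tables byte for byte.

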