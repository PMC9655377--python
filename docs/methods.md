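# Methods

## Model and assumptions

`stabselect` quantifies genotypic stability as geometric proximity in a
trait space. The assumptions, in order of consequence:

1. **A genotype's response to stress is summarized by its mean trait
   vector.** Replicates (default 4) are averaged per genotype ×
   environment after normalization; replicate dispersion is not
   propagated into the score. The distance is computed on means, not
   replicate-wise — replicate-wise distances are available only as a
   diagnostic via the underlying `distance` functions.
2. **Traits are comparable after max-normalization.** Each trait is
   divided by its maximum over the *entire* dataset — all genotypes,
   environments and replicates pooled — giving dimensionless values in
   [0, 1] with at least one exact 1 per trait. Pooling is deliberate:
   distances compare environments, so the control and stress vectors must
   share one scale; per-environment maxima would erase exactly the level
   differences being measured. Max-normalization is linear, so
   normalize-then-average equals average-then-normalize (tested), but it
   is sensitive to a single outlying maximum; screen raw data first.
3. **Stability = small Minkowski distance to the own-genotype control
   vector.** Default order p = 1 (Manhattan), which discriminates near
   from far vectors better than Euclidean in higher-dimensional spaces;
   any p ≥ 1 is accepted. The implementation satisfies the metric axioms
   and the norm ordering d(·,·,p₁) ≥ d(·,·,p₂) for p₁ < p₂ (tested).
4. **Two stresses are fused by TOPSIS with cost orientation.** The
   decision matrix is the per-genotype (ds, dd) pair. Distances are
   cost criteria — smaller is better — so the ideal point takes column
   minima and the anti-ideal column maxima. Orientation is an explicit
   argument (`cost`/`benefit` per criterion) rather than an implicit
   convention, so the module is safe to reuse on benefit-type criteria.

## Parameters that matter

| parameter | meaning | default | why |
|---|---|---|---|
| `p` | Minkowski order of the trait-space distance | 1 | best near/far contrast in ~7 dimensions |
| `weights` | TOPSIS criterion weights (w_s, w_d), sum 1 | (0.5, 0.5) | no a-priori preference between stresses |
| sweep grid | (w_s, w_d) pairs for robustness | (0.1,0.9) … (0.9,0.1) in steps of 0.2 | spans the trade-off; endpoints (1,0)/(0,1) allowed but flagged as single-criterion |
| `trait_names` | trait list / space dimension | GERM, SL, RL, TL, SDM, RDM, TDM | standard germination-assay panel; fully configurable |
| summary precision | printed decimals | 4 | matches the reporting convention of screening tables |

Osmotic calibration constants: R = 0.008314 MPa L mol⁻¹ K⁻¹, van't Hoff
factor i = 2 for NaCl, NaCl molar mass 58.44 g mol⁻¹, temperatures in °C
at the interface (Kelvin conversion internal). The Michel–Kaufmann
polynomial is quadratic in concentration at fixed temperature and is
inverted in closed form; when both roots are non-negative the smaller one
(the branch continuous with C = 0) is returned, for exactness and
determinism. At −0.20 MPa and 25 °C the inverses give 119.57 g/L PEG-6000
and 2.357 g/L (0.04034 mol/L) NaCl, the amounts used to impose matched
drought and saline stress.

## The synthetic-trial generator

`SyntheticConfig`/`simulate_phenotypes` emulate the replicated
multi-environment design the analysis assumes: 70 genotypes × 3
environments × 4 replicates by default. Per genotype g and trait t,

    stress_mean(g,t) = control_mean(g,t) · (1 − direction(t) · f · s_env(g))

with sensitivity s_env(g) ∈ [0, 1], maximal effect fraction f = 0.8, and
direction(t) = +1 (stress decreases the trait) unless overridden — root
traits can be set to −1 to emulate stress-stimulated root growth.
Replicates multiply the mean by (1 + cv·N(0,1)), truncated at 0 and capped
at 100 for percentage traits, with cv = 0.05 by default. Stress effects
are multiplicative because traits are strictly positive and stress
responses are conventionally reported as percentage change. Control means
are drawn uniformly per trait from ranges chosen as plausible 14-day
soybean germination-roll values (GERM 80–100 %, SL 8–14 cm, RL 12–20 cm,
TL 20–34 cm, SDM 0.10–0.18 g, RDM 0.04–0.08 g, TDM 0.14–0.26 g).

All randomness flows from one seed through three independent
`numpy.random.default_rng` streams (baselines, sensitivities, noise), so
`ground_truth_ranking` resolves unspecified sensitivities identically to
the simulator and identical configs give byte-identical tables.

What the generator does **not** emulate, and what passing tests therefore
do not show about real data: trait–trait correlations (TL is not forced
to equal SL + RL; dry matter is independent of length), genotype ×
environment interactions beyond a single scalar sensitivity per stress,
non-Gaussian replicate error, and missing data. The recovery experiments
show the pipeline recovers a known one-dimensional stability ordering
under 5 % replicate noise; they do not validate the biological adequacy
of a Manhattan-distance stability definition.

## Numerical and design choices

- **Ranking ties.** Distance ranks (`rank_ds`, `rank_dd`) and TOPSIS
  ranks use competition ranking (ties share the smallest position); the
  ordered genotype *list* breaks ties lexicographically by label, so all
  outputs are deterministic.
- **Weight hygiene.** Weights that do not sum to 1 (tolerance 1e−9) are an
  error; opt-in `normalize_weights=True` rescales explicitly. Silent
  renormalization hides bugs.
- **Degenerate TOPSIS input.** If every alternative coincides in weighted
  normalized space, all closeness values are defined as 0.5 with a
  warning, avoiding 0/0 symmetrically. A zero criterion column or fewer
  than two alternatives is an error.
- **Degenerate traits.** An all-zero trait column cannot be
  max-normalized and raises a named error rather than propagating NaN.
- **Missing replicates/environments.** A genotype absent from any required
  environment is flagged on table construction and excluded from
  comparisons with a warning — never imputed.
- **Percentage change** is computed on raw (un-normalized) replicate
  means, pct = 100·(control − stress)/control, so the sign convention is
  positive = decrease under stress, negative = increase; a zero control
  mean leaves the cell NaN with a warning.
- **I/O.** Long-format CSV (UTF-8, comma delimiter, `.` decimal) is the
  canonical layout; tidy `trait`/`value` files are pivoted on read.
  Writes are full-precision so read-back is value-identical.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` exercise: 200 random decision
matrices (2–8 alternatives × 1–4 criteria) against an independent
loop-based TOPSIS transcription at 1e−12; 500 random vector triples for
the metric axioms at p ∈ {1, 2, 3}; 100 seeded 20-genotype × 4-replicate
trials at cv = 0.05 for top-5 recovery (≥ 4/5 overlap required in ≥ 90 %
of runs); and dominance/sweep coherence on noise-free trials. These sizes
give stable pass/fail behaviour at sub-minute runtimes.

## Known limitations

- Max-normalization ties every score to the observed maxima: adding or
  removing a genotype can shift all distances. Report maxima alongside
  results (the model logs them at INFO level).
- TOPSIS rankings are not independent of the alternative set (a known
  property of the method family); the weight sweep probes weight
  robustness, not set robustness.
- With a single criterion the closeness score reduces to a monotone
  transform of the raw value — correct, but the fusion adds nothing.
- The stability notion is purely phenotypic distance; it does not weigh
  agronomic value. A genotype can be perfectly stable and uniformly poor.
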