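# Methods

This note documents the models, parameter choices and numerical decisions
behind `trpml`, and what the synthetic-data tests do and do not establish
about real data.

## Constraint-based target scoring

The scoring procedure asks how metabolic flux would redistribute if a cell
diverted resources from growth to tryptophan. For a stoichiometric model
(S, bounds, growth objective, tryptophan sink) each solve is a three-stage
LP: maximize growth to get μ_max; fix growth at f·μ_max and maximize the
tryptophan sink; fix both and minimize Σ|v| (parsimonious FBA, standard
positive/negative flux split). All LPs use scipy's HiGHS backend with a
fixed variable ordering, so flux vectors are bit-stable across runs. The
suboptimal grid is f = 0.30…0.80 in 0.05 steps — the unique equal spacing
that yields 11 conditions on that range — and is configurable.

Reaction scores are average absolute-flux fold changes against the
max-growth reference. Two numerical choices matter:

- **Zero reference fluxes.** A pseudo-flux δ (default 1e-4
  mmol·gDW⁻¹·h⁻¹) is added to numerator and denominator. Reactions whose
  flux stays below δ in the reference *and* every scan point are reported
  as *unscored* rather than given a meaningless fold change of 1. δ
  preserves ranking among reactions that genuinely activate (their scores
  are large but finite) while avoiding division by zero.
- **Reversible reactions.** Fold changes use |v|; a direction flip between
  reference and scan is flagged per reaction (`sign_change`) instead of
  being folded into the score, since a signed fold change has no natural
  scale across reversible reactions.

Gene scores are plain unweighted means over the gene's scored reactions,
deliberately ignoring AND/OR gene–reaction rule structure; rule-aware
scoring is out of scope. Classification uses a 1e-9 tolerance around 1.
Two carbon-source regimes are handled as two independent scans on two
model configurations with `regime_overlap` intersecting the classified
sets. Pathway overrepresentation is a two-sided Fisher exact test
(scipy) on the in/out-pathway × target/non-target table over an explicit
gene universe — the universe is a required input because results depend
on it strongly.

`demo_model()` is a small synthetic central-carbon network (glycolysis,
pentose phosphate branch, PEP/E4P condensation into a tryptophan sink)
used for demos and smoke runs; it is not a curated reconstruction, and the
package does not ship or require a genome-scale model.

## Library design and coverage

The design space is the Cartesian product of per-gene promoter bins
(default 5 genes × 6 promoters = 7776), enumerated gene-major so ordering
is deterministic. Parts accounting: each assembly uses one promoter + one
ORF unit per gene plus a marker cassette and two homology arms (13 parts);
the pool holds all 30 promoters, 5 ORF units, the marker and both arms
(38).

Coverage simulation: per repetition, n colonies are drawn; each assembles
correctly with probability p (default 0.82); correct colonies draw one
promoter per gene *independently* from the catalog's pick probabilities
(whether real libraries correlate picks across genes is unknown; the
independent model is flagged here as the package's choice). Incorrect
assemblies contribute no genotype. With uniform picks the expected unique
count has the exact occupancy form G(1−(1−1/G)^N) for fixed N correct
colonies, which the Monte Carlo must match within 3 standard errors — the
binomial spread of N adds a second-order correction below 0.1 genotypes at
study scale. The default pick distribution is uniform; a "skewed" catalog
(rarest promoter 1%, most common 35% per bin) mimics the uneven
representation real one-pot libraries show. No empirical pick
distribution is shipped — the skew is calibrated qualitatively to those
two extremes — so coverage estimates for any particular real library
require supplying its measured pick probabilities as input.

## Phenotyping

Background is the per-plate, per-timepoint mean of media wells, subtracted
from every well. The GFP synthesis rate is computed inside the OD600
window [0.075, 0.150], where per-cell fluorescence of the biosensor
reporter is stable. Choices:

- **Window points.** The first contiguous run of in-window time points is
  used; later re-entries (transient OD dips) are ignored. Boundary-nearest
  points are used as-is, without interpolating the exact OD crossings.
- **Estimator.** Default is the endpoint estimator ΔGFP/Δt between the
  first and last in-window points (the literal definition of the rate); a
  least-squares slope over all in-window points (~13–15 at the default
  growth settings) is available and preferred when noise is high. Both
  agree exactly for linear GFP(t), and the run configuration pins one.

QC is a conjunction of five criteria: max OD reaches the window top
(excludes uninoculated/slow wells), sequencing complete, assembly exactly
as designed, plasmid cured, single genotype. A missing metadata field
fails its criterion with reason "missing" — absence never passes.
Replicates aggregate to mean, SEM = sd/√n and CV of the mean = SEM/mean;
at n = 1 SEM/CV are undefined and the strain is excluded from model
training by default.

Two outlier schemes are implemented. The percentile rule flags replicates
whose relative deviation from their strain mean lies strictly above the
(1−q) quantile of all deviations (q = 0.01) and removes the owning strains
whole. The robust rule flags replicates with |rate − median| > 3·1.4826·MAD
within each strain, then drops any strain left with ≤1 replicate. The MAD
rule is degenerate for duplicate (n=2) strains — both deviations are equal
— so pairs whose relative difference exceeds 50% of their mean are treated
as irreproducible (one replicate flagged, hence the strain drops). The
3·MAD cutoff and the 50% pair cutoff are configurable; the median ± 3·MAD
rule is the canonical univariate robust filter and is the package's
chosen instantiation.

## Bayesian ensemble model

Genotypes are one-hot encoded (genes in catalog order, promoters in bin
order; 30 columns, exactly one 1 per gene block; invertible). The model is

y_i ~ Normal(Σ_m w_m g_m(x_i), σ²), w ~ Dirichlet(1,…,1),
σ ~ half-Cauchy(sd(y)).

The eight default base learners span linear, ridge, lasso, RBF kernel
ridge, k-nearest-neighbors, a depth-limited tree, random forest and
gradient boosting — all deterministic given their seeds. The weight
likelihood is evaluated on 5-fold *out-of-fold* base predictions
(stacking): this is the package's own choice, made so that a learner that
merely memorizes training data earns no posterior weight; fitting weights
on in-sample predictions demonstrably degenerates toward the most
overfit learner.

Sampling: random-walk Metropolis on stick-breaking-transformed weights
plus log σ (with the appropriate Jacobians), 4 chains × 5000 draws with
1000 burn-in, proposal scale adapted toward 30% acceptance during burn-in
only (frozen afterwards to preserve detailed balance). Acceptance rates
outside [0.05, 0.8] trigger a warning. Predictive moments are exact given
the pooled draws: μ(x) = p(x)ᵀE[w] and σ²(x) = p(x)ᵀCov[w]p(x) + E[σ²],
where p(x) stacks base-learner predictions — no re-sampling at predict
time. Training rows are canonically sorted inside `fit`, making the whole
posterior invariant to input row order. A base learner that raises during
fitting is excluded with a warning and the ensemble renormalizes over the
survivors.

Evaluation: k-fold cross-validated MAE with random fold assignment
(default k = 10, i.e. 90/10; the alternative 80/20 protocol is k = 5 via
configuration — both conventions are common in practice, and the run
manifest records which was used). Learning curves subsample the
dataset per size and repetition; the *train* MAE is computed on the whole
dataset after fitting on the subsample, the *test* MAE by cross-validation
inside the subsample; CIs are mean ± 1.96·sd/√reps over 10 repetitions.

## Recommendation

The 7776-point space is exhaustively enumerated and scored — exact search
replaces any stochastic optimizer (e.g. Parallel Tempering) because the
space is tiny; this is a deliberate departure that can only improve the
optimum found. Exploit ranks by predictive mean; explore by expected
improvement with incumbent f\* = the best observed training strain-mean
(the standard Bayesian-optimization convention). Seen designs are
excluded by default. Ties
break lexicographically on the genotype key for reproducibility.

## Synthetic-data generator

The generator targets the *statistical* structure of a biosensor-screened
library, not its mechanism (no tryptophan pools, binding kinetics or HPLC
titers):

- **Response surface.** Per-gene per-promoter additive effects on a latent
  log-rate scale (sd 0.35) plus small pairwise gene×gene interaction terms
  (sd 0.08, default on). Additive-only surfaces make exploit
  recommendation exactly solvable by a linear model (used in oracle
  tests); interactions keep the learning task non-trivial, mirroring the
  non-intuitive winning designs real screens produce. Calibration is a
  monotone piecewise-linear map hinged at the all-native reference design:
  the space minimum, maximum and reference hit 40, 260 and 145 MFI/h
  exactly (a single affine map cannot satisfy all three).
- **Noise.** Replicate rates are true·(1 + N(0, cv·√n_reps)) so the CV of
  the replicate mean is ≈ the target (default 4.3%). Noise is
  multiplicative because fluorescence measurement error scales with
  signal.
- **Defects.** Assembly-correct (82%), cured (92%), growing (91%) and
  sequencing flags are Bernoulli per strain; duplicate genotypes are
  injected at 3.7% by reusing earlier genotypes. Defects alter metadata
  (and growth rendering), not the measured signal — they exist to exercise
  the QC filter.
- **Plates.** OD follows a seeded logistic from 0.025 with carrying
  capacity 0.30 and rate 0.35 h⁻¹ (≈13 of the 82 points at 15-min spacing
  fall in the OD window; the grid's last point is 20.25 h). GFP integrates
  the true rate gated by an OD-dependent shape that is exactly 1 on a
  slightly widened window and declines above it, so the endpoint estimator
  recovers the true rate exactly at zero noise (within 2 MFI/h with
  discretization). Non-growing strains are rendered with carrying capacity
  0.10, below the window top, so QC criterion 1 fails for exactly the
  flagged strains.

**What passing tests show — and don't.** The round-trip results (rate
recovery, MAE ≈ 10 MFI/h at n = 250, exploit recommendations beating 0.9×
the best training design in ≥9/10 seeded runs) are statements about data
*with this generator's structure*: additive-dominant genetics, i.i.d.
multiplicative noise, defects independent of genotype. Real libraries may
have stronger epistasis, position effects, plate-batch structure and
genotype-correlated failure modes (e.g. unbuildable designs), none of
which are modeled; real-data MAEs are therefore not comparable targets and
are not asserted anywhere in the suite.

## Problem sizes and runtime

Defaults were chosen so a full test run and the acceptance script each
complete in minutes on a single CPU: coverage Monte Carlo at the study's
10,000 × 10,000 scale (~15 s vectorized), ensemble fits at n = 250 with
the full 4×5000-draw posterior (~2 s each), ten-fold CV (~12 s), and the
ten-run end-to-end recovery loop (~30 s). Unit tests use reduced MCMC
settings (2 chains × 1200 draws) where only correctness of the machinery,
not posterior precision, is at stake.

## Known limitations

- Gene scoring ignores gene–reaction rule logic (isozymes and complexes
  are averaged alike), and the pFBA scan treats the tryptophan sink as the
  only alternative flux use.
- The coverage model ignores partial/chimeric assemblies.
- The robust outlier rule at n = 2 rests on an arbitrary (configurable)
  50% irreproducibility cutoff.
- Predictive σ combines weight-posterior disagreement and noise variance;
  base-learner parameter uncertainty is not propagated (learners are
  point estimates), so σ is optimistic for small training sets.
- The generator's promoter pick skew is qualitative (two anchored
  extremes), not an empirical distribution.
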