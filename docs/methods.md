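# Methods

## Problem setting

`abopt` implements an in-silico affinity-maturation loop for antibody
variable domains (scFv chains). The inputs are a weak-binding candidate
sequence, the set of CDR positions allowed to vary, and a mutagenesis assay
table: random k ∈ {1, 2, 3} CDR mutants of the candidate with replicate
log-scale binding measurements (lower = stronger binding) and
limit-of-detection censoring. The outputs are ranked design libraries and
forecasts of how well they will perform.

The loop has four stages:

1. **Surrogate models** map a sequence to a predictive distribution
   (μ, s) of its log-affinity.
2. **The fitness landscape** converts that distribution into the posterior
   probability of improvement, f(x) = p(aff(x) < σ | x) = Φ((σ − μ)/s),
   where σ is the candidate's own averaged assay value and Φ the standard
   Gaussian CDF.
3. **Samplers** optimize f over sequence space and record every evaluated
   sequence.
4. **Library evaluation** ranks the sampled pool, truncates to a library,
   and scores success probability, diversity, and biophysical properties.

## Surrogate models

**Ensemble.** One regressor per (encoder × loss × missing-value policy)
cell. Losses are MSE (ridge regression) and MAE (a linear model fitted
under the exact L1 objective by seeded stochastic gradient descent with a
fixed epoch budget). Missing-value policies are `drop_assay` (censored
replicates removed before averaging; fully-censored records excluded) and
`median_impute` (censored replicates replaced by the dataset-wide median of
non-missing assays). Three encoders ship by default — one-hot (L × 20),
hashed 3-mer composition (2048 buckets, deterministic multiplicative hash),
and a 12-descriptor per-residue physico-chemical profile — giving a
12-member ensemble; a fourth, learned encoder can be plugged in to recover
the 16-member layout. The ensemble prediction is the member mean, and its
uncertainty is the **population** (divide-by-n) standard deviation of
member outputs. This convention was fixed for reproducibility; an ensemble
of identical members therefore reports s = 0, which the fitness layer
handles with a step rule (1 if μ < σ, 0 if μ > σ, ½ at equality).

**Gaussian process.** Sequences are one-hot encoded per residue,
concatenated, PCA-reduced and fitted with a GP using a constant × RBF
kernel plus a white-noise term, hyperparameters optimized by marginal
likelihood. Two numerical choices matter here:

- *PCA dimension.* One-hot indicator features spread variance almost
  isotropically across every (position, residue) direction, so a small
  component count discards most of the signal: at 64 components the GP
  captured roughly a tenth of the mutation directions and its held-out rank
  correlation collapsed. The desk default is therefore 512 components
  (capped at the training-set size); at full scale with learned embeddings
  a dimension of ~1024 is the conventional choice.
- *Latent vs. observed variance.* The white-kernel term models assay
  noise. Since f(x) concerns the underlying binding value, the fitted
  noise variance is subtracted from the predictive variance before use, so
  s reflects uncertainty about the latent affinity, not replicate scatter.

GP training cost is cubic; `train_gp(max_train=...)` optionally subsamples
the training set (the benchmark uses 800).

## Fitness landscape

f(x) = Φ((σ − μ)/s) with σ taken from the candidate's averaged training
measurement (`threshold_from_candidate`); a different σ can be passed to
sweep the strong-binder definition. Predictions are memoized per sequence
(models are deterministic), so re-scoring visited sequences is free.
The landscape also exposes the Gaussian margin z = (σ − μ)/s. Because Φ
rounds to exactly 1.0 in double precision beyond z ≈ 8, rank-ordering
libraries by Φ would break ties arbitrarily among strongly-predicted
designs; `rank_select_top_n` therefore ranks by z when a landscape is
supplied — the same ordering mathematically, without saturation.

## Samplers

All samplers draw from a single seeded generator recorded in the trace, emit
only sequences valid in the design space, and record every evaluated
sequence with its fitness at visit time.

- **Hill climb**: per restart, start from a random mutant (expected k = 2)
  of a randomly chosen seed among the 10 strongest training binders; the
  neighborhood is all k = 1 mutants plus distinct random k = 2 mutants
  filling to `neighborhood_size` (default 1000); move to the best neighbor
  while it strictly improves. Default 100 restarts.
- **Genetic algorithm**: Wright–Fisher parent selection p(x) ∝ exp(f(x)/β)
  (β defaults: 0.2 ensemble, 0.5 GP), parents drawn with replacement,
  single-point crossover at a uniform cut in [1, L−1], then a random
  mutation with expected k = 1 (k = 0 disables mutation). A run terminates
  when a generation introduces no unseen sequence, or at `max_generations`.
  Population size defaults to 100 — unspecified in the original recipe, a
  typical value for this family of explorers. No elitism: designs are drawn
  from the full trace, so the best-ever sequence is never lost.
- **Gibbs sampling**: random-scan single-site updates with full
  conditionals p(x_i | x_−i) ∝ exp(γ·f(x)) over all alphabet letters
  (including the current one); default 30,000 iterations, every iterate
  recorded, no burn-in discard (selection pressure comes from downstream
  ranking). Multiple γ values pool their runs in one trace.
- **Baselines**: a random library of unique expected-k = 2 mutants of the
  seeds, and a PSSM fitted to training sequences *as good or better than*
  the candidate, with pseudocount 0.1 (conventional small value), sampled
  position-independently. Softmaxes are computed with max-subtraction;
  log-probability differences are exact to 1e−12.

Substitution counts for "expected k mutations" follow a Poisson(k)
truncated to [1, n_designable] (every mutant differs from its seed), with
positions chosen uniformly without replacement and substitute residues
uniform over the 19 alternatives. The truncation is a documented assumption;
the distribution behind "an expected number of k mutations" was not pinned
down by the original description.

## Library evaluation

- **Percent success** of a measured library: fraction of all library
  members that have at least `min_replicates` (default 3, of 6 slots)
  non-missing measurements *and* a replicate mean strictly below the
  threshold; unmeasured and under-replicated designs count as failures.
  For distribution summaries, unsuccessful designs can be assigned a fixed
  worst value (the published heavy/light conventions are 5.48/5.53).
- **Diversity**: d_avg (mean Hamming distance to the candidate) and d_pw
  (mean pairwise distance) — exact up to 2,000 sequences, otherwise a
  seeded uniform subsample of 200,000 pairs.
- **Fold improvement**: ratio of best (lowest) linear-scale affinities,
  baseline / library.
- **Embedding**: one-hot vectors under t-SNE with the L1 metric and PCA
  initialization. Note that the L1 distance between one-hot sequences is
  exactly **2 ×** the Hamming distance (each differing site contributes two
  mismatched indicator blocks); the factor is implemented as-is and noted
  here because it is sometimes loosely described as equal to the edit
  distance.

## Synthetic ground-truth landscape

The built-in oracle makes every downstream stage testable without any
external data: log-affinity = baseline + per-(position, residue) additive
effects + pairwise epistatic terms active only when both substitutions are
present. The default generator draws additive effects from N(0, 1), ten
epistatic pairs from N(0, 0.5), replicate noise sd 0.3 (triplicates), and
censors measurements above baseline + 2 by marking the individual replicate
missing. Mutational distances of generated training variants are uniform
over the requested k values.

What this emulates: a rugged-but-learnable local fitness landscape, assay
noise, and top-coded measurements. What it does not emulate: global
epistasis/nonlinear assay response, biased mutation spectra, barcode or
sequencing artifacts, and real CDR sequence statistics. Tests passing on
this landscape show the machinery is correct and that the qualitative
method ordering holds when the landscape is largely additive; they do not
certify performance on real binding data.

## Desk-scale benchmark

`run_benchmark` reproduces the study design in miniature on one CPU: a
45-residue VH-like template with three 10-position designable spans, 2,000
training mutants (k ∈ {1,2,3}, triplicates, censoring), σ from the
candidate's own record, top-500 libraries. Sampler budgets are scaled to
desk size (hill climb: 400-mutant neighborhoods × 20 restarts; GA:
population 50 × ≤30 generations × 10 restarts; Gibbs: γ = 18, 2,000
iterations for the ensemble; smaller budgets with γ = 10 for the costlier
GP). The PSSM comparator library is raw unique draws — in the original
head-to-head only the six model-guided libraries were rank-selected, while
the PSSM designs went to validation as sampled.

Observed behavior mirrors the full-scale findings: ensemble-guided hill
climb and GA libraries dominate the PSSM baseline on both ground-truth
percent success and diversity; Gibbs buys much higher diversity (d_avg
approaching the designable-span size) at some cost in success; the GP
extrapolates poorly far from the training manifold, so GP-guided Gibbs
forecasts drift from the truth while the ensemble's forecasts stay
calibrated (within ~0.1) for its own libraries. The in-silico success
forecast is compared against ground truth per library, and the forecast
ranking of the six sampler libraries is checked against the ground-truth
ranking by Spearman correlation, averaging over replicate seeds.

## Biophysical descriptors

Designed chains are concatenated with their fixed partner (heavy chain
first) before scoring. The isoelectric point solves net charge = 0 by
bisection on pH ∈ [0, 14] to interval convergence (< 1e−7 pH), using the
Henderson–Hasselbalch per-group model with a Bjellqvist-style pK table
(N-term 7.5, C-term 3.55, D 4.05, E 4.45, C 9.0, Y 10.0, H 5.98, K 10.0,
R 12.0), printed in full in the code so results are self-contained; the
exact pK set behind the published numbers is not stated, and the table is
swappable. Cysteines are treated as free (no disulfide correction).
Hydrophobicity is the Kyte–Doolittle grand average (GRAVY).

## Known limitations

- The ensemble's uncertainty is the spread of similarly-trained members; at
  extreme mutational distances all members share the same censoring-induced
  bias, so the forecast is mildly overconfident there (the En-Gibbs library
  runs ~0.05–0.09 optimistic at d_avg ≈ 28). This is the desk-scale
  expression of the model-predictability limit seen at full scale.
- The GP reverts to its prior away from the training manifold; its
  forecasts for highly diverse libraries are conservative rather than
  calibrated.
- Detection-limit censoring truncates the training distribution from above;
  neither missing-value policy is a censoring-aware estimator, so severely
  deleterious effects are systematically underestimated.
- The alphabet is restricted to the 20 canonical amino acids; smaller
  alphabets are supported for reduced/toy spaces, gaps and ambiguity codes
  are not.
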