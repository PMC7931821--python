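# Methods

## Data model

A table is `n_samples x n_taxa` relative abundances; taxa are identified by
rank-prefixed, pipe-separated lineage strings
(`k__...|p__...|...|s__...`, the MetaPhlAn dialect). Ranks must be strictly
increasing but may skip unnamed intermediates. Internal tree nodes are
identified by the *full rank prefix*, so homonymous names under different
parents stay distinct. Input files may contain fractions, percents or raw
counts; by default every row is closed to sum 1 and the detected dialect is
recorded. Samples are always rows internally regardless of file
orientation.

Trees come either from the lineage strings themselves (unit branch
lengths) or from a Newick file (scikit-bio parser; branch lengths kept).

## Generative model

The generator is a fully connected ReLU network from `noise_dim`-dimensional
standard-normal noise to a simplex-valued output head. Two heads are
available:

* **sparsemax** (default): the Euclidean projection of the logits onto the
  probability simplex. It reaches the simplex boundary, so a generated
  sample can contain *exact* zeros — the defining feature of microbiome
  profiles, where typically 60–90% of taxa are absent per sample. Its
  Jacobian (identity minus mean, restricted to the support) is exact almost
  everywhere.
* **softmax**: strictly positive outputs; zeros only arise through the
  truncation rule below. In our scaled-down experiments a softmax generator
  left small abundances spread continuously near 1e-3 and under-recovered
  sparsity by a factor of two even with 4x the iteration budget, which is
  why sparsemax is the default. A `softmax_gain` (inverse temperature)
  sharpens either head.

Generated abundances below `truncation_threshold = 1e-4` are set to zero
and rows are **not** renormalized afterwards; the table records its broken
closure. All sample-level statistics are computed on the truncated table.

## Phylogeny transformation (critic input)

Both real and generated compositions pass through the same transformation
before the critic:

1. **Expansion.** Every tree node from phylum down to species receives the
   sum of its descendant species abundances (kingdom and any synthetic root
   are excluded by default; configurable). The map is linear
   (`expanded = x @ E` with `E[i, j] = w_j · 1[leaf i under node j]`), node
   order is root-first and deterministic, and parent = Σ children holds
   exactly before amplification. Node weights default to 1; branch-length
   weighting is an opt-in multiplier (useful transformations do not require
   it).
2. **Amplification.** Elementwise `y = log((1 + 1000x)/(1 + x))`, natural
   log. `y(0) = 0`, the slope at 0 is 999, the map is strictly increasing
   and bounded by `log(1000)`; rare taxa are magnified onto the same scale
   as common ones, which is what lets the critic police sparsity patterns.
   The log base is a fixed convention (any base is a constant rescale the
   critic absorbs).

## Training

WGAN-GP: per iteration, 5 critic updates minimizing
`mean f(fake) − mean f(real) + 10 · GP`, then one generator update
minimizing `−mean f(fake)`. The gradient penalty is
`mean((‖∇_x̂ f(x̂)‖₂ − 1)²)` over per-sample interpolates
`x̂ = ε·real + (1−ε)·fake`, `ε ~ U(0,1)`, taken in the critic's
(transformed) input space. Optimizer is RMSprop (ρ = 0.9, eps = 1e-7) at
learning rate 5e-5 by default with batch size 32. The critic uses
leaky-ReLU (slope 0.2) hidden layers and no normalization layers; the
default widths are 256/512 (generator) and 512/256 (critic), fully
configurable.

Because the implementation is plain numpy, the penalty's parameter gradient
is derived by hand: with piecewise-linear activations the input gradient is
`W₁ D₁ W₂ D₂ … W_L` for fixed activation masks `D_l`, so differentiating in
`W_l` is ordinary matrix calculus (prefix/suffix products); bias gradients
of the penalty vanish almost everywhere. Unit tests verify the penalty and
its parameter gradient against central finite differences (agreement to
~1e-10 on random small critics).

All randomness — weight init, batch sampling, noise, interpolation ε —
flows from a single seed; two runs with the same config produce bitwise
identical loss traces. Non-finite losses abort with the iteration index.
Batches are sampled without replacement unless the dataset is smaller than
the batch (then an explicit flag enables replacement).

**Convergence.** Two statistics per iteration: the summed generator and
critic Wasserstein losses, and the mean squared per-parameter change
between consecutive iterations. Training is declared converged when the
difference of the latter's means over two consecutive windows (default
1,000 iterations) drops below 1e-8. Neither statistic stops training by
default — training longer is harmless for this objective — but after the
convergence flag fires the checkpoint with the smallest |combined
Wasserstein loss| is retained and used for sampling (`select_best`).

## NorTA baseline

1. Taxa that are zero in every sample are removed.
2. The target correlation is Pearson on the raw counts (taking the step's
   wording literally; Spearman is available via `estimator=`). Empirical
   matrices that are not PSD are repaired by clipping eigenvalues at 1e-10
   and rescaling to unit diagonal.
3. Multivariate normals with that correlation are drawn (Cholesky), pushed
   through the standard normal CDF to uniforms, and
4. inverted through per-taxon ziNB quantile functions
   (`q(u) = 0 for u ≤ π, else NB-quantile((u−π)/(1−π))`). The ziNB
   (π, size, μ) is fitted per taxon by maximum likelihood, Nelder-Mead on
   (logit π, log size, log μ) from a moment start, with a
   method-of-moments fallback (warned) on failure. Note the ziNB is not
   identifiable for degenerate taxa (e.g. a single nonzero count): zero
   inflation and a near-zero NB mean fit equally well; either optimum
   reproduces the marginal.
5. Counts are closed row-wise to compositions; all-zero rows are emitted
   as-is with a warning. When only relative abundances are available,
   pseudo-counts are formed with a configurable library size (default 1e6).

## Fidelity metrics

* **Sparsity**: per-sample fraction of entries below the truncation
  threshold (default 1e-4).
* **Shannon index**: −Σ pⱼ log pⱼ (natural log) after renormalizing each
  row over its nonzero entries; an all-zero row scores 0 with a warning.
* **Unweighted UniFrac**: presence = abundance > threshold (the truncation
  threshold, for consistency across real and simulated sides); every
  non-root node owns the edge above it; U = (branch length leading only to
  taxa present in exactly one sample) / (branch length leading to taxa
  present in either). Unit branch lengths on taxonomy-derived trees. A
  sample with no present taxa yields a flagged missing value. Agreement
  with a brute-force branch classification and with scikit-bio is tested.
* **nMDS**: SMACOF non-metric MDS (scikit-learn) minimizing Kruskal
  stress-1, seeded, initialized from a classical (Torgerson) embedding plus
  random restarts, lowest stress kept.
* **Taxa filtering**: drop taxa with > 90% zeros across real samples; the
  taxa–taxa analyses then use the top 10% of the remainder by mean
  abundance (ceil, ties broken by taxon id; the selection keeps original
  column order).
* **Spearman structure**: pairwise rank-correlation matrices computed as
  `corrcoef(rankdata)` (average ranks; a constant taxon contaminates only
  its own pairs, which are dropped and counted), compared over the strict
  upper triangle; R² is the squared Pearson correlation of the scatter and
  MSE the mean squared difference. The upper triangle (rather than the
  full off-diagonal) is a configuration choice.
* **clr**: per-sample log-ratio to the geometric mean after replacing zeros
  with half the smallest positive value in that sample
  (multiplicative-replacement flavor; the policy is recorded in the
  report). Samples left all-zero by a taxa-subset restriction are dropped
  from clr-based analyses.
* **Proportionality φ**: var(clrₘ − clrₖ)/var(clrₘ) across samples
  (sample variance, ddof 1); 0 iff exact proportionality; zero denominator
  flagged missing.
* **Rank-sum comparisons**: Wilcoxon rank-sum on Shannon vectors, and on
  pooled abundances within zero-fraction strata of the real data (< 10%
  zeros; 10–20% zeros) — one p-value per stratum per simulator.
* **Report**: every section for every named simulator, serialized to
  deterministic JSON (sorted keys; reruns with the same seed are
  bit-identical), plus standard matplotlib panels.

## Synthetic ground truth

The fixture generator draws a logistic-normal composition — latent
`N(m, Σ)` pushed through softmax — then masks each taxon independently with
probability `zero_inflation` and renormalizes (all-zero samples are redrawn,
capped at 100 attempts). The latent correlation `Σ` (block or AR(1)
builders provided) is the recoverable taxa–taxa structure; per-taxon means
with spread 1.0 give the uneven abundance profile of real cohorts. The
reference cohort used in tests and in `scripts/acceptance.py` is 300
samples × 30 species, two blocks with within-block correlation 0.6,
zero-inflation 0.6 — matching the 0.6–0.9 sparsity regime of real gut
profiles at a size a single CPU trains in about a minute.
`truth_statistics` re-simulates at 10× the sample count on an independent
substream to provide reference sparsity/Shannon/Spearman distributions.

What the generator does *not* emulate: taxon-specific overdispersion
families, sequencing-depth artifacts, phylogenetic signal in the
correlation structure (the taxonomy is assigned independently of Σ), or
case/control covariate shifts. Passing recovery tests therefore shows the
machinery learns sparse correlated compositions, not that it reproduces
any particular real cohort.

## Problem sizes and numerical choices

Scaled-down runs used throughout the tests and the acceptance script:
hidden widths ≤ 128, noise dim 64, 2,000–5,000 iterations, batch 32,
500–1,000 samples simulated. At these budgets RMSprop at 1e-3 is used
(the 5e-5 default is calibrated for ~100k-iteration runs and underfits in
5k); this is recorded as the package's scaled-run convention. Ordination
subsamples each dataset to 150 samples before the UniFrac matrix. The
sparsemax support rule uses the standard cumulative-threshold computation;
RMSprop epsilon is 1e-7; PSD repair clips at 1e-10; the ziNB optimizer
caps size at 1e8 to avoid the Poisson-limit plateau.

## Limitations

* Exact zeros from sparsemax plus truncation make sparsity learnable, but
  the generator's zero patterns are driven by the critic alone; extremely
  rare taxa (present in < a few samples) are effectively never generated.
* The convergence rule is a heuristic on parameter drift; it says training
  stabilized, not that the Wasserstein distance is small.
* NorTA preserves marginals exactly but distorts rank correlations through
  the discrete quantile map — which is precisely the weakness the GAN
  comparison is meant to expose.
* Training is CPU-bound numpy; tables with thousands of taxa train, but
  expect hours rather than minutes at the default widths.
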