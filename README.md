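# phylogan

Phylogeny-aware generative-adversarial simulation of microbiome
relative-abundance tables, with a Normal-to-Anything (NorTA) baseline and a
full fidelity-evaluation suite.

## Why

Benchmarking statistical methods for metagenome-wide association studies
requires simulated abundance tables that look like real gut metagenomic
profiles: extremely sparse (most taxa absent from most samples),
overdispersed, compositional (rows sum to 1), and carrying non-trivial
taxa–taxa correlation. Parametric simulators reproduce the per-taxon
marginals but miss the joint structure. `phylogan` instead *learns* the
joint distribution from a training table with a Wasserstein GAN and emits
new samples that preserve both first-order properties (sparsity, α- and
β-diversity) and second-order properties (rank correlation and
proportionality between taxa).

## The model

A generator `g_θ` maps Gaussian noise `z ~ N(0, I)` through fully connected
ReLU layers to a simplex-valued head, so each output row is a species-level
composition. A critic `f_ω` scores samples, and both networks are trained
with the WGAN-GP objective

```
L_critic = E[f_ω(T(g_θ(z)))] − E[f_ω(T(x))] + λ · E[(‖∇ f_ω(x̂)‖₂ − 1)²],   λ = 10
L_gen    = −E[f_ω(T(g_θ(z)))]
```

with RMSprop, five critic steps per generator step, and per-sample
interpolates `x̂`. The map `T` is the *phylogeny transformation*: the
species composition is expanded along the taxonomic tree (every internal
node from phylum to species receives the sum of its descendant species,
optionally weighted by branch length), then each abundance `x` is amplified
by `log[(1 + 1000x)/(1 + x)]`, which magnifies rare taxa (slope 999 at 0)
while preserving order. The critic therefore compares real and generated
samples at every taxonomic resolution at once.

Convergence is monitored by (i) the summed generator + critic Wasserstein
losses and (ii) the mean squared per-parameter change between iterations,
declared converged when the difference of the latter's means over two
consecutive 1,000-iteration windows falls below 1e-8.

The NorTA comparator draws correlated Gaussians with the taxa–taxa
correlation of the training counts, pushes them through the normal CDF, and
inverts per-taxon zero-inflated negative-binomial quantile functions fitted
by maximum likelihood, then closes each row to a composition.

The evaluation suite computes per-sample sparsity and Shannon entropy
(−Σ pⱼ log pⱼ), unweighted UniFrac between samples (unique / observed
branch length) with non-metric MDS ordination, pairwise Spearman
correlation, and Lovell's proportionality statistic
φ(m, k) = var(clr(x)ₘ − clr(x)ₖ) / var(clr(x)ₘ) on clr-transformed data,
assembling real-vs-simulated comparisons (with Wilcoxon rank-sum tests)
into a single machine-readable report.

## Worked example

Train on a synthetic 200-sample, 20-species cohort with two correlated taxon
blocks and 50% zero-inflation, then check how well the generator reproduces
the data:

```python
import numpy as np
from phylogan import (FixtureSpec, GanConfig, compare, shannon, sparsity,
                      simulate, train)
from phylogan.fixtures import block_correlation, make_fixture

spec = FixtureSpec(n_samples=200, n_species=20,
                   correlation=block_correlation(20, 2, 0.6),
                   zero_inflation=0.5, seed=0)
table, tree, truth = make_fixture(spec)

cfg = GanConfig(noise_dim=32, generator_layers=(64, 64), critic_layers=(64, 64),
                batch_size=32, learning_rate=1e-3, seed=0,
                convergence_window=500)
model = train(table, tree, cfg, iterations=2000)
sim = simulate(model, 500, seed=1)

real_t = table.truncate(1e-4)
print(f"real  sparsity median: {np.median(sparsity(real_t)):.3f}")
print(f"sim   sparsity median: {np.median(sparsity(sim)):.3f}")
print(f"real  Shannon median:  {np.median(shannon(real_t)):.3f}")
print(f"sim   Shannon median:  {np.median(shannon(sim)):.3f}")

report = compare(table, {"mbgan": sim}, tree, top_fraction=1.0, nmds_seed=0)
print(f"Spearman R^2:          {report.sections['spearman']['mbgan']['r2']:.3f}")
print(f"phi R^2:               {report.sections['phi']['mbgan']['r2']:.3f}")
```

prints (about a minute on one CPU core)

```
real  sparsity median: 0.500
sim   sparsity median: 0.550
real  Shannon median:  1.890
sim   Shannon median:  1.961
Spearman R^2:          0.410
phi R^2:               0.332
```

The simulated samples land within 0.05 of the real sparsity median and
within 0.08 of the real Shannon median after only 2,000 iterations, and the
pairwise Spearman structure of the generated cohort tracks the real one
(R² = 0.41 over 190 taxon pairs; an independence baseline gives ≈ 0).
Longer training (the defaults assume 100k iterations) tightens all of
these.

The same pipeline is available from the shell:

```
phylogan fixture --n-samples 300 --seed 0 --out fix/
phylogan train    --input fix/table.tsv --iters 5000 --seed 0 --out run/
phylogan simulate --model run/model.npz --n 1000 --seed 1 --out sim.tsv
phylogan norta    --input fix/table.tsv --n 1000 --seed 2 --out norta.tsv
phylogan evaluate --real fix/table.tsv --sim mbgan sim.tsv \
                  --sim norta norta.tsv --out eval/
```

`evaluate` writes `report.json` plus the standard panels (Shannon box
plots, UniFrac nMDS ordination, Spearman and φ scatter plots).

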