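"""Seeded synthetic microbiome fixtures with known ground truth.

Samples are drawn from a logistic-normal model: a latent multivariate
normal with a specified correlation structure is pushed through a softmax
to the simplex, then independent per-taxon zero-masking and renormalization
produce the high sparsity typical of gut metagenomic profiles.  The latent
correlation is the controllable taxa-taxa structure a simulator is asked
to recover; the masks and generating parameters are returned as truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datamodel import AbundanceTable, TaxonomyTree
from .io import lineage_to_tree
from . import metrics

RANK_CODES = ("k", "p", "c", "o", "f", "g")


def block_correlation(p: int, n_blocks: int, rho: float) -> np.ndarray:
    """Block-diagonal correlation: ``rho`` within blocks, 0 between."""
    R = np.eye(p)
    sizes = [p // n_blocks + (1 if i < p % n_blocks else 0)
             for i in range(n_blocks)]
    start = 0
    for s in sizes:
        R[start:start + s, start:start + s] = rho
        start += s
    np.fill_diagonal(R, 1.0)
    return R


def ar1_correlation(p: int, rho: float) -> np.ndarray:
    idx = np.arange(p)
    return rho ** np.abs(idx[:, None] - idx[None, :])


@dataclass
class FixtureSpec:
    """Generating parameters of a synthetic dataset.

    ``correlation`` is the latent correlation matrix (identity if None);
    ``latent_sd`` scales the latent normals; ``mean_spread`` is the s.d. of
    per-taxon latent means, giving the uneven taxon abundances seen in real
    profiles; ``zero_inflation`` is the per-taxon masking probability
    (scalar or vector); ``branching`` controls how many sibling taxa merge
    at each rank going up the taxonomy.
    """

    n_samples: int = 300
    n_species: int = 30
    correlation: np.ndarray | None = None
    latent_sd: float = 1.0
    mean_spread: float = 1.0
    zero_inflation: float | np.ndarray = 0.6
    branching: int = 2
    seed: int = 0

    def zero_inflation_vector(self) -> np.ndarray:
        z = np.broadcast_to(np.asarray(self.zero_inflation, float),
                            (self.n_species,)).copy()
        if np.any((z < 0) | (z > 1)):
            raise ValueError("zero_inflation must lie in [0, 1]")
        return z

    def correlation_matrix(self) -> np.ndarray:
        if self.correlation is None:
            return np.eye(self.n_species)
        R = np.asarray(self.correlation, dtype=float)
        if R.shape != (self.n_species, self.n_species):
            raise ValueError("correlation shape mismatch")
        if not np.allclose(R, R.T):
            raise ValueError("correlation must be symmetric")
        vals = np.linalg.eigvalsh(R)
        if vals.min() < -1e-8:
            raise ValueError("correlation must be positive semi-definite")
        return R


def make_taxonomy(n_species: int, branching: int = 2) -> tuple[list[str], TaxonomyTree]:
    """Deterministic nested lineage strings for ``n_species`` species."""
    lineages = []
    for i in range(n_species):
        parts = ["k__K0"]
        # walk down from phylum to genus, grouping ~branching children per parent
        for depth, code in enumerate(RANK_CODES[1:], start=1):
            group = i // (branching ** (len(RANK_CODES) - depth))
            parts.append(f"{code}__{code.upper()}{group}")
        parts.append(f"s__sp{i:03d}")
        lineages.append("|".join(parts))
    return lineages, lineage_to_tree(lineages)


def make_fixture(spec: FixtureSpec) -> tuple[AbundanceTable, TaxonomyTree, dict]:
    """Draw a fixture table plus its taxonomy and generating truth.

    A sample left all-zero by masking is redrawn (up to 100 attempts per
    sample) so every row is a valid composition.
    """
    rng = np.random.default_rng(spec.seed)
    p = spec.n_species
    R = spec.correlation_matrix()
    zi = spec.zero_inflation_vector()
    means = (rng.standard_normal(p) * spec.mean_spread
             if spec.mean_spread > 0 else np.zeros(p))
    L = np.linalg.cholesky(R + 1e-10 * np.eye(p))

    def draw(n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        latent = means + spec.latent_sd * (rng.standard_normal((n, p)) @ L.T)
        latent -= latent.max(axis=1, keepdims=True)
        e = np.exp(latent)
        comp = e / e.sum(axis=1, keepdims=True)
        masks = rng.uniform(size=(n, p)) >= zi
        return comp, masks, latent

    comp, masks, _ = draw(spec.n_samples)
    for i in range(spec.n_samples):
        tries = 0
        while not masks[i].any():
            c, m, _ = draw(1)
            comp[i], masks[i] = c[0], m[0]
            tries += 1
            if tries >= 100:
                raise ValueError("could not draw a non-empty sample in 100 tries")
    masked = comp * masks
    masked /= masked.sum(axis=1, keepdims=True)

    lineages, tree = make_taxonomy(p, spec.branching)
    table = AbundanceTable(
        sample_ids=[f"fix{i}" for i in range(spec.n_samples)],
        taxon_ids=lineages,
        values=masked,
    )
    truth = {
        "correlation": R,
        "means": means,
        "zero_inflation": zi,
        "latent_sd": spec.latent_sd,
        "pre_mask": comp,
        "masks": masks,
        "spec": spec,
    }
    return table, tree, truth


def truth_statistics(
    spec: FixtureSpec,
    truth: dict,
    factor: int = 10,
    threshold: float = metrics.TRUNCATION_THRESHOLD,
) -> dict:
    """Large-n reference statistics from the same generating process.

    Re-simulates ``factor`` times the fixture's sample count (holding the
    truth's per-taxon means fixed, on an independent substream of the
    fixture seed) and reports the sparsity/Shannon distributions and the
    pairwise Spearman matrix a perfect simulator should approach.
    """
    rng = np.random.default_rng([spec.seed, 1])
    p = spec.n_species
    n = spec.n_samples * factor
    R = truth["correlation"]
    L = np.linalg.cholesky(R + 1e-10 * np.eye(p))
    latent = truth["means"] + truth["latent_sd"] * (
        rng.standard_normal((n, p)) @ L.T)
    latent -= latent.max(axis=1, keepdims=True)
    e = np.exp(latent)
    comp = e / e.sum(axis=1, keepdims=True)
    masks = rng.uniform(size=(n, p)) >= truth["zero_inflation"]
    keep = masks.any(axis=1)
    masked = (comp * masks)[keep]
    masked /= masked.sum(axis=1, keepdims=True)

    lineages, _ = make_taxonomy(p, spec.branching)
    table = AbundanceTable(
        sample_ids=[f"ref{i}" for i in range(masked.shape[0])],
        taxon_ids=lineages, values=masked,
    ).truncate(threshold)
    rho = metrics.spearman_matrix(table.values)
    return {
        "table": table,
        "sparsity": metrics.sparsity(table, threshold),
        "shannon": metrics.shannon(table),
        "spearman": rho,
    }
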