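"""Normal-to-Anything (NorTA) baseline with zero-inflated NB marginals.

The copula-style recipe: (i) drop taxa that are zero in every sample,
(ii) draw multivariate normals with the taxa-taxa correlation estimated
from the real counts, (iii) push each coordinate through the standard
normal CDF to get uniforms, (iv) invert the per-taxon fitted ziNB quantile
function to get counts, (v) close each row to a composition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .datamodel import AbundanceTable


@dataclass
class ZiNBParams:
    """Per-taxon zero-inflation probability, NB dispersion (size), and mean."""

    pi: np.ndarray
    size: np.ndarray
    mu: np.ndarray

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        self.size = np.asarray(self.size, dtype=float)
        self.mu = np.asarray(self.mu, dtype=float)
        if not (len(self.pi) == len(self.size) == len(self.mu)):
            raise ValueError("parameter vectors must have equal length")
        if np.any((self.pi < 0) | (self.pi > 1)):
            raise ValueError("pi must lie in [0, 1]")
        if np.any(self.size <= 0) or np.any(self.mu < 0):
            raise ValueError("size must be positive and mu nonnegative")

    def __len__(self) -> int:
        return len(self.pi)


@dataclass
class NortaSpec:
    """Everything needed to simulate: target correlation + marginals."""

    correlation: np.ndarray
    zinb: ZiNBParams
    taxon_ids: list[str]
    n_samples: int
    estimator: str = "pearson"

    def __post_init__(self) -> None:
        R = np.asarray(self.correlation, dtype=float)
        if R.shape != (len(self.zinb), len(self.zinb)):
            raise ValueError("correlation shape inconsistent with marginals")
        if not np.allclose(R, R.T, atol=1e-8):
            raise ValueError("correlation matrix must be symmetric")
        self.correlation = R


def _nb_p(size: float, mu: float) -> float:
    return size / (size + mu)


def zinb_logpmf(x: np.ndarray, pi: float, size: float, mu: float) -> np.ndarray:
    nb = stats.nbinom.pmf(x, size, _nb_p(size, mu))
    return np.log(np.where(x == 0, pi + (1.0 - pi) * nb, (1.0 - pi) * nb) + 1e-300)


def zinb_cdf(x: np.ndarray, pi: float, size: float, mu: float) -> np.ndarray:
    return pi + (1.0 - pi) * stats.nbinom.cdf(x, size, _nb_p(size, mu))


def zinb_quantile(u: np.ndarray, pi: float, size: float, mu: float) -> np.ndarray:
    """Mixture inversion: u <= pi maps to 0, the rest to the NB quantile."""
    u = np.asarray(u, dtype=float)
    out = np.zeros(u.shape)
    tail = u > pi
    if np.any(tail):
        out[tail] = stats.nbinom.ppf((u[tail] - pi) / (1.0 - pi), size,
                                     _nb_p(size, mu))
    return out


def _fit_zinb_one(x: np.ndarray) -> tuple[float, float, float]:
    """Maximum-likelihood ziNB fit for one taxon's counts.

    Optimizes over (logit pi, log size, log mu) with Nelder-Mead from a
    moment-based start; falls back to method of moments (with a warning)
    if the optimizer fails.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    f0 = np.mean(x == 0)
    mean, var = x.mean(), x.var(ddof=1) if n > 1 else x.var()

    pi0 = min(max(f0 * 0.5, 1e-3), 1 - 1e-3)
    mu0 = max(mean / (1.0 - pi0), 1e-3)
    excess = max(var - mu0, 1e-6)
    r0 = float(np.clip(mu0 ** 2 / excess, 1e-2, 1e3))

    def nll(params: np.ndarray) -> float:
        lp, ls, lm = params
        pi = 1.0 / (1.0 + np.exp(-lp))
        size, mu = np.exp(ls), np.exp(lm)
        if not np.isfinite(size) or not np.isfinite(mu) or size > 1e8:
            return 1e12
        return -float(np.sum(zinb_logpmf(x, pi, size, mu)))

    x0 = np.array([np.log(pi0 / (1 - pi0)), np.log(r0), np.log(mu0)])
    res = optimize.minimize(nll, x0, method="Nelder-Mead",
                            options={"maxiter": 2000, "xatol": 1e-6,
                                     "fatol": 1e-8})
    if res.success and np.isfinite(res.fun):
        lp, ls, lm = res.x
        return (1.0 / (1.0 + np.exp(-lp)), float(np.exp(ls)), float(np.exp(lm)))
    warnings.warn("ziNB fit did not converge; using method of moments")
    return (pi0, r0, mu0)


def fit_norta(
    counts,
    taxon_ids: list[str] | None = None,
    n_samples: int | None = None,
    estimator: str = "pearson",
) -> NortaSpec:
    """Estimate a NorTA specification from a samples x taxa count matrix.

    Taxa with zeros across all samples are removed before anything else.
    The target correlation defaults to Pearson on the raw counts;
    ``estimator="spearman"`` is available as an alternative.
    """
    C = np.asarray(counts, dtype=float)
    if C.ndim != 2:
        raise ValueError("counts must be a 2-D samples x taxa matrix")
    if np.any(C < 0) or not np.allclose(C, np.round(C)):
        raise ValueError("counts must be nonnegative integers")
    n, p = C.shape
    if taxon_ids is None:
        taxon_ids = [f"taxon{j}" for j in range(p)]

    keep = np.nonzero(C.sum(axis=0) > 0)[0]
    if keep.size < 2:
        raise ValueError(f"only {keep.size} taxa with nonzero counts; need >= 2")
    C = C[:, keep]
    kept_ids = [taxon_ids[j] for j in keep]

    if estimator == "pearson":
        R = np.corrcoef(C, rowvar=False)
    elif estimator == "spearman":
        from .metrics import spearman_matrix
        R = spearman_matrix(C)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    R = np.nan_to_num(R, nan=0.0)
    np.fill_diagonal(R, 1.0)

    fits = [_fit_zinb_one(C[:, j]) for j in range(C.shape[1])]
    pi, size, mu = map(np.array, zip(*fits))
    return NortaSpec(
        correlation=R,
        zinb=ZiNBParams(pi=pi, size=size, mu=mu),
        taxon_ids=kept_ids,
        n_samples=n if n_samples is None else n_samples,
        estimator=estimator,
    )


def repair_psd(R: np.ndarray, min_eig: float = 1e-10) -> np.ndarray:
    """Clip negative eigenvalues and rescale back to unit diagonal."""
    vals, vecs = np.linalg.eigh(R)
    if vals.min() >= min_eig:
        return R
    vals = np.clip(vals, min_eig, None)
    fixed = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return fixed


def norta_simulate(
    spec: NortaSpec,
    seed: int,
    n_samples: int | None = None,
) -> tuple[np.ndarray, AbundanceTable]:
    """Run NorTA steps (ii)-(v): MVN -> normal CDF -> ziNB quantile -> closure.

    Returns the simulated count matrix and the compositional table.  Rows
    whose total count is zero are emitted all-zero with a warning.
    """
    n = spec.n_samples if n_samples is None else n_samples
    if n <= 0:
        raise ValueError("n_samples must be positive")
    p = len(spec.zinb)
    rng = np.random.default_rng(seed)

    R = repair_psd(spec.correlation)
    try:
        L = np.linalg.cholesky(R + 1e-12 * np.eye(p))
    except np.linalg.LinAlgError as exc:
        raise ValueError("correlation matrix not PSD after repair") from exc
    Z = rng.standard_normal((n, p)) @ L.T
    U = stats.norm.cdf(Z)

    counts = np.empty((n, p))
    for j in range(p):
        counts[:, j] = zinb_quantile(U[:, j], spec.zinb.pi[j],
                                     spec.zinb.size[j], spec.zinb.mu[j])

    totals = counts.sum(axis=1)
    if np.any(totals == 0):
        warnings.warn(f"{int((totals == 0).sum())} all-zero rows in NorTA output")
    with np.errstate(invalid="ignore", divide="ignore"):
        comp = np.where(totals[:, None] > 0, counts / totals[:, None], 0.0)
    table = AbundanceTable(
        sample_ids=[f"norta{i}" for i in range(n)],
        taxon_ids=list(spec.taxon_ids),
        values=comp,
        normalized=False,
    )
    return counts, table


def counts_from_relative(table: AbundanceTable, library_size: int = 1_000_000) -> np.ndarray:
    """Scale relative abundances to pseudo-counts when only fractions exist."""
    return np.round(table.values * library_size)
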