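"""Fidelity statistics comparing real and simulated abundance tables.

Covers sample-level summaries (sparsity, Shannon alpha-diversity,
unweighted UniFrac beta-diversity with nMDS ordination) and taxa-taxa
structure (pairwise Spearman correlation and Lovell's proportionality
statistic phi on clr-transformed data), assembled into a
:class:`FidelityReport` with Wilcoxon rank-sum comparisons.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats
from sklearn.manifold import MDS

from .datamodel import AbundanceTable, TaxonomyTree

TRUNCATION_THRESHOLD = 1e-4


# ---------------------------------------------------------------------------
# sample-level statistics


def sparsity(table: AbundanceTable, threshold: float = TRUNCATION_THRESHOLD) -> np.ndarray:
    """Per-sample proportion of zero entries after thresholding."""
    return np.mean(table.values < threshold, axis=1)


def shannon(table: AbundanceTable) -> np.ndarray:
    """Per-sample Shannon index -sum p_j log p_j (natural log).

    Rows are renormalized over their nonzero entries first; an all-zero
    row gets index 0 with a warning.
    """
    vals = table.values
    totals = vals.sum(axis=1)
    if np.any(totals == 0):
        warnings.warn("all-zero sample: Shannon index set to 0")
    out = np.zeros(vals.shape[0])
    for i in range(vals.shape[0]):
        if totals[i] == 0:
            continue
        p = vals[i] / totals[i]
        p = p[p > 0]
        out[i] = float(-(p * np.log(p)).sum())
    return out


# ---------------------------------------------------------------------------
# UniFrac


def _presence_nodes(
    presence_leaves: np.ndarray,
    taxon_ids: list[str],
    tree: TaxonomyTree,
) -> tuple[np.ndarray, np.ndarray]:
    """Map per-sample leaf presence to per-branch presence.

    Branches are all non-root nodes (each node owns the edge above it).
    Returns (branch presence matrix n x B, branch lengths B).
    """
    branches = [n for n in tree.preorder() if n != tree.root]
    leaf_col = {t: j for j, t in enumerate(taxon_ids)}
    inc = np.zeros((len(taxon_ids), len(branches)))
    for bi, node in enumerate(branches):
        for leaf in tree.descendant_leaves(node):
            j = leaf_col.get(leaf)
            if j is not None:
                inc[j, bi] = 1.0
    pres = (presence_leaves.astype(float) @ inc) > 0
    lengths = np.array([tree.branch_length(b) for b in branches])
    return pres, lengths


def unweighted_unifrac(
    abund_a: np.ndarray,
    abund_b: np.ndarray,
    taxon_ids: list[str],
    tree: TaxonomyTree,
    threshold: float = TRUNCATION_THRESHOLD,
) -> float:
    """U = (branch length unique to one sample) / (branch length in either).

    Presence means abundance > threshold.  Branch lengths default to 1 on
    taxonomy-derived trees.  Returns nan if a sample has no present taxa.
    """
    pres_leaves = np.vstack([np.asarray(abund_a) > threshold,
                             np.asarray(abund_b) > threshold])
    pres, lengths = _presence_nodes(pres_leaves, taxon_ids, tree)
    if not pres[0].any() or not pres[1].any():
        return float("nan")
    either = pres[0] | pres[1]
    both = pres[0] & pres[1]
    observed = float(lengths[either].sum())
    unique = float(lengths[either & ~both].sum())
    return unique / observed if observed > 0 else float("nan")


def unifrac_matrix(
    values: np.ndarray,
    taxon_ids: list[str],
    tree: TaxonomyTree,
    threshold: float = TRUNCATION_THRESHOLD,
) -> np.ndarray:
    """All-pairs unweighted UniFrac, vectorized over branch incidences."""
    pres, w = _presence_nodes(np.asarray(values) > threshold, taxon_ids, tree)
    P = pres.astype(float)
    both = (P * w) @ P.T                 # shared branch length
    tot = P @ w                          # per-sample branch length
    either = tot[:, None] + tot[None, :] - both
    with np.errstate(invalid="ignore", divide="ignore"):
        D = (either - both) / either
    empty = tot == 0
    D[empty, :] = np.nan
    D[:, empty] = np.nan
    np.fill_diagonal(D, np.where(empty, np.nan, 0.0))
    return D


# ---------------------------------------------------------------------------
# ordination


def _classical_mds(D: np.ndarray, dims: int) -> np.ndarray:
    """Torgerson double-centering embedding used to seed the nMDS search."""
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1][:dims]
    vals = np.clip(vals[order], 0, None)
    return vecs[:, order] * np.sqrt(vals)


def nmds(
    distance_matrix: np.ndarray,
    dims: int = 2,
    seed: int = 0,
    n_restarts: int = 3,
) -> tuple[np.ndarray, float]:
    """Non-metric MDS minimizing Kruskal stress-1.

    Runs SMACOF from a classical-MDS start plus seeded random restarts and
    keeps the lowest-stress solution.
    """
    D = np.asarray(distance_matrix, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    if np.any(D < 0) or not np.allclose(np.diag(D), 0.0, atol=1e-8):
        raise ValueError("distances must be nonnegative with zero diagonal")

    best_coords, best_stress = None, np.inf
    rng = np.random.default_rng(seed)
    inits = [_classical_mds(D, dims)] + [
        rng.standard_normal((D.shape[0], dims)) for _ in range(n_restarts)]
    for trial, init in enumerate(inits):
        mds = MDS(
            n_components=dims, metric="precomputed", metric_mds=False,
            random_state=seed + trial, n_init=1, init="random",
            normalized_stress=True, max_iter=500, eps=1e-9,
        )
        coords = mds.fit_transform(D, init=init)
        if mds.stress_ < best_stress:
            best_stress, best_coords = float(mds.stress_), coords
    return best_coords, best_stress


# ---------------------------------------------------------------------------
# taxa filtering


def filter_taxa(table: AbundanceTable, max_zero_fraction: float = 0.9) -> AbundanceTable:
    """Drop taxa whose zero fraction across samples exceeds the threshold."""
    if not 0 < max_zero_fraction <= 1:
        raise ValueError("max_zero_fraction must be in (0, 1]")
    zero_frac = np.mean(table.values == 0, axis=0)
    keep = [t for t, z in zip(table.taxon_ids, zero_frac) if z <= max_zero_fraction]
    if not keep:
        raise ValueError(
            f"no taxa retained: all {table.n_taxa} exceed zero fraction "
            f"{max_zero_fraction}"
        )
    return table.subset_taxa(keep)


def top_abundant(table: AbundanceTable, fraction: float = 0.1) -> AbundanceTable:
    """Keep the most abundant taxa by mean relative abundance.

    ``ceil(fraction * n_taxa)`` taxa are retained; ties break
    deterministically by taxon id.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    k = math.ceil(fraction * table.n_taxa)
    means = table.values.mean(axis=0)
    order = sorted(range(table.n_taxa),
                   key=lambda j: (-means[j], table.taxon_ids[j]))
    chosen = {table.taxon_ids[j] for j in order[:k]}
    keep = [t for t in table.taxon_ids if t in chosen]  # original column order
    if not keep:
        raise ValueError("no taxa retained")
    return table.subset_taxa(keep)


# ---------------------------------------------------------------------------
# taxa-taxa structure


def _upper_pairs(M: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(M.shape[0], k=1)
    return M[iu]


def spearman_matrix(values: np.ndarray) -> np.ndarray:
    """Pairwise Spearman correlations (average ranks for ties).

    A constant column yields nan in its own row/column only, unlike
    scipy.stats.spearmanr which degenerates to a scalar nan.
    """
    ranks = stats.rankdata(values, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.corrcoef(ranks, rowvar=False)


def spearman_structure(
    real: AbundanceTable,
    sim: AbundanceTable,
    taxa: list[str] | None = None,
) -> dict:
    """Compare pairwise Spearman matrices between a real and simulated table.

    Returns the strict-upper-triangle scatter pairs, the squared Pearson
    correlation (R^2) between them, and the MSE of their differences.
    Pairs involving a constant (zero-variance) taxon are excluded and
    counted.
    """
    if taxa is None:
        taxa = list(real.taxon_ids)
    ra = spearman_matrix(real.subset_taxa(taxa).values)
    rb = spearman_matrix(sim.subset_taxa(taxa).values)
    pa, pb = _upper_pairs(ra), _upper_pairs(rb)
    ok = np.isfinite(pa) & np.isfinite(pb)
    n_dropped = int((~ok).sum())
    pa, pb = pa[ok], pb[ok]
    if pa.size < 2:
        raise ValueError("fewer than 2 usable taxon pairs")
    if np.std(pa) == 0 or np.std(pb) == 0:
        r2 = 1.0 if np.allclose(pa, pb) else 0.0
    else:
        r2 = float(np.corrcoef(pa, pb)[0, 1] ** 2)
    mse = float(np.mean((pa - pb) ** 2))
    return {"real_pairs": pa, "sim_pairs": pb, "r2": r2, "mse": mse,
            "n_dropped_pairs": n_dropped}


def clr(values: np.ndarray) -> np.ndarray:
    """Centered log-ratio transform, per sample (row).

    clr(x)_m = log(x_m / g(x)) with g the geometric mean.  Zeros are first
    replaced by half the smallest positive value in the same sample
    (multiplicative-replacement flavor); components of each output row sum
    to 0.
    """
    x = np.atleast_2d(np.asarray(values, dtype=float)).copy()
    for i in range(x.shape[0]):
        row = x[i]
        if np.any(row < 0):
            raise ValueError("negative abundance in clr input")
        pos = row[row > 0]
        if pos.size == 0:
            raise ValueError(f"all-zero sample at row {i}; clr undefined")
        row[row == 0] = pos.min() / 2.0
    logs = np.log(x)
    out = logs - logs.mean(axis=1, keepdims=True)
    return out if np.asarray(values).ndim == 2 else out[0]


def proportionality_phi(x_m: np.ndarray, x_k: np.ndarray) -> float:
    """Lovell's goodness-of-fit to proportionality.

    phi = var(x_m - x_k) / var(x_m) on clr-scale vectors across samples:
    0 iff the two taxa are exactly proportional.  Returns nan when the
    denominator variance is zero.
    """
    x_m = np.asarray(x_m, dtype=float)
    x_k = np.asarray(x_k, dtype=float)
    if x_m.size < 3:
        raise ValueError("need at least 3 samples")
    denom = np.var(x_m, ddof=1)
    if denom == 0:
        return float("nan")
    return float(np.var(x_m - x_k, ddof=1) / denom)


def phi_matrix(clr_values: np.ndarray) -> np.ndarray:
    """phi for every ordered taxon pair of a clr-transformed matrix."""
    V = np.asarray(clr_values, dtype=float)
    p = V.shape[1]
    var = np.var(V, axis=0, ddof=1)
    out = np.empty((p, p))
    for m in range(p):
        diff_var = np.var(V[:, m][:, None] - V, axis=0, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[m] = diff_var / var[m] if var[m] > 0 else np.nan
    return out


def _clr_nonempty(values: np.ndarray) -> np.ndarray:
    """clr of the rows having at least one positive entry.

    Restricting a table to an analysis subset of taxa can leave some
    samples all-zero; those carry no compositional information on the
    subset and are dropped before the transform.
    """
    keep = np.asarray(values).sum(axis=1) > 0
    return clr(np.asarray(values)[keep])


def phi_structure(
    real: AbundanceTable,
    sim: AbundanceTable,
    taxa: list[str] | None = None,
) -> dict:
    """Real-vs-simulated scatter of phi over the strict upper triangle."""
    if taxa is None:
        taxa = list(real.taxon_ids)
    pa = _upper_pairs(phi_matrix(_clr_nonempty(real.subset_taxa(taxa).values)))
    pb = _upper_pairs(phi_matrix(_clr_nonempty(sim.subset_taxa(taxa).values)))
    ok = np.isfinite(pa) & np.isfinite(pb)
    pa, pb = pa[ok], pb[ok]
    if pa.size < 2:
        raise ValueError("fewer than 2 usable taxon pairs")
    if np.std(pa) == 0 or np.std(pb) == 0:
        r2 = 1.0 if np.allclose(pa, pb) else 0.0
    else:
        r2 = float(np.corrcoef(pa, pb)[0, 1] ** 2)
    return {"real_pairs": pa, "sim_pairs": pb, "r2": r2,
            "mse": float(np.mean((pa - pb) ** 2))}


# ---------------------------------------------------------------------------
# report assembly


@dataclass
class FidelityReport:
    """Paired real-vs-simulated summaries for one or more simulators."""

    sections: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        def conv(obj):
            if isinstance(obj, dict):
                return {k: conv(v) for k, v in sorted(obj.items())}
            if isinstance(obj, (list, tuple)):
                return [conv(v) for v in obj]
            if isinstance(obj, np.ndarray):
                return conv(obj.tolist())
            if isinstance(obj, (np.floating, float)):
                f = float(obj)
                return None if math.isnan(f) else f
            if isinstance(obj, (np.integer,)):
                return int(obj)
            return obj
        return conv({"sections": self.sections, "metadata": self.metadata})

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), sort_keys=True, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text


def _summary(v: np.ndarray) -> dict:
    v = v[np.isfinite(v)]
    return {"min": float(v.min()), "median": float(np.median(v)),
            "max": float(v.max())}


def compare(
    real: AbundanceTable,
    sims: dict[str, AbundanceTable],
    tree: TaxonomyTree | None = None,
    threshold: float = TRUNCATION_THRESHOLD,
    top_fraction: float = 0.1,
    max_zero_fraction: float = 0.9,
    nmds_seed: int = 0,
    max_ordination_samples: int = 150,
) -> FidelityReport:
    """Assemble the full fidelity report for every named simulator.

    Taxa-taxa sections are computed on the top ``top_fraction`` most
    abundant species among taxa with zero fraction <= ``max_zero_fraction``
    in the real data.  UniFrac/nMDS is skipped with a notice when no tree
    is given; ordination subsamples each dataset deterministically to at
    most ``max_ordination_samples``.
    """
    report = FidelityReport()
    report.metadata = {
        "threshold": threshold,
        "top_fraction": top_fraction,
        "max_zero_fraction": max_zero_fraction,
        "simulators": sorted(sims),
        "n_real_samples": real.n_samples,
        "clr_zero_policy": "half minimum positive per sample",
        "branch_lengths": "from tree" if (tree is not None and
                                          tree.branch_lengths) else "unit",
    }

    real_t = real.truncate(threshold)
    sp_real = sparsity(real_t, threshold)
    sh_real = shannon(real_t)
    report.sections["sparsity"] = {
        "real": {"values": sp_real, **_summary(sp_real)}}
    report.sections["shannon"] = {
        "real": {"values": sh_real}}

    zero_frac = np.mean(real.values == 0, axis=0)
    strata = {
        "lt10pct_zeros": np.array(real.taxon_ids)[zero_frac < 0.10],
        "10to20pct_zeros": np.array(real.taxon_ids)[(zero_frac >= 0.10)
                                                    & (zero_frac <= 0.20)],
    }
    report.sections["stratified_abundance"] = {}

    subset_ids = top_abundant(filter_taxa(real, max_zero_fraction),
                              top_fraction).taxon_ids
    report.sections["taxa_subset"] = {"taxa": list(subset_ids)}
    report.sections["spearman"] = {}
    report.sections["phi"] = {}

    for name, sim in sims.items():
        sim_t = sim.truncate(threshold)
        sp = sparsity(sim_t, threshold)
        report.sections["sparsity"][name] = {"values": sp, **_summary(sp)}
        sh = shannon(sim_t)
        p_sh = float(stats.ranksums(sh_real, sh).pvalue)
        report.sections["shannon"][name] = {"values": sh, "ranksum_p": p_sh}

        report.sections["stratified_abundance"][name] = {}
        for stratum, taxa in strata.items():
            if taxa.size == 0:
                report.sections["stratified_abundance"][name][stratum] = None
                continue
            shared = [t for t in taxa if t in sim.taxon_ids]
            if not shared:
                report.sections["stratified_abundance"][name][stratum] = None
                continue
            a = real.subset_taxa(shared).values.ravel()
            b = sim.subset_taxa(shared).values.ravel()
            report.sections["stratified_abundance"][name][stratum] = float(
                stats.ranksums(a, b).pvalue)

        shared_subset = [t for t in subset_ids if t in sim.taxon_ids]
        if len(shared_subset) >= 3:
            ss = spearman_structure(real, sim, shared_subset)
            report.sections["spearman"][name] = {
                "r2": ss["r2"], "mse": ss["mse"],
                "n_dropped_pairs": ss["n_dropped_pairs"],
                "real_pairs": ss["real_pairs"], "sim_pairs": ss["sim_pairs"],
            }
            ph = phi_structure(real, sim, shared_subset)
            report.sections["phi"][name] = {
                "r2": ph["r2"], "mse": ph["mse"],
                "real_pairs": ph["real_pairs"], "sim_pairs": ph["sim_pairs"],
            }

    if tree is None:
        report.sections["unifrac"] = {"skipped": "no tree provided"}
    else:
        blocks, labels = [], []
        for name, tab in [("real", real_t)] + [(n, s.truncate(threshold))
                                               for n, s in sorted(sims.items())]:
            take = min(tab.n_samples, max_ordination_samples)
            blocks.append(tab.values[:take])
            labels.extend([name] * take)
        leaf_sets = [set(real.taxon_ids)] + [set(s.taxon_ids) for s in sims.values()]
        common = sorted(set.intersection(*leaf_sets))
        mats = []
        for (name, _), blk in zip([("real", real_t)] + sorted(sims.items()), blocks):
            tab = real_t if name == "real" else sims[name]
            cols = [tab.taxon_ids.index(t) for t in common]
            mats.append(blk[:, cols])
        values = np.vstack(mats)
        D = unifrac_matrix(values, common, tree, threshold)
        usable = ~np.isnan(D).all(axis=1)
        D2 = np.nan_to_num(D[np.ix_(usable, usable)], nan=1.0)
        coords, stress = nmds(D2, dims=2, seed=nmds_seed)
        report.sections["unifrac"] = {
            "labels": [l for l, u in zip(labels, usable) if u],
            "coordinates": coords,
            "stress": stress,
            "mean_within_real": float(np.nanmean(
                D[np.ix_([l == "real" for l in labels],
                         [l == "real" for l in labels])])),
        }
    return report


def plot_report(report: FidelityReport, out_dir: str | Path) -> list[Path]:
    """Write the standard panels (Shannon boxes, ordination, scatter plots)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    sh = report.sections.get("shannon", {})
    if sh:
        names = sorted(sh)
        fig, ax = plt.subplots(figsize=(1.5 * len(names) + 2, 4))
        ax.boxplot([np.asarray(sh[n]["values"]) for n in names], tick_labels=names)
        ax.set_ylabel("Shannon index")
        fig.savefig(out / "shannon.png", dpi=120, bbox_inches="tight")
        plt.close(fig)
        written.append(out / "shannon.png")

    uf = report.sections.get("unifrac", {})
    if "coordinates" in uf:
        coords = np.asarray(uf["coordinates"])
        labels = np.asarray(uf["labels"])
        fig, ax = plt.subplots(figsize=(5, 5))
        for name in sorted(set(labels)):
            m = labels == name
            ax.scatter(coords[m, 0], coords[m, 1], s=12, label=name, alpha=0.7)
        ax.legend()
        ax.set_title(f"nMDS of unweighted UniFrac (stress {uf['stress']:.3f})")
        fig.savefig(out / "nmds.png", dpi=120, bbox_inches="tight")
        plt.close(fig)
        written.append(out / "nmds.png")

    for section, fname in (("spearman", "spearman_scatter.png"),
                           ("phi", "phi_scatter.png")):
        data = report.sections.get(section, {})
        sims = [n for n in sorted(data) if isinstance(data[n], dict)]
        if not sims:
            continue
        fig, axes = plt.subplots(1, len(sims), figsize=(4 * len(sims), 4),
                                 squeeze=False)
        for ax, name in zip(axes[0], sims):
            d = data[name]
            ax.scatter(np.asarray(d["real_pairs"]), np.asarray(d["sim_pairs"]),
                       s=6, alpha=0.5)
            lim = ax.get_xlim()
            ax.plot(lim, lim, "k--", lw=0.8)
            ax.set_title(f"{name}: R2={d['r2']:.2f} MSE={d['mse']:.3f}")
            ax.set_xlabel("real")
        axes[0][0].set_ylabel("simulated")
        fig.savefig(out / fname, dpi=120, bbox_inches="tight")
        plt.close(fig)
        written.append(out / fname)
    return written
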