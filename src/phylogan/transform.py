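"""The weighted phylogeny transformation layer.

A species-level composition is expanded to the full set of tree nodes (each
internal node carrying the sum of its descendant leaves, optionally scaled
by a per-node weight), then small abundances are amplified with the log map

    y = log((1 + 1000 x) / (1 + x))

which maps 0 to 0, is strictly increasing, and saturates at log(1000); its
slope at the origin is 999, so rare taxa are strongly magnified while the
order of abundances is preserved.  The result is the critic's input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import AbundanceTable, TaxonomyTree

#: ranks never entering the expansion by default (the aggregation runs
#: phylum through species; a kingdom node is just the row total)
DEFAULT_EXCLUDED_RANKS = frozenset({"kingdom", "root"})


@dataclass
class ExpandedMatrix:
    """Samples x tree-nodes matrix produced by the transformation layer."""

    sample_ids: list[str]
    node_ids: list[str]
    values: np.ndarray
    node_weights: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite values in expanded matrix")


def expansion_nodes(
    tree: TaxonomyTree,
    excluded_ranks: frozenset[str] = DEFAULT_EXCLUDED_RANKS,
) -> list[str]:
    """Deterministic root-first node order entering the expansion."""
    return [n for n in tree.preorder() if tree.ranks.get(n) not in excluded_ranks]


def expansion_matrix(
    tree: TaxonomyTree,
    leaf_order: list[str],
    weights: dict[str, float] | None = None,
    excluded_ranks: frozenset[str] = DEFAULT_EXCLUDED_RANKS,
) -> tuple[list[str], np.ndarray]:
    """Linear map from leaf abundances to all node abundances.

    Returns ``(node_ids, E)`` with ``E`` of shape (n_leaves, n_nodes) such
    that ``expanded = leaf_values @ E``.  ``E[i, j]`` is the node weight of
    node ``j`` if leaf ``i`` descends from (or is) node ``j``, else 0.
    """
    nodes = expansion_nodes(tree, excluded_ranks)
    missing = [l for l in leaf_order if l not in tree]
    if missing:
        raise ValueError(f"taxa not found in tree: {missing[:5]}")
    leaf_idx = {l: i for i, l in enumerate(leaf_order)}
    E = np.zeros((len(leaf_order), len(nodes)))
    for j, node in enumerate(nodes):
        w = 1.0 if weights is None else weights.get(node, 1.0)
        if w < 0:
            raise ValueError(f"negative weight at node {node!r}")
        for leaf in tree.descendant_leaves(node):
            i = leaf_idx.get(leaf)
            if i is not None:
                E[i, j] = w
    return nodes, E


def expand(
    table: AbundanceTable,
    tree: TaxonomyTree,
    weights: dict[str, float] | None = None,
    excluded_ranks: frozenset[str] = DEFAULT_EXCLUDED_RANKS,
) -> ExpandedMatrix:
    """Aggregate leaf abundances up the tree (phylum through species)."""
    for t in table.taxon_ids:
        if t not in tree:
            raise ValueError(f"taxon {t!r} has no tree node")
        if not tree.is_leaf(t):
            raise ValueError(f"taxon {t!r} maps to an internal node, not a leaf")
    nodes, E = expansion_matrix(tree, table.taxon_ids, weights, excluded_ranks)
    node_w = np.array(
        [1.0 if weights is None else weights.get(n, 1.0) for n in nodes]
    )
    return ExpandedMatrix(
        sample_ids=list(table.sample_ids),
        node_ids=nodes,
        values=table.values @ E,
        node_weights=node_w,
    )


def amplify(values: np.ndarray, check_domain: bool = True) -> np.ndarray:
    """Elementwise y = log((1 + 1000 x) / (1 + x)), natural log."""
    x = np.asarray(values, dtype=float)
    if np.any(x < 0):
        raise ValueError("amplify requires nonnegative input")
    if check_domain and np.any(x > 1 + 1e-9):
        raise ValueError("abundance above 1; pass check_domain=False for weighted nodes")
    return np.log1p(1000.0 * x) - np.log1p(x)


def amplify_grad(x: np.ndarray) -> np.ndarray:
    """dy/dx of the amplification map (999 at the origin)."""
    return 1000.0 / (1.0 + 1000.0 * x) - 1.0 / (1.0 + x)


def critic_input(
    table: AbundanceTable,
    tree: TaxonomyTree,
    weights: dict[str, float] | None = None,
    excluded_ranks: frozenset[str] = DEFAULT_EXCLUDED_RANKS,
) -> ExpandedMatrix:
    """Expansion followed by amplification — what the critic sees.

    Applied identically to real and generated batches (same tree, same
    deterministic node order).
    """
    ex = expand(table, tree, weights, excluded_ranks)
    unit_weights = weights is None or all(w == 1.0 for w in weights.values())
    ex.values = amplify(ex.values, check_domain=unit_weights)
    return ex
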