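"""Core data containers: lineages, taxonomy trees, and abundance tables.

Taxon identifiers follow the rank-prefixed, pipe-separated lineage dialect
used by MetaPhlAn-style taxonomic profiles, e.g.::

    k__Bacteria|p__Firmicutes|c__Clostridia|o__Clostridiales|f__X|g__Y|s__Z

Internal node identity is the *full rank prefix* of a lineage, so two genera
that happen to share a name under different families remain distinct nodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

RANK_ORDER = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
RANK_PREFIXES = {"k": "kingdom", "p": "phylum", "c": "class", "o": "order",
                 "f": "family", "g": "genus", "s": "species"}

ROW_SUM_TOL = 1e-6


@dataclass(frozen=True)
class Lineage:
    """An ordered path of (rank, name) pairs from kingdom down to some rank.

    Ranks must appear in strictly increasing canonical order; intermediate
    ranks may be omitted (MetaPhlAn profiles do this for unnamed clades).
    """

    pairs: tuple[tuple[str, str], ...]

    @classmethod
    def parse(cls, taxon_id: str, sep: str = "|") -> "Lineage":
        pairs = []
        for token in taxon_id.split(sep):
            token = token.strip()
            if len(token) < 3 or token[1:3] != "__" or token[0] not in RANK_PREFIXES:
                raise ValueError(
                    f"cannot parse lineage token {token!r} in {taxon_id!r}; "
                    "expected rank-prefixed names like 'p__Firmicutes'"
                )
            pairs.append((RANK_PREFIXES[token[0]], token[3:]))
        if not pairs:
            raise ValueError("empty lineage string")
        ranks = [p[0] for p in pairs]
        order = [RANK_ORDER.index(r) for r in ranks]
        if order != sorted(order) or len(set(order)) != len(order):
            raise ValueError(f"ranks out of order in lineage {taxon_id!r}")
        return cls(tuple(pairs))

    @property
    def ranks(self) -> tuple[str, ...]:
        return tuple(p[0] for p in self.pairs)

    @property
    def depth_rank(self) -> str:
        return self.pairs[-1][0]

    def prefix(self, k: int) -> "Lineage":
        return Lineage(self.pairs[:k])

    def to_string(self, sep: str = "|") -> str:
        inv = {v: k for k, v in RANK_PREFIXES.items()}
        return sep.join(f"{inv[r]}__{n}" for r, n in self.pairs)

    def __len__(self) -> int:
        return len(self.pairs)


class TaxonomyTree:
    """Rooted tree over taxonomic (or phylogenetic) node identifiers.

    Stored as a parent map plus ordered children lists.  Branch lengths are
    per-node (the length of the edge above the node) and optional; absent
    lengths mean unit lengths downstream.
    """

    def __init__(
        self,
        root: str,
        parent: dict[str, str],
        children: dict[str, list[str]],
        ranks: dict[str, str] | None = None,
        branch_lengths: dict[str, float] | None = None,
    ):
        self.root = root
        self.parent = parent
        self.children = children
        self.ranks = ranks or {}
        self.branch_lengths = branch_lengths
        self._validate()

    def _validate(self) -> None:
        if self.root in self.parent:
            raise ValueError("root must not have a parent")
        seen: set[str] = set()
        stack = [self.root]
        while stack:
            node = stack.pop()
            if node in seen:
                raise ValueError(f"cycle or duplicate node {node!r}")
            seen.add(node)
            stack.extend(self.children.get(node, []))
        all_nodes = {self.root} | set(self.parent)
        unreachable = all_nodes - seen
        if unreachable:
            raise ValueError(f"nodes unreachable from root: {sorted(unreachable)[:5]}")
        if self.branch_lengths is not None:
            for n, b in self.branch_lengths.items():
                if b < 0:
                    raise ValueError(f"negative branch length at {n!r}")

    @property
    def nodes(self) -> list[str]:
        return self.preorder()

    def is_leaf(self, node: str) -> bool:
        return not self.children.get(node)

    def leaves(self) -> list[str]:
        return [n for n in self.preorder() if self.is_leaf(n)]

    def preorder(self) -> list[str]:
        """Root-first traversal; children visited in stored order."""
        out: list[str] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(reversed(self.children.get(node, [])))
        return out

    def postorder(self) -> list[str]:
        return list(reversed(self._reverse_postorder()))

    def _reverse_postorder(self) -> list[str]:
        out: list[str] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(self.children.get(node, []))
        return out

    def descendant_leaves(self, node: str) -> list[str]:
        out = []
        stack = [node]
        while stack:
            n = stack.pop()
            if self.is_leaf(n):
                out.append(n)
            else:
                stack.extend(self.children[n])
        return out

    def branch_length(self, node: str, default: float = 1.0) -> float:
        if self.branch_lengths is None:
            return default
        return self.branch_lengths.get(node, default)

    def __contains__(self, node: str) -> bool:
        return node == self.root or node in self.parent

    def __len__(self) -> int:
        return 1 + len(self.parent)


@dataclass
class AbundanceTable:
    """Samples x taxa relative-abundance matrix.

    ``values[i, j]`` is the relative abundance of taxon ``taxon_ids[j]`` in
    sample ``sample_ids[i]``.  ``normalized`` records whether every row sums
    to 1; truncation of small abundances (which breaks exact closure on
    purpose, and is never followed by renormalization) clears the flag.
    """

    sample_ids: list[str]
    taxon_ids: list[str]
    values: np.ndarray
    rank_level: str = "species"
    normalized: bool = True
    lineage_sep: str = "|"
    _lineages: list[Lineage] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n, p = self.values.shape
        if n != len(self.sample_ids) or p != len(self.taxon_ids):
            raise ValueError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.taxon_ids)} taxa"
            )
        if len(set(self.taxon_ids)) != p:
            raise ValueError("duplicate taxon ids")
        if np.any(self.values < 0):
            raise ValueError("negative abundance values")
        if self.normalized:
            sums = self.values.sum(axis=1)
            if not np.allclose(sums, 1.0, atol=ROW_SUM_TOL):
                bad = int(np.argmax(np.abs(sums - 1.0)))
                raise ValueError(
                    f"row {self.sample_ids[bad]!r} sums to {sums[bad]:.6g}, "
                    "not 1, but table declared normalized"
                )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.values.shape[1]

    @property
    def lineages(self) -> list[Lineage]:
        if self._lineages is None:
            self._lineages = [Lineage.parse(t, self.lineage_sep) for t in self.taxon_ids]
            depths = {len(lin) for lin in self._lineages}
            if len(depths) > 1:
                raise ValueError(
                    f"taxon lineages have inconsistent rank depth: {sorted(depths)}"
                )
        return self._lineages

    def subset_taxa(self, keep: list[str]) -> "AbundanceTable":
        """Column subset (breaks closure; returned table is unnormalized)."""
        idx = [self.taxon_ids.index(t) for t in keep]
        return AbundanceTable(
            sample_ids=list(self.sample_ids),
            taxon_ids=list(keep),
            values=self.values[:, idx].copy(),
            rank_level=self.rank_level,
            normalized=False,
            lineage_sep=self.lineage_sep,
        )

    def truncate(self, threshold: float = 1e-4) -> "AbundanceTable":
        """Zero out entries below ``threshold`` without renormalizing."""
        vals = self.values.copy()
        vals[vals < threshold] = 0.0
        return AbundanceTable(
            sample_ids=list(self.sample_ids),
            taxon_ids=list(self.taxon_ids),
            values=vals,
            rank_level=self.rank_level,
            normalized=False,
            lineage_sep=self.lineage_sep,
        )
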