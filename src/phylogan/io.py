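"""Readers/writers for abundance tables and trees, and lineage -> tree construction.

Tables are delimited text (TSV/CSV) with taxon lineages in the header and
sample identifiers in the index.  Input bodies may be fractions, percents, or
raw counts; by default every row is closed to sum 1 and the detected dialect
is recorded on the returned table.  Newick I/O is delegated to scikit-bio.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

from .datamodel import AbundanceTable, Lineage, TaxonomyTree

_AUTO_PREFIX = "__anon"


def _looks_like_lineages(labels: list[str]) -> bool:
    try:
        for lab in labels[: min(5, len(labels))]:
            Lineage.parse(str(lab))
        return True
    except ValueError:
        return False


def read_abundance_table(
    path: str | Path,
    orientation: str = "auto",
    normalize: str = "auto",
    sep: str | None = None,
    lineage_sep: str = "|",
) -> AbundanceTable:
    """Read a samples x taxa table from delimited text.

    Parameters
    ----------
    orientation
        ``"rows-are-samples"``, ``"rows-are-taxa"``, or ``"auto"`` (decide by
        which axis parses as lineage strings).  Samples are always rows in
        the returned table.
    normalize
        ``"auto"`` closes each row to sum 1 (detecting fraction / percent /
        count dialects by row totals); ``"none"`` requires rows that already
        sum to 1 and rejects anything else.
    """
    # disable NA sniffing so a malformed cell keeps its literal text and can
    # be reported; duplicate header labels are checked before pandas would
    # silently mangle them
    df = pd.read_csv(path, sep=sep, index_col=0, engine="python",
                     keep_default_na=False)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"empty table in {path}")
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
    delim = sep or ("\t" if first.count("\t") >= first.count(",") else ",")
    header = first.split(delim)[1:]
    dupes = sorted({h for h in header if header.count(h) > 1})
    if dupes:
        raise ValueError(f"duplicate taxon ids: {dupes[:5]}")

    # locate non-numeric cells before coercing
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().values.any() and df.notna().values.any():
        bad = np.argwhere(numeric.isna().values & df.notna().values)
        if bad.size:
            i, j = bad[0]
            raise ValueError(
                f"non-numeric cell {df.iat[i, j]!r} at row {df.index[i]!r}, "
                f"column {df.columns[j]!r}"
            )
    if numeric.isna().values.any():
        i, j = np.argwhere(numeric.isna().values)[0]
        raise ValueError(f"missing value at row {df.index[i]!r}, column {df.columns[j]!r}")
    df = numeric

    if orientation == "auto":
        cols_lin = _looks_like_lineages(list(df.columns))
        rows_lin = _looks_like_lineages(list(df.index))
        if rows_lin and not cols_lin:
            orientation = "rows-are-taxa"
        else:
            orientation = "rows-are-samples"
    if orientation == "rows-are-taxa":
        df = df.T
    elif orientation != "rows-are-samples":
        raise ValueError(f"unknown orientation {orientation!r}")

    values = df.to_numpy(dtype=float)
    if np.any(values < 0):
        i, j = np.argwhere(values < 0)[0]
        raise ValueError(
            f"negative value at row {df.index[i]!r}, column {df.columns[j]!r}"
        )
    taxon_ids = [str(c) for c in df.columns]
    if len(set(taxon_ids)) != len(taxon_ids):
        dupes = sorted({t for t in taxon_ids if taxon_ids.count(t) > 1})
        raise ValueError(f"duplicate taxon ids: {dupes[:5]}")

    row_sums = values.sum(axis=1)
    if normalize == "none":
        dialect = "fractions"
    elif normalize == "auto":
        if np.allclose(row_sums, 1.0, atol=1e-6):
            dialect = "fractions"
        elif np.allclose(row_sums, 100.0, rtol=1e-6):
            dialect = "percent"
        else:
            dialect = "counts"
        with np.errstate(invalid="ignore", divide="ignore"):
            values = np.where(row_sums[:, None] > 0, values / row_sums[:, None], 0.0)
    else:
        raise ValueError(f"unknown normalize mode {normalize!r}")

    table = AbundanceTable(
        sample_ids=[str(i) for i in df.index],
        taxon_ids=taxon_ids,
        values=values,
        normalized=bool(np.allclose(values.sum(axis=1), 1.0, atol=1e-6)),
        lineage_sep=lineage_sep,
    )
    table.dialect = dialect  # record the applied normalization
    return table


def write_table(table: AbundanceTable, path: str | Path, sep: str = "\t") -> None:
    df = pd.DataFrame(table.values, index=table.sample_ids, columns=table.taxon_ids)
    df.to_csv(path, sep=sep, float_format="%.17g")


def lineage_to_tree(taxon_ids: list[str], sep: str = "|") -> TaxonomyTree:
    """Build the rank tree implied by lineage strings.

    Node identity is the full rank prefix, so same-named taxa under
    different parents stay distinct.  Leaves are the full input lineages;
    branch lengths are absent (unit lengths assumed downstream).
    """
    lineages = [Lineage.parse(t, sep) for t in taxon_ids]
    if len(set(taxon_ids)) != len(taxon_ids):
        raise ValueError("duplicate lineages")
    root_ranks = {lin.ranks[0] for lin in lineages}
    if len(root_ranks) > 1:
        raise ValueError(f"lineages start at different ranks: {sorted(root_ranks)}")

    parent: dict[str, str] = {}
    children: dict[str, list[str]] = {}
    ranks: dict[str, str] = {}
    tops: list[str] = []

    def add_edge(par: str | None, child: str, rank: str) -> None:
        if child in ranks:
            if ranks[child] != rank or parent.get(child) != par:
                raise ValueError(f"inconsistent taxonomy at node {child!r}")
            return
        ranks[child] = rank
        if par is None:
            tops.append(child)
        else:
            parent[child] = par
            children.setdefault(par, []).append(child)

    for lin in lineages:
        prev: str | None = None
        for k in range(1, len(lin) + 1):
            pref = lin.prefix(k)
            node_id = pref.to_string(sep)
            add_edge(prev, node_id, pref.depth_rank)
            prev = node_id

    if len(tops) == 1:
        root = tops[0]
    else:
        root = "root"
        for t in tops:
            parent[t] = root
            children.setdefault(root, []).append(t)
        ranks[root] = "root"
    return TaxonomyTree(root=root, parent=parent, children=children, ranks=ranks)


def _skbio_to_tree(root: TreeNode) -> TaxonomyTree:
    parent: dict[str, str] = {}
    children: dict[str, list[str]] = {}
    lengths: dict[str, float] = {}
    names: dict[int, str] = {}
    used: set[str] = set()
    counter = [0]

    def name_of(node: TreeNode) -> str:
        key = id(node)
        if key in names:
            return names[key]
        nm = node.name
        if nm is None or nm in used:
            nm = f"{_AUTO_PREFIX}{counter[0]}"
            counter[0] += 1
        used.add(nm)
        names[key] = nm
        return nm

    root_id = name_of(root)
    any_length = False
    for node in root.preorder(include_self=True):
        nid = name_of(node)
        if node.length is not None:
            lengths[nid] = float(node.length)
            if node is not root:
                any_length = True
        for child in node.children:
            cid = name_of(child)
            parent[cid] = nid
            children.setdefault(nid, []).append(cid)
    return TaxonomyTree(
        root=root_id,
        parent=parent,
        children=children,
        branch_lengths=lengths if any_length else None,
    )


def read_newick(path: str | Path) -> TaxonomyTree:
    try:
        skb = TreeNode.read(str(path), format="newick")
    except Exception as exc:  # skbio raises its own parse errors
        raise ValueError(f"newick parse error in {path}: {exc}") from exc
    return _skbio_to_tree(skb)


def _tree_to_skbio(tree: TaxonomyTree) -> TreeNode:
    nodes: dict[str, TreeNode] = {}
    for nid in tree.preorder():
        name = None if nid.startswith(_AUTO_PREFIX) else nid
        node = TreeNode(name=name)
        if tree.branch_lengths is not None and nid in tree.branch_lengths:
            node.length = tree.branch_lengths[nid]
        nodes[nid] = node
        if nid != tree.root:
            nodes[tree.parent[nid]].append(node)
    return nodes[tree.root]


def write_newick(tree: TaxonomyTree, path: str | Path) -> None:
    skb = _tree_to_skbio(tree)
    buf = _io.StringIO()
    skb.write(buf, format="newick")
    Path(path).write_text(buf.getvalue())
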