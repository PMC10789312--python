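"""Input/output and the core data model.

Tables are pandas DataFrames with samples in rows and OTUs in columns;
readers normalize orientation.  Trees are wrapped :class:`PhyloTree`
objects built on :class:`skbio.TreeNode`.  A *branch* is identified by the
name of its child node, so a tree with M nodes has R = M - 1 branches (the
root carries no branch).
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import skbio

logger = logging.getLogger("mkbmc")

__all__ = [
    "PhyloTree",
    "BranchProfiles",
    "read_newick",
    "read_otu_table",
    "read_metadata",
    "to_relative_abundance",
    "align_tree_and_table",
    "branch_profiles",
]


class NewickFormatError(ValueError):
    """Raised when a Newick string cannot be parsed."""


def _scan_newick(text: str) -> None:
    """Pre-scan for structural errors, reporting the character position."""
    depth = 0
    for pos, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise NewickFormatError(
                    f"unbalanced ')' at character position {pos}"
                )
    if depth != 0:
        raise NewickFormatError(
            f"unbalanced '(' — {depth} unclosed at end of string "
            f"(position {len(text) - 1})"
        )
    if ";" not in text:
        raise NewickFormatError(
            f"missing terminating ';' (position {len(text) - 1})"
        )


class PhyloTree:
    """A rooted phylogenetic tree with branch lengths.

    Wraps a ``skbio.TreeNode`` and exposes postorder index arrays used by
    the branch-profile accumulation.  Every node has a unique name; the
    branch above a non-root node is identified by that node's name.
    """

    def __init__(self, tree: skbio.TreeNode):
        self._tree = tree
        self._index()

    def _index(self) -> None:
        nodes = list(self._tree.postorder(include_self=True))
        # auto-name unnamed internal nodes deterministically (postorder)
        existing = {n.name for n in nodes if n.name is not None}
        counter = 1
        for n in nodes:
            if n.name is None:
                while f"node{counter}" in existing:
                    counter += 1
                n.name = f"node{counter}"
                existing.add(n.name)
        names = [n.name for n in nodes]
        if len(set(names)) != len(names):
            dupes = sorted({x for x in names if names.count(x) > 1})
            raise ValueError(f"duplicate node names in tree: {dupes}")
        pos = {id(n): i for i, n in enumerate(nodes)}
        self._nodes = nodes
        self.names: list[str] = names
        self.parent = np.array(
            [pos[id(n.parent)] if n.parent is not None else -1 for n in nodes],
            dtype=np.intp,
        )
        lengths = []
        for n in nodes:
            if n.parent is None:
                lengths.append(0.0)
            elif n.length is None:
                warnings.warn(
                    f"branch above node {n.name!r} has no length; using 0"
                )
                lengths.append(0.0)
            else:
                if n.length < 0:
                    raise ValueError(
                        f"negative branch length {n.length} above {n.name!r}"
                    )
                lengths.append(float(n.length))
        self.lengths = np.asarray(lengths)
        self.is_leaf = np.array([n.is_tip() for n in nodes], dtype=bool)
        self.root_index = int(np.flatnonzero(self.parent == -1)[0])

    # -- basic accessors -------------------------------------------------
    @property
    def leaf_names(self) -> list[str]:
        return [n for n, lf in zip(self.names, self.is_leaf) if lf]

    @property
    def n_branches(self) -> int:
        return len(self.names) - 1

    @property
    def branch_names(self) -> list[str]:
        """Names of non-root nodes (postorder) = branch identifiers."""
        return [n for i, n in enumerate(self.names) if i != self.root_index]

    @property
    def branch_lengths(self) -> pd.Series:
        keep = np.arange(len(self.names)) != self.root_index
        return pd.Series(self.lengths[keep], index=self.branch_names)

    # -- construction / serialization ------------------------------------
    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        _scan_newick(text)
        try:
            tree = skbio.TreeNode.read(io.StringIO(text), format="newick")
        except Exception as exc:  # pragma: no cover - skbio message varies
            raise NewickFormatError(f"Newick parse failure: {exc}") from exc
        root_children = len(tree.children)
        if root_children > 2:
            raise ValueError(
                f"tree root has {root_children} children (unrooted "
                "trifurcation); root the tree before use"
            )
        return cls(tree)

    def to_newick(self) -> str:
        buf = io.StringIO()
        self._tree.write(buf, format="newick")
        return buf.getvalue().strip()

    def copy(self) -> "PhyloTree":
        return PhyloTree(self._tree.copy())

    # -- operations -------------------------------------------------------
    def shear(self, leaf_names) -> "PhyloTree":
        """Restrict the tree to a subset of leaves.

        Unbranched internal paths created by the removal are collapsed and
        their branch lengths summed.
        """
        keep = set(leaf_names)
        missing = keep - set(self.leaf_names)
        if missing:
            raise KeyError(f"leaves not in tree: {sorted(missing)[:5]}")
        sub = self._tree.copy().shear(keep)
        sub.prune()
        # prune() can leave a single-child root; collapse it into the child
        while len(sub.children) == 1:
            child = sub.children[0]
            child.parent = None
            child.length = None
            sub = child
        return PhyloTree(sub)

    def cophenetic(self) -> pd.DataFrame:
        """Leaf-to-leaf path-length (cophenetic) distance matrix."""
        dm = self._tree.tip_tip_distances()
        return pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids))


@dataclass
class BranchProfiles:
    """Per-sample cumulative descendant abundance for every branch.

    ``values`` is samples x branches; ``branch_lengths`` is aligned to the
    columns.  Entry (i, r) is the summed relative abundance, in sample i,
    of all leaves descending through branch r.
    """

    values: pd.DataFrame
    branch_lengths: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        if not self.values.columns.equals(self.branch_lengths.index):
            raise ValueError("branch_lengths must align with profile columns")


def read_newick(text_or_path: str) -> PhyloTree:
    """Parse a rooted Newick tree from a string or a file path."""
    text = text_or_path
    if "(" not in text and ";" not in text:
        with open(text_or_path) as fh:
            text = fh.read()
    return PhyloTree.from_newick(text)


def _validate_table(df: pd.DataFrame, what: str) -> None:
    if df.index.has_duplicates:
        raise ValueError(f"duplicate sample ids in {what}")
    if df.columns.has_duplicates:
        raise ValueError(f"duplicate feature ids in {what}")
    if (df.values < 0).any():
        raise ValueError(f"negative entries in {what}")


def read_otu_table(path: str, otus_as_rows: bool = False) -> pd.DataFrame:
    """Read a tab-separated OTU table into a samples x OTUs DataFrame.

    The first column holds sample ids (or OTU ids when *otus_as_rows* is
    set, in which case the table is transposed).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if otus_as_rows:
        df = df.T
    df = df.astype(float)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    _validate_table(df, f"OTU table {path!r}")
    return df


def write_otu_table(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t")


def read_metadata(path: str) -> pd.DataFrame:
    """Read sample metadata: a `label` column in {0,1} plus numeric covariates."""
    meta = pd.read_csv(path, sep="\t", index_col=0)
    meta.index = meta.index.astype(str)
    if "label" not in meta.columns:
        raise ValueError(f"metadata {path!r} lacks required column 'label'")
    labels = meta["label"]
    if not set(np.unique(labels)) <= {0, 1}:
        raise ValueError("metadata labels must be 0/1")
    meta["label"] = labels.astype(int)
    return meta


def to_relative_abundance(tab: pd.DataFrame) -> pd.DataFrame:
    """Row-normalize counts to proportions; all-zero rows stay zero."""
    _validate_table(tab, "OTU table")
    totals = tab.sum(axis=1)
    zero = totals == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} sample(s) have zero total count; "
            "their rows stay all-zero"
        )
    safe = totals.replace(0, 1.0)
    return tab.div(safe, axis=0)


def align_tree_and_table(
    tree: PhyloTree, rel: pd.DataFrame, renormalize: bool = True
) -> tuple[PhyloTree, pd.DataFrame]:
    """Restrict tree and table to their shared OTU ids.

    The tree is sheared to the shared leaves (unbranched paths collapsed,
    lengths summed); table columns outside the tree are dropped and rows
    re-normalized so each nonzero row still sums to 1.
    """
    leaves = set(tree.leaf_names)
    cols = set(rel.columns)
    shared = leaves & cols
    if not shared:
        raise ValueError("tree leaves and table OTU ids do not overlap")
    n_drop_tree = len(leaves - shared)
    n_drop_tab = len(cols - shared)
    if n_drop_tree or n_drop_tab:
        logger.info(
            "align: dropping %d tree leaves and %d table OTUs outside the "
            "shared set of %d", n_drop_tree, n_drop_tab, len(shared),
        )
    if n_drop_tree:
        tree = tree.shear(shared)
    if n_drop_tab:
        rel = rel[[c for c in rel.columns if c in shared]]
        if renormalize:
            rel = to_relative_abundance(rel)
    # consistent column order: tree leaf postorder
    rel = rel[[n for n in tree.leaf_names]]
    return tree, rel


def branch_profiles(tree: PhyloTree, rel: pd.DataFrame) -> BranchProfiles:
    """Accumulate leaf abundances up the tree, one postorder pass per sample.

    The profile of a leaf branch equals that leaf's relative abundance;
    the profile of an internal branch is the sum over its children.
    """
    if set(rel.columns) != set(tree.leaf_names):
        raise ValueError("table OTU ids must equal tree leaves; align first")
    n = rel.shape[0]
    m = len(tree.names)
    node_vals = np.zeros((n, m))
    col_of = {name: j for j, name in enumerate(rel.columns)}
    for i, (name, leaf) in enumerate(zip(tree.names, tree.is_leaf)):
        if leaf:
            node_vals[:, i] = rel.iloc[:, col_of[name]].to_numpy()
    # postorder guarantees children appear before their parent, so each
    # node's subtree total is complete by the time it is pushed upward
    for i in range(m):
        p = tree.parent[i]
        if p >= 0:
            node_vals[:, p] += node_vals[:, i]
    keep = np.arange(m) != tree.root_index
    values = pd.DataFrame(
        node_vals[:, keep], index=rel.index, columns=tree.branch_names
    )
    return BranchProfiles(values=values, branch_lengths=tree.branch_lengths)
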