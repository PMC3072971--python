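"""Phylogeny container, newick I/O, pruning and bipartition-based tree comparison.

A :class:`Phylogeny` is a rooted tree with tip labels and branch lengths in
expected substitutions per site.  It wraps a :class:`dendropy.Tree` for
parsing, writing and taxon pruning, and adds the topology computations the
analyses need: canonical bipartition sets and the Robinson–Foulds symmetric
difference, both computed on the unrooted version of the tree (the standard
RF convention; rooting is outgroup-determined and carries no extra signal).

Node identifiers are stable postorder integers, assigned at construction and
reassigned after pruning, so downstream event tables can reference edges by
child-node id across runs.
"""

from __future__ import annotations

import warnings
from typing import Iterator

import dendropy

__all__ = [
    "TreeError",
    "Phylogeny",
    "parse_newick",
    "write_newick",
    "bipartitions",
    "rf_distance",
    "prune_to_taxa",
]


class TreeError(ValueError):
    """Malformed newick, invalid branch lengths, or inconsistent taxa."""


class Phylogeny:
    """Rooted phylogeny with unique tip labels and non-negative branch lengths.

    Parameters
    ----------
    tree
        A dendropy tree; it is adopted (not copied), normalized in place
        (missing branch lengths set to 0) and validated.

    Notes
    -----
    Internal-node labels, when present, are treated as support annotations
    and round-trip through newick; they are never interpreted as taxa.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._normalize_and_validate()

    # -- construction -------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "Phylogeny":
        return parse_newick(text)

    @classmethod
    def from_file(cls, path) -> "Phylogeny":
        with open(path, "r", encoding="utf-8") as fh:
            return parse_newick(fh.read())

    def _normalize_and_validate(self) -> None:
        t = self._tree
        root = t.seed_node
        missing = []
        for nd in t.preorder_node_iter():
            if nd.edge.length is None:
                if nd is not root:
                    missing.append(nd)
                nd.edge.length = 0.0
            else:
                bl = float(nd.edge.length)
                if not (bl >= 0.0) or bl != bl or bl == float("inf"):
                    raise TreeError(f"branch length must be finite and >= 0, got {nd.edge.length!r}")
                nd.edge.length = bl
        if missing:
            warnings.warn(
                f"{len(missing)} branch length(s) missing; defaulting to 0",
                stacklevel=3,
            )
        labels = [lf.taxon.label if lf.taxon is not None else None for lf in t.leaf_node_iter()]
        if any(lb is None or lb == "" for lb in labels):
            raise TreeError("every tip must carry a non-empty label")
        dupes = {lb for lb in labels if labels.count(lb) > 1}
        if dupes:
            raise TreeError(f"duplicate tip labels: {sorted(dupes)}")
        self._index_nodes()

    def _index_nodes(self) -> None:
        self._postorder = list(self._tree.postorder_node_iter())
        for i, nd in enumerate(self._postorder):
            nd.index = i
        self._tips = [nd for nd in self._postorder if nd.is_leaf()]

    # -- basic accessors ----------------------------------------------

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def root(self):
        return self._tree.seed_node

    @property
    def n_tips(self) -> int:
        return len(self._tips)

    @property
    def n_nodes(self) -> int:
        return len(self._postorder)

    @property
    def tip_labels(self) -> list[str]:
        return [nd.taxon.label for nd in self._tips]

    def postorder(self) -> Iterator:
        return iter(self._postorder)

    def preorder(self) -> Iterator:
        return iter(self._tree.preorder_node_iter())

    def node(self, index: int):
        return self._postorder[index]

    def tip_label(self, node) -> str:
        return node.taxon.label

    def leafset_below(self, node) -> frozenset[str]:
        return frozenset(lf.taxon.label for lf in node.leaf_iter())

    def copy(self) -> "Phylogeny":
        return Phylogeny(self._tree.clone(depth=1))

    # -- metrics ------------------------------------------------------

    def root_to_tip_depths(self) -> dict[str, float]:
        depth = {self.root: 0.0}
        out: dict[str, float] = {}
        for nd in self._tree.preorder_node_iter():
            if nd is not self.root:
                depth[nd] = depth[nd.parent_node] + nd.edge.length
            if nd.is_leaf():
                out[nd.taxon.label] = depth[nd]
        return out

    def total_length(self) -> float:
        return sum(nd.edge.length for nd in self._postorder if nd is not self.root)

    def tip_path_length(self, a: str, b: str) -> float:
        """Patristic distance between two tips (sum of branch lengths)."""
        depth: dict = {}
        for nd in self._tree.preorder_node_iter():
            depth[nd] = 0.0 if nd is self.root else depth[nd.parent_node] + nd.edge.length
        find = {lf.taxon.label: lf for lf in self._tips}
        try:
            na, nb = find[a], find[b]
        except KeyError as exc:
            raise TreeError(f"unknown tip label: {exc.args[0]!r}") from None
        anc_a = set()
        nd = na
        while nd is not None:
            anc_a.add(nd)
            nd = nd.parent_node
        nd = nb
        while nd not in anc_a:
            nd = nd.parent_node
        return depth[na] + depth[nb] - 2.0 * depth[nd]

    def scale_to_height(self, height: float) -> "Phylogeny":
        """Return a copy rescaled so the maximum root-to-tip depth equals *height*."""
        cur = max(self.root_to_tip_depths().values())
        if cur <= 0:
            raise TreeError("cannot rescale a zero-height tree")
        out = self.copy()
        f = height / cur
        for nd in out._postorder:
            nd.edge.length *= f
        return out

    # -- newick -------------------------------------------------------

    def to_newick(self) -> str:
        return write_newick(self)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<Phylogeny with {self.n_tips} tips>"


def parse_newick(text: str) -> Phylogeny:
    """Parse a single newick tree.

    Lines starting with ``#`` are comments and ignored.  Missing branch
    lengths default to 0 with a warning; duplicate or empty tip labels and
    malformed newick raise :class:`TreeError`.
    """
    cleaned = "\n".join(ln for ln in text.splitlines() if not ln.lstrip().startswith("#"))
    if not cleaned.strip():
        raise TreeError("empty newick input")
    try:
        dtree = dendropy.Tree.get(
            data=cleaned,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise TreeError(f"newick parse error: {exc}") from exc
    return Phylogeny(dtree)


def write_newick(tree: Phylogeny) -> str:
    """Serialize to a single-line newick string (lengths and labels preserved)."""
    s = tree.dendropy_tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        suppress_internal_node_labels=False,
    )
    return s.strip()


def bipartitions(tree: Phylogeny) -> frozenset[frozenset[str]]:
    """Nontrivial splits of the unrooted topology, in canonical orientation.

    Each internal edge induces a two-block partition of the tip set; the
    canonical representative is the block *not* containing the
    lexicographically smallest tip label.  Trivial splits (singleton | rest)
    and the root's artificial edge are excluded.  Trees with fewer than 4
    tips have no nontrivial splits.
    """
    taxa = frozenset(tree.tip_labels)
    if len(taxa) < 4:
        return frozenset()
    ref = min(taxa)
    splits: set[frozenset[str]] = set()
    for nd in tree.postorder():
        if nd.is_leaf() or nd is tree.root:
            continue
        below = tree.leafset_below(nd)
        if len(below) < 2 or len(taxa) - len(below) < 2:
            continue
        splits.add(below if ref not in below else taxa - below)
    return frozenset(splits)


def rf_distance(t1: Phylogeny, t2: Phylogeny) -> int:
    """Robinson–Foulds symmetric-difference distance on the unrooted topologies.

    Zero exactly when the two trees have identical unrooted topology; for
    binary trees with n tips the maximum is 2(n-3).
    """
    s1, s2 = frozenset(t1.tip_labels), frozenset(t2.tip_labels)
    if s1 != s2:
        only1, only2 = sorted(s1 - s2), sorted(s2 - s1)
        raise TreeError(
            f"tip sets differ: only in first {only1}; only in second {only2}"
        )
    return len(bipartitions(t1) ^ bipartitions(t2))


def prune_to_taxa(tree: Phylogeny, keep) -> Phylogeny:
    """Induced subtree on *keep*; degree-2 nodes suppressed, lengths summed.

    Patristic distances between retained tips are preserved.
    """
    keep = set(keep)
    tips = set(tree.tip_labels)
    unknown = keep - tips
    if unknown:
        raise TreeError(f"unknown tip labels: {sorted(unknown)}")
    if len(keep) < 2:
        raise TreeError("need at least 2 tips to prune to")
    sub = tree.dendropy_tree.extract_tree_with_taxa_labels(labels=keep)
    # extract_tree keeps the original root even when it has become degree-1;
    # collapse any leading unifurcation chain so lengths stay additive.
    sub.suppress_unifurcations()
    while sub.seed_node.num_child_nodes() == 1:
        child = sub.seed_node.child_nodes()[0]
        child.edge.length = (child.edge.length or 0.0)
        sub.seed_node = child
        child.parent_node = None
    return Phylogeny(sub)
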