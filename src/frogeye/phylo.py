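"""Phylogeny handling: Newick I/O, tree editing, and phylogenetic covariance.

The comparative analyses in this package assume a rooted tree with branch
lengths (a phylogram; units are irrelevant as long as they are consistent).
Species sampled but absent from the source tree are accommodated the way
comparative studies usually do it: close relatives already in the tree are
relabelled (`substitute_tips`), remaining species are grafted next to their
closest relative as polytomous sisters (`graft_polytomy_tip`), and polytomies
are then randomly resolved with zero-length internal edges so that no
pairwise tip distance -- and hence no downstream covariance -- depends on the
arbitrary resolution.

The phylogenetic covariance matrix ``C`` has ``C[i, j]`` equal to the shared
root-to-tip path length of tips *i* and *j* (the depth of their most recent
common ancestor) and ``C[i, i]`` equal to the root-to-tip distance of *i*.
Pagel's lambda rescales the off-diagonal entries only; ``lambda = 0`` removes
all phylogenetic signal, ``lambda = 1`` is the Brownian-motion expectation.

dendropy provides the underlying tree structure and Newick parsing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Phylogeny",
    "PhyloCovariance",
    "read_newick",
    "parse_newick",
    "write_newick",
    "prune_to_taxa",
    "substitute_tips",
    "graft_polytomy_tip",
    "resolve_polytomies",
    "phylo_covariance",
    "apply_lambda",
]


def _normalize_label(label: str) -> str:
    # Mixed space/underscore conventions across Newick producers; internal
    # representation uses underscores throughout.
    return label.strip().replace(" ", "_")


@dataclass
class Phylogeny:
    """A rooted tree with branch lengths, wrapping a ``dendropy.Tree``.

    Tip labels are unique and underscore-normalized. Every non-root edge has
    a finite length >= 0 (a missing root edge length is treated as 0).
    """

    tree: dendropy.Tree

    def __post_init__(self) -> None:
        self._validate()

    def _validate(self) -> None:
        seen: dict[str, int] = {}
        for leaf in self.tree.leaf_node_iter():
            if leaf.taxon is None or not leaf.taxon.label:
                raise ValueError("unlabelled tip in tree")
            seen[leaf.taxon.label] = seen.get(leaf.taxon.label, 0) + 1
        dups = sorted(k for k, v in seen.items() if v > 1)
        if dups:
            raise ValueError(f"duplicate tip labels: {dups}")
        root = self.tree.seed_node
        if root.edge.length is None:
            root.edge.length = 0.0
        for node in self.tree.preorder_node_iter():
            if node is root:
                continue
            bl = node.edge.length
            if bl is None:
                name = node.taxon.label if node.is_leaf() and node.taxon else "internal node"
                raise ValueError(
                    f"missing branch length on edge above {name!r}"
                )
            if not np.isfinite(bl) or bl < 0:
                name = node.taxon.label if node.is_leaf() and node.taxon else "internal node"
                raise ValueError(f"invalid branch length {bl!r} above {name!r}")

    @property
    def tips(self) -> list[str]:
        """Tip labels in tree (preorder leaf) order."""
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self.tree.leaf_node_iter())

    def is_binary(self) -> bool:
        return all(
            len(nd.child_nodes()) == 2
            for nd in self.tree.preorder_internal_node_iter()
        )

    def to_newick(self) -> str:
        s = self.tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
        ).strip()
        return s

    def copy(self) -> "Phylogeny":
        # Round-trip through Newick: cheap at the sizes used here and avoids
        # shared taxon-namespace surprises from shallow clones.
        return parse_newick(self.to_newick())

    def distance_matrix(self) -> "tuple[list[str], np.ndarray]":
        """Pairwise patristic distances between tips, in tip order."""
        labels = self.tips
        cov = phylo_covariance(self)
        C = cov.matrix
        d = np.diag(C)
        D = d[:, None] + d[None, :] - 2.0 * C
        np.fill_diagonal(D, 0.0)
        return labels, D

    def _find_leaf(self, label: str) -> dendropy.Node:
        label = _normalize_label(label)
        for leaf in self.tree.leaf_node_iter():
            if leaf.taxon.label == label:
                return leaf
        raise KeyError(f"tip {label!r} not found in tree")


def parse_newick(text: str) -> Phylogeny:
    """Parse a Newick string (branch lengths required) into a Phylogeny."""
    # leaf labels sit after '(' or ',' and before ':'; scan for duplicates
    # up front so the error can list them (dendropy's own is less direct)
    import re

    tokens = re.findall(r"[(,]\s*(?:'([^']*)'|([^\s(),:;]+))\s*(?=:)", text)
    labels = [_normalize_label(a or b) for a, b in tokens]
    dups = sorted({l for l in labels if labels.count(l) > 1})
    if dups:
        raise ValueError(f"duplicate tip labels: {dups}")
    tree = dendropy.Tree.get(
        data=text,
        schema="newick",
        preserve_underscores=True,
        suppress_internal_node_taxa=True,
    )
    for leaf in tree.leaf_node_iter():
        leaf.taxon.label = _normalize_label(leaf.taxon.label)
    tree.is_rooted = True
    return Phylogeny(tree)


def read_newick(path) -> Phylogeny:
    """Read a rooted Newick tree with branch lengths from ``path``."""
    with open(path) as fh:
        return parse_newick(fh.read())


def write_newick(phy: Phylogeny, path) -> None:
    with open(path, "w") as fh:
        fh.write(phy.to_newick() + "\n")


def prune_to_taxa(phy: Phylogeny, keep: Iterable[str]) -> Phylogeny:
    """Prune the tree down to ``keep``, preserving pairwise tip path lengths.

    Degree-2 internal nodes left by the pruning are collapsed by summing the
    adjacent edge lengths.
    """
    keep_set = {_normalize_label(k) for k in keep}
    have = set(phy.tips)
    unknown = sorted(keep_set - have)
    if unknown:
        raise KeyError(f"taxa not in tree: {unknown}")
    out = phy.copy()
    out.tree.retain_taxa_with_labels(sorted(keep_set))
    # retain_taxa suppresses internal unifurcations, but the root itself can
    # be left with a single child; collapse it into the child.
    root = out.tree.seed_node
    while len(root.child_nodes()) == 1:
        child = root.child_nodes()[0]
        child.edge.length = (child.edge.length or 0.0) + (root.edge.length or 0.0)
        out.tree.seed_node = child
        child.parent_node = None
        root = child
    out.tree.is_rooted = True
    pruned = Phylogeny(out.tree)
    logger.info("prune_to_taxa: %d -> %d tips", phy.n_tips, pruned.n_tips)
    return pruned


def substitute_tips(phy: Phylogeny, mapping: Mapping[str, str]) -> Phylogeny:
    """Rename tips ``old -> new`` (close-relative substitutions).

    Topology and branch lengths are untouched. Raises on a rename that would
    collide with a label that remains in the tree.
    """
    mapping = {
        _normalize_label(o): _normalize_label(n) for o, n in mapping.items()
    }
    tips = set(phy.tips)
    missing = sorted(set(mapping) - tips)
    if missing:
        raise KeyError(f"substitution source taxa not in tree: {missing}")
    survivors = (tips - set(mapping)) | set(mapping.values())
    if len(survivors) != len(tips):
        collisions = sorted(
            n for n in mapping.values()
            if n in (tips - set(mapping)) or list(mapping.values()).count(n) > 1
        )
        raise ValueError(f"substitution would duplicate tip labels: {collisions}")
    out = phy.copy()
    for leaf in out.tree.leaf_node_iter():
        if leaf.taxon.label in mapping:
            new = mapping[leaf.taxon.label]
            logger.info("substitute_tips: %s -> %s", leaf.taxon.label, new)
            leaf.taxon.label = new
    return Phylogeny(out.tree)


def graft_polytomy_tip(phy: Phylogeny, new_taxon: str, sister: str) -> Phylogeny:
    """Attach ``new_taxon`` at the parent of tip ``sister``.

    This creates (or extends) a polytomy at the sister's parent node. The new
    terminal branch copies the sister's terminal branch length, which keeps
    the pair exchangeable in the covariance matrix.
    """
    new_taxon = _normalize_label(new_taxon)
    if new_taxon in phy.tips:
        raise ValueError(f"taxon {new_taxon!r} already present in tree")
    out = phy.copy()
    sis = out._find_leaf(sister)
    parent = sis.parent_node
    if parent is None:
        raise ValueError("cannot graft at the root of a single-tip tree")
    taxon = out.tree.taxon_namespace.new_taxon(label=new_taxon)
    parent.new_child(taxon=taxon, edge_length=sis.edge.length)
    logger.info(
        "graft_polytomy_tip: %s as sister of %s (branch %.6g)",
        new_taxon, sis.taxon.label, sis.edge.length,
    )
    return Phylogeny(out.tree)


def resolve_polytomies(phy: Phylogeny, seed: int) -> Phylogeny:
    """Randomly binarize all polytomies with zero-length internal edges.

    Because the inserted edges have length 0, all pairwise tip path lengths
    (and so the phylogenetic covariance) are unchanged by the resolution.
    Identical seeds give identical output trees.
    """
    rng = np.random.default_rng(seed)
    out = phy.copy()
    for node in list(out.tree.preorder_internal_node_iter()):
        while len(node.child_nodes()) > 2:
            children = node.child_nodes()
            i, j = sorted(rng.choice(len(children), size=2, replace=False))
            a, b = children[i], children[j]
            node.remove_child(a)
            node.remove_child(b)
            merged = node.new_child(edge_length=0.0)
            merged.add_child(a)
            merged.add_child(b)
    return Phylogeny(out.tree)


@dataclass
class PhyloCovariance:
    """Phylogenetic covariance: shared root-to-tip path lengths, with lambda.

    ``matrix[i, j]`` is the depth of the MRCA of ``taxa[i]`` and ``taxa[j]``
    multiplied by ``lam`` off the diagonal; the diagonal holds root-to-tip
    distances and is never rescaled.
    """

    taxa: list[str]
    matrix: np.ndarray
    lam: float = 1.0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.taxa)
        if self.matrix.shape != (n, n):
            raise ValueError("covariance shape does not match taxa")
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("covariance matrix is not symmetric")
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError(f"lambda must be in [0, 1], got {self.lam}")

    @property
    def n(self) -> int:
        return len(self.taxa)

    def subset(self, taxa: Sequence[str]) -> "PhyloCovariance":
        """Reorder / subset to ``taxa`` (all must be present)."""
        index = {t: i for i, t in enumerate(self.taxa)}
        missing = [t for t in taxa if t not in index]
        if missing:
            raise KeyError(f"taxa not in covariance: {missing}")
        idx = np.array([index[t] for t in taxa])
        return PhyloCovariance(list(taxa), self.matrix[np.ix_(idx, idx)], self.lam)


def phylo_covariance(phy: Phylogeny) -> PhyloCovariance:
    """Build the Brownian (lambda = 1) covariance matrix from a tree.

    Computed in a single post-order pass: for each internal node of depth d,
    every pair of tips whose paths join there shares covariance d. Tips made
    indistinguishable by zero-length terminal branches (identical matrix
    rows) receive a diagonal jitter of 1e-8 x tree depth so the matrix stays
    invertible; this is logged.
    """
    labels = phy.tips
    index = {t: i for i, t in enumerate(labels)}
    n = len(labels)
    C = np.zeros((n, n))

    depth: dict[dendropy.Node, float] = {}
    for node in phy.tree.preorder_node_iter():
        parent = node.parent_node
        base = depth[parent] if parent is not None else 0.0
        edge = node.edge.length or 0.0 if parent is not None else 0.0
        depth[node] = base + edge

    leafsets: dict[dendropy.Node, list[int]] = {}
    for node in phy.tree.postorder_node_iter():
        if node.is_leaf():
            i = index[node.taxon.label]
            C[i, i] = depth[node]
            leafsets[node] = [i]
        else:
            kids = [leafsets[c] for c in node.child_nodes()]
            d = depth[node]
            for a in range(len(kids)):
                for b in range(a + 1, len(kids)):
                    for i in kids[a]:
                        for j in kids[b]:
                            C[i, j] = C[j, i] = d
            merged = [i for k in kids for i in k]
            leafsets[node] = merged

    # guard: identical rows (duplicate zero-length tips) make C singular
    tree_depth = float(np.max(np.diag(C))) if n else 0.0
    for i in range(n):
        for j in range(i + 1, n):
            if C[i, i] == C[j, j] == C[i, j]:
                eps = 1e-8 * (tree_depth or 1.0)
                C[i, i] += eps
                C[j, j] += eps
                logger.warning(
                    "phylo_covariance: tips %s and %s are indistinguishable; "
                    "applied diagonal jitter %.3g", labels[i], labels[j], eps,
                )
    return PhyloCovariance(labels, C, lam=1.0)


def apply_lambda(cov: PhyloCovariance, lam: float) -> PhyloCovariance:
    """Rescale off-diagonal covariances by Pagel's lambda."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    # compose relative to the Brownian base so apply_lambda(apply_lambda(c, a), b)
    # is not silently double-scaled: always derive from the stored matrix
    C = cov.matrix.copy()
    d = np.diag(C).copy()
    scale = lam / cov.lam if cov.lam > 0 else None
    if scale is None:
        if lam != 0.0 and not np.allclose(C, np.diag(d)):
            raise ValueError("cannot rescale a lambda=0 covariance upward")
        return PhyloCovariance(list(cov.taxa), C, lam=lam)
    out = C * scale
    np.fill_diagonal(out, d)
    return PhyloCovariance(list(cov.taxa), out, lam=lam)
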