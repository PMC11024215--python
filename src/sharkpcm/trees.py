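"""Tree ingestion, summarization and phylogenetic covariance structures.

Trees are held as :class:`dendropy.Tree` objects (rooted, branch lengths in
time units).  Everything downstream — trait likelihoods, chromosome-number
CTMCs, PGLS — consumes either a tree or the :class:`PhyloCovariance` built
here, whose entries are shared root-to-MRCA path lengths.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import dendropy
import numpy as np

__all__ = [
    "PhyloCovariance",
    "MccResult",
    "parse_newick",
    "write_newick",
    "prune",
    "tip_labels",
    "tree_depth",
    "total_branch_length",
    "resolve_polytomies",
    "mcc_tree",
    "phylo_covariance",
    "transform_tree",
]


@dataclass
class PhyloCovariance:
    """Phylogenetic covariance matrix C with C[i, j] = root-to-MRCA(i, j) path length."""

    taxa: list[str]
    matrix: np.ndarray
    transforms: dict = field(default_factory=dict)

    def index(self, label: str) -> int:
        return self.taxa.index(label)

    def subset(self, keep: Sequence[str]) -> "PhyloCovariance":
        idx = [self.taxa.index(k) for k in keep]
        return PhyloCovariance(list(keep), self.matrix[np.ix_(idx, idx)], dict(self.transforms))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.matrix, index=self.taxa, columns=self.taxa)


@dataclass
class MccResult:
    """Maximum clade credibility summary of a tree sample."""

    tree: dendropy.Tree
    log_credibility: float
    clade_frequencies: dict


def parse_newick(text: str) -> dendropy.Tree:
    """Parse a single rooted newick tree, validating labels and branch lengths."""
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", rooting="force-rooted",
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy reports line/column in its message
        raise ValueError(f"malformed newick: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate tip labels: {dupes}")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is not None and edge.length < 0:
            raise ValueError(f"negative branch length {edge.length}")
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def _clone(tree: dendropy.Tree) -> dendropy.Tree:
    return dendropy.Tree(tree)


def prune(tree: dendropy.Tree, keep: Iterable[str]) -> dendropy.Tree:
    """Restrict the tree to ``keep``, suppressing degree-2 nodes (lengths summed)."""
    keep = list(keep)
    present = set(tip_labels(tree))
    unknown = sorted(set(keep) - present)
    if unknown:
        raise ValueError(f"labels not on tree: {unknown}")
    pruned = tree.extract_tree_with_taxa_labels(keep)
    pruned.purge_taxon_namespace()
    root = pruned.seed_node
    # extraction leaves the old root-to-MRCA stem on the new root's edge;
    # keep it as an explicit unifurcation so shared root-path covariance and
    # tip depths are both preserved
    if root.edge.length:
        new_root = dendropy.Node()
        stem = root.edge.length
        pruned.seed_node = new_root
        new_root.add_child(root)
        root.edge.length = stem
    return pruned


def tree_depth(tree: dendropy.Tree) -> float:
    """Maximum root-to-tip path length."""
    return max(leaf.distance_from_root() for leaf in tree.leaf_node_iter())


def total_branch_length(tree: dendropy.Tree) -> float:
    return sum(e.length or 0.0 for e in tree.preorder_edge_iter() if e.head_node is not tree.seed_node)


def resolve_polytomies(tree: dendropy.Tree, seed: int = 0) -> dendropy.Tree:
    """Randomly resolve soft polytomies with zero-length inserted branches.

    A binary input is returned unchanged (as a copy).  Fixed seed gives an
    identical resolution.
    """
    out = _clone(tree)
    rng = random.Random(seed)
    out.resolve_polytomies(limit=2, update_bipartitions=False, rng=rng)
    for edge in out.preorder_edge_iter():
        if edge.head_node is not out.seed_node and edge.length is None:
            edge.length = 0.0
    return out


def _clade_map(tree: dendropy.Tree) -> dict:
    """Map frozenset(tip labels) -> node height (max distance to descendant tip)."""
    clades = {}
    below: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[node] = (frozenset([node.taxon.label]), 0.0)
        else:
            labels: set = set()
            height = 0.0
            for child in node.child_nodes():
                cl, ch = below[child]
                labels |= cl
                height = max(height, ch + (child.edge.length or 0.0))
            clade = frozenset(labels)
            below[node] = (clade, height)
            clades[clade] = height
    return clades


def mcc_tree(sample: Sequence[dendropy.Tree]) -> MccResult:
    """Maximum clade credibility tree of a sample sharing one taxon set.

    The returned tree is the sample member maximizing the sum of log clade
    frequencies; its node heights are replaced by the median height of each
    clade across the trees containing it (parent-child order enforced by
    clamping, tips at height 0).
    """
    sample = list(sample)
    if not sample:
        raise ValueError("empty tree sample")
    taxon_sets = {frozenset(tip_labels(t)) for t in sample}
    if len(taxon_sets) != 1:
        raise ValueError("trees do not share a taxon set")

    maps = [_clade_map(t) for t in sample]
    counts: dict = {}
    heights: dict = {}
    for m in maps:
        for clade, h in m.items():
            counts[clade] = counts.get(clade, 0) + 1
            heights.setdefault(clade, []).append(h)
    n = len(sample)
    freqs = {clade: c / n for clade, c in counts.items()}

    best_i, best_score = 0, -np.inf
    for i, m in enumerate(maps):
        score = sum(np.log(freqs[c]) for c in m)
        if score > best_score:
            best_i, best_score = i, score

    out = _clone(sample[best_i])
    # annotate node heights with clade medians and rebuild branch lengths
    below: dict = {}
    target: dict = {}
    for node in out.postorder_node_iter():
        if node.is_leaf():
            below[node] = frozenset([node.taxon.label])
            target[node] = 0.0
        else:
            clade = frozenset().union(*(below[c] for c in node.child_nodes()))
            below[node] = clade
            target[node] = float(np.median(heights[clade]))
    for node in out.preorder_node_iter():
        if node.parent_node is not None:
            target[node] = min(target[node], target[node.parent_node])
    for node in out.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = target[node.parent_node] - target[node]
    return MccResult(tree=out, log_credibility=float(best_score), clade_frequencies=freqs)


def phylo_covariance(tree: dendropy.Tree, order: Sequence[str] | None = None) -> PhyloCovariance:
    """Shared-path-length matrix: C[i, j] = depth of MRCA(i, j), C[i, i] = tip depth."""
    for edge in tree.preorder_edge_iter():
        if edge.head_node is not tree.seed_node and edge.length is not None and edge.length < 0:
            raise ValueError("negative branch length")
    labels = tip_labels(tree)
    if order is None:
        order = labels
    else:
        missing = sorted(set(order) - set(labels))
        if missing:
            raise ValueError(f"taxa not on tree: {missing}")
    idx = {lab: i for i, lab in enumerate(order)}
    m = len(order)
    C = np.zeros((m, m))
    depth: dict = {}
    below: dict = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        depth[node] = 0.0 if parent is None else depth[parent] + (node.edge.length or 0.0)
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            lab = node.taxon.label
            below[node] = [lab] if lab in idx else []
            if lab in idx:
                C[idx[lab], idx[lab]] = depth[node]
        else:
            groups = [below[c] for c in node.child_nodes()]
            d = depth[node]
            for a in range(len(groups)):
                for b in range(a + 1, len(groups)):
                    for la in groups[a]:
                        for lb in groups[b]:
                            C[idx[la], idx[lb]] = d
                            C[idx[lb], idx[la]] = d
            below[node] = [l for g in groups for l in g]
    return PhyloCovariance(list(order), C)


def _lambda_cov(cov: PhyloCovariance, lam: float) -> PhyloCovariance:
    C = cov.matrix.copy()
    off = ~np.eye(C.shape[0], dtype=bool)
    C[off] *= lam
    t = dict(cov.transforms)
    t["lambda"] = lam
    return PhyloCovariance(list(cov.taxa), C, t)


def transform_tree(obj, kind: str, value: float):
    """Pagel lambda/delta/kappa transforms and total-length normalization.

    ``lambda`` acts on a :class:`PhyloCovariance` (a tree is converted first)
    and multiplies off-diagonal entries by ``value``; ``delta`` raises node
    depths (normalized by tree depth) to ``value`` and rescales to the original
    depth; ``kappa`` raises each branch length to ``value`` (0**0 = 1);
    ``normalize_length`` divides branch lengths by their sum.
    """
    if value < 0:
        raise ValueError("transform value must be >= 0")
    if kind == "lambda":
        if value > 1:
            raise ValueError("lambda must be in [0, 1]")
        cov = obj if isinstance(obj, PhyloCovariance) else phylo_covariance(obj)
        return _lambda_cov(cov, value)
    if not isinstance(obj, dendropy.Tree):
        raise TypeError(f"{kind} transform requires a tree")
    out = _clone(obj)
    if kind == "delta":
        depth: dict = {}
        for node in out.preorder_node_iter():
            parent = node.parent_node
            depth[node] = 0.0 if parent is None else depth[parent] + (node.edge.length or 0.0)
        T = max(depth[l] for l in out.leaf_node_iter())
        if T <= 0:
            return out
        new = {n: T * (d / T) ** value if d > 0 else 0.0 for n, d in depth.items()}
        for node in out.preorder_node_iter():
            if node.parent_node is not None:
                node.edge.length = new[node] - new[node.parent_node]
        return out
    if kind == "kappa":
        for edge in out.preorder_edge_iter():
            if edge.head_node is out.seed_node:
                continue
            b = edge.length or 0.0
            edge.length = 1.0 if (b == 0 and value == 0) else b ** value
        return out
    if kind == "normalize_length":
        total = total_branch_length(out)
        if total <= 0:
            raise ValueError("tree has zero total branch length")
        for edge in out.preorder_edge_iter():
            if edge.head_node is not out.seed_node and edge.length is not None:
                edge.length /= total
        return out
    raise ValueError(f"unknown transform kind: {kind}")
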