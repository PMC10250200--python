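"""Phylogeny handling: parsing, covariance construction, replicate augmentation.

Trees are the source of all covariance structure in the comparative analyses:
the phylogenetic random effect of a mixed model and the GLS correlation of the
path analysis are both built from shared root-to-ancestor path lengths. Trees
are stored rooted; branch lengths are in arbitrary (time) units.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "Phylogeny",
    "TreeEnsemble",
    "PhyloCovariance",
    "TreeParseError",
    "parse_newick",
    "parse_tree_sample",
    "phylo_covariance",
    "augment_with_replicates",
]


class TreeParseError(ValueError):
    """Raised for malformed or inconsistent tree input."""


class Phylogeny:
    """A rooted tree with branch lengths, wrapping a dendropy tree.

    Tip labels must be unique and branch lengths non-negative.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._validate()

    # -- construction ------------------------------------------------------
    @classmethod
    def from_newick(cls, text: str) -> "Phylogeny":
        return parse_newick(text)

    def _validate(self) -> None:
        labels = self.tip_labels
        if len(labels) != len(set(labels)):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise TreeParseError(f"duplicate tip labels: {dupes}")
        for edge in self._tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise TreeParseError(
                    f"negative branch length {edge.length} on edge above "
                    f"{_node_name(edge.head_node)}"
                )

    # -- basic accessors ---------------------------------------------------
    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self._tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self._tree.leaf_node_iter())

    def tip_depths(self) -> dict[str, float]:
        """Root-to-tip path length per tip."""
        depths = {}
        for leaf, d in self._node_depths().items():
            if leaf.is_leaf():
                depths[leaf.taxon.label] = d
        return depths

    def _node_depths(self) -> dict[dendropy.Node, float]:
        depths: dict[dendropy.Node, float] = {}
        for node in self._tree.preorder_node_iter():
            parent = node.parent_node
            edge = node.edge.length or 0.0
            depths[node] = (depths[parent] if parent is not None else 0.0) + (
                edge if parent is not None else 0.0
            )
        return depths

    @property
    def depth(self) -> float:
        """Maximum root-to-tip distance."""
        return max(self.tip_depths().values())

    def is_ultrametric(self, rtol: float = 1e-6) -> bool:
        depths = np.array(list(self.tip_depths().values()))
        dmax = depths.max()
        if dmax == 0:
            return True
        return bool(np.all(np.abs(depths - dmax) <= rtol * dmax))

    # -- serialization -----------------------------------------------------
    def to_newick(self) -> str:
        s = self._tree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        ).strip()
        return s

    def copy(self) -> "Phylogeny":
        return parse_newick(self.to_newick())

    def __repr__(self) -> str:  # pragma: no cover
        return f"Phylogeny(n_tips={self.n_tips}, depth={self.depth:.4g})"


def _node_name(node: dendropy.Node) -> str:
    if node.taxon is not None:
        return node.taxon.label
    return "<internal>"


def parse_newick(text: str) -> Phylogeny:
    """Parse a single rooted Newick statement.

    Raises :class:`TreeParseError` on unbalanced parentheses, duplicate tip
    labels, negative branch lengths, or explicit unrooted annotation.
    """
    text = text.strip()
    if not text:
        raise TreeParseError("empty Newick input")
    if text.count("(") != text.count(")"):
        raise TreeParseError(
            f"unbalanced parentheses: {text.count('(')} '(' vs {text.count(')')} ')'"
        )
    if "[&U]" in text or "[&u]" in text:
        raise TreeParseError("explicitly unrooted tree rejected; trees are stored rooted")
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            rooting="default-rooted",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises assorted error types
        raise TreeParseError(f"Newick parse failure: {exc}") from exc
    return Phylogeny(tree)


@dataclass
class TreeEnsemble:
    """An ordered sample of trees over one shared tip set.

    Order matters: the chained MCMC procedure consumes trees in sequence.
    """

    trees: list[Phylogeny]
    source: str = ""

    def __post_init__(self) -> None:
        if not self.trees:
            raise TreeParseError("empty tree ensemble")
        ref = set(self.trees[0].tip_labels)
        for i, t in enumerate(self.trees[1:], start=2):
            tips = set(t.tip_labels)
            if tips != ref:
                diff = sorted(tips.symmetric_difference(ref))
                raise TreeParseError(
                    f"tree {i} has a different tip set; symmetric difference: {diff}"
                )

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees)

    def __getitem__(self, i: int) -> Phylogeny:
        return self.trees[i]

    @property
    def tip_labels(self) -> list[str]:
        return self.trees[0].tip_labels


def parse_tree_sample(text: str, format: str = "newick-lines") -> TreeEnsemble:
    """Parse a multi-tree sample (e.g. a posterior sample of trees).

    Parameters
    ----------
    text:
        File contents: one Newick statement per line, or a NEXUS document with
        a trees block (translate tables supported).
    format:
        ``"newick-lines"`` or ``"nexus-trees"``.
    """
    if format == "newick-lines":
        lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
        trees = [parse_newick(ln) for ln in lines]
        return TreeEnsemble(trees, source="newick-lines")
    if format == "nexus-trees":
        try:
            tl = dendropy.TreeList.get(
                data=text,
                schema="nexus",
                rooting="default-rooted",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except Exception as exc:
            raise TreeParseError(f"NEXUS parse failure: {exc}") from exc
        trees = [parse_newick(t.as_string(schema="newick").strip()) for t in tl]
        if not trees:
            raise TreeParseError("no trees found in NEXUS input")
        return TreeEnsemble(trees, source="nexus-trees")
    raise ValueError(f"unknown tree sample format: {format!r}")


@dataclass
class PhyloCovariance:
    """A labelled phylogenetic (co)variance matrix of shared path lengths."""

    labels: list[str]
    matrix: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match labels")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.labels, columns=self.labels)

    def to_csv(self, path_or_buf) -> None:
        self.to_dataframe().to_csv(path_or_buf)

    @classmethod
    def from_csv(cls, path_or_buf) -> "PhyloCovariance":
        df = pd.read_csv(path_or_buf, index_col=0)
        return cls(labels=list(df.index), matrix=df.to_numpy())

    def reorder(self, labels: list[str]) -> "PhyloCovariance":
        """Restrict/permute to the given labels (all must be present)."""
        missing = [l for l in labels if l not in self.labels]
        if missing:
            raise KeyError(f"labels not in covariance: {missing}")
        idx = [self.labels.index(l) for l in labels]
        return PhyloCovariance(list(labels), self.matrix[np.ix_(idx, idx)])

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.matrix).min())


def phylo_covariance(tree: Phylogeny, as_correlation: bool = False) -> PhyloCovariance:
    """Covariance matrix of shared root-to-MRCA path lengths between tips.

    Entry (i, j) is the depth of the most recent common ancestor of tips i and
    j; the diagonal is the root-to-tip depth. With ``as_correlation`` the
    matrix is divided by the tree depth (ultrametric trees only), giving unit
    diagonal.
    """
    if tree.n_tips < 2:
        raise ValueError("covariance requires a tree with >= 2 tips")
    depths = tree._node_depths()
    labels = tree.tip_labels
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    C = np.zeros((n, n))
    # leaf sets per node, postorder; covariance between tips in different
    # child subtrees equals the depth of their joining node
    leafsets: dict[dendropy.Node, list[int]] = {}
    for node in tree._tree.postorder_node_iter():
        if node.is_leaf():
            i = index[node.taxon.label]
            C[i, i] = depths[node]
            leafsets[node] = [i]
        else:
            children = [leafsets[c] for c in node.child_nodes()]
            d = depths[node]
            for a in range(len(children)):
                for b in range(a + 1, len(children)):
                    ia = np.array(children[a])
                    ib = np.array(children[b])
                    C[np.ix_(ia, ib)] = d
                    C[np.ix_(ib, ia)] = d
            leafsets[node] = [i for ch in children for i in ch]
    if as_correlation:
        if not tree.is_ultrametric():
            raise ValueError("as_correlation requires an ultrametric tree")
        C = C / tree.depth
    return PhyloCovariance(labels, C)


def augment_with_replicates(
    tree: Phylogeny,
    mapping: dict[str, dict[str, list[str]]],
    tip_length: float | None = None,
) -> Phylogeny:
    """Bind replicate tips to a species tree for repeated-measures analyses.

    For each species tip, a polytomy of strain nodes is attached, and each
    strain node receives one tip per observation id. The resulting tree's tips
    are the observation ids, so its covariance matrix has one row per
    observation with within-strain blocks sharing the full species path.

    Parameters
    ----------
    mapping:
        ``{species: {strain: [observation ids]}}``. Every species must be a
        tip of ``tree``; observation ids must be globally unique.
    tip_length:
        Branch length of the added strain and observation edges. Defaults to
        ``1e-6 *`` tree depth, keeping the augmented covariance strictly
        positive-definite for GLS while remaining numerically negligible.
    """
    tips = set(tree.tip_labels)
    missing = [sp for sp in mapping if sp not in tips]
    if missing:
        raise KeyError(f"species not found in tree: {sorted(missing)}")
    all_obs: list[str] = []
    for strains in mapping.values():
        for obs_ids in strains.values():
            all_obs.extend(obs_ids)
    if len(all_obs) != len(set(all_obs)):
        dupes = sorted({o for o in all_obs if all_obs.count(o) > 1})
        raise ValueError(f"observation ids not globally unique: {dupes}")
    if tip_length is None:
        tip_length = 1e-6 * tree.depth
    if tip_length < 0:
        raise ValueError("tip_length must be non-negative")

    # fresh dendropy tree (independent namespace) we can mutate
    dt = dendropy.Tree.get(
        data=tree.to_newick(),
        schema="newick",
        rooting="default-rooted",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
    ns = dt.taxon_namespace
    leaves = {leaf.taxon.label: leaf for leaf in dt.leaf_node_iter()}
    for species, strains in mapping.items():
        node = leaves[species]
        node.taxon = None
        for strain, obs_ids in strains.items():
            strain_node = node.new_child(edge_length=tip_length)
            for obs in obs_ids:
                strain_node.new_child(
                    taxon=ns.new_taxon(label=obs), edge_length=tip_length
                )
    # drop species tips not in the mapping? No: they remain ordinary tips.
    return Phylogeny(dt)
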