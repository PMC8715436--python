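"""Lineage-tree utilities: patristic distances, ancestral presence/absence
reconstruction, and gain/loss counting.

The tree's leaves are lineages, not individual genomes.  A gene counts as
present in a lineage as soon as a single genome of that lineage carries it
(within-lineage frequency is deliberately ignored here), so the binary
character handed to the reconstruction describes lineage-level occupancy.

Ancestral states use accelerated transformation (ACCTRAN): among the
minimum-change (maximum-parsimony) assignments of presence/absence to the
internal nodes, state changes are placed as close to the root as possible.
Gains (absence -> presence along a branch) and losses are then read off the
reconstruction, per gene and per branch.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import dendropy
import numpy as np
import pandas as pd

from .errors import ValidationError

#: effectively-infinite cost for a leaf forced into its unobserved state
_INF = np.int64(1) << 40


def read_tree(source) -> dendropy.Tree:
    """Read a rooted Newick tree whose leaf labels are lineage ids.

    ``source`` may be a path or a Newick string.
    """
    text = None
    if isinstance(source, str) and source.lstrip().startswith("("):
        text = source
    if text is None:
        with open(source, encoding="utf-8") as fh:
            text = fh.read()
    tree = dendropy.Tree.get(
        data=text, schema="newick", preserve_underscores=True,
        suppress_internal_node_taxa=False,
    )
    tree.is_rooted = True
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise ValidationError("tree has duplicate leaf labels")
    return tree


def _node_label(node: dendropy.Node, counter: dict) -> str:
    if node.taxon is not None and node.taxon.label:
        return node.taxon.label
    if node.label:
        return node.label
    counter["n"] += 1
    return f"node{counter['n']}"


@dataclass
class TreeIndex:
    """Flat arrays describing a rooted tree in postorder.

    ``parent[i]`` is the postorder index of node i's parent (-1 for the
    root); ``labels[i]`` names node i (leaf label, internal label, or a
    generated ``nodeK``); ``lengths[i]`` is the branch length above node i.
    """

    labels: list[str]
    parent: np.ndarray
    lengths: np.ndarray
    is_leaf: np.ndarray

    @property
    def root(self) -> int:
        return len(self.labels) - 1

    @property
    def leaf_labels(self) -> list[str]:
        return [l for l, leaf in zip(self.labels, self.is_leaf) if leaf]


def index_tree(tree: dendropy.Tree) -> TreeIndex:
    """Index a dendropy tree into postorder arrays (root last)."""
    nodes = list(tree.postorder_node_iter())
    pos = {id(n): i for i, n in enumerate(nodes)}
    counter = {"n": 0}
    labels, parent, lengths, is_leaf = [], [], [], []
    seen = set()
    for node in nodes:
        lab = _node_label(node, counter)
        while lab in seen:  # defensively uniquify generated labels
            counter["n"] += 1
            lab = f"node{counter['n']}"
        seen.add(lab)
        labels.append(lab)
        parent.append(pos[id(node.parent_node)] if node.parent_node else -1)
        lengths.append(node.edge.length if node.edge.length is not None else np.nan)
        is_leaf.append(node.is_leaf())
    return TreeIndex(
        labels=labels,
        parent=np.asarray(parent, dtype=np.int64),
        lengths=np.asarray(lengths, dtype=float),
        is_leaf=np.asarray(is_leaf, dtype=bool),
    )


def patristic_distances(tree: dendropy.Tree) -> pd.DataFrame:
    """Symmetric leaf-by-leaf matrix of path-length (patristic) distances."""
    for edge in tree.preorder_edge_iter():
        if edge.head_node.parent_node is not None and edge.length is None:
            raise ValidationError(
                "tree has a branch without a length; patristic distances "
                "need a fully length-annotated tree"
            )
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    taxa = [t for t in taxa if any(l.taxon is t for l in tree.leaf_node_iter())]
    labels = [t.label for t in taxa]
    mat = np.zeros((len(taxa), len(taxa)))
    for i, a in enumerate(taxa):
        for j, b in enumerate(taxa):
            if i < j:
                d = pdm.patristic_distance(a, b)
                mat[i, j] = mat[j, i] = d
    return pd.DataFrame(mat, index=labels, columns=labels)


def lineage_presence(matrix: pd.DataFrame, assignment: pd.Series) -> pd.DataFrame:
    """Binary genes x lineages table: 1 iff >= 1 genome of the lineage
    carries the gene (the within-lineage frequency is ignored)."""
    common = [g for g in matrix.columns if g in assignment.index]
    if not common:
        raise ValidationError("no matrix genome has a lineage assignment")
    sub = matrix[common]
    groups = assignment.loc[common]
    counts = sub.astype(np.int64).T.groupby(groups).sum().T
    return (counts > 0).astype(np.int8)


def check_lineages_on_tree(tree_index: TreeIndex, lineages) -> None:
    missing = sorted(set(lineages) - set(tree_index.leaf_labels))
    if missing:
        raise ValidationError(
            f"lineage(s) missing from the tree leaves: {missing}"
        )


@dataclass
class AncestralStates:
    """ACCTRAN reconstruction for a batch of genes on one tree.

    ``states``: genes x nodes DataFrame of 0/1 (columns in postorder,
    root last).  ``downpass``: same shape, Fitch downpass state-sets coded
    0 -> {absent}, 1 -> {present}, 2 -> {absent, present}.
    """

    states: pd.DataFrame
    downpass: pd.DataFrame
    tree_index: TreeIndex


def acctran_reconstruct(
    tree, leaf_states: pd.DataFrame, ambiguous_root_state: int = 0
) -> AncestralStates:
    """Minimum-change ancestral presence/absence with rootward changes.

    Parameters
    ----------
    tree : dendropy.Tree or TreeIndex.
    leaf_states : genes x leaves DataFrame of 0/1; every tree leaf must
        have a column.
    ambiguous_root_state : state taken by the root when both states are
        equally parsimonious there.  The default (absent) reads a
        phyletically restricted gene as gained within the tree rather than
        ancestrally present and repeatedly lost.

    Notes
    -----
    The downpass is a binary Sankoff recursion (handles polytomies); the
    preorder resolution gives each node the state minimising
    branch-change-plus-subtree cost given its parent's state, breaking
    exact ties toward the state *opposite* the parent.  The tie-break is
    what accelerates transformations: an ambiguous node absorbs the change
    on its own (rootward) branch instead of deferring it to its children.
    """
    idx = tree if isinstance(tree, TreeIndex) else index_tree(tree)
    leaves = idx.leaf_labels
    missing = [l for l in leaves if l not in leaf_states.columns]
    if missing:
        raise ValidationError(f"leaf state(s) missing for: {missing[:5]}")

    n_nodes = len(idx.labels)
    n_genes = leaf_states.shape[0]
    obs = leaf_states[leaves].to_numpy().astype(np.int64)
    if not np.isin(obs, (0, 1)).all():
        raise ValidationError("leaf states must be 0/1")

    # cost[s][i, v] = min changes in subtree of node v given state s at v
    cost = np.zeros((2, n_genes, n_nodes), dtype=np.int64)
    leaf_pos = {lab: k for k, lab in enumerate(leaves)}
    for v, lab in enumerate(idx.labels):
        if idx.is_leaf[v]:
            s = obs[:, leaf_pos[lab]]
            cost[0][:, v] = np.where(s == 0, 0, _INF)
            cost[1][:, v] = np.where(s == 1, 0, _INF)
    for v in range(n_nodes):  # postorder: children precede parents
        p = idx.parent[v]
        if p < 0:
            continue
        through0 = np.minimum(cost[0][:, v], cost[1][:, v] + 1)
        through1 = np.minimum(cost[1][:, v], cost[0][:, v] + 1)
        cost[0][:, p] += through0
        cost[1][:, p] += through1

    # Fitch downpass sets (for reporting): 0/1 singleton or 2 = {0,1}
    down = np.where(
        cost[0] < cost[1], 0, np.where(cost[1] < cost[0], 1, 2)
    ).astype(np.int8)

    states = np.zeros((n_genes, n_nodes), dtype=np.int8)
    r = idx.root
    root_state = np.where(
        cost[0][:, r] < cost[1][:, r], 0,
        np.where(cost[1][:, r] < cost[0][:, r], 1, ambiguous_root_state),
    )
    states[:, r] = root_state
    for v in range(n_nodes - 2, -1, -1):  # preorder: parents precede children
        p = idx.parent[v]
        sp = states[:, p].astype(np.int64)
        cost_keep = cost[0][:, v] * (1 - sp) + cost[1][:, v] * sp
        cost_flip = cost[1][:, v] * (1 - sp) + cost[0][:, v] * sp + 1
        # flip on ties: the change lands on this (rootward) branch
        states[:, v] = np.where(cost_flip <= cost_keep, 1 - sp, sp)

    cols = pd.Index(idx.labels, name="node")
    genes = leaf_states.index
    return AncestralStates(
        states=pd.DataFrame(states, index=genes, columns=cols),
        downpass=pd.DataFrame(down, index=genes, columns=cols),
        tree_index=idx,
    )


@dataclass
class GainLossCounts:
    """Gain/loss tallies from an ancestral reconstruction.

    ``per_gene``: DataFrame gene -> n_gains, n_losses.
    ``per_branch``: DataFrame branch (named by its child node) -> gains,
    losses; ``per_branch_by_class`` adds a distribution-class level when a
    classification was supplied.
    """

    per_gene: pd.DataFrame
    per_branch: pd.DataFrame
    per_branch_by_class: pd.DataFrame | None = None


def count_gain_loss(
    states: AncestralStates,
    classification: Mapping[str, str] | pd.Series | None = None,
) -> GainLossCounts:
    """Count absence->presence (gain) and presence->absence (loss) events
    along every branch of the reconstruction."""
    idx = states.tree_index
    s = states.states.to_numpy()
    child_nodes = [v for v in range(len(idx.labels)) if idx.parent[v] >= 0]
    gains = np.zeros((s.shape[0], len(child_nodes)), dtype=np.int64)
    losses = np.zeros_like(gains)
    for k, v in enumerate(child_nodes):
        p = idx.parent[v]
        gains[:, k] = (s[:, p] == 0) & (s[:, v] == 1)
        losses[:, k] = (s[:, p] == 1) & (s[:, v] == 0)

    genes = states.states.index
    per_gene = pd.DataFrame(
        {"n_gains": gains.sum(axis=1), "n_losses": losses.sum(axis=1)},
        index=genes,
    )
    branch_names = pd.Index([idx.labels[v] for v in child_nodes], name="branch")
    per_branch = pd.DataFrame(
        {"gains": gains.sum(axis=0), "losses": losses.sum(axis=0)},
        index=branch_names,
    )
    per_class = None
    if classification is not None:
        cls = pd.Series(classification).reindex(genes)
        if cls.isna().any():
            raise ValidationError(
                f"gene(s) missing from classification: "
                f"{genes[cls.isna()].tolist()[:5]}"
            )
        rows = []
        for c in sorted(cls.unique()):
            mask = (cls == c).to_numpy()
            rows.append(pd.DataFrame({
                "branch": branch_names,
                "distribution_class": c,
                "gains": gains[mask].sum(axis=0),
                "losses": losses[mask].sum(axis=0),
            }))
        per_class = pd.concat(rows, ignore_index=True)
    return GainLossCounts(
        per_gene=per_gene, per_branch=per_branch, per_branch_by_class=per_class
    )
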