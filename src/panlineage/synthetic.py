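"""Seed-deterministic generators with known ground truth.

Two generators back the test surface of every other module:

* ``plant_pangenome`` builds a presence/absence matrix over a multi-lineage
  collection in which each planted gene realises a chosen distribution
  class exactly (at zero noise), emulating the shape of real clinical
  collections — including the heavy over-representation of a few lineages
  that motivates population-structure-aware classification.
* ``simulate_gain_loss`` evolves binary presence along a lineage tree as a
  two-state Markov jump process and records the true event log, giving an
  independent truth for ancestral-state reconstruction.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .classify import Thresholds, assign_distribution_class
from .errors import ValidationError
from .phylo import index_tree, read_tree


@dataclass(frozen=True)
class PlantedGene:
    """One gene with prescribed within-lineage labels.

    ``labels`` maps lineage id -> label in {core, intermediate, rare};
    lineages not listed are absent.  ``frequencies`` may pin exact
    within-lineage frequencies; otherwise a representative frequency for
    the label is used (1.0 for core, 0.5 for intermediate, the largest
    frequency strictly below the rare cut-off for rare).
    """

    name: str
    labels: Mapping[str, str]
    frequencies: Mapping[str, float] | None = None


def skewed_lineage_sizes(
    n_lineages: int, total_genomes: int, dominant_fraction: float = 0.5
) -> list[int]:
    """Lineage sizes with one lineage holding ``dominant_fraction`` of all
    genomes and the rest split evenly — the over-sampling pattern typical
    of clinical genome collections."""
    if n_lineages < 1:
        raise ValidationError("need >= 1 lineage")
    if n_lineages == 1:
        return [total_genomes]
    big = max(1, int(round(total_genomes * dominant_fraction)))
    rest, extra = divmod(total_genomes - big, n_lineages - 1)
    sizes = [big] + [rest + (1 if i < extra else 0) for i in range(n_lineages - 1)]
    if min(sizes) < 1:
        raise ValidationError("total_genomes too small for the requested lineages")
    return sizes


@dataclass
class PlantSpec:
    """Specification of a planted pan-genome.

    ``genomes_per_lineage`` may be a single size, an explicit size list, or
    None for the default skewed layout (one lineage holding ~50 % of the
    genomes).  ``genes`` of None plants the default panel of 13 genes, one
    per distribution class.  ``noise`` flips each cell independently.
    """

    n_lineages: int = 10
    genomes_per_lineage: int | Sequence[int] | None = None
    genes: Sequence[PlantedGene] | None = None
    noise: float = 0.0
    seed: int = 0
    thresholds: Thresholds = field(default_factory=Thresholds)

    def __post_init__(self) -> None:
        if not (0 <= self.noise < 0.5):
            raise ValidationError("noise must be in [0, 0.5)")
        if self.n_lineages < 1:
            raise ValidationError("need >= 1 lineage")

    def lineage_ids(self) -> list[str]:
        return [f"L{i + 1}" for i in range(self.n_lineages)]

    def sizes(self) -> list[int]:
        if self.genomes_per_lineage is None:
            return skewed_lineage_sizes(self.n_lineages, 60 * self.n_lineages)
        if isinstance(self.genomes_per_lineage, int):
            return [self.genomes_per_lineage] * self.n_lineages
        sizes = list(self.genomes_per_lineage)
        if len(sizes) != self.n_lineages:
            raise ValidationError("one size per lineage required")
        return sizes


def default_planted_genes(
    lineage_ids: Sequence[str], rng: np.random.Generator
) -> list[PlantedGene]:
    """One planted gene per distribution class.

    Multi-lineage classes occupy a seeded random subset of 2..N-1
    lineages; varied classes place each of their labels in one (or more)
    lineages.  Requires >= 3 lineages.
    """
    L = list(lineage_ids)
    if len(L) < 3:
        raise ValidationError("default gene panel needs >= 3 lineages")
    genes: list[PlantedGene] = []

    def pick(k: int) -> list[str]:
        return sorted(rng.choice(L, size=k, replace=False).tolist())

    for label in ("core", "intermediate", "rare"):
        genes.append(PlantedGene(f"collection_{label}", {l: label for l in L}))
        k = int(rng.integers(2, len(L)))  # multiple but not all
        genes.append(PlantedGene(f"multi_lineage_{label}",
                                 {l: label for l in pick(k)}))
        genes.append(PlantedGene(f"lineage_specific_{label}", {pick(1)[0]: label}))
    combos = [
        ("core_and_intermediate", ("core", "intermediate")),
        ("core_and_rare", ("core", "rare")),
        ("intermediate_and_rare", ("intermediate", "rare")),
        ("core_intermediate_and_rare", ("core", "intermediate", "rare")),
    ]
    for name, labels in combos:
        chosen = pick(len(labels))
        genes.append(PlantedGene(name, dict(zip(chosen, labels))))
    return genes


def _carriers_for_label(label: str, n: int, thresholds: Thresholds) -> int:
    """A carrier count realising the label in a lineage of size n."""
    core_cut = thresholds.core_cutoff(n)
    inter_cut = thresholds.intermediate_cutoff(n)
    if label == "core":
        return n
    if label == "intermediate":
        c = int(round(n / 2))
        if not (inter_cut <= c < core_cut):
            c = inter_cut
        if c >= core_cut:
            raise ValidationError(
                f"lineage of size {n} cannot realise an intermediate "
                f"frequency under the thresholds"
            )
        return c
    if label == "rare":
        c = inter_cut - 1
        if c < 1:
            raise ValidationError(
                f"lineage of size {n} cannot realise a rare frequency "
                f"under the thresholds"
            )
        return c
    raise ValidationError(f"unknown label {label!r}")


def plant_pangenome(
    spec: PlantSpec,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Build (matrix, assignment, truth) realising the planted classes.

    At ``noise=0`` classification under ``spec.thresholds`` recovers every
    planted gene's class exactly; the returned truth table carries the
    expected class per gene.
    """
    rng = np.random.default_rng(spec.seed)
    lineages = spec.lineage_ids()
    sizes = spec.sizes()
    genomes = []
    lineage_of = []
    for lin, n in zip(lineages, sizes):
        for k in range(n):
            genomes.append(f"{lin}_g{k + 1}")
            lineage_of.append(lin)
    assignment = pd.Series(lineage_of, index=pd.Index(genomes, name="genome_id"),
                           name="lineage_id")

    genes = list(spec.genes) if spec.genes is not None else \
        default_planted_genes(lineages, rng)
    size_of = dict(zip(lineages, sizes))
    start = {}
    ofs = 0
    for lin, n in zip(lineages, sizes):
        start[lin] = ofs
        ofs += n

    matrix = np.zeros((len(genes), len(genomes)), dtype=np.int8)
    truth_rows = []
    for gi, gene in enumerate(genes):
        bad = set(gene.labels.values()) - {"core", "intermediate", "rare"}
        if bad:
            raise ValidationError(f"gene {gene.name!r}: invalid label(s) {sorted(bad)}")
        unknown = set(gene.labels) - set(lineages)
        if unknown:
            raise ValidationError(
                f"gene {gene.name!r}: unknown lineage(s) {sorted(unknown)}"
            )
        for lin, label in gene.labels.items():
            n = size_of[lin]
            if gene.frequencies and lin in gene.frequencies:
                c = int(round(gene.frequencies[lin] * n))
                realised = _label_of_count(c, n, spec.thresholds)
                if realised != label:
                    raise ValidationError(
                        f"gene {gene.name!r}: frequency "
                        f"{gene.frequencies[lin]} in lineage {lin} labels as "
                        f"{realised!r}, not {label!r}"
                    )
            else:
                c = _carriers_for_label(label, n, spec.thresholds)
            carriers = rng.choice(n, size=c, replace=False)
            matrix[gi, start[lin] + carriers] = 1
        labels_all = [gene.labels.get(l, "absent") for l in lineages]
        truth_rows.append({
            "gene_id": gene.name,
            "distribution_class": assign_distribution_class(labels_all, len(lineages)),
        })

    if spec.noise > 0:
        flips = rng.random(matrix.shape) < spec.noise
        matrix = np.where(flips, 1 - matrix, matrix).astype(np.int8)

    gene_ids = pd.Index([g.name for g in genes], name="gene_id")
    if gene_ids.has_duplicates:
        raise ValidationError("duplicate planted gene names")
    mat = pd.DataFrame(matrix, index=gene_ids, columns=genomes)
    truth = pd.DataFrame(truth_rows).set_index("gene_id")
    return mat, assignment, truth


def _label_of_count(c: int, n: int, thresholds: Thresholds) -> str:
    if c == 0:
        return "absent"
    if c >= thresholds.core_cutoff(n):
        return "core"
    if c >= thresholds.intermediate_cutoff(n):
        return "intermediate"
    return "rare"


def mobile_gene_collection(
    n_lineages: int = 47,
    min_size: int = 20,
    max_size: int = 400,
    n_mobile: int = 400,
    n_core: int = 30,
    carriage: tuple[float, float] = (0.003, 0.03),
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """A collection with size-driven *raw* gene sharing and none after
    size correction.

    Lineage sizes are log-spaced between ``min_size`` and ``max_size``
    (few large, many small lineages — the sampling bias of real
    collections).  Each mobile gene is carried by every genome
    independently with a per-gene probability drawn from ``carriage``, so
    the chance a lineage contains a carrier grows with lineage size: raw
    pairwise sharing counts correlate with lineage size by construction.
    Because carriage is i.i.d. per genome, any fixed-size subsample of a
    lineage has a size-independent carrier distribution, so corrected
    counts carry no size signal.  ``n_core`` all-present genes are added
    as background.
    """
    rng = np.random.default_rng(seed)
    sizes = np.round(
        np.logspace(np.log10(min_size), np.log10(max_size), n_lineages)
    ).astype(int)
    lineages = [f"L{i + 1}" for i in range(n_lineages)]
    genomes, lineage_of = [], []
    for lin, n in zip(lineages, sizes):
        for k in range(n):
            genomes.append(f"{lin}_g{k + 1}")
            lineage_of.append(lin)
    assignment = pd.Series(
        lineage_of, index=pd.Index(genomes, name="genome_id"), name="lineage_id"
    )
    p = rng.uniform(*carriage, size=n_mobile)
    mobile = (rng.random((n_mobile, len(genomes))) < p[:, None]).astype(np.int8)
    core = np.ones((n_core, len(genomes)), dtype=np.int8)
    gene_ids = [f"mobile{i + 1}" for i in range(n_mobile)] + [
        f"core{i + 1}" for i in range(n_core)
    ]
    matrix = pd.DataFrame(
        np.vstack([mobile, core]),
        index=pd.Index(gene_ids, name="gene_id"),
        columns=genomes,
    )
    return matrix, assignment


@dataclass
class GainLossSimSpec:
    """Specification of a gain/loss simulation on a lineage tree.

    ``tree`` is a Newick string (or None to simulate a birth-death tree
    with ``n_leaves`` leaves).  ``gain_rate`` / ``loss_rate`` are the
    per-branch-length-unit jump rates; ``root_present_prob`` of None uses
    the stationary probability gain/(gain+loss).
    """

    n_genes: int = 100
    tree: str | None = None
    n_leaves: int = 10
    birth_rate: float = 1.0
    gain_rate: float = 0.1
    loss_rate: float = 0.1
    root_present_prob: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gain_rate < 0 or self.loss_rate < 0:
            raise ValidationError("rates must be >= 0")
        if self.root_present_prob is not None and not (
            0 <= self.root_present_prob <= 1
        ):
            raise ValidationError("root_present_prob must be in [0, 1]")


def _simulated_tree(spec: GainLossSimSpec) -> dendropy.Tree:
    if spec.tree is not None:
        return read_tree(spec.tree)
    from dendropy.simulate import treesim

    tree = treesim.birth_death_tree(
        birth_rate=spec.birth_rate,
        death_rate=0.0,
        num_extant_tips=spec.n_leaves,
        rng=random.Random(spec.seed),
    )
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"L{i + 1}"
    tree.is_rooted = True
    return tree


def simulate_gain_loss(
    spec: GainLossSimSpec,
) -> tuple[dendropy.Tree, pd.DataFrame, pd.DataFrame]:
    """Simulate presence/absence evolution; return (tree, leaf_states,
    events).

    ``leaf_states`` is genes x leaves (0/1); ``events`` is a long-form log
    with one row per true transition: gene_id, branch (named by the child
    node), event ('gain'/'loss').  Branches without a length evolve over
    length 1.
    """
    tree = _simulated_tree(spec)
    idx = index_tree(tree)
    rng = np.random.default_rng(spec.seed)
    p_root = (
        spec.root_present_prob
        if spec.root_present_prob is not None
        else (
            spec.gain_rate / (spec.gain_rate + spec.loss_rate)
            if spec.gain_rate + spec.loss_rate > 0
            else 0.0
        )
    )

    n_nodes = len(idx.labels)
    gene_ids = [f"gene{g + 1}" for g in range(spec.n_genes)]
    states = np.zeros((spec.n_genes, n_nodes), dtype=np.int8)
    events = []
    root = idx.root
    states[:, root] = rng.random(spec.n_genes) < p_root
    # preorder walk: simulate each branch as a two-state jump process
    for v in range(n_nodes - 2, -1, -1):
        p = idx.parent[v]
        t_total = idx.lengths[v]
        if not np.isfinite(t_total):
            t_total = 1.0
        for g in range(spec.n_genes):
            s = int(states[g, p])
            t = 0.0
            while True:
                rate = spec.loss_rate if s == 1 else spec.gain_rate
                if rate == 0:
                    break
                t += rng.exponential(1.0 / rate)
                if t >= t_total:
                    break
                s = 1 - s
                events.append({
                    "gene_id": gene_ids[g],
                    "branch": idx.labels[v],
                    "event": "loss" if s == 0 else "gain",
                })
            states[g, v] = s

    leaf_cols = [i for i in range(n_nodes) if idx.is_leaf[i]]
    leaf_states = pd.DataFrame(
        states[:, leaf_cols],
        index=pd.Index(gene_ids, name="gene_id"),
        columns=[idx.labels[i] for i in leaf_cols],
    )
    events_df = pd.DataFrame(events, columns=["gene_id", "branch", "event"])
    return tree, leaf_states, events_df
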