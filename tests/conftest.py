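import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def planted():
    """Default 13-gene planted collection (one gene per class)."""
    from panlineage import PlantSpec, plant_pangenome

    return plant_pangenome(PlantSpec(seed=7))


@pytest.fixture()
def toy_matrix():
    """4 genes x 4 genomes, lineages L1={g1,g2}, L2={g3,g4}."""
    matrix = pd.DataFrame(
        [
            [1, 1, 1, 0],  # core in L1, intermediate in L2
            [0, 0, 0, 0],  # absent everywhere
            [1, 1, 1, 1],  # core in both
            [1, 0, 0, 0],  # intermediate in L1 only
        ],
        index=pd.Index(["gA", "gB", "gC", "gD"], name="gene_id"),
        columns=["g1", "g2", "g3", "g4"],
        dtype=np.int8,
    )
    assignment = pd.Series(
        ["L1", "L1", "L2", "L2"],
        index=pd.Index(["g1", "g2", "g3", "g4"], name="genome_id"),
    )
    return matrix, assignment


def random_rooted_tree(rng, n_leaves, allow_polytomy=False):
    """Random rooted tree as (newick string, leaf labels) for oracle tests."""
    labels = [f"T{i+1}" for i in range(n_leaves)]
    nodes = [f"{l}:{rng.uniform(0.01, 1.0):.4f}" for l in labels]
    while len(nodes) > 1:
        k = 2
        if allow_polytomy and len(nodes) > 2 and rng.random() < 0.3:
            k = 3
        pick = rng.choice(len(nodes), size=min(k, len(nodes)), replace=False)
        children = [nodes[i] for i in pick]
        for i in sorted(pick, reverse=True):
            del nodes[i]
        nodes.append(f"({','.join(children)}):{rng.uniform(0.01, 1.0):.4f}")
    newick = nodes[0]
    # strip the root branch length
    newick = newick[: newick.rfind(":")] + ";"
    return newick, labels
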