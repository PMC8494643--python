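import numpy as np
import pandas as pd
import pytest

from axonmap.swc import SWC_COLUMNS, NeuronMorphology
from axonmap.synthetic import ToyAtlasSpec, make_toy_atlas


def random_tree(
    seed: int,
    n_nodes: int = 30,
    step: float = 5.0,
    axon: bool = True,
) -> NeuronMorphology:
    """Random rooted tree: node i attaches to a uniform earlier node."""
    rng = np.random.default_rng(seed)
    xyz = np.zeros((n_nodes, 3))
    parents = [-1]
    for i in range(1, n_nodes):
        p = int(rng.integers(0, i))
        parents.append(p + 1)
        xyz[i] = xyz[p] + rng.normal(scale=step, size=3)
    nodes = pd.DataFrame(
        {
            "id": np.arange(1, n_nodes + 1),
            "type": [1] + [2 if axon else 3] * (n_nodes - 1),
            "x": xyz[:, 0],
            "y": xyz[:, 1],
            "z": xyz[:, 2],
            "radius": 0.5,
            "parent": parents,
        }
    )[SWC_COLUMNS]
    return NeuronMorphology(nodes, {"lr_axis": 2})


def chain_neuron(points, types=None) -> NeuronMorphology:
    """A single unbranched path through the given 3D points."""
    points = np.asarray(points, dtype=float)
    n = len(points)
    if types is None:
        types = [1] + [2] * (n - 1)
    nodes = pd.DataFrame(
        {
            "id": np.arange(1, n + 1),
            "type": types,
            "x": points[:, 0],
            "y": points[:, 1],
            "z": points[:, 2],
            "radius": 1.0,
            "parent": [-1] + list(range(1, n)),
        }
    )[SWC_COLUMNS]
    return NeuronMorphology(nodes, {"lr_axis": 2})


@pytest.fixture(scope="session")
def toy_atlas():
    return make_toy_atlas(ToyAtlasSpec(seed=0))
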