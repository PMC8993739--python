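import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from musclegrn.io import ExpressionMatrix, GeneSet
from musclegrn.synthetic import SynthConfig

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")

PAPER_SIGNATURE = ("DUPD1", "KLHL38", "METTL11B", "MYH6", "MYL7", "OR5H2", "OR6C70", "OR9Q1")
STAGES = ("pluripotent", "presomite", "myogenic_progenitor", "myoblast", "myotube")


@pytest.fixture
def cfg():
    return SynthConfig(seed=7, n_background=0, noise_sd=0.4)


@pytest.fixture
def tissues():
    return [f"tissue_{i:02d}" for i in range(1, 62)] + ["skeletal muscle"]


@pytest.fixture
def small_matrix():
    rng = np.random.default_rng(11)
    vals = pd.DataFrame(rng.uniform(0, 10, size=(5, 4)),
                        index=[f"G{i}" for i in range(5)],
                        columns=[f"S{j}" for j in range(4)])
    return ExpressionMatrix(vals, "fpkm")


def random_graph_edges(rng, n_nodes, p_edge):
    nodes = [f"n{i}" for i in range(n_nodes)]
    edges = [(a, b) for i, a in enumerate(nodes) for b in nodes[i + 1:]
             if rng.random() < p_edge]
    return nodes, edges
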