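import numpy as np
import pytest

from rcsp.graph import CausalGraph, SemParameters
from rcsp.simulate import sample_sem


@pytest.fixture
def chain_sem():
    """X0 -> X1 -> Y with weights 0.5 and 1.0, error scales 0.5."""
    graph = CausalGraph(3, frozenset({(0, 1), (1, 2)}))
    weights = np.zeros((3, 3))
    weights[0, 1] = 0.5
    weights[1, 2] = 1.0
    return SemParameters(graph, weights, np.full(3, 0.5), target_index=2)


@pytest.fixture
def random_sem():
    """A moderately sized random SEM with the protocol's edge density."""
    return sample_sem(21, 0.1, seed=42)


def oracle_sa_sets(sem):
    """True surrogate-ancestor sets in gene-position space (self excluded)."""
    from rcsp.graph import relatives

    genes = sem.gene_indices()
    pos = {int(g): k for k, g in enumerate(genes)}
    out = {}
    for k, g in enumerate(genes):
        anc = relatives(sem.graph, int(g), "ancestors") - {int(g)}
        out[k] = {pos[a] for a in anc if a in pos}
    return out
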