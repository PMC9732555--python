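"""Shared fixtures and the independent brute-force inference oracle.

The oracle materializes the full joint distribution of a (small) network as
a dense tensor product of its CPTs and computes posteriors by masking and
summation; it shares no code path with the engine's disorder-configuration
enumeration.
"""

from __future__ import annotations

import numpy as np
import pytest

from clusterbn import builtin_cluster_b, build_network
from clusterbn.network import NetworkModel, ROLE_DISORDER


@pytest.fixture(scope="session")
def builtin_ps():
    return builtin_cluster_b()


@pytest.fixture(scope="session")
def builtin_model(builtin_ps):
    return build_network(builtin_ps, "clinical")


@pytest.fixture(scope="session")
def builtin_model_general(builtin_ps):
    return build_network(builtin_ps, "general")


# ---------------------------------------------------------------------------
# brute-force joint-table oracle
# ---------------------------------------------------------------------------

def joint_table(model: NetworkModel) -> tuple[list[str], np.ndarray]:
    """Dense joint distribution over every node (small networks only)."""

    ids = list(model.nodes)
    cards = [len(model.nodes[i].states) for i in ids]
    assert int(np.prod(cards)) <= 2_000_000, "network too large for oracle"
    joint = np.ones(cards)
    for nid in ids:
        node = model.nodes[nid]
        if node.role == ROLE_DISORDER:
            arr = np.array([1.0 - node.prior, node.prior])
            dims = [nid]
        else:
            shape = [len(model.nodes[p].states) for p in node.cpt.parents]
            arr = node.cpt.table.reshape(shape + [len(node.states)])
            dims = list(node.cpt.parents) + [nid]
        positions = [ids.index(d) for d in dims]
        arr = np.transpose(arr, np.argsort(positions))
        view = [1] * len(ids)
        for d in dims:
            view[ids.index(d)] = cards[ids.index(d)]
        joint = joint * arr.reshape(view)
    return ids, joint


def oracle_posterior(model: NetworkModel, evidence: dict[str, str],
                     target: str) -> dict[str, float]:
    """Posterior of ``target`` by full joint enumeration."""

    ids, joint = joint_table(model)
    for nid, state in evidence.items():
        node = model.nodes[nid]
        idx = [slice(None)] * len(ids)
        mask = np.zeros(len(node.states))
        mask[node.states.index(state)] = 1.0
        view = [1] * len(ids)
        view[ids.index(nid)] = len(node.states)
        joint = joint * mask.reshape(view)
    axis = ids.index(target)
    other = tuple(i for i in range(len(ids)) if i != axis)
    marginal = joint.sum(axis=other)
    total = marginal.sum()
    assert total > 0.0, "zero-probability evidence in oracle"
    node = model.nodes[target]
    return {s: float(v) for s, v in zip(node.states, marginal / total)}
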