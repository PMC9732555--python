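"""Strength-of-influence and finding-impact analyses.

``arc_strength`` quantifies a single edge: for every configuration of the
child's other parents it measures a distance between the child's conditional
distributions across the arc parent's states, then aggregates by unweighted
average or maximum.  ``finding_impact`` ranks candidate observations by how
much a single finding would move a query target's posterior — the
therapeutic-target ranking.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .inference import EvidenceSet, posterior_marginals
from .network import ROLE_DISORDER, NetworkModel

__all__ = [
    "ArcStrengthReport",
    "FindingImpactReport",
    "arc_strength",
    "finding_impact",
]


@dataclass
class ArcStrengthReport:
    arc: tuple[str, str]
    metric: str
    distance: str
    value: float


@dataclass
class FindingImpactReport:
    target: str
    deviant_state: str
    baseline_probability: float
    impacts: list[tuple[str, float]]  # ranked descending


def _distance(p: np.ndarray, q: np.ndarray, kind: str) -> float:
    if kind == "euclidean":
        return float(np.linalg.norm(p - q))
    if kind == "absolute":
        return float(np.max(np.abs(p - q)))
    if kind == "hellinger":
        return float(np.linalg.norm(np.sqrt(p) - np.sqrt(q)) / math.sqrt(2))
    raise ValueError(f"unknown distance {kind!r}")


def arc_strength(
    model: NetworkModel,
    arc: tuple[str, str],
    metric: str = "average",
    distance: str = "euclidean",
) -> ArcStrengthReport:
    """Strength of a parent->child edge.

    For each joint state of the child's other parents, the distance between
    the child's conditional distributions is taken as the maximum pairwise
    distance across the arc parent's states (for a binary parent this is
    simply the distance between its two rows); contexts are aggregated by
    unweighted ``average`` or ``maximum``.  The value is zero iff the child
    is independent of the parent in every context.
    """

    parent_id, child_id = arc
    child = model.nodes.get(child_id)
    if child is None or child.cpt is None or parent_id not in child.parents:
        raise ValueError(f"no arc {parent_id!r} -> {child_id!r} in the model")
    if metric not in ("average", "maximum"):
        raise ValueError(f"unknown metric {metric!r}")
    cpt = child.cpt
    axis = cpt.parents.index(parent_id)
    other_states = [
        states for i, states in enumerate(cpt.parent_states) if i != axis
    ]
    parent_states = cpt.parent_states[axis]
    values = []
    for combo in itertools.product(*other_states):
        rows = []
        for pstate in parent_states:
            config = {}
            it = iter(combo)
            for i, pid in enumerate(cpt.parents):
                config[pid] = pstate if i == axis else next(it)
            rows.append(cpt.row(config))
        pairwise = [
            _distance(a, b, distance)
            for a, b in itertools.combinations(rows, 2)
        ]
        values.append(max(pairwise))
    value = max(values) if metric == "maximum" else sum(values) / len(values)
    return ArcStrengthReport(arc, metric, distance, value)


def _deviant_state(model: NetworkModel, node_id: str) -> str:
    node = model.nodes[node_id]
    # binary nodes deviate into "present"; graded nodes report the high tail
    return node.states[-1]


def finding_impact(
    model: NetworkModel,
    target: str,
    candidates: list[str] | None = None,
    evidence: EvidenceSet | dict[str, str] | None = None,
) -> FindingImpactReport:
    """Rank candidate observables by the largest shift (over their states)
    they would induce in P(target = deviant), on top of current evidence."""

    if isinstance(evidence, EvidenceSet):
        ev = dict(evidence.findings)
    else:
        ev = dict(evidence or {})
    if target in ev:
        raise ValueError(f"target is observed: {target!r}")
    if candidates is None:
        candidates = [
            n.id for n in model.nodes.values()
            if n.role != ROLE_DISORDER and n.id != target and n.id not in ev
        ]
    deviant = _deviant_state(model, target)
    base = posterior_marginals(model, ev, [target]).prob(target, deviant)
    impacts = []
    for cand in candidates:
        if cand == target or cand in ev:
            continue
        node = model.nodes[cand]
        shift = 0.0
        for state in node.states:
            post = posterior_marginals(
                model, {**ev, cand: state}, [target]
            ).prob(target, deviant)
            shift = max(shift, abs(post - base))
        impacts.append((cand, shift))
    impacts.sort(key=lambda t: (-t[1], t[0]))
    return FindingImpactReport(target, deviant, base, impacts)
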