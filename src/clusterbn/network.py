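"""Assembly of the three-layer augmented BN2O network.

Layer 1 holds the five disorder roots with prevalence priors; layer 2 the
symptom variables, each a child of exactly the disorders with an elicited
probability in its table row; layer 3 the psychological-distress nodes.
There are no disorder-disorder or symptom-symptom edges: comorbidity is
carried entirely by shared symptoms.

Each distress node is a binary leak-free noisy-OR child of its symptom
group, with link strength equal to each symptom's elicited distress
probability: a single deviant symptom alone provokes distress with exactly
that probability, and with every parent neutral the distress probability is
zero.  The general distress node aggregates the five disorder nodes the same
way.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .canonical import (
    CPT,
    DEFAULT_MEDIUM_FLOOR,
    evidence_logistic_cpt,
    leaky_max_cpt,
    leaky_or_cpt,
)
from .parameters import (
    BINARY_STATES,
    DISORDERS,
    GENERAL_DISTRESS_GROUP,
    ParameterSet,
    validate_parameter_set,
)

__all__ = [
    "PopulationContext",
    "Node",
    "NetworkModel",
    "build_network",
    "attach_distress_layer",
    "validate_network",
    "NetworkStructureError",
]

DISTRESS_STATES = ("absent", "present")

ROLE_DISORDER = "disorder"
ROLE_SYMPTOM = "symptom"
ROLE_DISTRESS = "distress"


class NetworkStructureError(ValueError):
    """Raised when the parameter set cannot be assembled into a network."""


@dataclass(frozen=True)
class PopulationContext:
    """Selects which prevalence column seeds the disorder priors."""

    setting: str = "clinical"

    def __post_init__(self) -> None:
        if self.setting not in ("clinical", "general"):
            raise ValueError(f"unknown population setting {self.setting!r}")

    def prior(self, entry) -> float:
        return entry.clinical if self.setting == "clinical" else entry.general


@dataclass(frozen=True)
class DistressParent:
    """One noisy-OR link into a distress node: the parent id, the link
    strength, and the parent states that activate the link."""

    parent: str
    strength: float
    trigger_states: tuple[str, ...]


@dataclass
class Node:
    id: str
    role: str
    states: tuple[str, ...]
    parents: tuple[str, ...] = ()
    cpt: CPT | None = None
    prior: float | None = None
    distress_parents: tuple[DistressParent, ...] | None = None


@dataclass
class NetworkModel:
    """The assembled three-layer network."""

    nodes: dict[str, Node] = field(default_factory=dict)
    population: str = "clinical"

    @property
    def disorder_ids(self) -> list[str]:
        return [n.id for n in self.nodes.values() if n.role == ROLE_DISORDER]

    @property
    def symptom_ids(self) -> list[str]:
        return [n.id for n in self.nodes.values() if n.role == ROLE_SYMPTOM]

    @property
    def distress_ids(self) -> list[str]:
        return [n.id for n in self.nodes.values() if n.role == ROLE_DISTRESS]

    def edges(self) -> list[tuple[str, str]]:
        return [(p, n.id) for n in self.nodes.values() for p in n.parents]

    def children_of(self, node_id: str) -> list[str]:
        return [n.id for n in self.nodes.values() if node_id in n.parents]

    def census(self) -> dict[str, int]:
        return {
            "disorders": len(self.disorder_ids),
            "symptoms": len(self.symptom_ids),
            "distress": len(self.distress_ids),
            "nodes": len(self.nodes),
            "edges": len(self.edges()),
        }


def _symptom_cpt(
    ps: ParameterSet,
    symptom_id: str,
    medium_floor: float,
    medium_split: float,
    link: str,
) -> CPT:
    spec = ps.symptom(symptom_id)
    arcs = ps.arcs_for(symptom_id)
    base = ps.baseline(symptom_id)
    if spec.framework in ("DSM", "DEFENSE"):
        return leaky_or_cpt(symptom_id, arcs, base.base_present)
    if spec.framework == "LPF":
        return leaky_max_cpt(symptom_id, arcs, base.base_high,
                             medium_split=medium_split)
    return evidence_logistic_cpt(symptom_id, arcs, base.base_high,
                                 base.base_low, medium_floor=medium_floor,
                                 link=link)


def build_network(
    ps: ParameterSet,
    population: PopulationContext | str = "clinical",
    *,
    medium_floor: float = DEFAULT_MEDIUM_FLOOR,
    medium_split: float = 0.0,
    link: str = "logit",
    distress: bool = True,
) -> NetworkModel:
    """Assemble the network from a validated parameter set.

    The canonical model of each symptom CPT is dictated by its framework:
    DSM and defense mechanisms use the leaky noisy-OR; LPF scales the leaky
    noisy-MAX; five-factor traits and biosocial polarities the
    evidence-weighting model.
    """

    if isinstance(population, str):
        population = PopulationContext(population)
    violations = validate_parameter_set(ps)
    if violations:
        raise NetworkStructureError(
            "invalid parameter set:\n" + "\n".join(violations)
        )
    model = NetworkModel(population=population.setting)
    for entry in ps.prevalence:
        model.nodes[entry.disorder] = Node(
            entry.disorder, ROLE_DISORDER, BINARY_STATES,
            prior=population.prior(entry),
        )
    for spec in ps.symptoms:
        cpt = _symptom_cpt(ps, spec.id, medium_floor, medium_split, link)
        model.nodes[spec.id] = Node(
            spec.id, ROLE_SYMPTOM, spec.states, parents=cpt.parents, cpt=cpt,
        )
        for parent in cpt.parents:
            if parent not in model.nodes:
                raise NetworkStructureError(
                    f"{spec.id}: arc from disorder {parent!r} without a "
                    f"prevalence entry"
                )
    if distress:
        attach_distress_layer(model, ps)
    return model


def _trigger_states(ps: ParameterSet, source: str) -> tuple[str, ...]:
    # A graded parent activates its distress link from any deviant state
    # that some arc targets; binary parents and disorders from "present".
    try:
        spec = ps.symptom(source)
    except KeyError:
        return ("present",)  # disorder parent of the general node
    if spec.is_binary:
        return ("present",)
    targets = sorted({a.target_state() for a in ps.arcs_for(source)},
                     key=spec.states.index)
    if not targets:
        raise NetworkStructureError(f"{source}: distress link on a symptom "
                                    f"with no arcs")
    return tuple(targets)


def _noisy_or_table(model: NetworkModel, parents: tuple[DistressParent, ...]) -> CPT:
    state_lists = tuple(model.nodes[p.parent].states for p in parents)
    rows = []
    for combo in itertools.product(*state_lists):
        q_absent = 1.0
        for p, state in zip(parents, combo):
            if state in p.trigger_states:
                q_absent *= 1.0 - p.strength
        rows.append([q_absent, 1.0 - q_absent])
    return CPT("", tuple(p.parent for p in parents), state_lists,
               DISTRESS_STATES, np.array(rows))


def attach_distress_layer(model: NetworkModel, ps: ParameterSet) -> NetworkModel:
    """Attach one binary leak-free noisy-OR distress node per group.

    Symptom groups aggregate their member symptoms with the per-symptom
    distress probabilities; the general group aggregates the five disorder
    nodes with the disorder-level distress probabilities.
    """

    order = list(model.nodes)
    for group, links in ps.distress_groups().items():
        parents = []
        for link in sorted(links, key=lambda l: order.index(l.source)
                           if l.source in order else -1):
            if link.source not in model.nodes:
                raise NetworkStructureError(
                    f"distress group {group!r}: parent {link.source!r} not "
                    f"in the network"
                )
            parents.append(DistressParent(link.source, link.pd,
                                          _trigger_states(ps, link.source)))
        if not parents:
            raise NetworkStructureError(f"distress group {group!r} has no "
                                        f"members")
        parents = tuple(parents)
        cpt = _noisy_or_table(model, parents)
        cpt.variable = group
        model.nodes[group] = Node(
            group, ROLE_DISTRESS, DISTRESS_STATES,
            parents=tuple(p.parent for p in parents),
            cpt=cpt, distress_parents=parents,
        )
    return model


def validate_network(model: NetworkModel) -> list[str]:
    """Structural and numerical checks; returns violations (empty iff valid)."""

    import networkx as nx

    violations: list[str] = []
    graph = nx.DiGraph()
    graph.add_nodes_from(model.nodes)
    for parent, child in model.edges():
        if parent not in model.nodes:
            violations.append(f"{child}: unknown parent {parent!r}")
        else:
            graph.add_edge(parent, child)
    if not nx.is_directed_acyclic_graph(graph):
        violations.append("graph contains a cycle")
    role = {n.id: n.role for n in model.nodes.values()}
    for parent, child in model.edges():
        if parent not in role:
            continue
        ok = (
            (role[parent], role[child]) == (ROLE_DISORDER, ROLE_SYMPTOM)
            or (role[child] == ROLE_DISTRESS
                and role[parent] in (ROLE_SYMPTOM, ROLE_DISORDER))
        )
        if not ok:
            violations.append(
                f"layering violation: {role[parent]} {parent!r} -> "
                f"{role[child]} {child!r}"
            )
    for node in model.nodes.values():
        if node.role == ROLE_DISORDER:
            if node.prior is None or not 0.0 <= node.prior <= 1.0:
                violations.append(f"{node.id}: prior {node.prior} outside "
                                  f"[0,1]")
            continue
        if node.cpt is None:
            violations.append(f"{node.id}: missing CPT")
            continue
        if node.cpt.parents != node.parents:
            violations.append(f"{node.id}: CPT parents do not match node "
                              f"parents")
        sums = node.cpt.table.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-12, rtol=0.0):
            worst = float(np.abs(sums - 1.0).max())
            violations.append(
                f"{node.id}: CPT rows deviate from 1 by up to {worst:.3e}"
            )
        if (node.cpt.table < -1e-15).any() or (node.cpt.table > 1 + 1e-15).any():
            violations.append(f"{node.id}: CPT entries outside [0,1]")
    return violations
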