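"""Exact inference on the three-layer network.

The BN2O layering admits a simple exact scheme: enumerate the joint states
of the disorder roots (2^5 = 32 configurations for the built-in model),
weight each configuration by its prior times the likelihood of the evidence,
and normalize.  Given a disorder configuration the symptoms are mutually
independent, so the evidence likelihood factors over the observed symptom
nodes; an observed distress node contributes a factor computed from the
leak-free noisy-OR decomposition, marginalizing its unobserved symptom
parents in closed form.  Unobserved leaf symptoms contribute factor 1.

Weights are accumulated in log space (86 likelihood factors can underflow)
with a single final normalization.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

from .network import (
    ROLE_DISORDER,
    ROLE_DISTRESS,
    ROLE_SYMPTOM,
    NetworkModel,
    Node,
)

__all__ = [
    "EvidenceSet",
    "PosteriorReport",
    "EvidenceError",
    "ZeroProbabilityEvidence",
    "posterior_marginals",
    "joint_configuration_probability",
    "distress_profile",
]

_NEG_INF = float("-inf")


class EvidenceError(ValueError):
    """Invalid evidence: unknown node, unknown state, or observed target."""


class ZeroProbabilityEvidence(ValueError):
    """The entered findings are mutually contradictory under the model."""


@dataclass(frozen=True)
class EvidenceSet:
    """A mapping from observed variables to their found states."""

    findings: dict[str, str] = field(default_factory=dict)

    def validate(self, model: NetworkModel) -> None:
        for node_id, state in self.findings.items():
            node = model.nodes.get(node_id)
            if node is None:
                raise EvidenceError(f"unknown node {node_id!r}")
            if state not in node.states:
                raise EvidenceError(
                    f"{node_id}: unknown state {state!r} "
                    f"(expected one of {node.states})"
                )

    def __contains__(self, node_id: str) -> bool:
        return node_id in self.findings

    def __len__(self) -> int:
        return len(self.findings)


@dataclass
class PosteriorReport:
    """Posterior distributions per query target (each sums to 1)."""

    posteriors: dict[str, dict[str, float]]
    evidence: dict[str, str]
    population: str

    def prob(self, node_id: str, state: str) -> float:
        return self.posteriors[node_id][state]


def _log(p: float) -> float:
    return math.log(p) if p > 0.0 else _NEG_INF


def _symptom_factor(node: Node, state: str, config: dict[str, str]) -> float:
    return node.cpt.prob(state, config)


def _trigger_probability(
    model: NetworkModel,
    parent_id: str,
    trigger_states: tuple[str, ...],
    config: dict[str, str],
    clamps: dict[str, str],
) -> float:
    """P(parent in a triggering state) given the disorder configuration,
    honouring clamped findings on the parent."""

    if parent_id in clamps:
        return 1.0 if clamps[parent_id] in trigger_states else 0.0
    node = model.nodes[parent_id]
    if node.role == ROLE_DISORDER:
        return 1.0 if config[parent_id] in trigger_states else 0.0
    row = node.cpt.row(config)
    return float(sum(row[node.states.index(s)] for s in trigger_states))


def _distress_factor(
    model: NetworkModel,
    node: Node,
    state: str,
    config: dict[str, str],
    clamps: dict[str, str],
) -> float:
    """P(distress node = state | disorder config, clamped parents).

    Uses the noisy-OR decomposition when available (unobserved symptom
    parents marginalize in closed form); falls back to explicit
    marginalization over the CPT for generic imported models.
    """

    if node.distress_parents is not None:
        q_absent = 1.0
        for link in node.distress_parents:
            p_trig = _trigger_probability(model, link.parent,
                                          link.trigger_states, config, clamps)
            q_absent *= 1.0 - link.strength * p_trig
    else:
        q_absent = 0.0
        state_lists = [model.nodes[p].states for p in node.parents]
        absent_idx = node.states.index(node.states[0])
        for combo in itertools.product(*state_lists):
            weight = 1.0
            for pid, pstate in zip(node.parents, combo):
                parent = model.nodes[pid]
                if pid in clamps:
                    if pstate != clamps[pid]:
                        weight = 0.0
                        break
                elif parent.role == ROLE_DISORDER:
                    if pstate != config[pid]:
                        weight = 0.0
                        break
                else:
                    weight *= parent.cpt.prob(pstate, config)
            if weight:
                q_absent += weight * node.cpt.prob(node.states[absent_idx],
                                                   dict(zip(node.parents,
                                                            combo)))
    p_absent = q_absent
    return p_absent if state == node.states[0] else 1.0 - p_absent


def _config_log_weight(
    model: NetworkModel,
    config: dict[str, str],
    evidence: dict[str, str],
    extra_clamp: dict[str, str] | None = None,
) -> float:
    """log( prior(config) * P(evidence, extra clamps | config) )."""

    clamps = dict(evidence)
    if extra_clamp:
        clamps.update(extra_clamp)
    logw = 0.0
    for disorder_id in model.disorder_ids:
        node = model.nodes[disorder_id]
        p = node.prior if config[disorder_id] == "present" else 1.0 - node.prior
        logw += _log(p)
        if logw == _NEG_INF:
            return _NEG_INF
    for node_id, state in clamps.items():
        node = model.nodes[node_id]
        if node.role == ROLE_DISORDER:
            if config[node_id] != state:
                return _NEG_INF
            continue
        if node.role == ROLE_SYMPTOM:
            factor = _symptom_factor(node, state, config)
        else:
            symptom_clamps = {k: v for k, v in clamps.items()
                             if model.nodes[k].role != ROLE_DISTRESS}
            factor = _distress_factor(model, node, state, config,
                                      symptom_clamps)
        logw += _log(factor)
        if logw == _NEG_INF:
            return _NEG_INF
    return logw


def _disorder_configs(model: NetworkModel, evidence: dict[str, str]):
    ids = model.disorder_ids
    for combo in itertools.product(("absent", "present"), repeat=len(ids)):
        config = dict(zip(ids, combo))
        if all(config[d] == evidence[d] for d in ids if d in evidence):
            yield config


def _logsumexp(values: list[float]) -> float:
    peak = max(values, default=_NEG_INF)
    if peak == _NEG_INF:
        return _NEG_INF
    return peak + math.log(sum(math.exp(v - peak) for v in values))


def posterior_marginals(
    model: NetworkModel,
    evidence: EvidenceSet | dict[str, str],
    targets: list[str],
) -> PosteriorReport:
    """Exact posterior marginals of the query targets given the evidence.

    Targets may be disorder, symptom or distress nodes; a target that is
    itself observed raises :class:`EvidenceError`, and evidence of
    probability zero raises :class:`ZeroProbabilityEvidence`.
    """

    if isinstance(evidence, dict):
        evidence = EvidenceSet(dict(evidence))
    evidence.validate(model)
    ev = evidence.findings
    for target in targets:
        if target not in model.nodes:
            raise EvidenceError(f"unknown query target {target!r}")
        if target in ev:
            raise EvidenceError(f"target is observed: {target!r}")

    configs = list(_disorder_configs(model, ev))
    base_logw = [_config_log_weight(model, c, ev) for c in configs]
    total = _logsumexp(base_logw)
    if total == _NEG_INF:
        raise ZeroProbabilityEvidence(
            "zero-probability evidence: the findings are contradictory "
            "under the model"
        )
    weights = [math.exp(lw - total) if lw != _NEG_INF else 0.0
               for lw in base_logw]

    posteriors: dict[str, dict[str, float]] = {}
    for target in targets:
        node = model.nodes[target]
        if node.role == ROLE_DISORDER:
            p_present = sum(w for w, c in zip(weights, configs)
                            if c[target] == "present")
            posteriors[target] = {"absent": 1.0 - p_present,
                                  "present": p_present}
        elif node.role == ROLE_DISTRESS:
            dist = {s: 0.0 for s in node.states}
            for w, c in zip(weights, configs):
                if w == 0.0:
                    continue
                for s in node.states:
                    dist[s] += w * _distress_factor(model, node, s, c, ev)
            posteriors[target] = dist
        else:
            # A symptom target couples with observed distress descendants:
            # recompute those factors with the target clamped to each state.
            coupled = [
                model.nodes[d] for d in ev
                if model.nodes[d].role == ROLE_DISTRESS
                and target in model.nodes[d].parents
            ]
            dist = {s: 0.0 for s in node.states}
            for w, c, lw in zip(weights, configs, base_logw):
                if w == 0.0:
                    continue
                for s in node.states:
                    p = node.cpt.prob(s, c)
                    for dnode in coupled:
                        base = _distress_factor(model, dnode, ev[dnode.id],
                                                c, ev)
                        clamped = _distress_factor(
                            model, dnode, ev[dnode.id], c, {**ev, target: s}
                        )
                        p *= clamped / base if base > 0.0 else 0.0
                    dist[s] += w * p
            norm = sum(dist.values())
            posteriors[target] = {s: v / norm for s, v in dist.items()}
    return PosteriorReport(posteriors, dict(ev), model.population)


def joint_configuration_probability(
    model: NetworkModel,
    disorder_config: dict[str, str],
    evidence: EvidenceSet | dict[str, str],
) -> float:
    """Unnormalized ``prior(config) * P(evidence | config)``.

    Summing over all disorder configurations and normalizing reproduces
    :func:`posterior_marginals`.
    """

    if isinstance(evidence, dict):
        evidence = EvidenceSet(dict(evidence))
    evidence.validate(model)
    missing = [d for d in model.disorder_ids if d not in disorder_config]
    if missing:
        raise EvidenceError(f"disorder configuration must assign all roots; "
                            f"missing {missing}")
    logw = _config_log_weight(model, disorder_config, evidence.findings)
    return math.exp(logw) if logw != _NEG_INF else 0.0


def distress_profile(
    model: NetworkModel,
    evidence: EvidenceSet | dict[str, str],
) -> PosteriorReport:
    """Posterior of every (unobserved) distress node: the therapeutic-target
    profile."""

    if isinstance(evidence, dict):
        evidence = EvidenceSet(dict(evidence))
    targets = [d for d in model.distress_ids if d not in evidence.findings]
    return posterior_marginals(model, evidence, targets)
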