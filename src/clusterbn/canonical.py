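"""Canonical CPT models: leaky noisy-OR, leaky noisy-MAX, and an additive
log-odds evidence-weighting model for graded trait variables.

All three models assume independence of causal influence: each disorder's
effect on the symptom does not depend on which other disorders are present,
their order, or their interaction.  Each is calibrated so that

* the all-causes-absent row reproduces the no-disorder baseline, and
* the row where exactly one disorder is present reproduces that arc's
  elicited probability ``q`` exactly.

The evidence-weighting model covers graded traits whose neutral state is the
population-typical medium and whose causes may push toward either tail:
each active arc contributes log-odds evidence for its target tail and
against the opposite one, weighted by how far ``q`` sits above the tail's
population baseline.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logit
from scipy.stats import norm

from .parameters import (
    BINARY_STATES,
    GRADED_STATES,
    TOWARD_HIGH,
    TOWARD_LOW,
    TOWARD_PRESENT,
    InfluenceArc,
)

__all__ = [
    "CPT",
    "CalibrationError",
    "calibrate_link",
    "leaky_or_cpt",
    "leaky_max_cpt",
    "evidence_logistic_cpt",
]

DEFAULT_MEDIUM_FLOOR = 0.01


class CalibrationError(ValueError):
    """Raised when an arc cannot be calibrated against its baseline."""


@dataclass
class CPT:
    """A conditional probability table.

    ``table`` has one row per parent configuration (row-major: the first
    parent varies slowest) and one column per child state.
    """

    variable: str
    parents: tuple[str, ...]
    parent_states: tuple[tuple[str, ...], ...]
    states: tuple[str, ...]
    table: np.ndarray

    def __post_init__(self) -> None:
        expected = int(np.prod([len(s) for s in self.parent_states])) \
            if self.parents else 1
        assert self.table.shape == (expected, len(self.states))

    def row_index(self, config: dict[str, str]) -> int:
        idx = 0
        for parent, states in zip(self.parents, self.parent_states):
            idx = idx * len(states) + states.index(config[parent])
        return idx

    def row(self, config: dict[str, str]) -> np.ndarray:
        return self.table[self.row_index(config)]

    def prob(self, state: str, config: dict[str, str]) -> float:
        return float(self.row(config)[self.states.index(state)])


def calibrate_link(q: float, leak: float) -> float:
    """Noisy-OR/MAX link strength ``c = (q - leak) / (1 - leak)``.

    This is the unique calibration under which the child's single-cause
    marginal equals the elicited ``q`` while the all-absent row equals the
    leak.
    """

    if leak >= 1.0:
        raise CalibrationError(f"leak {leak} must be < 1")
    if q < leak:
        raise CalibrationError(
            f"arc weaker than leak: q={q:.4f} < leak={leak:.4f}"
        )
    return (q - leak) / (1.0 - leak)


def _parent_configs(n: int):
    # 0 = absent, 1 = present; first parent varies slowest
    return itertools.product((0, 1), repeat=n)


def leaky_or_cpt(symptom: str, arcs: list[InfluenceArc], leak: float) -> CPT:
    """Leaky noisy-OR table for a binary symptom.

    ``P(present | config) = 1 - (1 - leak) * prod_i (1 - c_i)`` over the
    present parents; the all-absent row equals the leak.
    """

    for arc in arcs:
        if arc.direction != TOWARD_PRESENT:
            raise CalibrationError(
                f"{symptom}: noisy-OR requires binary toward-present arcs"
            )
    cs = [calibrate_link(a.q, leak) for a in arcs]
    parents = tuple(a.disorder for a in arcs)
    rows = []
    for config in _parent_configs(len(arcs)):
        q_absent = (1.0 - leak) * float(
            np.prod([1.0 - c for c, on in zip(cs, config) if on])
        )
        rows.append([q_absent, 1.0 - q_absent])
    return CPT(symptom, parents, (BINARY_STATES,) * len(parents),
               BINARY_STATES, np.array(rows))


def leaky_max_cpt(
    symptom: str,
    arcs: list[InfluenceArc],
    leak_high: float,
    medium_split: float = 0.0,
) -> CPT:
    """Leaky noisy-MAX table for a graded symptom whose neutral state is the
    lowest (the LPF scales); every arc targets ``high``.

    Each cause contributes an independent graded effect with mass ``c_i`` on
    ``high``; the child takes the ordinal maximum of all effects and the
    leak.  The elicited tables carry one number per arc, so the per-cause
    effect places no mass on ``medium`` by default; ``medium_split`` moves
    the stated fraction of each effect's non-high mass from ``low`` to
    ``medium`` (calibration of the high state is unaffected).
    """

    if not 0.0 <= medium_split <= 1.0:
        raise CalibrationError("medium_split must be in [0, 1]")
    for arc in arcs:
        if arc.direction != TOWARD_HIGH:
            raise CalibrationError(
                f"{symptom}: leaky MAX requires toward-high arcs; an arc "
                f"toward low needs the evidence-weighting model"
            )
    cs = [calibrate_link(a.q, leak_high) for a in arcs]
    parents = tuple(a.disorder for a in arcs)

    def cumulative(c: float) -> tuple[float, float]:
        # P(effect <= low), P(effect <= medium) for a two-point effect with
        # mass c on high and (1 - c) split between low and medium.
        p_low = (1.0 - c) * (1.0 - medium_split)
        return p_low, 1.0 - c

    rows = []
    leak_cum = cumulative(leak_high)
    for config in _parent_configs(len(arcs)):
        f_low, f_med = leak_cum
        for c, on in zip(cs, config):
            if on:
                cl, cm = cumulative(c)
                f_low *= cl
                f_med *= cm
        rows.append([f_low, f_med - f_low, 1.0 - f_med])
    return CPT(symptom, parents, (BINARY_STATES,) * len(parents),
               GRADED_STATES, np.array(rows))


def evidence_logistic_cpt(
    symptom: str,
    arcs: list[InfluenceArc],
    base_high: float,
    base_low: float,
    medium_floor: float = DEFAULT_MEDIUM_FLOOR,
    link: str = "logit",
) -> CPT:
    """Evidence-weighting table for a graded trait with neutral ``medium``.

    Each arc carries weight ``w_i = link(q_i) - link(b_tail)`` on its target
    tail.  For a parent configuration, the raw tail probabilities are

        p_high = link^-1( link(b_high) + sum(w, toward high) - sum(w, toward low) )
        p_low  = link^-1( link(b_low)  + sum(w, toward low)  - sum(w, toward high) )

    so evidence for one tail simultaneously counts against the other.  The
    medium state takes the remaining mass; if the tails overflow past
    ``1 - medium_floor`` they are rescaled proportionally so the distribution
    stays proper under many simultaneous strong causes.

    ``link`` is ``"logit"`` (default) or ``"probit"`` (latent-normal
    threshold reading); single-cause calibration holds under either.
    """

    if not 0.0 < medium_floor < 1.0:
        raise CalibrationError("medium_floor must be in (0, 1)")
    if base_high + base_low >= 1.0:
        raise CalibrationError(
            f"{symptom}: tail baselines sum to {base_high + base_low:.4f} >= 1"
        )
    if link == "logit":
        fwd, inv = logit, expit
    elif link == "probit":
        fwd, inv = norm.ppf, norm.cdf
    else:
        raise CalibrationError(f"unknown link {link!r}")
    weights = []
    for arc in arcs:
        if arc.direction == TOWARD_HIGH:
            tail = base_high
        elif arc.direction == TOWARD_LOW:
            tail = base_low
        else:
            raise CalibrationError(
                f"{symptom}: evidence model requires graded arcs"
            )
        if arc.q <= tail:
            raise CalibrationError(
                f"arc weaker than baseline: {arc.disorder} -> {symptom}: "
                f"q={arc.q:.4f} <= baseline {tail:.4f}"
            )
        weights.append(float(fwd(arc.q) - fwd(tail)))
    parents = tuple(a.disorder for a in arcs)
    s_high0 = float(fwd(base_high))
    s_low0 = float(fwd(base_low))
    rows = []
    for config in _parent_configs(len(arcs)):
        up = sum(w for w, a, on in zip(weights, arcs, config)
                 if on and a.direction == TOWARD_HIGH)
        down = sum(w for w, a, on in zip(weights, arcs, config)
                   if on and a.direction == TOWARD_LOW)
        p_high = float(inv(s_high0 + up - down))
        p_low = float(inv(s_low0 + down - up))
        total = p_high + p_low
        if total > 1.0 - medium_floor:
            scale = (1.0 - medium_floor) / total
            p_high *= scale
            p_low *= scale
        rows.append([p_low, 1.0 - p_low - p_high, p_high])
    return CPT(symptom, parents, (BINARY_STATES,) * len(parents),
               GRADED_STATES, np.array(rows))
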