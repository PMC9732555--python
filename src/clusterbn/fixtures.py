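"""Seeded synthetic parameter sets for property testing.

The generator emits random knowledge bases that honour every invariant of
the real one (arcs strictly stronger than their baselines, tail baselines
summing below one, every symptom with at least one arc, clinical prevalence
above general) while staying on the 0.1% elicitation grid, so that
table round-trips are exact.  The same seed always yields the same set.
"""

from __future__ import annotations

import numpy as np

from .parameters import (
    BINARY_STATES,
    DISORDERS,
    GENERAL_DISTRESS_GROUP,
    GRADED_STATES,
    BaselineSpec,
    DistressLink,
    InfluenceArc,
    ParameterSet,
    PrevalenceEntry,
    SymptomSpec,
    TOWARD_HIGH,
    TOWARD_LOW,
    TOWARD_PRESENT,
)

__all__ = ["generate_fixture"]


def _grid(rng: np.random.Generator, lo: float, hi: float) -> float:
    """A value on the 0.1-percentage-point grid, as a fraction."""

    return float(rng.integers(round(lo * 10), round(hi * 10) + 1)) / 1000.0


def generate_fixture(
    seed: int,
    n_disorders: int = 2,
    n_symptoms: int = 6,
    graded_fraction: float = 0.4,
    with_distress: bool = True,
) -> ParameterSet:
    """A reproducible random :class:`ParameterSet`.

    ``n_disorders`` (1-5) selects a prefix of the disorder codes; about
    ``graded_fraction`` of the symptoms are graded, alternating between
    LPF-style (neutral low) and trait-style (neutral medium) variables.
    """

    if n_disorders < 1 or n_disorders > len(DISORDERS):
        raise ValueError(f"n_disorders must be in 1..{len(DISORDERS)}")
    if n_symptoms < 1:
        raise ValueError("n_symptoms must be >= 1")
    if not 0.0 <= graded_fraction <= 1.0:
        raise ValueError("graded_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    disorders = DISORDERS[:n_disorders]
    ps = ParameterSet()
    for disorder in disorders:
        general = _grid(rng, 1.0, 8.0)
        clinical = general + _grid(rng, 5.0, 20.0)
        ps.prevalence.append(
            PrevalenceEntry(disorder, clinical, general, _grid(rng, 40.0, 90.0))
        )
        if with_distress:
            ps.distress.append(
                DistressLink(disorder, ps.prevalence[-1].pd,
                             GENERAL_DISTRESS_GROUP)
            )
    n_graded = round(n_symptoms * graded_fraction)
    kinds = ["graded"] * n_graded + ["binary"] * (n_symptoms - n_graded)
    lpf_toggle = True
    for i, kind in enumerate(kinds):
        n_parents = int(rng.integers(1, n_disorders + 1))
        parents = [disorders[j] for j in sorted(
            rng.choice(n_disorders, size=n_parents, replace=False)
        )]
        if kind == "binary":
            sid = f"DSM-{parents[0]}-{i + 1:02d}"
            ps.symptoms.append(SymptomSpec(sid, "DSM", BINARY_STATES,
                                           "absent"))
            base = _grid(rng, 5.0, 45.0)
            ps.baselines.append(BaselineSpec(sid, base_present=base))
            for disorder in parents:
                q = _grid(rng, base * 100 + 5.0, 95.0)
                ps.arcs.append(InfluenceArc(disorder, sid, TOWARD_PRESENT, q))
            group = f"PD-DSM-{parents[0]}"
        elif lpf_toggle:
            lpf_toggle = False
            sid = f"LPF-Scale-{i + 1:02d}"
            ps.symptoms.append(SymptomSpec(sid, "LPF", GRADED_STATES, "low"))
            base = _grid(rng, 5.0, 30.0)
            ps.baselines.append(BaselineSpec(sid, base_high=base,
                                             base_low=0.0))
            for disorder in parents:
                q = _grid(rng, base * 100 + 5.0, 95.0)
                ps.arcs.append(InfluenceArc(disorder, sid, TOWARD_HIGH, q))
            group = "PD-LPF"
        else:
            lpf_toggle = True
            sid = f"FFM-Trait-{i + 1:02d}"
            ps.symptoms.append(SymptomSpec(sid, "FFM", GRADED_STATES,
                                           "medium"))
            b_high = _grid(rng, 10.0, 45.0)
            b_low = _grid(rng, 10.0, min(45.0, 95.0 - b_high * 100))
            ps.baselines.append(BaselineSpec(sid, base_high=b_high,
                                             base_low=b_low))
            for disorder in parents:
                direction = TOWARD_HIGH if rng.random() < 0.5 else TOWARD_LOW
                tail = b_high if direction == TOWARD_HIGH else b_low
                q = _grid(rng, tail * 100 + 5.0, 95.0)
                ps.arcs.append(InfluenceArc(disorder, sid, direction, q))
            group = "PD-FFM"
        if with_distress:
            ps.distress.append(
                DistressLink(sid, _grid(rng, 20.0, 80.0), group)
            )
    return ps
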