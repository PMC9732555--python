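"""Likelihood-ratio diagnostics: per-symptom LR+ / LR- against each disorder,
confirmatory and screening panels, and pre-test to post-test updating.

For a symptom S with target (deviant) state s and disorder D,

    LR+ = P(S=s | D) / P(S=s | no disorder) = q / baseline
    LR- = P(S!=s | D) / P(S!=s | no disorder) = (1 - q) / (1 - baseline)

For graded symptoms "test positive" means the arc's target tail state and
"test negative" any other state.  A symptom with LR+ >= 5 can efficiently
confirm the disorder in a clinical setting; one with LR- <= 0.2 can rule it
out in screening.  Ratios are computed from the stored (unrounded)
fractions; display rounding is two decimals.
"""

from __future__ import annotations

from dataclasses import dataclass

from .parameters import ParameterSet

__all__ = [
    "LikelihoodRatioEntry",
    "PanelReport",
    "likelihood_ratio_table",
    "select_panel",
    "posttest_probability",
    "DEFAULT_LR_PLUS_MIN",
    "DEFAULT_LR_MINUS_MAX",
]

DEFAULT_LR_PLUS_MIN = 5.0
DEFAULT_LR_MINUS_MAX = 0.2


@dataclass(frozen=True)
class LikelihoodRatioEntry:
    symptom: str
    state: str
    disorder: str
    lr_plus: float
    lr_minus: float
    q: float
    baseline: float


@dataclass
class PanelReport:
    """Symptoms selected per disorder at a likelihood-ratio cut-off,
    sorted by diagnostic strength (boundary values included)."""

    mode: str
    threshold: float
    entries: dict[str, list[LikelihoodRatioEntry]]

    def members(self, disorder: str) -> list[str]:
        return [e.symptom for e in self.entries.get(disorder, [])]


def likelihood_ratio_table(ps: ParameterSet) -> list[LikelihoodRatioEntry]:
    """One entry per influence arc; graded arcs use the baseline of their
    target tail."""

    entries = []
    for arc in ps.arcs:
        state = arc.target_state()
        baseline = ps.baseline(arc.symptom).for_state(state)
        if baseline <= 0.0:
            raise ValueError(
                f"{arc.symptom}: baseline 0 makes LR+ undefined"
            )
        if baseline >= 1.0:
            raise ValueError(
                f"{arc.symptom}: baseline 1 makes LR- undefined"
            )
        entries.append(
            LikelihoodRatioEntry(
                symptom=arc.symptom,
                state=state,
                disorder=arc.disorder,
                lr_plus=arc.q / baseline,
                lr_minus=(1.0 - arc.q) / (1.0 - baseline),
                q=arc.q,
                baseline=baseline,
            )
        )
    return entries


def select_panel(
    entries: list[LikelihoodRatioEntry],
    mode: str,
    threshold: float | None = None,
) -> PanelReport:
    """Filter and rank the LR table into a confirmatory (LR+ >= threshold,
    default 5) or screening (LR- <= threshold, default 0.2) panel.

    Comparison uses unrounded values and includes the boundary.  Ties are
    broken by symptom id for determinism.
    """

    if not entries:
        raise ValueError("empty likelihood-ratio table")
    if mode == "confirmatory":
        threshold = DEFAULT_LR_PLUS_MIN if threshold is None else threshold
        kept = [e for e in entries if e.lr_plus >= threshold]
        key = lambda e: (-e.lr_plus, e.symptom)
    elif mode == "screening":
        threshold = DEFAULT_LR_MINUS_MAX if threshold is None else threshold
        kept = [e for e in entries if e.lr_minus <= threshold]
        key = lambda e: (e.lr_minus, e.symptom)
    else:
        raise ValueError(f"unknown panel mode {mode!r}")
    by_disorder: dict[str, list[LikelihoodRatioEntry]] = {}
    for entry in sorted(kept, key=key):
        by_disorder.setdefault(entry.disorder, []).append(entry)
    return PanelReport(mode, threshold, by_disorder)


def posttest_probability(pretest: float, lr: float) -> float:
    """Odds-form Bayes update: post-test odds = pre-test odds x LR."""

    if not 0.0 < pretest < 1.0:
        raise ValueError(f"degenerate prior {pretest}: pretest must be in "
                         f"(0, 1)")
    if lr < 0.0:
        raise ValueError(f"likelihood ratio must be nonnegative, got {lr}")
    return pretest * lr / (1.0 - pretest + pretest * lr)
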