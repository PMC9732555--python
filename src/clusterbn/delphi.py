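"""Delphi consensus elicitation: round aggregation, the one-standard-
deviation consensus rule, second-round item construction, and final
parameter extraction.

Experts rate each item (a probability to elicit) on a 0-100 scale.  After a
round, every item is summarized by its mean and sample standard deviation;
a response is *in consensus* unless it lies strictly more than one standard
deviation from the item mean.  Experts receive back only the items on which
they dissented, bundled with their prior answer and the item's mean/SD, and
may revise them; consensus answers are frozen.  The value finally adopted
for each probability is the mean of the last round, rescaled to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RoundResponses",
    "ConsensusReport",
    "FollowUpItem",
    "aggregate_round",
    "build_second_round",
    "finalize_parameters",
]

INSUFFICIENT = "insufficient responses"


@dataclass
class RoundResponses:
    """An expert x item response matrix on the 0-100 scale (NaN = missing)."""

    experts: list[str]
    items: list[str]
    responses: np.ndarray  # shape (n_experts, n_items)

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses, dtype=float)
        if self.responses.shape != (len(self.experts), len(self.items)):
            raise ValueError(
                f"response matrix shape {self.responses.shape} does not "
                f"match {len(self.experts)} experts x {len(self.items)} items"
            )
        finite = self.responses[np.isfinite(self.responses)]
        if ((finite < 0) | (finite > 100)).any():
            raise ValueError("responses must lie within [0, 100]")


@dataclass
class ConsensusReport:
    items: list[str]
    means: dict[str, float]
    sds: dict[str, float]
    flags: dict[str, dict[str, bool]]  # item -> expert -> in consensus
    excluded: list[str] = field(default_factory=list)  # < 2 responses
    consensus_rate: float = float("nan")  # % of responses within one SD


def aggregate_round(round_: RoundResponses) -> ConsensusReport:
    """Per-item mean and sample (n-1) standard deviation over the non-missing
    responses, per-response consensus flags, and the overall consensus rate.

    The consensus bound is inclusive: a response exactly one standard
    deviation from the mean still counts as consensus.  Items with fewer
    than two responses are flagged and excluded from the rate.
    """

    means: dict[str, float] = {}
    sds: dict[str, float] = {}
    flags: dict[str, dict[str, bool]] = {}
    excluded: list[str] = []
    in_consensus = 0
    total = 0
    for j, item in enumerate(round_.items):
        col = round_.responses[:, j]
        mask = np.isfinite(col)
        if mask.sum() < 2:
            excluded.append(item)
            continue
        mean = float(col[mask].mean())
        sd = float(col[mask].std(ddof=1))
        means[item] = mean
        sds[item] = sd
        flags[item] = {}
        for i, expert in enumerate(round_.experts):
            if not mask[i]:
                continue
            ok = abs(col[i] - mean) <= sd
            flags[item][expert] = bool(ok)
            total += 1
            in_consensus += ok
    rate = 100.0 * in_consensus / total if total else float("nan")
    return ConsensusReport(list(round_.items), means, sds, flags, excluded,
                           rate)


@dataclass(frozen=True)
class FollowUpItem:
    """A second-round item for one dissenting expert: the item, the expert's
    previous answer, and the group's aggregated feedback."""

    item: str
    previous_answer: float
    mean: float
    sd: float


def build_second_round(
    previous: RoundResponses,
    report: ConsensusReport,
) -> dict[str, list[FollowUpItem]]:
    """Per-expert follow-up lists: exactly the items on which the expert's
    response fell outside the consensus band.  Consensus items are frozen
    and therefore excluded."""

    if list(report.items) != list(previous.items):
        raise ValueError("consensus report does not match the round")
    followups: dict[str, list[FollowUpItem]] = {e: [] for e in previous.experts}
    for j, item in enumerate(previous.items):
        if item not in report.flags:
            continue
        for i, expert in enumerate(previous.experts):
            flag = report.flags[item].get(expert)
            if flag is False:
                followups[expert].append(
                    FollowUpItem(
                        item,
                        float(previous.responses[i, j]),
                        report.means[item],
                        report.sds[item],
                    )
                )
    return followups


def finalize_parameters(last: RoundResponses) -> dict[str, float]:
    """Item means of the final round, rescaled to [0, 1] for direct
    insertion into a parameter set."""

    report = aggregate_round(last)
    if report.excluded:
        raise ValueError(
            f"items with fewer than two responses: {report.excluded}"
        )
    return {item: report.means[item] / 100.0 for item in last.items}
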