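"""Elicited knowledge base for the cluster-B diagnostic network.

This module is the single source of truth for all downstream computation: it
defines the variable catalogue (symptoms, traits and scales from five
diagnostic frameworks), the disorder->symptom influence arcs with their
expert-elicited presence probabilities, the no-disorder baselines, the
psychological-distress links and the disorder prevalences.

All probabilities are stored as fractions in [0, 1]; the packaged tables are
tab-separated text on the 0-100 percentage scale and are converted at load
time.  Reports render back on the percentage scale.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "DISORDERS",
    "FRAMEWORKS",
    "SymptomSpec",
    "InfluenceArc",
    "BaselineSpec",
    "DistressLink",
    "PrevalenceEntry",
    "ParameterSet",
    "ParameterLoadError",
    "load_parameter_set",
    "write_parameter_set",
    "builtin_cluster_b",
    "validate_parameter_set",
    "elicitation_summary",
    "dump_parameter_set",
    "restore_parameter_set",
]

#: The five dramatic/emotional (cluster-B) personality disorders, in canonical
#: order: antisocial, borderline, narcissistic, histrionic, passive-aggressive.
DISORDERS: tuple[str, ...] = ("ATS", "BDL", "NAR", "HST", "PAG")

#: Diagnostic frameworks contributing symptom variables.
FRAMEWORKS: tuple[str, ...] = ("DSM", "DEFENSE", "LPF", "FFM", "BIOSOCIAL")

#: State spaces.  DSM criteria and defense mechanisms are binary; level of
#: personality functioning (LPF) scales and the trait variables (five-factor
#: model and Millon biosocial polarities) are graded into three states.
BINARY_STATES: tuple[str, ...] = ("absent", "present")
GRADED_STATES: tuple[str, ...] = ("low", "medium", "high")

#: Neutral (non-deviant) state per framework.  For LPF scales the neutral
#: state is the lowest; for trait variables it is the population-typical
#: medium.
NEUTRAL_STATE: dict[str, str] = {
    "DSM": "absent",
    "DEFENSE": "absent",
    "LPF": "low",
    "FFM": "medium",
    "BIOSOCIAL": "medium",
}

TOWARD_PRESENT = "toward_present"
TOWARD_HIGH = "toward_high"
TOWARD_LOW = "toward_low"

GENERAL_DISTRESS_GROUP = "PD-General"

#: NEO domain membership of the retained five-factor traits.  Openness traits
#: carry no distress link (their elicited distress is N/A), so they map to no
#: group.
FFM_DOMAIN: dict[str, str | None] = {
    "FFM-Anxiety": "Neuroticism",
    "FFM-Angry-hostility": "Neuroticism",
    "FFM-Depression": "Neuroticism",
    "FFM-Self-consciousness": "Neuroticism",
    "FFM-Impulsiveness": "Neuroticism",
    "FFM-Vulnerability": "Neuroticism",
    "FFM-Warmth": "Extraversion",
    "FFM-Gregariousness": "Extraversion",
    "FFM-Assertiveness": "Extraversion",
    "FFM-Activity": "Extraversion",
    "FFM-Excitement-seeking": "Extraversion",
    "FFM-Positive-emotions": "Extraversion",
    "FFM-Fantasy": None,
    "FFM-Feelings": None,
    "FFM-Actions": None,
    "FFM-Trust": "Agreeableness",
    "FFM-Straightforwardness": "Agreeableness",
    "FFM-Altruism": "Agreeableness",
    "FFM-Compliance": "Agreeableness",
    "FFM-Modesty": "Agreeableness",
    "FFM-Tender-mindedness": "Agreeableness",
    "FFM-Competence": "Conscientiousness",
    "FFM-Order": "Conscientiousness",
    "FFM-Dutifulness": "Conscientiousness",
    "FFM-Self-discipline": "Conscientiousness",
    "FFM-Deliberation": "Conscientiousness",
}

#: LPFS self/interpersonal split: identity and self-direction form the
#: self-functioning cluster; empathy and intimacy each keep their own node.
LPF_GROUP: dict[str, str] = {
    "LPF-Identity": "PD-LPF-Self",
    "LPF-Self-direction": "PD-LPF-Self",
    "LPF-Empathy": "PD-LPF-Empathy",
    "LPF-Intimacy": "PD-LPF-Intimacy",
}

_TABLE_FILES = {
    "DSM": "dsm.tsv",
    "DEFENSE": "defense.tsv",
    "LPF": "lpf.tsv",
    "FFM": "ffm.tsv",
    "BIOSOCIAL": "biosocial.tsv",
}
_PREVALENCE_FILE = "prevalence.tsv"
_MISSING = ("", "—", "-", "--")


class ParameterLoadError(ValueError):
    """Raised when a parameter table cannot be parsed or is malformed."""


@dataclass(frozen=True)
class SymptomSpec:
    """A symptom / trait / scale variable of the model."""

    id: str
    framework: str
    states: tuple[str, ...]
    neutral_state: str
    description: str = ""

    @property
    def is_binary(self) -> bool:
        return len(self.states) == 2


@dataclass(frozen=True)
class InfluenceArc:
    """A disorder -> symptom influence with its elicited presence probability.

    ``q`` is the probability that the arc's target state is observed when the
    disorder alone is present (the per-disorder column of the elicitation
    tables); ``direction`` names the target state.
    """

    disorder: str
    symptom: str
    direction: str
    q: float

    def target_state(self) -> str:
        return {
            TOWARD_PRESENT: "present",
            TOWARD_HIGH: "high",
            TOWARD_LOW: "low",
        }[self.direction]


@dataclass(frozen=True)
class BaselineSpec:
    """Prevalence of a symptom's deviant state(s) absent any disorder.

    Binary symptoms carry a single ``base_present``; graded symptoms carry one
    baseline per tail.  When the source table prints a single norm value for a
    two-tailed trait, it is applied to both tails; ``low_defaulted`` records a
    low tail that was not printed and defaults to the high value.
    """

    symptom: str
    base_present: float | None = None
    base_high: float | None = None
    base_low: float | None = None
    low_defaulted: bool = False

    def for_state(self, state: str) -> float:
        if state == "present":
            assert self.base_present is not None
            return self.base_present
        if state == "high":
            assert self.base_high is not None
            return self.base_high
        if state == "low":
            assert self.base_low is not None
            return self.base_low
        raise KeyError(state)


@dataclass(frozen=True)
class DistressLink:
    """Capacity of a symptom (or disorder) to cause significant distress.

    ``pd`` is the elicited probability that the source alone provokes
    clinically significant psychological distress; ``group`` is the distress
    node the source feeds.
    """

    source: str
    pd: float
    group: str


@dataclass(frozen=True)
class PrevalenceEntry:
    """Per-disorder prevalence (clinical and general population) and the
    disorder-level distress probability feeding the general distress node."""

    disorder: str
    clinical: float
    general: float
    pd: float


@dataclass
class ParameterSet:
    """The complete elicited knowledge base."""

    symptoms: list[SymptomSpec] = field(default_factory=list)
    arcs: list[InfluenceArc] = field(default_factory=list)
    baselines: list[BaselineSpec] = field(default_factory=list)
    distress: list[DistressLink] = field(default_factory=list)
    prevalence: list[PrevalenceEntry] = field(default_factory=list)

    # -- indexed access -------------------------------------------------
    def symptom(self, symptom_id: str) -> SymptomSpec:
        return self._symptom_index()[normalize_symptom_id(symptom_id)]

    def _symptom_index(self) -> dict[str, SymptomSpec]:
        return {s.id: s for s in self.symptoms}

    def baseline(self, symptom_id: str) -> BaselineSpec:
        sid = normalize_symptom_id(symptom_id)
        for b in self.baselines:
            if b.symptom == sid:
                return b
        raise KeyError(symptom_id)

    def arcs_for(self, symptom_id: str) -> list[InfluenceArc]:
        sid = normalize_symptom_id(symptom_id)
        order = {d: i for i, d in enumerate(DISORDERS)}
        return sorted(
            (a for a in self.arcs if a.symptom == sid),
            key=lambda a: order.get(a.disorder, 99),
        )

    def distress_for(self, source: str) -> DistressLink | None:
        for link in self.distress:
            if link.source == source:
                return link
        return None

    def prevalence_for(self, disorder: str) -> PrevalenceEntry:
        for p in self.prevalence:
            if p.disorder == disorder:
                return p
        raise KeyError(disorder)

    @property
    def disorders(self) -> tuple[str, ...]:
        return tuple(p.disorder for p in self.prevalence)

    def distress_groups(self) -> dict[str, list[DistressLink]]:
        groups: dict[str, list[DistressLink]] = {}
        for link in self.distress:
            groups.setdefault(link.group, []).append(link)
        return groups


def normalize_symptom_id(raw: str) -> str:
    """Map a printed spelling (``"DSM - BDL 03"``, ``"MD - Acting out"``,
    ``"LPF Empathy"``) onto the canonical slug (``"DSM-BDL-03"``)."""

    s = raw.strip().replace("–", "-")
    # collapse "DSM - BDL 03" style spacing
    s = s.replace(" - ", "-").replace(" ", "-")
    while "--" in s:
        s = s.replace("--", "-")
    parts = s.split("-")
    if not parts:
        return s
    head = parts[0].upper()
    if head in ("DSM",):
        return "-".join([head] + [p.upper() for p in parts[1:]])
    if head in ("MD", "LPF", "FFM", "BIO"):
        rest = "-".join(parts[1:])
        return f"{head}-{rest[:1].upper()}{rest[1:].lower()}" if rest else head
    return s


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

def _parse_pct(cell: str, *, file: str, row: str, fieldname: str) -> float:
    text = cell.strip().replace("%", "").replace("↑", "").replace("↓", "")
    try:
        value = float(text)
    except ValueError:
        raise ParameterLoadError(
            f"{file}: row {row!r}, field {fieldname!r}: not a number: {cell!r}"
        ) from None
    if not 0.0 <= value <= 100.0:
        raise ParameterLoadError(
            f"{file}: row {row!r}, field {fieldname!r}: "
            f"probability {value} outside [0, 100]"
        )
    return value / 100.0


def _read_rows(path: Path) -> list[dict[str, str]]:
    lines = path.read_text(encoding="utf-8").splitlines()
    lines = [ln for ln in lines if ln.strip()]
    if len(lines) < 2:
        raise ParameterLoadError(f"{path.name}: no symptom rows")
    header = lines[0].split("\t")
    rows = []
    for ln in lines[1:]:
        cells = ln.split("\t")
        if len(cells) != len(header):
            raise ParameterLoadError(
                f"{path.name}: row {cells[0]!r} has {len(cells)} fields, "
                f"expected {len(header)}"
            )
        rows.append(dict(zip(header, cells)))
    return rows


def _load_framework_table(path: Path, framework: str, ps: ParameterSet) -> None:
    fname = path.name
    graded = framework in ("LPF", "FFM", "BIOSOCIAL")
    states = GRADED_STATES if graded else BINARY_STATES
    neutral = NEUTRAL_STATE[framework]
    for row in _read_rows(path):
        sid = normalize_symptom_id(row["symptom"])
        ps.symptoms.append(SymptomSpec(sid, framework, states, neutral))
        for disorder in DISORDERS:
            if disorder not in row:
                raise ParameterLoadError(f"{fname}: missing column {disorder!r}")
            cell = row[disorder].strip()
            if cell in _MISSING:
                continue
            if framework in ("DSM", "DEFENSE"):
                direction = TOWARD_PRESENT
            elif framework == "LPF":
                direction = TOWARD_HIGH
            else:
                if cell.startswith(("-", "↓")):
                    direction = TOWARD_LOW
                elif cell.startswith(("+", "↑")):
                    direction = TOWARD_HIGH
                else:
                    raise ParameterLoadError(
                        f"{fname}: row {sid!r}, field {disorder!r}: graded arc "
                        f"needs a +/- direction prefix: {cell!r}"
                    )
                cell = cell.lstrip("+-↑↓")
            q = _parse_pct(cell, file=fname, row=sid, fieldname=disorder)
            ps.arcs.append(InfluenceArc(disorder, sid, direction, q))
        # baselines
        if framework in ("DSM", "DEFENSE"):
            b = _parse_pct(row["norm"], file=fname, row=sid, fieldname="norm")
            ps.baselines.append(BaselineSpec(sid, base_present=b))
        elif framework == "LPF":
            b = _parse_pct(row["norm"], file=fname, row=sid, fieldname="norm")
            # LPF neutral is "low"; the norm value is the baseline of "high"
            # and the low tail carries the remaining leak-free mass.
            ps.baselines.append(BaselineSpec(sid, base_high=b, base_low=0.0))
        elif framework == "FFM":
            b = _parse_pct(row["norm"], file=fname, row=sid, fieldname="norm")
            ps.baselines.append(BaselineSpec(sid, base_high=b, base_low=b))
        else:  # BIOSOCIAL: separate tail baselines, low may be unprinted
            bh = _parse_pct(row["norm_high"], file=fname, row=sid,
                            fieldname="norm_high")
            low_cell = row["norm_low"].strip()
            if low_cell in _MISSING:
                bl, defaulted = bh, True
            else:
                bl = _parse_pct(low_cell, file=fname, row=sid,
                                fieldname="norm_low")
                defaulted = False
            ps.baselines.append(
                BaselineSpec(sid, base_high=bh, base_low=bl,
                             low_defaulted=defaulted)
            )
        # distress link
        pd_cell = row["pd"].strip()
        if pd_cell.upper() == "N/A":
            continue
        pd = _parse_pct(pd_cell, file=fname, row=sid, fieldname="pd")
        group = _distress_group(sid, framework)
        if group is None:
            raise ParameterLoadError(
                f"{fname}: row {sid!r}: distress probability given but the "
                f"symptom maps to no distress group"
            )
        ps.distress.append(DistressLink(sid, pd, group))


def _distress_group(symptom_id: str, framework: str) -> str | None:
    if framework == "DSM":
        return "PD-DSM-" + symptom_id.split("-")[1]
    if framework == "DEFENSE":
        return "PD-MD"
    if framework == "LPF":
        return LPF_GROUP[symptom_id]
    if framework == "FFM":
        domain = FFM_DOMAIN.get(symptom_id)
        return None if domain is None else f"PD-FFM-{domain}"
    return None  # biosocial polarities carry no distress link


def load_parameter_set(path: str | Path) -> ParameterSet:
    """Load a parameter-table directory (one TSV per framework plus a
    prevalence file) into a validated :class:`ParameterSet`.

    Percentages are converted to [0, 1] fractions.  Malformed rows, unknown
    labels and out-of-range probabilities raise :class:`ParameterLoadError`
    naming the file, row and field.
    """

    root = Path(path)
    ps = ParameterSet()
    for framework, fname in _TABLE_FILES.items():
        fpath = root / fname
        if fpath.exists():
            _load_framework_table(fpath, framework, ps)
    if not ps.symptoms:
        raise ParameterLoadError(f"{root}: no symptom rows")
    ppath = root / _PREVALENCE_FILE
    if ppath.exists():
        for row in _read_rows(ppath):
            disorder = row["disorder"].strip().upper()
            if disorder not in DISORDERS:
                raise ParameterLoadError(
                    f"{ppath.name}: unknown disorder code {disorder!r}"
                )
            ps.prevalence.append(
                PrevalenceEntry(
                    disorder,
                    clinical=_parse_pct(row["clinical"], file=ppath.name,
                                        row=disorder, fieldname="clinical"),
                    general=_parse_pct(row["general"], file=ppath.name,
                                       row=disorder, fieldname="general"),
                    pd=_parse_pct(row["pd"], file=ppath.name, row=disorder,
                                  fieldname="pd"),
                )
            )
        for entry in ps.prevalence:
            ps.distress.append(
                DistressLink(entry.disorder, entry.pd, GENERAL_DISTRESS_GROUP)
            )
    return ps


def _fmt_pct(value: float) -> str:
    """Render a fraction on the percentage scale, losslessly for the 0.1%
    grid the elicitation scale uses."""

    pct = value * 100.0
    return f"{pct:.10g}"


def write_parameter_set(ps: ParameterSet, path: str | Path) -> None:
    """Write a :class:`ParameterSet` back to the tabular directory layout.

    ``load_parameter_set(write_parameter_set(ps))`` reproduces ``ps``
    field-for-field for values on the elicitation grid.
    """

    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    arcs_by_symptom: dict[str, dict[str, InfluenceArc]] = {}
    for arc in ps.arcs:
        arcs_by_symptom.setdefault(arc.symptom, {})[arc.disorder] = arc
    by_framework: dict[str, list[SymptomSpec]] = {}
    for spec in ps.symptoms:
        by_framework.setdefault(spec.framework, []).append(spec)
    for framework, fname in _TABLE_FILES.items():
        specs = by_framework.get(framework)
        if not specs:
            continue
        if framework == "BIOSOCIAL":
            header = ["symptom", *DISORDERS, "norm_high", "norm_low", "pd"]
        else:
            header = ["symptom", *DISORDERS, "norm", "pd"]
        lines = ["\t".join(header)]
        for spec in specs:
            cells = [spec.id]
            for disorder in DISORDERS:
                arc = arcs_by_symptom.get(spec.id, {}).get(disorder)
                if arc is None:
                    cells.append("—")
                elif arc.direction == TOWARD_LOW:
                    cells.append("-" + _fmt_pct(arc.q))
                elif arc.direction == TOWARD_HIGH and framework != "LPF":
                    cells.append("+" + _fmt_pct(arc.q))
                else:
                    cells.append(_fmt_pct(arc.q))
            b = ps.baseline(spec.id)
            if framework in ("DSM", "DEFENSE"):
                cells.append(_fmt_pct(b.base_present))
            elif framework in ("LPF", "FFM"):
                cells.append(_fmt_pct(b.base_high))
            else:
                cells.append(_fmt_pct(b.base_high))
                cells.append("—" if b.low_defaulted else _fmt_pct(b.base_low))
            link = ps.distress_for(spec.id)
            cells.append("N/A" if link is None else _fmt_pct(link.pd))
            lines.append("\t".join(cells))
        (root / fname).write_text("\n".join(lines) + "\n", encoding="utf-8")
    if ps.prevalence:
        lines = ["\t".join(["disorder", "clinical", "general", "pd"])]
        for p in ps.prevalence:
            lines.append("\t".join([p.disorder, _fmt_pct(p.clinical),
                                    _fmt_pct(p.general), _fmt_pct(p.pd)]))
        (root / _PREVALENCE_FILE).write_text("\n".join(lines) + "\n",
                                             encoding="utf-8")


def builtin_cluster_b() -> ParameterSet:
    """The packaged transcription of the full elicited knowledge base:
    86 symptom variables, 179 influence arcs, 14 distress groups and the five
    disorder prevalences."""

    data_dir = resources.files("clusterbn") / "data"
    with resources.as_file(data_dir) as path:
        return load_parameter_set(path)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_parameter_set(ps: ParameterSet) -> list[str]:
    """Check every invariant of the knowledge base; returns the list of
    violations (empty iff valid).  Validation reports, it never raises."""

    violations: list[str] = []
    index = {s.id: s for s in ps.symptoms}
    if len(index) != len(ps.symptoms):
        seen: set[str] = set()
        for s in ps.symptoms:
            if s.id in seen:
                violations.append(f"duplicate symptom id {s.id!r}")
            seen.add(s.id)
    if not ps.symptoms:
        violations.append("no symptoms declared")
    for s in ps.symptoms:
        if s.framework not in FRAMEWORKS:
            violations.append(f"{s.id}: unknown framework {s.framework!r}")
            continue
        expected = GRADED_STATES if s.framework in ("LPF", "FFM", "BIOSOCIAL") \
            else BINARY_STATES
        if s.states != expected:
            violations.append(f"{s.id}: states {s.states} != {expected}")
        if s.neutral_state != NEUTRAL_STATE[s.framework]:
            violations.append(
                f"{s.id}: neutral state {s.neutral_state!r} != "
                f"{NEUTRAL_STATE[s.framework]!r}"
            )
    baseline_count: dict[str, int] = {}
    for b in ps.baselines:
        baseline_count[b.symptom] = baseline_count.get(b.symptom, 0) + 1
        spec = index.get(b.symptom)
        if spec is None:
            violations.append(f"dangling baseline for {b.symptom!r}")
            continue
        if spec.is_binary:
            if b.base_present is None or not 0 <= b.base_present <= 1:
                violations.append(f"{b.symptom}: invalid binary baseline")
        else:
            if b.base_high is None or b.base_low is None:
                violations.append(f"{b.symptom}: missing tail baseline")
            elif b.base_high + b.base_low >= 1:
                violations.append(
                    f"{b.symptom}: tail baselines sum to "
                    f"{b.base_high + b.base_low:.4f} >= 1"
                )
    for sid in index:
        if baseline_count.get(sid, 0) != 1:
            violations.append(
                f"{sid}: expected exactly one baseline record, found "
                f"{baseline_count.get(sid, 0)}"
            )
    for arc in ps.arcs:
        if arc.disorder not in DISORDERS:
            violations.append(f"arc {arc.symptom}: unknown disorder "
                              f"{arc.disorder!r}")
        spec = index.get(arc.symptom)
        if spec is None:
            violations.append(f"dangling arc ({arc.disorder} -> "
                              f"{arc.symptom!r})")
            continue
        if spec.is_binary and arc.direction != TOWARD_PRESENT:
            violations.append(f"{arc.symptom}: binary symptom with graded "
                              f"direction {arc.direction!r}")
        if not spec.is_binary and arc.direction == TOWARD_PRESENT:
            violations.append(f"{arc.symptom}: graded symptom with binary "
                              f"direction")
        if not 0 <= arc.q <= 1:
            violations.append(f"{arc.symptom} ({arc.disorder}): q={arc.q} "
                              f"outside [0,1]")
            continue
        if baseline_count.get(arc.symptom, 0) == 1:
            try:
                base = ps.baseline(arc.symptom).for_state(arc.target_state())
            except (AssertionError, KeyError):
                continue
            if arc.q <= base:
                violations.append(
                    f"arc weaker than baseline: {arc.disorder} -> "
                    f"{arc.symptom} ({arc.direction}): q={arc.q:.4f} <= "
                    f"baseline {base:.4f}"
                )
    declared = set(index) | set(DISORDERS)
    for link in ps.distress:
        if link.source not in declared:
            violations.append(f"dangling distress link for {link.source!r}")
        if not 0 <= link.pd <= 1:
            violations.append(f"{link.source}: distress probability "
                              f"{link.pd} outside [0,1]")
    seen_disorders: set[str] = set()
    for p in ps.prevalence:
        if p.disorder in seen_disorders:
            violations.append(f"duplicate prevalence entry for {p.disorder}")
        seen_disorders.add(p.disorder)
        for label, value in (("clinical", p.clinical), ("general", p.general),
                             ("pd", p.pd)):
            if not 0 < value < 1:
                violations.append(
                    f"{p.disorder}: {label} prevalence {value} outside (0,1)"
                )
        if p.clinical <= p.general:
            violations.append(
                f"{p.disorder}: clinical prevalence {p.clinical:.4f} not "
                f"greater than general {p.general:.4f}"
            )
    return violations


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

def _mean_sd(values: list[float]) -> tuple[float, float]:
    n = len(values)
    mean = sum(values) / n
    if n < 2:
        return mean, 0.0
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    return mean, math.sqrt(var)


def elicitation_summary(ps: ParameterSet) -> dict[str, float]:
    """Mean and sample standard deviation (percentage scale) of the elicited
    quantities: arc presence probabilities, baselines, and symptom distress
    probabilities.

    Baselines are counted once per printed value: a graded trait whose two
    tails share a single printed norm contributes one value; separately
    printed tail baselines contribute two.
    """

    if not ps.arcs:
        raise ValueError("empty parameter set: no arcs to summarize")
    arc_values = [a.q * 100 for a in ps.arcs]
    base_values: list[float] = []
    for b in ps.baselines:
        if b.base_present is not None:
            base_values.append(b.base_present * 100)
        else:
            base_values.append(b.base_high * 100)
            if not b.low_defaulted and b.base_low != b.base_high \
                    and b.base_low > 0:
                base_values.append(b.base_low * 100)
    pd_values = [l.pd * 100 for l in ps.distress
                 if l.group != GENERAL_DISTRESS_GROUP]
    out: dict[str, float] = {}
    out["arc_mean"], out["arc_sd"] = _mean_sd(arc_values)
    out["n_arcs"] = float(len(arc_values))
    if base_values:
        out["baseline_mean"], out["baseline_sd"] = _mean_sd(base_values)
        out["n_baselines"] = float(len(base_values))
    if pd_values:
        out["distress_mean"], out["distress_sd"] = _mean_sd(pd_values)
        out["n_distress"] = float(len(pd_values))
    return out


# ---------------------------------------------------------------------------
# structured dump / restore (provenance document)
# ---------------------------------------------------------------------------

def dump_parameter_set(ps: ParameterSet, path: str | Path) -> None:
    """Serialize the full knowledge base to a single nested structured-text
    (JSON) document for provenance."""

    doc = {
        "symptoms": [vars(s).copy() | {"states": list(s.states)}
                     for s in ps.symptoms],
        "arcs": [vars(a).copy() for a in ps.arcs],
        "baselines": [vars(b).copy() for b in ps.baselines],
        "distress": [vars(l).copy() for l in ps.distress],
        "prevalence": [vars(p).copy() for p in ps.prevalence],
    }
    Path(path).write_text(json.dumps(doc, indent=1), encoding="utf-8")


def restore_parameter_set(path: str | Path) -> ParameterSet:
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    return ParameterSet(
        symptoms=[SymptomSpec(**{**d, "states": tuple(d["states"])})
                  for d in doc["symptoms"]],
        arcs=[InfluenceArc(**d) for d in doc["arcs"]],
        baselines=[BaselineSpec(**d) for d in doc["baselines"]],
        distress=[DistressLink(**d) for d in doc["distress"]],
        prevalence=[PrevalenceEntry(**d) for d in doc["prevalence"]],
    )
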