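"""Model and evidence I/O: XMLBIF export/import and evidence files.

XMLBIF (version 0.3) is the vendor-neutral interchange format used to hand
the network to other Bayesian-network tools.  Tables are written row-major
over the parent configurations (the first GIVEN parent varies slowest) with
the child states varying fastest, at 12 significant digits so that a
round-trip reproduces every entry to 1e-12.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from lxml import etree

from .canonical import CPT
from .network import (
    ROLE_DISORDER,
    NetworkModel,
    Node,
)

__all__ = [
    "export_xmlbif",
    "import_xmlbif",
    "read_evidence_file",
    "write_evidence_file",
]


def export_xmlbif(model: NetworkModel, path: str | Path) -> None:
    """Write the model as well-formed XMLBIF 0.3."""

    bif = etree.Element("BIF", VERSION="0.3")
    net = etree.SubElement(bif, "NETWORK")
    etree.SubElement(net, "NAME").text = "clusterbn"
    etree.SubElement(net, "PROPERTY").text = f"population = {model.population}"
    for node in model.nodes.values():
        var = etree.SubElement(net, "VARIABLE", TYPE="nature")
        etree.SubElement(var, "NAME").text = node.id
        for state in node.states:
            etree.SubElement(var, "OUTCOME").text = state
        etree.SubElement(var, "PROPERTY").text = f"role = {node.role}"
    for node in model.nodes.values():
        definition = etree.SubElement(net, "DEFINITION")
        etree.SubElement(definition, "FOR").text = node.id
        for parent in node.parents:
            etree.SubElement(definition, "GIVEN").text = parent
        if node.role == ROLE_DISORDER:
            flat = np.array([1.0 - node.prior, node.prior])
        else:
            flat = node.cpt.table.reshape(-1)
        etree.SubElement(definition, "TABLE").text = " ".join(
            f"{v:.12g}" for v in flat
        )
    tree = etree.ElementTree(bif)
    tree.write(str(path), pretty_print=True, xml_declaration=True,
               encoding="UTF-8")


def import_xmlbif(path: str | Path) -> NetworkModel:
    """Read an XMLBIF file written by :func:`export_xmlbif` back into a
    :class:`NetworkModel`.

    Distress nodes come back with explicit tables (the closed-form noisy-OR
    decomposition is not part of the interchange format); inference falls
    back to explicit marginalization for them.
    """

    tree = etree.parse(str(path))
    net = tree.find("NETWORK")
    population = "clinical"
    for prop in net.findall("PROPERTY"):
        text = (prop.text or "").strip()
        if text.startswith("population"):
            population = text.split("=", 1)[1].strip()
    model = NetworkModel(population=population)
    states: dict[str, tuple[str, ...]] = {}
    roles: dict[str, str] = {}
    for var in net.findall("VARIABLE"):
        name = var.findtext("NAME").strip()
        outcomes = tuple(o.text.strip() for o in var.findall("OUTCOME"))
        states[name] = outcomes
        role = "symptom"
        for prop in var.findall("PROPERTY"):
            text = (prop.text or "").strip()
            if text.startswith("role"):
                role = text.split("=", 1)[1].strip()
        roles[name] = role
    for definition in net.findall("DEFINITION"):
        name = definition.findtext("FOR").strip()
        parents = tuple(g.text.strip() for g in definition.findall("GIVEN"))
        flat = np.array([float(v) for v in
                         definition.findtext("TABLE").split()])
        if roles[name] == ROLE_DISORDER and not parents:
            model.nodes[name] = Node(name, roles[name], states[name],
                                     prior=float(flat[1]))
            continue
        n_states = len(states[name])
        table = flat.reshape(-1, n_states)
        cpt = CPT(name, parents, tuple(states[p] for p in parents),
                  states[name], table)
        model.nodes[name] = Node(name, roles[name], states[name],
                                 parents=parents, cpt=cpt)
    return model


def read_evidence_file(path: str | Path) -> dict[str, str]:
    """Parse an evidence file: one ``node<TAB>state`` (or ``node=state``)
    finding per line; ``#`` starts a comment."""

    findings: dict[str, str] = {}
    for lineno, raw in enumerate(
        Path(path).read_text(encoding="utf-8").splitlines(), start=1
    ):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "\t" in line:
            node, state = line.split("\t", 1)
        elif "=" in line:
            node, state = line.split("=", 1)
        else:
            raise ValueError(
                f"{path}:{lineno}: expected 'node<TAB>state' or "
                f"'node=state', got {raw!r}"
            )
        node, state = node.strip(), state.strip()
        if node in findings:
            raise ValueError(f"{path}:{lineno}: duplicate finding for "
                             f"{node!r}")
        findings[node] = state
    return findings


def write_evidence_file(findings: dict[str, str], path: str | Path) -> None:
    Path(path).write_text(
        "".join(f"{node}\t{state}\n" for node, state in findings.items()),
        encoding="utf-8",
    )
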