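"""Molecular knowledge base: element-property triples and graph augmentation.

Every covered element carries exactly five discrete property labels —
periodicity, metallicity, group, radius group and weight group — and each
label becomes a typed virtual node with a directed edge *into* the atoms it
describes. Functional-group substructure matches likewise become virtual
nodes wired to their member atoms. Atom–atom bonds stay bidirectional;
knowledge edges are strictly one-way (property → atom).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit import Chem

from .molio import MolecularGraph

logger = logging.getLogger(__name__)

#: the five property categories and their relation names
PROPERTY_CATEGORIES: tuple[str, ...] = ("period", "metallicity", "group", "radius", "weight")
RELATION_NAMES: dict[str, str] = {
    "period": "isperiodOf",
    "metallicity": "ismetallicityOf",
    "group": "isgroupOf",
    "radius": "isradiusOf",
    "weight": "isweightOf",
}
#: relation label used for functional-group → member-atom edges
FUNCTIONAL_GROUP_RELATION = "issubstructureOf"


class KnowledgeError(ValueError):
    """Configuration problem in the knowledge base (bad table, uncovered element)."""


@dataclass(frozen=True)
class Triple:
    head: str  # property-group label, e.g. "Weight2"
    relation: str  # e.g. "isweightOf"
    tail: str  # element symbol

    def __post_init__(self):
        valid = set(RELATION_NAMES.values())
        if self.relation not in valid:
            raise KnowledgeError(f"unknown relation {self.relation!r}; expected one of {sorted(valid)}")


@dataclass(frozen=True)
class FunctionalGroup:
    name: str
    smarts: str
    include_h: bool
    pattern: Chem.Mol = field(repr=False, compare=False, default=None)


@dataclass
class KnowledgeBase:
    """Element → five property labels, plus functional-group patterns."""

    element_properties: dict[str, dict[str, str]]
    functional_groups: list[FunctionalGroup]

    def labels_for(self, symbol: str) -> dict[str, str]:
        try:
            return self.element_properties[symbol]
        except KeyError:
            raise KnowledgeError(f"element {symbol!r} not covered by the knowledge base") from None

    def triples(self) -> list[Triple]:
        out = []
        for symbol, props in self.element_properties.items():
            for cat in PROPERTY_CATEGORIES:
                out.append(Triple(head=props[cat], relation=RELATION_NAMES[cat], tail=symbol))
        return out

    @property
    def property_labels(self) -> list[str]:
        labels = {p[cat] for p in self.element_properties.values() for cat in PROPERTY_CATEGORIES}
        return sorted(labels)


def _default_periodic_table() -> pd.DataFrame:
    with resources.files("sgatt.data").joinpath("periodic_table.csv").open() as fh:
        return pd.read_csv(fh)


def _default_fg_table() -> pd.DataFrame:
    with resources.files("sgatt.data").joinpath("functional_groups.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def _quantile_labels(values: pd.Series, n_bins: int, prefix: str) -> pd.Series:
    """Discretise a continuous attribute into `prefix`1..`prefix`N quantile groups."""
    if n_bins == 1:
        return pd.Series([f"{prefix}1"] * len(values), index=values.index)
    binned = pd.qcut(values.rank(method="first"), q=n_bins, labels=False, duplicates="drop")
    return binned.map(lambda b: f"{prefix}{int(b) + 1}")


def build_knowledge_base(
    periodic_table: pd.DataFrame | str | Path | None = None,
    n_bins: int = 5,
    fg_patterns: pd.DataFrame | str | Path | None = None,
) -> KnowledgeBase:
    """Build the knowledge base from an element-attribute table.

    Parameters
    ----------
    periodic_table
        DataFrame (or CSV path) with columns symbol, period, group,
        metallicity, radius_pm, weight. Defaults to the bundled table.
    n_bins
        Number of quantile groups for the continuous radius and weight
        attributes (≥ 1; labels "Radius1…", "Weight1…").
    fg_patterns
        DataFrame (or TSV path) with columns name, smarts and optional
        include_h. Defaults to the bundled functional-group table.
    """
    if periodic_table is None:
        table = _default_periodic_table()
    elif isinstance(periodic_table, (str, Path)):
        table = pd.read_csv(periodic_table)
    else:
        table = periodic_table.copy()
    if n_bins < 1:
        raise KnowledgeError(f"n_bins must be >= 1, got {n_bins}")

    required = {"symbol", "period", "group", "metallicity", "radius_pm", "weight"}
    missing_cols = required - set(table.columns)
    if missing_cols:
        raise KnowledgeError(f"periodic table missing columns: {sorted(missing_cols)}")
    bad = table[table[list(required)].isna().any(axis=1)]
    if len(bad):
        raise KnowledgeError(f"elements missing attributes: {sorted(bad['symbol'].tolist())}")

    table = table.reset_index(drop=True)
    radius_labels = _quantile_labels(table["radius_pm"].astype(float), n_bins, "Radius")
    weight_labels = _quantile_labels(table["weight"].astype(float), n_bins, "Weight")

    element_properties: dict[str, dict[str, str]] = {}
    for idx, row in table.iterrows():
        element_properties[str(row["symbol"])] = {
            "period": f"Period{int(row['period'])}",
            "metallicity": str(row["metallicity"]).capitalize(),
            "group": f"Group{int(row['group'])}",
            "radius": radius_labels.loc[idx],
            "weight": weight_labels.loc[idx],
        }

    if fg_patterns is None:
        fg_table = _default_fg_table()
    elif isinstance(fg_patterns, (str, Path)):
        fg_table = pd.read_csv(fg_patterns, sep="\t")
    else:
        fg_table = fg_patterns.copy()
    if not {"name", "smarts"} <= set(fg_table.columns):
        raise KnowledgeError("functional-group table needs columns: name, smarts")

    groups: list[FunctionalGroup] = []
    for _, row in fg_table.iterrows():
        patt = Chem.MolFromSmarts(str(row["smarts"]))
        if patt is None:
            raise KnowledgeError(f"malformed SMARTS for group {row['name']!r}: {row['smarts']!r}")
        include_h = bool(int(row["include_h"])) if "include_h" in fg_table.columns else False
        groups.append(FunctionalGroup(str(row["name"]), str(row["smarts"]), include_h, patt))

    return KnowledgeBase(element_properties=element_properties, functional_groups=groups)


def match_functional_groups(
    graph: MolecularGraph, kb: KnowledgeBase
) -> list[tuple[str, frozenset[int]]]:
    """Find functional-group occurrences; returns (name, atom index set) records.

    Matches with identical atom sets are deduplicated; results are ordered
    by group-table order then lowest atom index. For groups flagged
    ``include_h`` on an explicit-H graph, attached hydrogens of matched
    heavy atoms join the member set (the hydroxyl virtual node connects to
    both O and H).
    """
    mol = graph.rdkit_mol()
    results: list[tuple[str, frozenset[int]]] = []
    for fg in kb.functional_groups:
        matches = mol.GetSubstructMatches(fg.pattern, uniquify=True)
        seen: set[frozenset[int]] = set()
        found: list[frozenset[int]] = []
        for match in matches:
            atoms = set(match)
            if fg.include_h and graph.explicit_h:
                for idx in list(atoms):
                    for nbr in mol.GetAtomWithIdx(idx).GetNeighbors():
                        if nbr.GetSymbol() == "H":
                            atoms.add(nbr.GetIdx())
            fs = frozenset(atoms)
            if fs not in seen:
                seen.add(fs)
                found.append(fs)
        found.sort(key=min)
        results.extend((fg.name, fs) for fs in found)
    return results


@dataclass(frozen=True)
class VirtualNode:
    id: int  # index within the augmented graph (offset past atoms)
    kind: str  # "element-property" | "functional-group"
    label: str  # e.g. "Weight2" or "hydroxyl"


@dataclass(frozen=True)
class VirtualEdge:
    source: int  # virtual node id
    target: int  # atom index
    relation: str


@dataclass
class AugmentedGraph:
    """Molecular graph plus typed virtual nodes and directed property→atom edges."""

    base: MolecularGraph
    virtual_nodes: list[VirtualNode]
    virtual_edges: list[VirtualEdge]

    @property
    def num_nodes(self) -> int:
        return self.base.num_atoms + len(self.virtual_nodes)

    @property
    def node_kinds(self) -> list[str]:
        return ["atom"] * self.base.num_atoms + [v.kind for v in self.virtual_nodes]

    def property_edges_for(self, atom_index: int) -> list[VirtualEdge]:
        by_id = {v.id: v for v in self.virtual_nodes}
        return [
            e
            for e in self.virtual_edges
            if e.target == atom_index and by_id[e.source].kind == "element-property"
        ]

    def to_json(self) -> str:
        return json.dumps(
            {
                "base": json.loads(self.base.to_json()),
                "virtual_nodes": [
                    {"id": v.id, "kind": v.kind, "label": v.label} for v in self.virtual_nodes
                ],
                "virtual_edges": [
                    {"source": e.source, "target": e.target, "relation": e.relation}
                    for e in self.virtual_edges
                ],
            }
        )


def augment_graph(graph: MolecularGraph, kb: KnowledgeBase) -> AugmentedGraph:
    """Attach knowledge virtual nodes to a molecular graph.

    Per atom: five property virtual nodes (one per category), shared
    between atoms carrying the same label. Per functional-group match: one
    virtual node with a directed edge to each member atom. The base graph
    is embedded untouched.
    """
    if isinstance(graph, AugmentedGraph):
        raise TypeError("graph is already augmented")

    n_atoms = graph.num_atoms
    label_to_node: dict[str, VirtualNode] = {}
    virtual_nodes: list[VirtualNode] = []
    virtual_edges: list[VirtualEdge] = []

    def get_property_node(label: str) -> VirtualNode:
        node = label_to_node.get(label)
        if node is None:
            node = VirtualNode(id=n_atoms + len(virtual_nodes), kind="element-property", label=label)
            label_to_node[label] = node
            virtual_nodes.append(node)
        return node

    for atom in graph.nodes:
        props = kb.labels_for(atom.symbol)
        for cat in PROPERTY_CATEGORIES:
            node = get_property_node(props[cat])
            virtual_edges.append(
                VirtualEdge(source=node.id, target=atom.index, relation=RELATION_NAMES[cat])
            )

    for name, atom_set in match_functional_groups(graph, kb):
        node = VirtualNode(id=n_atoms + len(virtual_nodes), kind="functional-group", label=name)
        virtual_nodes.append(node)
        for idx in sorted(atom_set):
            virtual_edges.append(
                VirtualEdge(source=node.id, target=idx, relation=FUNCTIONAL_GROUP_RELATION)
            )

    return AugmentedGraph(base=graph, virtual_nodes=virtual_nodes, virtual_edges=virtual_edges)
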