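"""Per-structure subunit interaction network: assembly, typing and export.

The network has one node per subunit and one undirected edge per binary
interaction that passes the contact-pair thresholds.  Eight subunit kinds
give 36 unordered interaction types (8 self-pairs + 28 cross-pairs), coded
with the short kind symbols D, C, N, L, U, P, DNA, RNA.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

import networkx as nx
import pandas as pd

from .annotation import (AnnotationParams, DomainAssignment, KIND_CODE,
                         KIND_ORDER, SubunitSpan, annotate_structure)
from .contacts import (BinaryInteraction, ContactPair, ContactParams,
                       detect_interaction, interaction_code)
from .structure_io import StructureModel

__all__ = [
    "InteractionTypeLabel",
    "InteractionNetwork",
    "enumerate_interaction_types",
    "build_network",
    "export_network",
    "load_network_json",
    "network_summary",
    "summary_table",
]


@dataclass(frozen=True)
class InteractionTypeLabel:
    """One of the 36 interaction-type codes with its unordered kind pair."""

    code: str
    kinds: frozenset


@dataclass
class InteractionNetwork:
    """Subunits (nodes) and passing binary interactions (edges) of one
    structure, together with the parameter snapshot that produced them."""

    entry_id: str
    nodes: list[SubunitSpan]
    edges: list[BinaryInteraction]
    contact_params: ContactParams = field(default_factory=ContactParams)
    annotation_params: AnnotationParams = field(
        default_factory=AnnotationParams)

    def node_by_label(self, label: str) -> SubunitSpan:
        for n in self.nodes:
            if n.label == label:
                return n
        raise KeyError(
            f"no subunit {label!r}; valid labels: "
            + ", ".join(sorted(n.label for n in self.nodes)))


def enumerate_interaction_types() -> list[InteractionTypeLabel]:
    """All 36 type labels, each unordered kind pair exactly once, in
    canonical kind order."""
    labels = []
    for i, ka in enumerate(KIND_ORDER):
        for kb in KIND_ORDER[i:]:
            labels.append(InteractionTypeLabel(
                code=interaction_code(ka, kb), kinds=frozenset({ka, kb})))
    return labels


def build_network(structure: StructureModel,
                  assignments: Iterable[DomainAssignment] = (),
                  params: ContactParams = ContactParams(),
                  annotation_params: AnnotationParams = AnnotationParams(),
                  include_unpaired_dna: bool = False) -> InteractionNetwork:
    """Annotate a structure and detect all binary interactions.

    Nodes are the annotated subunits (hybrid chains are never annotated;
    DNA chains without an inter-chain base-pair partner are excluded unless
    ``include_unpaired_dna``).  Every unordered node pair is tested; nodes
    whose contacts stay below threshold remain in the network as isolated
    nodes.
    """
    spans = annotate_structure(structure, assignments, annotation_params)
    if not include_unpaired_dna:
        spans = [s for s in spans if "unpaired" not in s.flags]
    edges: list[BinaryInteraction] = []
    for i, sa in enumerate(spans):
        for sb in spans[i + 1:]:
            inter = detect_interaction(sa, sb, structure, params)
            if inter is not None:
                edges.append(inter)
    return InteractionNetwork(entry_id=structure.entry_id, nodes=spans,
                              edges=edges, contact_params=params,
                              annotation_params=annotation_params)


# ---------------------------------------------------------------------------
# serialization

def _span_to_dict(span: SubunitSpan) -> dict:
    d = {
        "subunit_kind": span.subunit_kind,
        "chain_id": span.chain_id,
        "segments": [list(s) for s in span.segments],
        "label": span.label,
        "flags": sorted(span.flags),
    }
    if span.annotation is not None:
        d["annotation"] = asdict(span.annotation)
    return d


def _span_from_dict(d: dict) -> SubunitSpan:
    ann = None
    if d.get("annotation"):
        ann = DomainAssignment(**d["annotation"])
    return SubunitSpan(
        subunit_kind=d["subunit_kind"], chain_id=d["chain_id"],
        segments=tuple(tuple(s) for s in d["segments"]),
        label=d.get("label", ""), annotation=ann,
        flags=frozenset(d.get("flags", [])))


def _edge_to_dict(edge: BinaryInteraction) -> dict:
    return {
        "subunit_a": edge.subunit_a.label,
        "subunit_b": edge.subunit_b.label,
        "interaction_type": edge.interaction_type,
        "is_intra_chain": edge.is_intra_chain,
        "contact_pairs": [
            {"chain_a": p.unit_a.chain_id, "seq_a": p.unit_a.seq_index,
             "auth_a": p.unit_a.auth_seq_id, "comp_a": p.unit_a.comp_id,
             "chain_b": p.unit_b.chain_id, "seq_b": p.unit_b.seq_index,
             "auth_b": p.unit_b.auth_seq_id, "comp_b": p.unit_b.comp_id,
             "min_distance": round(p.min_distance, 6),
             "atom_a": p.atom_a, "atom_b": p.atom_b}
            for p in edge.contact_pairs],
    }


def network_to_dict(network: InteractionNetwork) -> dict:
    return {
        "entry_id": network.entry_id,
        "nodes": [_span_to_dict(n) for n in network.nodes],
        "edges": [_edge_to_dict(e) for e in network.edges],
        "contact_params": asdict(network.contact_params),
        "annotation_params": asdict(network.annotation_params),
    }


def export_network(network: InteractionNetwork, format: str, path) -> None:
    """Write a network as ``json`` (lossless), ``graphml`` or a ``tsv``
    edge list."""
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(network_to_dict(network), indent=1))
    elif format == "graphml":
        g = _to_networkx(network)
        nx.write_graphml(g, str(path))
    elif format == "tsv":
        lines = ["subunit_a\tsubunit_b\tinteraction_type\tis_intra_chain\t"
                 "n_contact_pairs"]
        for e in network.edges:
            lines.append("\t".join([
                e.subunit_a.label, e.subunit_b.label, e.interaction_type,
                str(int(e.is_intra_chain)), str(len(e.contact_pairs))]))
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown export format {format!r}")


def _to_networkx(network: InteractionNetwork) -> nx.Graph:
    g = nx.Graph(entry_id=network.entry_id)
    for n in network.nodes:
        g.add_node(n.label, kind=n.subunit_kind, kind_code=n.kind_code,
                   chain=n.chain_id, start=n.start_index, end=n.end_index)
    for e in network.edges:
        g.add_edge(e.subunit_a.label, e.subunit_b.label,
                   interaction_type=e.interaction_type,
                   n_contact_pairs=len(e.contact_pairs),
                   is_intra_chain=e.is_intra_chain)
    return g


class _UnitStub:
    """Minimal unit reference reconstructed from serialized contact pairs."""

    __slots__ = ("chain_id", "seq_index", "auth_seq_id", "comp_id")

    def __init__(self, chain_id, seq_index, auth_seq_id, comp_id):
        self.chain_id = chain_id
        self.seq_index = seq_index
        self.auth_seq_id = auth_seq_id
        self.comp_id = comp_id


def load_network_json(path) -> InteractionNetwork:
    """Rebuild a network from its JSON export (nodes, edges and params are
    reconstructed; contact-pair unit references become lightweight stubs)."""
    data = json.loads(Path(path).read_text())
    nodes = [_span_from_dict(d) for d in data["nodes"]]
    by_label = {n.label: n for n in nodes}
    edges = []
    for ed in data["edges"]:
        pairs = [ContactPair(
            _UnitStub(p["chain_a"], p["seq_a"], p["auth_a"], p["comp_a"]),
            _UnitStub(p["chain_b"], p["seq_b"], p["auth_b"], p["comp_b"]),
            p["min_distance"], p["atom_a"], p["atom_b"])
            for p in ed["contact_pairs"]]
        edges.append(BinaryInteraction(
            subunit_a=by_label[ed["subunit_a"]],
            subunit_b=by_label[ed["subunit_b"]],
            contact_pairs=pairs,
            interaction_type=ed["interaction_type"],
            is_intra_chain=ed["is_intra_chain"]))
    return InteractionNetwork(
        entry_id=data["entry_id"], nodes=nodes, edges=edges,
        contact_params=ContactParams(**data["contact_params"]),
        annotation_params=AnnotationParams(**data["annotation_params"]))


# ---------------------------------------------------------------------------
# summary

def network_summary(network: InteractionNetwork) -> dict:
    """Edge counts over all 36 interaction-type codes (zeros included)."""
    counts = {t.code: 0 for t in enumerate_interaction_types()}
    for e in network.edges:
        counts[e.interaction_type] += 1
    return counts


def summary_table(network: InteractionNetwork) -> pd.DataFrame:
    """8x8 upper-triangular count matrix over the kind codes."""
    codes = [KIND_CODE[k] for k in KIND_ORDER]
    df = pd.DataFrame(0, index=codes, columns=codes, dtype=int)
    for e in network.edges:
        a, b = _split_code(e.interaction_type)
        df.loc[a, b] += 1
    return df


def _split_code(code: str) -> tuple[str, str]:
    # codes are built from the fixed symbols; resolve e.g. "DNA-RNA"
    symbols = sorted({KIND_CODE[k] for k in KIND_ORDER}, key=len,
                     reverse=True)
    for s in symbols:
        if code.startswith(s + "-"):
            return s, code[len(s) + 1:]
    raise ValueError(f"unparseable type code {code!r}")
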