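"""Interface contact detection and binary-interaction decisions.

Three contact definitions are implemented:

* protein-protein — two residues are a contact pair when the smallest
  Euclidean distance between their heavy atoms is no more than 6 A;
* protein-nucleic — a residue and a nucleotide are a contact pair when some
  oxygen or nitrogen atom of the nucleic *base* lies within 3.5 A of a
  heavy atom of the residue;
* nucleic-nucleic — two nucleotides are a contact pair when some N-N or
  O-N atom pair (never O-O) is within 3.5 A.

Distances exactly at a cutoff qualify; comparisons use a 1e-9 A tolerance
so boundary fixtures behave identically across platforms.  A k-d tree
accelerates the atom search; the per-pair result is exactly the brute-force
all-pairs answer.  Contact pairs between sequence-adjacent subunits of the
same chain that are fewer than 11 residues apart are discarded as
covalent-proximity false positives before the minimum-pair-count rule is
applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .annotation import KIND_CODE, KIND_ORDER, NUCLEIC_KINDS, PROTEIN_KINDS, \
    SubunitSpan
from .structure_io import PolymerUnit, StructureModel

logger = logging.getLogger(__name__)

__all__ = [
    "ContactParams",
    "ContactPair",
    "BinaryInteraction",
    "min_heavy_atom_distance",
    "protein_protein_contacts",
    "protein_nucleic_contacts",
    "nucleic_nucleic_contacts",
    "apply_adjacency_exclusion",
    "detect_interaction",
    "interaction_code",
    "contact_pairs_to_tsv",
]

_EPS = 1e-9  # cutoff comparison tolerance, A

_PHOSPHATE_NAMES = {"P", "OP1", "OP2", "OP3", "O1P", "O2P", "O3P"}


@dataclass(frozen=True)
class ContactParams:
    """Distance cutoffs and pair-count thresholds of the three definitions.

    Defaults: 6.0 A heavy-atom cutoff and a 10-pair minimum for
    protein-protein interfaces; 3.5 A and a single qualifying pair for any
    interface involving a nucleic subunit; contact pairs between adjacent
    intra-chain subunits must be more than 10 residues apart in sequence.
    ``nucleic_atom_scope`` widens the nucleotide-side atom set from the base
    moiety to the whole nucleotide when set to ``"nucleotide"``.
    """

    pp_distance_cutoff: float = 6.0
    nucleic_distance_cutoff: float = 3.5
    min_pp_contact_pairs: int = 10
    min_nucleic_contact_pairs: int = 1
    adjacency_min_separation: int = 10
    nucleic_atom_scope: str = "base"

    def __post_init__(self):
        for name in ("pp_distance_cutoff", "nucleic_distance_cutoff",
                     "min_pp_contact_pairs", "min_nucleic_contact_pairs",
                     "adjacency_min_separation"):
            v = getattr(self, name)
            if not (v > 0 and np.isfinite(v)):
                raise ValueError(f"{name} must be positive and finite")
        if self.nucleic_atom_scope not in ("base", "nucleotide"):
            raise ValueError("nucleic_atom_scope must be base|nucleotide")


@dataclass(frozen=True)
class ContactPair:
    """One unit-pair contact: the minimal qualifying distance and the atom
    names achieving it.  ``unit_a`` belongs to the first subunit."""

    unit_a: PolymerUnit
    unit_b: PolymerUnit
    min_distance: float
    atom_a: str
    atom_b: str

    def swapped(self) -> "ContactPair":
        return ContactPair(self.unit_b, self.unit_a, self.min_distance,
                           self.atom_b, self.atom_a)


@dataclass
class BinaryInteraction:
    """A subunit pair whose surviving contact pairs meet the minimum-count
    threshold, labelled with one of the 36 interaction-type codes."""

    subunit_a: SubunitSpan
    subunit_b: SubunitSpan
    contact_pairs: list[ContactPair]
    interaction_type: str
    is_intra_chain: bool


def interaction_code(kind_a: str, kind_b: str) -> str:
    """Canonical type code for an unordered pair of subunit kinds,
    e.g. ``D-D``, ``D-N``, ``RNA-L``.

    Protein-protein pairs follow the fixed kind ordering (D, C, N, L, U,
    P); when a nucleic subunit meets a protein subunit the nucleic symbol
    comes first (``DNA-D``, ``RNA-L``), matching the established search
    syntax; DNA precedes RNA.
    """
    ia, ib = KIND_ORDER.index(kind_a), KIND_ORDER.index(kind_b)
    if ia > ib:
        ia, ib = ib, ia
        kind_a, kind_b = kind_b, kind_a
    if kind_b in NUCLEIC_KINDS and kind_a not in NUCLEIC_KINDS:
        kind_a, kind_b = kind_b, kind_a
    return f"{KIND_CODE[kind_a]}-{KIND_CODE[kind_b]}"


# ---------------------------------------------------------------------------
# atom eligibility

def _is_base_atom(atom) -> bool:
    """Base-moiety atom: no sugar prime mark, not part of the phosphate."""
    name = atom.atom_name.upper()
    return "'" not in name and "*" not in name and \
        name not in _PHOSPHATE_NAMES


def _nucleic_no_atoms(unit: PolymerUnit, scope: str):
    """O/N atoms of a nucleotide eligible for nucleic contact definitions."""
    atoms = []
    for a in unit.atoms:
        if not a.is_heavy or a.element.upper() not in ("N", "O"):
            continue
        if scope == "base" and not _is_base_atom(a):
            continue
        atoms.append(a)
    return atoms


def min_heavy_atom_distance(u1: PolymerUnit, u2: PolymerUnit) -> float:
    """Exact minimum Euclidean distance over all heavy-atom cross pairs."""
    c1, c2 = u1.heavy_coords(), u2.heavy_coords()
    if c1.size == 0 or c2.size == 0:
        raise ValueError(
            f"unit without heavy atoms: {u1.comp_id}/{u2.comp_id}")
    d = np.linalg.norm(c1[:, None, :] - c2[None, :, :], axis=-1)
    return float(d.min())


# ---------------------------------------------------------------------------
# k-d-tree contact engine

def _span_units(span: SubunitSpan, structure: StructureModel
                ) -> list[PolymerUnit]:
    chain = structure.chain(span.chain_id)
    return [chain.units[i] for i in span.indices()]


def _collect_atoms(units: Sequence[PolymerUnit], side: str, scope: str):
    """Flatten eligible atoms: returns (coords array, unit idx, atom refs)."""
    coords, unit_idx, atoms = [], [], []
    for i, unit in enumerate(units):
        if side == "protein":
            eligible = [a for a in unit.atoms if a.is_heavy]
        else:
            eligible = _nucleic_no_atoms(unit, scope)
        for a in eligible:
            coords.append(a.coords)
            unit_idx.append(i)
            atoms.append(a)
    arr = np.array(coords, dtype=float) if coords else np.empty((0, 3))
    return arr, np.array(unit_idx, dtype=int), atoms


def _pairwise_contacts(units_a, units_b, side_a, side_b, cutoff, scope,
                       require_n=False) -> list[ContactPair]:
    """Unit-pair contacts from the eligible-atom sets within ``cutoff``.

    ``require_n`` enforces the N-N / O-N rule (at least one nitrogen per
    qualifying atom pair) of the nucleic-nucleic definition.
    """
    ca, ia, atoms_a = _collect_atoms(units_a, side_a, scope)
    cb, ib, atoms_b = _collect_atoms(units_b, side_b, scope)
    if ca.shape[0] == 0 or cb.shape[0] == 0:
        logger.warning("degenerate subunit with no eligible atoms")
        return []
    tree_a, tree_b = cKDTree(ca), cKDTree(cb)
    best: dict[tuple[int, int], tuple[float, str, str]] = {}
    for ka, kb in _ball_pairs(tree_a, tree_b, cutoff):
        a, b = atoms_a[ka], atoms_b[kb]
        if require_n and not (a.element.upper() == "N"
                              or b.element.upper() == "N"):
            continue
        d = float(np.linalg.norm(ca[ka] - cb[kb]))
        if d > cutoff + _EPS:
            continue
        key = (int(ia[ka]), int(ib[kb]))
        cand = (d, a.atom_name, b.atom_name)
        if key not in best or cand < best[key]:
            best[key] = cand
    pairs = []
    for (ua, ub), (d, name_a, name_b) in sorted(best.items()):
        pairs.append(ContactPair(units_a[ua], units_b[ub], d, name_a, name_b))
    return pairs


def _ball_pairs(tree_a: cKDTree, tree_b: cKDTree, cutoff: float):
    neighbours = tree_a.query_ball_tree(tree_b, cutoff + _EPS)
    for ka, hits in enumerate(neighbours):
        for kb in hits:
            yield ka, kb


def protein_protein_contacts(su_a: SubunitSpan, su_b: SubunitSpan,
                             structure: StructureModel,
                             params: ContactParams = ContactParams()
                             ) -> list[ContactPair]:
    """Residue-residue contact pairs between two protein subunits, with the
    adjacency exclusion applied when the spans abut on one chain."""
    units_a = _span_units(su_a, structure)
    units_b = _span_units(su_b, structure)
    pairs = _pairwise_contacts(units_a, units_b, "protein", "protein",
                               params.pp_distance_cutoff,
                               params.nucleic_atom_scope)
    return apply_adjacency_exclusion(pairs, su_a, su_b, params)


def protein_nucleic_contacts(su_p: SubunitSpan, su_n: SubunitSpan,
                             structure: StructureModel,
                             params: ContactParams = ContactParams()
                             ) -> list[ContactPair]:
    """Residue-nucleotide contact pairs: base O/N atoms versus protein heavy
    atoms within the nucleic cutoff.  ``unit_a`` of each returned pair is on
    the protein side."""
    units_p = _span_units(su_p, structure)
    units_n = _span_units(su_n, structure)
    return _pairwise_contacts(units_p, units_n, "protein", "nucleic",
                              params.nucleic_distance_cutoff,
                              params.nucleic_atom_scope)


def nucleic_nucleic_contacts(su_1: SubunitSpan, su_2: SubunitSpan,
                             structure: StructureModel,
                             params: ContactParams = ContactParams()
                             ) -> list[ContactPair]:
    """Nucleotide-nucleotide contact pairs via N-N or O-N atom pairs within
    the nucleic cutoff; O-O proximity alone never qualifies."""
    units_1 = _span_units(su_1, structure)
    units_2 = _span_units(su_2, structure)
    return _pairwise_contacts(units_1, units_2, "nucleic", "nucleic",
                              params.nucleic_distance_cutoff,
                              params.nucleic_atom_scope, require_n=True)


# ---------------------------------------------------------------------------
# filters and the interaction decision

def _spans_adjacent(su_a: SubunitSpan, su_b: SubunitSpan) -> bool:
    """Sequence-adjacent: same chain and some segment of one span starts
    right after a segment of the other ends."""
    if su_a.chain_id != su_b.chain_id:
        return False
    for sa, ea in su_a.segments:
        for sb, eb in su_b.segments:
            if sb == ea + 1 or sa == eb + 1:
                return True
    return False


def apply_adjacency_exclusion(pairs: Iterable[ContactPair],
                              su_a: SubunitSpan, su_b: SubunitSpan,
                              params: ContactParams = ContactParams()
                              ) -> list[ContactPair]:
    """Drop contact pairs within ``adjacency_min_separation`` sequence
    positions when the two subunits are adjacent spans of one chain; leave
    non-adjacent subunit pairs untouched."""
    pairs = list(pairs)
    if not _spans_adjacent(su_a, su_b):
        return pairs
    keep = []
    for p in pairs:
        gap = abs(p.unit_a.seq_index - p.unit_b.seq_index)
        if gap > params.adjacency_min_separation:
            keep.append(p)
    return keep


def detect_interaction(su_a: SubunitSpan, su_b: SubunitSpan,
                       structure: StructureModel,
                       params: ContactParams = ContactParams()
                       ) -> Optional[BinaryInteraction]:
    """Decide whether two subunits form a binary interaction.

    Dispatches on the kind pair to the matching contact definition and
    applies the governing minimum pair count: ``min_pp_contact_pairs`` when
    both subunits are protein, ``min_nucleic_contact_pairs`` when a nucleic
    subunit is involved.  Returns ``None`` below threshold.
    """
    if su_a is su_b or (su_a.chain_id == su_b.chain_id
                        and su_a.segments == su_b.segments):
        return None
    ka, kb = su_a.subunit_kind, su_b.subunit_kind
    if ka in PROTEIN_KINDS and kb in PROTEIN_KINDS:
        pairs = protein_protein_contacts(su_a, su_b, structure, params)
        minimum = params.min_pp_contact_pairs
    elif ka in PROTEIN_KINDS and kb in NUCLEIC_KINDS:
        pairs = protein_nucleic_contacts(su_a, su_b, structure, params)
        minimum = params.min_nucleic_contact_pairs
    elif ka in NUCLEIC_KINDS and kb in PROTEIN_KINDS:
        pairs = [p.swapped() for p in
                 protein_nucleic_contacts(su_b, su_a, structure, params)]
        pairs.sort(key=lambda p: (p.unit_a.seq_index, p.unit_b.seq_index))
        minimum = params.min_nucleic_contact_pairs
    elif ka in NUCLEIC_KINDS and kb in NUCLEIC_KINDS:
        pairs = nucleic_nucleic_contacts(su_a, su_b, structure, params)
        minimum = params.min_nucleic_contact_pairs
    else:
        raise ValueError(f"unsupported subunit kinds {ka}/{kb}")
    if len(pairs) < minimum:
        return None
    return BinaryInteraction(
        subunit_a=su_a, subunit_b=su_b, contact_pairs=pairs,
        interaction_type=interaction_code(ka, kb),
        is_intra_chain=(su_a.chain_id == su_b.chain_id))


def contact_pairs_to_tsv(interaction: BinaryInteraction, path=None) -> str:
    """Export an interaction's contact-pair list as TSV (one row per pair:
    chain/auth number/component for both sides, minimal distance, atoms)."""
    lines = ["chain_a\tauth_seq_a\tcomp_a\tchain_b\tauth_seq_b\tcomp_b\t"
             "min_distance\tatom_a\tatom_b"]
    for p in interaction.contact_pairs:
        lines.append("\t".join([
            p.unit_a.chain_id, p.unit_a.auth_seq_id, p.unit_a.comp_id,
            p.unit_b.chain_id, p.unit_b.auth_seq_id, p.unit_b.comp_id,
            f"{p.min_distance:.3f}", p.atom_a, p.atom_b]))
    text = "\n".join(lines) + "\n"
    if path is not None:
        from pathlib import Path
        Path(path).write_text(text)
    return text
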