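"""Synthetic structures with planned subunit layouts and contact maps.

Every pipeline rule depends only on distances, chemical composition and
sequence positions, so idealized geometry (no physical relaxation, no
side-chain rotamers) is sufficient to exercise each stage exactly:

* protein chains on an extended or helical backbone trace;
* B-form-like DNA duplexes whose pairing nitrogens sit at Watson-Crick
  distance, emitted together with mmCIF text carrying
  ``_ndb_struct_na_base_pair`` rows;
* docked chain pairs whose residue-pair contact map — which pairs are in
  contact and at which minimal distance — is planned, achieved exactly by
  construction, and therefore usable as ground truth for the contact
  engine;
* random atom clouds for engine-versus-brute-force equivalence checks;
* domain-assignment files in the tab-separated classification dialect.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .annotation import DomainAssignment
from .structure_io import (AtomRecord, BasePairRecord, ChainModel,
                           PolymerUnit, StructureModel)

__all__ = [
    "FixtureSpec",
    "FixtureError",
    "make_protein_chain",
    "make_nucleic_chain",
    "make_duplex_dna",
    "make_docked_pair",
    "make_random_structure",
    "write_scop_fixture",
]


class FixtureError(ValueError):
    """Raised for infeasible fixture plans."""


# amino acids cycled through generated protein chains
_AA_CYCLE = ["ALA", "GLY", "SER", "VAL", "LEU", "THR", "ASP", "LYS"]

# base-atom names (no sugar/phosphate) per base letter
_BASE_ATOMS = {
    "A": ["N9", "C8", "N7", "C5", "C6", "N6", "N1", "C2", "N3", "C4"],
    "G": ["N9", "C8", "N7", "C5", "C6", "O6", "N1", "C2", "N2", "N3", "C4"],
    "T": ["N1", "C2", "O2", "N3", "C4", "O4", "C5", "C7", "C6"],
    "C": ["N1", "C2", "O2", "N3", "C4", "N4", "C5", "C6"],
    "U": ["N1", "C2", "O2", "N3", "C4", "O4", "C5", "C6"],
}
_PURINES = {"A", "G"}
_COMPLEMENT_DNA = {"A": "T", "T": "A", "G": "C", "C": "G"}


def _element_of(name: str) -> str:
    return name.lstrip("0123456789")[0]


def _residue_atoms(center: np.ndarray, away: np.ndarray) -> list[AtomRecord]:
    """Backbone + CB atoms: CA exactly at ``center``, the rest displaced in
    the ``away`` direction so CA realizes the residue's minimal distance to
    anything on the opposite side of ``away``."""
    away = away / max(np.linalg.norm(away), 1e-12)
    offsets = {"CA": 0.0, "N": 1.0, "C": 1.45, "O": 2.4, "CB": 1.9}
    side = np.array([away[1], -away[0], away[2]])  # in-plane orthogonal-ish
    atoms = []
    for i, (name, off) in enumerate(offsets.items()):
        pos = center + away * off + side * (0.15 * i)
        atoms.append(AtomRecord(atom_name=name, element=_element_of(name),
                                coords=tuple(float(x) for x in pos)))
    return atoms


def make_protein_chain(n: int, geometry: str = "extended",
                       chain_id: str = "A", start_auth: int = 1,
                       origin=(0.0, 0.0, 0.0)) -> ChainModel:
    """An idealized protein chain of ``n`` residues (>=4 heavy atoms each).

    ``extended`` places consecutive CA atoms 3.8 A apart along x;
    ``helix`` winds them on an alpha-helix-like trace (1.5 A rise,
    100 degrees per residue, 2.3 A radius).
    """
    if n < 1:
        raise FixtureError("protein chain needs n >= 1")
    origin = np.asarray(origin, dtype=float)
    units = []
    for i in range(n):
        if geometry == "extended":
            center = origin + np.array([3.8 * i, 0.0, 0.0])
        elif geometry == "helix":
            theta = np.deg2rad(100.0 * i)
            center = origin + np.array([2.3 * np.cos(theta),
                                        2.3 * np.sin(theta), 1.5 * i])
        else:
            raise FixtureError(f"unknown geometry {geometry!r}")
        atoms = _residue_atoms(center, np.array([0.0, -1.0, 0.0]))
        units.append(PolymerUnit(
            chain_id=chain_id, seq_index=i, auth_seq_id=str(start_auth + i),
            comp_id=_AA_CYCLE[i % len(_AA_CYCLE)], unit_kind="amino_acid",
            atoms=atoms))
    return ChainModel(chain_id=chain_id, units=units)


def _nucleotide_atoms(letter: str, anchor: np.ndarray,
                      away: np.ndarray) -> list[AtomRecord]:
    """Base + sugar + phosphate atoms.  The Watson-Crick pairing nitrogen
    (purine N1 / pyrimidine N3) sits exactly at ``anchor``; everything else
    is displaced along ``away``."""
    away = away / max(np.linalg.norm(away), 1e-12)
    pairing = "N1" if letter in _PURINES else "N3"
    atoms = []
    for i, name in enumerate(_BASE_ATOMS[letter]):
        if name == pairing:
            pos = anchor
        else:
            pos = anchor + away * (1.0 + 0.3 * i) + \
                np.array([0.0, 0.0, 0.2 * i])
        atoms.append(AtomRecord(atom_name=name, element=_element_of(name),
                                coords=tuple(float(x) for x in pos)))
    for j, name in enumerate(["C1'", "C2'", "C3'", "C4'", "O4'", "C5'",
                              "O5'", "O3'", "P", "OP1", "OP2"]):
        pos = anchor + away * (6.0 + 0.5 * j)
        atoms.append(AtomRecord(atom_name=name, element=_element_of(name),
                                coords=tuple(float(x) for x in pos)))
    return atoms


def make_probe_chain(chain_id: str, centers: Sequence,
                     start_auth: int = 1) -> ChainModel:
    """A protein chain with one residue per given CA position.

    Each residue's CA sits exactly at its centre and the remaining backbone
    atoms are displaced in +y, so the CA realizes the residue's minimal
    distance to anything at lower y — convenient for placing residues at
    exact contact distances.
    """
    units = []
    for i, c in enumerate(centers):
        center = np.asarray(c, dtype=float)
        atoms = _residue_atoms(center, np.array([0.0, 1.0, 0.0]))
        units.append(PolymerUnit(
            chain_id=chain_id, seq_index=i, auth_seq_id=str(start_auth + i),
            comp_id=_AA_CYCLE[i % len(_AA_CYCLE)], unit_kind="amino_acid",
            atoms=atoms))
    return ChainModel(chain_id=chain_id, units=units)


def make_nucleic_chain(sequence: str, kind: str = "dna",
                       chain_id: str = "X", start_auth: int = 1,
                       origin=(0.0, 0.0, 0.0), rise: float = 3.4,
                       away=(-1.0, 0.0, 0.0)) -> ChainModel:
    """A single idealized nucleotide chain stacked along z."""
    origin = np.asarray(origin, dtype=float)
    away = np.asarray(away, dtype=float)
    units = []
    for i, letter in enumerate(sequence.upper()):
        if letter not in _BASE_ATOMS:
            raise FixtureError(f"unknown base {letter!r}")
        comp = ("D" + letter) if kind == "dna" else letter
        anchor = origin + np.array([0.0, 0.0, rise * i])
        atoms = _nucleotide_atoms(letter, anchor, away)
        units.append(PolymerUnit(
            chain_id=chain_id, seq_index=i, auth_seq_id=str(start_auth + i),
            comp_id=comp,
            unit_kind="dna_nucleotide" if kind == "dna" else "rna_nucleotide",
            atoms=atoms))
    return ChainModel(chain_id=chain_id, units=units)


def make_duplex_dna(n_bp: int, chain_ids: tuple[str, str] = ("X", "Y"),
                    sequence: Optional[str] = None, seed: int = 0,
                    origin=(0.0, 0.0, 0.0), entry_id: str = "duplex"
                    ) -> tuple[StructureModel, str]:
    """An idealized DNA duplex with its base-pair annotation.

    Pairing nitrogens of complementary strands are set 2.9 A apart
    (Watson-Crick hydrogen-bond distance); base pairs stack 3.4 A apart.
    Returns the structure (base-pair records included) and mmCIF text that
    carries both the coordinates and one ``_ndb_struct_na_base_pair`` row
    per pair.
    """
    if n_bp < 1:
        raise FixtureError("duplex needs n_bp >= 1")
    rng = np.random.default_rng(seed)
    if sequence is None:
        sequence = "".join(rng.choice(list("ATGC"), size=n_bp))
    if len(sequence) != n_bp:
        raise FixtureError("sequence length != n_bp")
    comp_seq = "".join(_COMPLEMENT_DNA[b] for b in sequence.upper())
    origin = np.asarray(origin, dtype=float)
    ca = make_nucleic_chain(sequence, "dna", chain_ids[0], origin=origin,
                            away=(-1.0, 0.0, 0.0))
    cb = make_nucleic_chain(comp_seq, "dna", chain_ids[1],
                            origin=origin + np.array([2.9, 0.0, 0.0]),
                            away=(1.0, 0.0, 0.0))
    pairs = [BasePairRecord(chain_a=chain_ids[0], unit_a=str(i + 1),
                            chain_b=chain_ids[1], unit_b=str(i + 1))
             for i in range(n_bp)]
    structure = StructureModel(entry_id=entry_id, chains=[ca, cb],
                               base_pairs=pairs, source_format="mmcif")
    return structure, structure_to_mmcif(structure)


def structure_to_mmcif(structure: StructureModel, path=None) -> str:
    """Minimal mmCIF serialization: ``_atom_site`` plus the base-pair
    category when the structure has base-pair records."""
    lines = [f"data_{structure.entry_id}",
             f"_entry.id {structure.entry_id}",
             "loop_"]
    cols = ["group_PDB", "id", "type_symbol", "label_atom_id",
            "label_alt_id", "label_comp_id", "label_asym_id",
            "label_entity_id", "label_seq_id", "pdbx_PDB_ins_code",
            "Cartn_x", "Cartn_y", "Cartn_z", "occupancy", "B_iso_or_equiv",
            "auth_seq_id", "auth_comp_id", "auth_asym_id",
            "pdbx_PDB_model_num"]
    lines.extend(f"_atom_site.{c}" for c in cols)
    serial = 1
    for entity_id, chain in enumerate(structure.chains, start=1):
        for unit in chain.units:
            for atom in unit.atoms:
                name = atom.atom_name
                qname = f'"{name}"' if "'" in name else name
                x, y, z = atom.coords
                lines.append(
                    f"ATOM {serial} {atom.element} {qname} . "
                    f"{unit.comp_id} {chain.chain_id} {entity_id} "
                    f"{unit.seq_index + 1} ? {x:.3f} {y:.3f} {z:.3f} "
                    f"1.00 0.00 {unit.auth_seq_id} {unit.comp_id} "
                    f"{chain.chain_id} 1")
                serial += 1
    if structure.base_pairs:
        lines.append("loop_")
        for c in ["i_auth_asym_id", "i_auth_seq_id",
                  "j_auth_asym_id", "j_auth_seq_id"]:
            lines.append(f"_ndb_struct_na_base_pair.{c}")
        for p in structure.base_pairs:
            lines.append(f"{p.chain_a} {p.unit_a} {p.chain_b} {p.unit_b}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


# ---------------------------------------------------------------------------
# docked pairs with planned contact maps

@dataclass(frozen=True)
class FixtureSpec:
    """Plan for a docked chain pair with an exact contact map.

    Residue ``i`` of each chain is centred at ``x = spacing * i``; chain B
    floats above chain A.  ``planned`` lists ``(column, distance)`` pairs:
    at those sequence positions the two probe atoms face each other at
    exactly ``distance`` A, producing the unit-pair contact ``(i, i)``;
    all other columns sit at ``off_distance``.  With ``spacing`` larger
    than any cutoff, off-column pairs can never come within range, so the
    brute-force contact map of the generated structure equals the plan.
    """

    n_a: int
    n_b: int
    planned: tuple[tuple[int, float], ...] = ()
    kinds: tuple[str, str] = ("protein", "protein")
    off_distance: float = 12.0
    spacing: float = 20.0
    seed: int = 0

    def __post_init__(self):
        cols = [c for c, _ in self.planned]
        if len(cols) != len(set(cols)):
            raise FixtureError("duplicate planned column")
        for c, d in self.planned:
            if not (0 <= c < min(self.n_a, self.n_b)):
                raise FixtureError(f"planned column {c} out of range")
            if not (0 < d < self.off_distance):
                raise FixtureError(
                    f"planned distance {d} conflicts with off_distance")
        # columns must be far enough apart that only same-column probe
        # pairs can ever reach a planned or cutoff-scale distance
        if self.spacing <= self.off_distance:
            raise FixtureError("spacing too small for planned map")


def _probe_chain(kind: str, n: int, chain_id: str, heights: Sequence[float],
                 spacing: float, facing_up: bool) -> ChainModel:
    """Chain whose per-residue probe atom (CA, or the pairing base nitrogen)
    sits exactly at (spacing*i, height_i, 0), other atoms displaced away
    from the partner chain."""
    away = np.array([0.0, -1.0, 0.0]) if facing_up else \
        np.array([0.0, 1.0, 0.0])
    units = []
    for i in range(n):
        center = np.array([spacing * i, heights[i], 0.0])
        if kind == "protein":
            atoms = _residue_atoms(center, away)
            comp = _AA_CYCLE[i % len(_AA_CYCLE)]
            unit_kind = "amino_acid"
        else:
            letter = "G" if kind != "rna" else "A"
            comp = ("D" + letter) if kind == "dna" else letter
            atoms = _nucleotide_atoms(letter, center, away)
            unit_kind = ("dna_nucleotide" if kind == "dna"
                         else "rna_nucleotide")
        units.append(PolymerUnit(
            chain_id=chain_id, seq_index=i, auth_seq_id=str(i + 1),
            comp_id=comp, unit_kind=unit_kind, atoms=atoms))
    return ChainModel(chain_id=chain_id, units=units)


def make_docked_pair(spec: FixtureSpec, chain_ids: tuple[str, str] = ("A", "B"),
                     entry_id: str = "docked"
                     ) -> tuple[StructureModel, list[tuple[int, int, float]]]:
    """Build the docked pair of a :class:`FixtureSpec`.

    Returns the structure and the expected contact map as
    ``(seq_index_a, seq_index_b, min_distance)`` triples (sorted).
    """
    planned = dict(spec.planned)
    heights_a = [0.0] * spec.n_a
    heights_b = [planned.get(i, spec.off_distance)
                 for i in range(spec.n_b)]
    chain_a = _probe_chain(spec.kinds[0], spec.n_a, chain_ids[0], heights_a,
                           spec.spacing, facing_up=True)
    chain_b = _probe_chain(spec.kinds[1], spec.n_b, chain_ids[1], heights_b,
                           spec.spacing, facing_up=False)
    structure = StructureModel(entry_id=entry_id, chains=[chain_a, chain_b],
                               source_format="pdb")
    expected = sorted((c, c, d) for c, d in spec.planned)
    return structure, expected


# ---------------------------------------------------------------------------
# random structures for oracle-equivalence checks

def make_random_structure(seed: int, kinds: tuple[str, str] = ("protein",
                                                               "protein"),
                          n_a: int = 30, n_b: int = 30,
                          box: float = 25.0, atom_jitter: float = 1.5,
                          entry_id: str = "random") -> StructureModel:
    """Two chains of randomly placed units inside a cubic box.

    Unit centres are uniform in the box and each unit's atoms are scattered
    within ``atom_jitter`` of its centre, so unit pairs fall on both sides
    of the contact cutoffs — ground for engine-versus-brute-force
    comparisons.  Nucleotide units keep their full base/sugar/phosphate
    atom naming so eligibility rules are exercised.
    """
    rng = np.random.default_rng(seed)
    chains = []
    for chain_id, kind, n in (("A", kinds[0], n_a), ("B", kinds[1], n_b)):
        units = []
        for i in range(n):
            center = rng.uniform(0.0, box, size=3)
            if kind == "protein":
                base = _residue_atoms(center, np.array([0.0, -1.0, 0.0]))
                comp = _AA_CYCLE[i % len(_AA_CYCLE)]
                unit_kind = "amino_acid"
            else:
                letter = "GACT"[i % 4] if kind == "dna" else "GACU"[i % 4]
                base = _nucleotide_atoms(letter, center,
                                         np.array([0.0, -1.0, 0.0]))
                comp = ("D" + letter) if kind == "dna" else letter
                unit_kind = ("dna_nucleotide" if kind == "dna"
                             else "rna_nucleotide")
            atoms = [AtomRecord(
                atom_name=a.atom_name, element=a.element,
                coords=tuple(np.asarray(a.coords)
                             - np.mean([b.coords for b in base], axis=0)
                             + center
                             + rng.uniform(-atom_jitter, atom_jitter, 3)))
                for a in base]
            units.append(PolymerUnit(
                chain_id=chain_id, seq_index=i, auth_seq_id=str(i + 1),
                comp_id=comp, unit_kind=unit_kind, atoms=atoms))
        chains.append(ChainModel(chain_id=chain_id, units=units))
    return StructureModel(entry_id=entry_id, chains=chains,
                          source_format="pdb")


# ---------------------------------------------------------------------------
# domain-assignment fixture files

def write_scop_fixture(assignments: Sequence[DomainAssignment], path,
                       header_comment: str = "# synthetic domain "
                       "assignments") -> str:
    """Write assignments as a tab-separated classification-dialect file.

    Segments sharing a ``domain_id`` are folded into one multi-segment
    region (``A:1-40,A:61-100``); reading the file back reproduces the
    assignments.
    """
    groups: dict[str, list[DomainAssignment]] = {}
    order: list[str] = []
    for a in assignments:
        key = a.domain_id or f"{a.pdb_id}:{a.chain_id}:{a.start}"
        if key not in groups:
            order.append(key)
        groups.setdefault(key, []).append(a)
    lines = [header_comment]
    for key in order:
        segs = groups[key]
        first = segs[0]
        region = ",".join(
            f"{s.chain_id}:" if s.start is None
            else f"{s.chain_id}:{s.start}-{s.end}" for s in segs)
        fields = [first.domain_id or key, first.pdb_id, region,
                  first.scop_family_id, first.sunid or "-"]
        if first.source == "superfamily_predicted":
            fields.append("superfamily")
        lines.append("\t".join(fields))
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text
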