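"""Structure reading, chain classification and PDB-format coordinate output.

Reads PDB and mmCIF files into a uniform in-memory model built from ordered
polymer units (residues / nucleotides) with heavy-atom coordinates, drops
waters and free ligands, and classifies each chain as protein, DNA, RNA,
DNA/RNA hybrid or other.  Base-pair annotations are read from the
``_ndb_struct_na_base_pair`` category when the source is mmCIF.  Extracted
binary complexes are written back out as plain fixed-column PDB ATOM records.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "AtomRecord",
    "PolymerUnit",
    "ChainModel",
    "BasePairRecord",
    "StructureModel",
    "StructureParseError",
    "EmptyStructureError",
    "parse_structure",
    "classify_polymer_kind",
    "read_base_pairs",
    "write_binary_complex",
    "structure_to_pdb",
]

_HYDROGEN = {"H", "D", "T"}

#: canonical one-letter RNA components and two-letter deoxy components
_RNA_COMPS = {"A", "C", "G", "U", "I", "N"}
_DNA_COMPS = {"DA", "DC", "DG", "DT", "DU", "DI", "DN"}


class StructureParseError(ValueError):
    """Raised when an input file cannot be read as PDB or mmCIF."""


class EmptyStructureError(StructureParseError):
    """Raised when a file contains no polymer chains."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom: name, element, Cartesian coordinates in Angstroms."""

    atom_name: str
    element: str
    coords: tuple[float, float, float]
    alt_loc: str = ""

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() not in _HYDROGEN

    def __post_init__(self) -> None:
        if not all(math.isfinite(c) for c in self.coords):
            raise ValueError(f"non-finite coordinates for atom {self.atom_name}")


@dataclass
class PolymerUnit:
    """A residue or nucleotide: one position in a polymer chain.

    ``seq_index`` is the gap-free 0-based ordinal within the chain (all
    interval logic downstream runs on it); ``auth_seq_id`` preserves the
    author numbering (with insertion code) for reporting and PDB output.
    """

    chain_id: str
    seq_index: int
    auth_seq_id: str
    comp_id: str
    unit_kind: str  # amino_acid | dna_nucleotide | rna_nucleotide | other
    atoms: list[AtomRecord] = field(default_factory=list)

    def heavy_atoms(self) -> list[AtomRecord]:
        return [a for a in self.atoms if a.is_heavy]

    def heavy_coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms if a.is_heavy], dtype=float)


@dataclass
class ChainModel:
    """An ordered polymer chain with a derived polymer-kind label."""

    chain_id: str
    units: list[PolymerUnit]
    polymer_kind: str = ""  # protein | dna | rna | hybrid | other

    def __post_init__(self) -> None:
        if not self.polymer_kind and self.units:
            self.polymer_kind = classify_polymer_kind(self)

    def __len__(self) -> int:
        return len(self.units)

    def unit_by_auth(self, auth_seq_id: str) -> Optional[PolymerUnit]:
        for u in self.units:
            if u.auth_seq_id == auth_seq_id:
                return u
        return None


@dataclass(frozen=True)
class BasePairRecord:
    """One row of the base-pair category: two nucleotides on (possibly
    different) chains, referenced by auth numbering."""

    chain_a: str
    unit_a: str
    chain_b: str
    unit_b: str


@dataclass
class StructureModel:
    """All polymer chains of one structure entry (first model only)."""

    entry_id: str
    chains: list[ChainModel]
    base_pairs: list[BasePairRecord] = field(default_factory=list)
    source_format: str = "pdb"

    def chain(self, chain_id: str) -> ChainModel:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r} in {self.entry_id}")

    def has_chain(self, chain_id: str) -> bool:
        return any(c.chain_id == chain_id for c in self.chains)


def unit_kind_of(comp_id: str) -> str:
    """Map a chemical component name to amino_acid / dna_nucleotide /
    rna_nucleotide / other using gemmi's component tables, with a
    prefix-convention fallback for unknown components."""
    comp = comp_id.strip().upper()
    info = gemmi.find_tabulated_residue(comp)
    if info is not None and info.found():
        if info.is_amino_acid():
            return "amino_acid"
        if info.is_nucleic_acid():
            if info.kind == gemmi.ResidueKind.DNA:
                return "dna_nucleotide"
            if info.kind == gemmi.ResidueKind.RNA:
                return "rna_nucleotide"
            return "other"
        return "other"
    if comp in _DNA_COMPS or (len(comp) == 2 and comp.startswith("D")):
        return "dna_nucleotide"
    if comp in _RNA_COMPS:
        return "rna_nucleotide"
    return "other"


def classify_polymer_kind(chain: ChainModel) -> str:
    """Classify a chain from the set of its unit kinds.

    protein: has amino acids and no nucleotides; dna/rna: nucleotides of a
    single type and no amino acids; hybrid: both DNA and RNA bases present.
    The result depends only on the set of unit kinds, not their order.
    """
    kinds = {u.unit_kind for u in chain.units}
    has_aa = "amino_acid" in kinds
    has_dna = "dna_nucleotide" in kinds
    has_rna = "rna_nucleotide" in kinds
    if has_dna and has_rna:
        return "hybrid"
    if has_aa and not (has_dna or has_rna):
        return "protein"
    if has_dna and not has_aa:
        return "dna"
    if has_rna and not has_aa:
        return "rna"
    return "other"


def _auth_id(res: gemmi.Residue) -> str:
    icode = res.seqid.icode.strip()
    return f"{res.seqid.num}{icode}"


def _select_alt_locs(res: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep one atom per atom name: highest occupancy, ties broken by the
    alphabetically first altloc."""
    best: dict[str, gemmi.Atom] = {}
    for atom in res:
        prev = best.get(atom.name)
        if prev is None:
            best[atom.name] = atom
            continue
        key_new = (-atom.occ, atom.altloc or "")
        key_old = (-prev.occ, prev.altloc or "")
        if key_new < key_old:
            best[atom.name] = atom
    return list(best.values())


def _residue_to_unit(chain_id: str, seq_index: int, res: gemmi.Residue,
                     kind: str) -> PolymerUnit:
    atoms = []
    for atom in _select_alt_locs(res):
        atoms.append(AtomRecord(
            atom_name=atom.name,
            element=atom.element.name,
            coords=(atom.pos.x, atom.pos.y, atom.pos.z),
            alt_loc=(atom.altloc or "").strip(),
        ))
    return PolymerUnit(
        chain_id=chain_id,
        seq_index=seq_index,
        auth_seq_id=_auth_id(res),
        comp_id=res.name,
        unit_kind=kind,
        atoms=atoms,
    )


def parse_structure(path, format_hint: Optional[str] = None) -> StructureModel:
    """Parse a PDB or mmCIF file into a :class:`StructureModel`.

    Only the first model is read.  Waters and non-polymer heteroatoms
    (ligands, ions) are excluded; modified residues tabulated as amino acids
    or nucleotides (e.g. MSE, PSU) are kept as polymer units.  Hydrogens are
    retained but flagged non-heavy.  For mmCIF sources the
    ``_ndb_struct_na_base_pair`` category is read alongside the coordinates.
    """
    path = Path(path)
    if not path.exists():
        raise StructureParseError(f"no such file: {path}")
    fmt = _resolve_format(path, format_hint)
    try:
        if fmt == "mmcif":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no models")
    model = st[0]

    chains: list[ChainModel] = []
    for ch in model:
        units: list[PolymerUnit] = []
        seen_auth: set[str] = set()
        for res in ch:
            info = gemmi.find_tabulated_residue(res.name)
            if info is not None and info.is_water():
                continue
            kind = unit_kind_of(res.name)
            # free ligands/ions come in as HETATM with an unknown polymer kind
            if kind == "other" and res.het_flag != "A":
                continue
            auth = _auth_id(res)
            if auth in seen_auth:  # point-mutation altloc residues: keep first
                continue
            seen_auth.add(auth)
            units.append(_residue_to_unit(ch.name, len(units), res, kind))
        if units:
            chains.append(ChainModel(chain_id=ch.name, units=units))

    if not chains:
        raise EmptyStructureError(f"{path}: no polymer chains")

    entry_id = (st.name or path.stem).strip().lower() or path.stem
    base_pairs: list[BasePairRecord] = []
    structure = StructureModel(entry_id=entry_id, chains=chains,
                               source_format=fmt)
    if fmt == "mmcif":
        base_pairs = read_base_pairs(path, structure=structure)
        structure.base_pairs = base_pairs
    return structure


def _resolve_format(path: Path, format_hint: Optional[str]) -> str:
    if format_hint:
        hint = format_hint.lower()
        if hint in ("pdb",):
            return "pdb"
        if hint in ("cif", "mmcif"):
            return "mmcif"
        raise ValueError(f"unknown format hint {format_hint!r}")
    suffix = path.suffix.lower()
    if suffix in (".cif", ".mmcif"):
        return "mmcif"
    return "pdb"


def read_base_pairs(mmcif_source,
                    structure: Optional[StructureModel] = None
                    ) -> list[BasePairRecord]:
    """Read ``_ndb_struct_na_base_pair`` rows from an mmCIF file or string.

    Returns one record per row (auth naming preferred, label naming as a
    fallback).  When a structure is supplied, rows referencing units absent
    from it are dropped with a warning.  A missing category yields an empty
    list, not an error.
    """
    source = str(mmcif_source)
    if "\n" in source or source.lstrip().startswith("data_"):
        doc = gemmi.cif.read_string(source)
    else:
        doc = gemmi.cif.read(source)
    block = doc.sole_block()
    records: list[BasePairRecord] = []
    for cols in (["i_auth_asym_id", "i_auth_seq_id",
                  "j_auth_asym_id", "j_auth_seq_id"],
                 ["i_label_asym_id", "i_label_seq_id",
                  "j_label_asym_id", "j_label_seq_id"]):
        table = block.find("_ndb_struct_na_base_pair.", cols)
        if len(table) > 0:
            for row in table:
                records.append(BasePairRecord(
                    chain_a=row[0], unit_a=row[1],
                    chain_b=row[2], unit_b=row[3]))
            break
    if structure is None:
        return records
    kept = []
    for rec in records:
        ok = True
        for cid, uid in ((rec.chain_a, rec.unit_a), (rec.chain_b, rec.unit_b)):
            if not structure.has_chain(cid) or \
                    structure.chain(cid).unit_by_auth(uid) is None:
                ok = False
        if ok:
            kept.append(rec)
        else:
            logger.warning("base-pair row %s references absent unit; dropped",
                           rec)
    return kept


# ---------------------------------------------------------------------------
# PDB output

_AUTH_RE = re.compile(r"^(-?\d+)([A-Za-z]?)$")


def _split_auth(auth_seq_id: str) -> tuple[int, str]:
    m = _AUTH_RE.match(auth_seq_id.strip())
    if not m:
        raise ValueError(f"unparseable auth_seq_id {auth_seq_id!r}")
    return int(m.group(1)), m.group(2)


def _format_atom_line(serial: int, atom: AtomRecord, unit: PolymerUnit) -> str:
    name = atom.atom_name
    # PDB name column: 1-char elements start at column 14
    if len(name) < 4 and len(atom.element) == 1:
        name = " " + name
    name = name.ljust(4)[:4]
    num, icode = _split_auth(unit.auth_seq_id)
    x, y, z = atom.coords
    return (f"ATOM  {serial:5d} {name}{'':1s}{unit.comp_id:>3s} "
            f"{unit.chain_id[:1]:1s}{num:4d}{icode or ' ':1s}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
            f"{atom.element.upper():>2s}")


def _write_units_pdb(groups: Sequence[tuple[str, Sequence[PolymerUnit]]]) -> str:
    """Write chains of units as PDB ATOM records with TER separators."""
    lines: list[str] = []
    serial = 1
    for chain_id, units in groups:
        last_unit = None
        for unit in units:
            for atom in unit.atoms:
                lines.append(_format_atom_line(serial, atom, unit))
                serial += 1
            last_unit = unit
        if last_unit is not None:
            num, icode = _split_auth(last_unit.auth_seq_id)
            lines.append(f"TER   {serial:5d}      {last_unit.comp_id:>3s} "
                         f"{chain_id[:1]:1s}{num:4d}{icode or ' ':1s}")
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


def structure_to_pdb(structure: StructureModel, path=None) -> str:
    """Serialize a whole structure model as PDB text."""
    groups = [(c.chain_id, c.units) for c in structure.chains]
    text = _write_units_pdb(groups)
    if path is not None:
        Path(path).write_text(text)
    return text


def write_binary_complex(structure: StructureModel, interaction, path) -> str:
    """Write the coordinates of one binary interaction as a PDB file.

    The output contains exactly the units covered by the interaction's two
    subunit spans, with the original chain identifiers and author numbering.
    """
    groups: dict[str, list[PolymerUnit]] = {}
    for span in (interaction.subunit_a, interaction.subunit_b):
        if not structure.has_chain(span.chain_id):
            raise ValueError(
                f"subunit chain {span.chain_id!r} not in structure "
                f"{structure.entry_id}")
        chain = structure.chain(span.chain_id)
        for idx in span.indices():
            if idx >= len(chain.units):
                raise ValueError(
                    f"subunit span {span.label or span.chain_id} exceeds "
                    f"chain {span.chain_id} length")
            groups.setdefault(span.chain_id, []).append(chain.units[idx])
    ordered = []
    for chain_id, units in groups.items():
        units = sorted({u.seq_index: u for u in units}.values(),
                       key=lambda u: u.seq_index)
        ordered.append((chain_id, units))
    text = _write_units_pdb(ordered)
    if path is not None:
        Path(path).write_text(text)
    return text
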