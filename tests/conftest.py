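import numpy as np
import pytest

from macrodissect.structure_io import (AtomRecord, ChainModel, PolymerUnit,
                                       StructureModel)
from macrodissect import fixtures as fx


def probe_residue(chain_id: str, seq_index: int, center, auth=None,
                  comp="ALA") -> PolymerUnit:
    """A residue whose CA sits exactly at ``center``; backbone atoms are
    displaced in +y so CA realizes the residue's minimal distance to
    anything at lower y."""
    cx, cy, cz = center
    atoms = [
        AtomRecord("CA", "C", (cx, cy, cz)),
        AtomRecord("N", "N", (cx + 0.1, cy + 1.2, cz)),
        AtomRecord("C", "C", (cx - 0.1, cy + 1.5, cz)),
        AtomRecord("O", "O", (cx, cy + 2.4, cz)),
        AtomRecord("CB", "C", (cx + 0.2, cy + 1.9, cz)),
    ]
    return PolymerUnit(chain_id=chain_id, seq_index=seq_index,
                       auth_seq_id=str(auth if auth is not None
                                       else seq_index + 1),
                       comp_id=comp, unit_kind="amino_acid", atoms=atoms)


def protein_chain_at(chain_id, centers, start_auth=1) -> ChainModel:
    units = [probe_residue(chain_id, i, c, auth=start_auth + i)
             for i, c in enumerate(centers)]
    return ChainModel(chain_id=chain_id, units=units)


@pytest.fixture
def duplex():
    structure, cif_text = fx.make_duplex_dna(10, seed=7)
    return structure, cif_text


@pytest.fixture
def duplex_cif(tmp_path, duplex):
    _, cif_text = duplex
    path = tmp_path / "duplex.cif"
    path.write_text(cif_text)
    return path


@pytest.fixture
def three_ala_pdb(tmp_path):
    """Minimal hand-written one-chain PDB with 3 alanines."""
    lines = []
    serial = 1
    for res in range(1, 4):
        for name, elem, dy in (("N", "N", 0.0), ("CA", "C", 1.2),
                               ("C", "C", 2.4), ("O", "O", 3.1),
                               ("CB", "C", 1.8)):
            x = 3.8 * res
            pad_name = f" {name}" if len(elem) == 1 else name
            lines.append(f"ATOM  {serial:5d} {pad_name:<4s} ALA A{res:4d}"
                         f"    {x:8.3f}{dy:8.3f}{0.0:8.3f}  1.00  0.00"
                         f"          {elem:>2s}")
            serial += 1
    lines.append("END")
    path = tmp_path / "three_ala.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path
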