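"""Brute-force contact oracles, written independently of the package's
k-d-tree engine: plain nested loops over all atom cross pairs, with the
atom-eligibility rules restated from first principles."""

import numpy as np

_HYDROGEN = {"H", "D", "T"}
_PHOSPHATE = {"P", "OP1", "OP2", "OP3", "O1P", "O2P", "O3P"}
TOL = 1e-9


def _dist(a, b):
    return float(np.linalg.norm(np.subtract(a.coords, b.coords)))


def _heavy(unit):
    return [a for a in unit.atoms if a.element.upper() not in _HYDROGEN]


def _base_no(unit):
    out = []
    for a in _heavy(unit):
        if a.element.upper() not in ("N", "O"):
            continue
        if "'" in a.atom_name or a.atom_name.upper() in _PHOSPHATE:
            continue
        out.append(a)
    return out


def bf_protein_protein(units_a, units_b, cutoff=6.0):
    """All residue pairs whose minimal heavy-atom distance <= cutoff."""
    result = {}
    for ua in units_a:
        for ub in units_b:
            dmin = min(_dist(x, y) for x in _heavy(ua) for y in _heavy(ub))
            if dmin <= cutoff + TOL:
                result[(ua.seq_index, ub.seq_index)] = dmin
    return result

def bf_protein_nucleic(units_p, units_n, cutoff=3.5):
    """Residue-nucleotide pairs with a base O/N atom within cutoff of a
    protein heavy atom."""
    result = {}
    for up in units_p:
        for un in units_n:
            ds = [_dist(x, y) for x in _heavy(up) for y in _base_no(un)]
            if ds and min(ds) <= cutoff + TOL:
                result[(up.seq_index, un.seq_index)] = min(ds)
    return result


def bf_nucleic_nucleic(units_1, units_2, cutoff=3.5):
    """Nucleotide pairs with an N-N or O-N base-atom pair within cutoff
    (O-O never qualifies)."""
    result = {}
    for u1 in units_1:
        for u2 in units_2:
            ds = [_dist(x, y)
                  for x in _base_no(u1) for y in _base_no(u2)
                  if "N" in (x.element.upper(), y.element.upper())]
            if ds and min(ds) <= cutoff + TOL:
                result[(u1.seq_index, u2.seq_index)] = min(ds)
    return result
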