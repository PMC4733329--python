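import numpy as np
import pytest

import oracles
from macrodissect import fixtures as fx
from macrodissect.annotation import SubunitSpan
from macrodissect.contacts import (ContactParams,
                                   apply_adjacency_exclusion,
                                   detect_interaction,
                                   min_heavy_atom_distance,
                                   nucleic_nucleic_contacts,
                                   protein_nucleic_contacts,
                                   protein_protein_contacts)
from macrodissect.structure_io import (AtomRecord, ChainModel, PolymerUnit,
                                       StructureModel)

from conftest import probe_residue, protein_chain_at


def _nt(chain, idx, atoms, comp="DG", kind="dna_nucleotide"):
    return PolymerUnit(chain_id=chain, seq_index=idx, auth_seq_id=str(idx + 1),
                       comp_id=comp, unit_kind=kind, atoms=atoms)


def _whole_span(chain_model, kind):
    return SubunitSpan(kind, chain_model.chain_id,
                       ((0, len(chain_model.units) - 1),))


class TestMinHeavyAtomDistance:
    def test_three_four_five(self):
        u1 = _nt("A", 0, [AtomRecord("C1", "C", (0, 0, 0))])
        u2 = _nt("B", 0, [AtomRecord("C1", "C", (3, 4, 0))])
        assert min_heavy_atom_distance(u1, u2) == pytest.approx(5.0)

    def test_unit_against_itself_is_zero(self):
        u = _nt("A", 0, [AtomRecord("C1", "C", (1, 2, 3))])
        assert min_heavy_atom_distance(u, u) == 0.0

    def test_hydrogens_ignored(self):
        u1 = _nt("A", 0, [AtomRecord("C1", "C", (0, 0, 0)),
                          AtomRecord("H1", "H", (0, 0, 9.9))])
        u2 = _nt("B", 0, [AtomRecord("C1", "C", (0, 0, 10))])
        assert min_heavy_atom_distance(u1, u2) == pytest.approx(10.0)

    def test_no_heavy_atoms_errors(self):
        u1 = _nt("A", 0, [AtomRecord("H1", "H", (0, 0, 0))])
        u2 = _nt("B", 0, [AtomRecord("C1", "C", (1, 0, 0))])
        with pytest.raises(ValueError):
            min_heavy_atom_distance(u1, u2)

    def test_matches_exhaustive_minimum(self):
        rng = np.random.default_rng(11)
        a1 = [AtomRecord(f"C{i}", "C", tuple(rng.uniform(0, 8, 3)))
              for i in range(5)]
        a2 = [AtomRecord(f"C{i}", "C", tuple(rng.uniform(0, 8, 3)))
              for i in range(7)]
        u1, u2 = _nt("A", 0, a1), _nt("B", 0, a2)
        expected = min(np.linalg.norm(np.subtract(x.coords, y.coords))
                       for x in a1 for y in a2)
        assert min_heavy_atom_distance(u1, u2) == pytest.approx(expected)


class TestProteinProteinContacts:
    @pytest.mark.parametrize("d,expected", [(5.99, 1), (6.00, 1), (6.01, 0)])
    def test_cutoff_boundary(self, d, expected):
        a = protein_chain_at("A", [(0, 0, 0)])
        b = protein_chain_at("B", [(0, -d, 0)])
        # chain B probe faces down: CA at -d, rest lower; min dist is d
        b.units[0].atoms[:] = [AtomRecord("CA", "C", (0, -d, 0))]
        structure = StructureModel("t", [a, b])
        pairs = protein_protein_contacts(_whole_span(a, "domain"),
                                         _whole_span(b, "domain"), structure)
        assert len(pairs) == expected
        if pairs:
            assert pairs[0].min_distance == pytest.approx(d)

    def test_docked_fixture_planned_map_recovered(self):
        spec = fx.FixtureSpec(n_a=20, n_b=20,
                              planned=tuple((i, 4.0 + 0.1 * i)
                                            for i in range(12)))
        structure, expected = fx.make_docked_pair(spec)
        sa = _whole_span(structure.chains[0], "undefined_chain")
        sb = _whole_span(structure.chains[1], "undefined_chain")
        pairs = protein_protein_contacts(sa, sb, structure)
        got = sorted((p.unit_a.seq_index, p.unit_b.seq_index,
                      round(p.min_distance, 6)) for p in pairs)
        assert got == [(i, j, round(d, 6)) for i, j, d in expected]

    def test_distant_subunits_no_contacts(self):
        a = protein_chain_at("A", [(0, 0, 0), (3.8, 0, 0)])
        b = protein_chain_at("B", [(100, 0, 0), (103.8, 0, 0)])
        structure = StructureModel("t", [a, b])
        assert protein_protein_contacts(_whole_span(a, "domain"),
                                        _whole_span(b, "domain"),
                                        structure) == []


def _guanine(chain, idx, anchor, away=(0, 1, 0)):
    """Guanine base with N7 exactly at ``anchor``; sugar/phosphate far."""
    ax, ay, az = anchor
    dx, dy, dz = away
    atoms = [AtomRecord("N7", "N", (ax, ay, az))]
    for k, (name, elem) in enumerate([("O6", "O"), ("N1", "N"), ("C2", "C"),
                                      ("N2", "N"), ("N3", "N"), ("C4", "C"),
                                      ("C5", "C"), ("C6", "C"), ("C8", "C"),
                                      ("N9", "N")]):
        atoms.append(AtomRecord(name, elem,
                                (ax + dx * (1 + 0.3 * k),
                                 ay + dy * (1 + 0.3 * k),
                                 az + dz * (1 + 0.3 * k))))
    for k, name in enumerate(["C1'", "O4'", "P", "OP1", "OP2"]):
        atoms.append(AtomRecord(name, name[0],
                                (ax + dx * 8, ay + dy * 8, az + dz * 8 + k)))
    return _nt(chain, idx, atoms, comp="DG")


class TestProteinNucleicContacts:
    @pytest.mark.parametrize("d,expected", [(3.4, 1), (3.5, 1), (3.6, 0)])
    def test_base_nitrogen_cutoff_boundary(self, d, expected):
        res = probe_residue("A", 0, (0, 0, 0))  # CA at origin, rest +y
        protein = ChainModel("A", [res])
        nt = _guanine("B", 0, (0, -d, 0), away=(0, -1, 0))
        nucleic = ChainModel("B", [nt])
        structure = StructureModel("t", [protein, nucleic])
        pairs = protein_nucleic_contacts(_whole_span(protein, "domain"),
                                         _whole_span(nucleic, "dna"),
                                         structure)
        assert len(pairs) == expected

    def test_phosphate_only_proximity_is_not_contact(self):
        # protein residue 3.0 A from OP1; every base atom >= 8 A away
        res = probe_residue("A", 0, (0, 0, 0))
        protein = ChainModel("A", [res])
        atoms = [AtomRecord("N7", "N", (0, -8.5, 0)),
                 AtomRecord("O6", "O", (0, -9.0, 0)),
                 AtomRecord("OP1", "O", (0, -3.0, 0)),
                 AtomRecord("P", "P", (0, -4.0, 0)),
                 AtomRecord("O5'", "O", (0, -3.2, 1.0))]
        nucleic = ChainModel("B", [_nt("B", 0, atoms)])
        structure = StructureModel("t", [protein, nucleic])
        pairs = protein_nucleic_contacts(_whole_span(protein, "domain"),
                                         _whole_span(nucleic, "dna"),
                                         structure)
        assert pairs == []
        # whole-nucleotide scope recovers it
        wide = ContactParams(nucleic_atom_scope="nucleotide")
        pairs = protein_nucleic_contacts(_whole_span(protein, "domain"),
                                         _whole_span(nucleic, "dna"),
                                         structure, wide)
        assert len(pairs) == 1

    def test_distant_duplex_no_contacts(self, duplex):
        dna, _ = duplex
        protein = protein_chain_at("A", [(200, 0, 3.8 * i)
                                         for i in range(5)])
        structure = StructureModel("t", [protein] + dna.chains,
                                   base_pairs=dna.base_pairs)
        sa = _whole_span(protein, "undefined_chain")
        for chain in dna.chains:
            assert protein_nucleic_contacts(
                sa, _whole_span(chain, "dna"), structure) == []


class TestNucleicNucleicContacts:
    def test_watson_crick_pair_is_contact(self, duplex):
        dna, _ = duplex
        structure = dna
        sa = _whole_span(dna.chains[0], "dna")
        sb = _whole_span(dna.chains[1], "dna")
        pairs = nucleic_nucleic_contacts(sa, sb, structure)
        assert len(pairs) >= 10  # at least every planned base pair
        diag = [p for p in pairs
                if p.unit_a.seq_index == p.unit_b.seq_index]
        assert len(diag) == 10
        assert all(p.min_distance == pytest.approx(2.9) for p in diag)

    def test_oxygen_oxygen_only_never_qualifies(self):
        a = ChainModel("A", [_nt("A", 0, [
            AtomRecord("O6", "O", (0, 0, 0)),
            AtomRecord("N1", "N", (0, 8, 0))])])
        b = ChainModel("B", [_nt("B", 0, [
            AtomRecord("O6", "O", (2.5, 0, 0)),
            AtomRecord("N1", "N", (2.5, -8, 0))])])
        structure = StructureModel("t", [a, b])
        assert nucleic_nucleic_contacts(_whole_span(a, "dna"),
                                        _whole_span(b, "dna"),
                                        structure) == []

    def test_separated_strands_no_contacts(self):
        a = fx.make_nucleic_chain("GACT", "dna", chain_id="A")
        b = fx.make_nucleic_chain("GACT", "dna", chain_id="B",
                                  origin=(50, 0, 0))
        structure = StructureModel("t", [a, b])
        assert nucleic_nucleic_contacts(_whole_span(a, "dna"),
                                        _whole_span(b, "dna"),
                                        structure) == []


class TestAdjacencyExclusion:
    def _pair(self, ia, ib):
        ua = probe_residue("A", ia, (0, 0, 0))
        ub = probe_residue("A", ib, (3, 0, 0))
        from macrodissect.contacts import ContactPair
        return ContactPair(ua, ub, 3.0, "CA", "CA")

    def test_adjacent_spans_drop_small_gaps(self):
        dom = SubunitSpan("domain", "A", ((0, 80),))
        link = SubunitSpan("linker", "A", ((81, 100),))
        pairs = [self._pair(80, 85), self._pair(80, 95)]
        kept = apply_adjacency_exclusion(pairs, dom, link)
        assert [(p.unit_a.seq_index, p.unit_b.seq_index) for p in kept] == \
            [(80, 95)]

    def test_gap_exactly_ten_dropped_eleven_kept(self):
        dom = SubunitSpan("domain", "A", ((0, 80),))
        link = SubunitSpan("linker", "A", ((81, 100),))
        kept = apply_adjacency_exclusion(
            [self._pair(80, 90), self._pair(80, 91)], dom, link)
        assert [(p.unit_a.seq_index, p.unit_b.seq_index) for p in kept] == \
            [(80, 91)]

    def test_non_adjacent_spans_keep_everything(self):
        dom = SubunitSpan("domain", "A", ((0, 40),))
        link = SubunitSpan("linker", "A", ((60, 100),))
        pairs = [self._pair(40, 61), self._pair(40, 99)]
        assert apply_adjacency_exclusion(pairs, dom, link) == pairs

    def test_different_chains_keep_everything(self):
        sa = SubunitSpan("domain", "A", ((0, 40),))
        sb = SubunitSpan("domain", "B", ((41, 80),))
        pairs = [self._pair(40, 41)]
        assert apply_adjacency_exclusion(pairs, sa, sb) == pairs


class TestDetectInteraction:
    def _docked(self, n_contacts, d=5.0):
        spec = fx.FixtureSpec(
            n_a=25, n_b=25,
            planned=tuple((i, d) for i in range(n_contacts)))
        return fx.make_docked_pair(spec)[0]

    def test_nine_pairs_absent_ten_present(self):
        for n, present in ((9, False), (10, True)):
            structure = self._docked(n)
            sa = _whole_span(structure.chains[0], "domain")
            sb = _whole_span(structure.chains[1], "domain")
            inter = detect_interaction(sa, sb, structure)
            assert (inter is not None) == present
            if inter:
                assert len(inter.contact_pairs) == 10
                assert inter.interaction_type == "D-D"
                assert not inter.is_intra_chain

    def test_single_nucleic_pair_suffices(self):
        res = probe_residue("A", 0, (0, 0, 0))
        protein = ChainModel("A", [res])
        nt = _guanine("B", 0, (0, -3.2, 0), away=(0, -1, 0))
        nucleic = ChainModel("B", [nt])
        structure = StructureModel("t", [protein, nucleic])
        inter = detect_interaction(_whole_span(protein, "domain"),
                                   _whole_span(nucleic, "rna"), structure)
        assert inter is not None
        assert len(inter.contact_pairs) == 1
        assert inter.interaction_type == "RNA-D"

    def test_symmetry_swapped_arguments(self):
        structure = self._docked(12)
        sa = _whole_span(structure.chains[0], "domain")
        sb = _whole_span(structure.chains[1], "peptide")
        fwd = detect_interaction(sa, sb, structure)
        rev = detect_interaction(sb, sa, structure)
        assert fwd is not None and rev is not None
        assert fwd.interaction_type == rev.interaction_type == "D-P"
        fwd_pairs = {(p.unit_a.seq_index, p.unit_b.seq_index,
                      round(p.min_distance, 9)) for p in fwd.contact_pairs}
        rev_pairs = {(p.unit_b.seq_index, p.unit_a.seq_index,
                      round(p.min_distance, 9)) for p in rev.contact_pairs}
        assert fwd_pairs == rev_pairs

    def test_intra_chain_adjacent_boundary_contacts_excluded(self):
        # extended chain: only the covalent-neighbour pair (9, 10) crosses
        # the span boundary within 6 A, and it is sequence-adjacent
        chain = fx.make_protein_chain(20)
        structure = StructureModel("t", [chain])
        dom = SubunitSpan("domain", "A", ((0, 9),))
        link = SubunitSpan("linker", "A", ((10, 19),))
        params = ContactParams(min_pp_contact_pairs=1)
        assert detect_interaction(dom, link, structure, params) is None

    def test_threshold_monotonicity(self):
        structure = fx.make_random_structure(5)
        sa = _whole_span(structure.chains[0], "undefined_chain")
        sb = _whole_span(structure.chains[1], "undefined_chain")
        tight = protein_protein_contacts(sa, sb, structure,
                                         ContactParams(pp_distance_cutoff=4.5))
        loose = protein_protein_contacts(sa, sb, structure,
                                         ContactParams(pp_distance_cutoff=6.0))
        tight_keys = {(p.unit_a.seq_index, p.unit_b.seq_index)
                      for p in tight}
        loose_keys = {(p.unit_a.seq_index, p.unit_b.seq_index)
                      for p in loose}
        assert tight_keys <= loose_keys

    def test_unsupported_kind_errors(self):
        structure = self._docked(10)
        sa = _whole_span(structure.chains[0], "domain")
        bad = SubunitSpan("hybrid", "B", ((0, 24),))
        with pytest.raises(ValueError):
            detect_interaction(sa, bad, structure)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(12))
    @pytest.mark.parametrize("kinds", [("protein", "protein"),
                                       ("protein", "dna"),
                                       ("rna", "dna")])
    def test_engine_matches_bruteforce(self, seed, kinds):
        structure = fx.make_random_structure(seed * 3 + 1, kinds=kinds,
                                             n_a=25, n_b=25, box=22.0)
        ca, cb = structure.chains
        sa = _whole_span(ca, "undefined_chain" if kinds[0] == "protein"
                         else kinds[0])
        sb = _whole_span(cb, "undefined_chain" if kinds[1] == "protein"
                         else kinds[1])
        if kinds == ("protein", "protein"):
            got = protein_protein_contacts(sa, sb, structure)
            want = oracles.bf_protein_protein(ca.units, cb.units)
        elif kinds == ("protein", "dna"):
            got = protein_nucleic_contacts(sa, sb, structure)
            want = oracles.bf_protein_nucleic(ca.units, cb.units)
        else:
            got = nucleic_nucleic_contacts(sa, sb, structure)
            want = oracles.bf_nucleic_nucleic(ca.units, cb.units)
        got_map = {(p.unit_a.seq_index, p.unit_b.seq_index): p.min_distance
                   for p in got}
        assert set(got_map) == set(want)
        for key, d in want.items():
            assert got_map[key] == pytest.approx(d, abs=1e-9)
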