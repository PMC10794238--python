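"""PDB parsing, contact maps, contact energies, and structure mapping."""

import numpy as np
import pytest

from tcsevo.alphabet import AA_INDEX, GAP_CODE
from tcsevo.errors import ConfigurationError, SelectionError
from tcsevo.msa import alignment_from_codes
from tcsevo.structure import (
    ContactMap,
    Residue,
    Structure,
    build_contact_map,
    complex_energy,
    map_alignment_to_structure,
    pair_min_distance,
    read_structure,
    sequence_energy,
)

PDB_THREE_RESIDUES = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.400   0.000   0.000  1.00  0.00           C
ATOM      3  CA  GLY A   2       5.000   0.000   0.000  1.00  0.00           C
ATOM      4  HA  GLY A   2       5.500   0.500   0.000  1.00  0.00           H
ATOM      5  CA  TRP A   3      10.000   0.000   0.000  1.00  0.00           C
END
"""

PDB_ALTLOC = """\
ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.40  0.00           C
ATOM      2  CA BALA A   1       0.500   0.000   0.000  0.60  0.00           C
ATOM      3  CB  ALA A   1       1.000   1.000   0.000  1.00  0.00           C
ATOM      4  CA  GLY A   2       3.800   0.000   0.000  1.00  0.00           C
END
"""


class TestReadStructure:
    def test_three_residue_fixture(self, tmp_path):
        p = tmp_path / "s.pdb"
        p.write_text(PDB_THREE_RESIDUES)
        s = read_structure(p)
        assert s.n_residues == 3
        assert [r.name for r in s.residues] == ["A", "G", "W"]
        # hydrogens dropped: GLY keeps only its CA
        assert s.residues[1].coords.shape == (1, 3)

    def test_missing_chain_rejected(self, tmp_path):
        p = tmp_path / "s.pdb"
        p.write_text(PDB_THREE_RESIDUES)
        with pytest.raises(SelectionError):
            read_structure(p, chain_selection=("B",))

    def test_altloc_resolved_to_highest_occupancy(self, tmp_path):
        p = tmp_path / "s.pdb"
        p.write_text(PDB_ALTLOC)
        s = read_structure(p)
        # hand count: ALA keeps one CA conformer (occupancy 0.60) + CB = 2 atoms
        assert s.residues[0].coords.shape == (2, 3)
        assert s.residues[0].coords[0] == pytest.approx([0.5, 0.0, 0.0])


def _point_structure(points, chain="A", names=None):
    """One single-atom residue per 3-D point."""
    res = []
    for i, xyz in enumerate(points):
        res.append(
            Residue(
                chain=chain if isinstance(chain, str) else chain[i],
                resnum=i + 1,
                name=(names[i] if names else "A"),
                coords=np.asarray([xyz], dtype=float),
            )
        )
    return Structure(residues=tuple(res))


class TestBuildContactMap:
    def test_contact_within_cutoff_and_separation(self):
        s = _point_structure([(0, 0, 0), (20, 0, 0), (30, 0, 0), (4.0, 0, 0)])
        cmap = build_contact_map(s, cutoff=5.0, min_sep=2)
        assert (0, 3) in cmap.contact_set()

    def test_sequence_adjacent_pairs_never_contact(self):
        s = _point_structure([(0, 0, 0), (1.0, 0, 0), (2.0, 0, 0)])
        cmap = build_contact_map(s, cutoff=5.0, min_sep=2)
        assert (0, 1) not in cmap.contact_set()
        assert (1, 2) not in cmap.contact_set()
        assert (0, 2) in cmap.contact_set()  # separation 2, distance 2.0

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_brute_force_all_atom_loop(self, seed):
        rng = np.random.default_rng(seed)
        res = []
        chains = ["A"] * 5 + ["B"] * 3
        for i, ch in enumerate(chains):
            coords = rng.uniform(0, 12, size=(rng.integers(1, 4), 3))
            res.append(Residue(chain=ch, resnum=i + 1, name="A", coords=coords))
        s = Structure(residues=tuple(res))
        cmap = build_contact_map(s, cutoff=6.0, min_sep=2)

        expected = set()
        pos_in_chain = {}
        counter = {}
        for i, r in enumerate(s.residues):
            pos_in_chain[i] = counter.get(r.chain, 0)
            counter[r.chain] = pos_in_chain[i] + 1
        for i in range(8):
            for j in range(i + 1, 8):
                ri, rj = s.residues[i], s.residues[j]
                dmin = min(
                    float(np.linalg.norm(a - b))
                    for a in ri.coords
                    for b in rj.coords
                )
                same = ri.chain == rj.chain
                if same and abs(pos_in_chain[i] - pos_in_chain[j]) < 2:
                    continue
                if dmin < 6.0:
                    expected.add((i, j))
        assert cmap.contact_set() == expected

    def test_inter_chain_pairs_exempt_from_separation(self):
        s = _point_structure([(0, 0, 0), (1, 0, 0)], chain=["A", "B"])
        cmap = build_contact_map(s, cutoff=5.0, min_sep=2)
        assert cmap.contact_set() == {(0, 1)}
        assert cmap.labels == ("inter",)

    def test_cutoff_monotonicity(self, toy_single):
        s = toy_single.structure
        small = build_contact_map(s, cutoff=4.5)
        large = build_contact_map(s, cutoff=6.0)
        assert small.contact_set() <= large.contact_set()

    def test_atom_order_permutation_invariance(self):
        rng = np.random.default_rng(5)
        coords = rng.uniform(0, 8, size=(4, 3))
        s1 = _point_structure([(0, 0, 0), (9, 9, 9)])
        r = Residue(chain="A", resnum=3, name="A", coords=coords)
        r_perm = Residue(chain="A", resnum=3, name="A", coords=coords[::-1])
        s1 = Structure(residues=(s1.residues[0], s1.residues[1], r))
        s2 = Structure(residues=(s1.residues[0], s1.residues[1], r_perm))
        assert build_contact_map(s1).contact_set() == build_contact_map(s2).contact_set()


class TestSequenceEnergy:
    def test_empty_contact_map_is_zero(self, em):
        cmap = ContactMap(
            n_residues=3,
            pairs=np.empty((0, 2), dtype=int),
            labels=(),
            cutoff=5.0,
            min_sep=2,
            chain_of=("A", "A", "A"),
            chain_pos=np.arange(3),
        )
        assert sequence_energy("ACD", cmap, em) == 0.0

    def test_single_contact_is_table_lookup(self, em):
        cmap = _simple_map(4, [(0, 3)])
        e = sequence_energy("LKAW", cmap, em)
        assert e == pytest.approx(em[AA_INDEX["L"], AA_INDEX["W"]])

    @pytest.mark.parametrize("seed", [0, 3])
    def test_matches_naive_double_loop(self, em, seed, toy_single):
        rng = np.random.default_rng(seed)
        cmap = toy_single.contact_map
        codes = rng.integers(0, 20, size=20).astype(np.int8)
        expected = sum(
            float(em[codes[i], codes[j]]) for i, j in cmap.pairs
        )
        assert sequence_energy(codes, cmap, em) == pytest.approx(expected)

    def test_additive_over_contact_partition(self, em, toy_single):
        cmap = toy_single.contact_map
        rng = np.random.default_rng(1)
        codes = rng.integers(0, 20, size=20).astype(np.int8)
        k = cmap.pairs.shape[0] // 2
        e1 = sequence_energy(codes, cmap, em, cmap.pairs[:k])
        e2 = sequence_energy(codes, cmap, em, cmap.pairs[k:])
        assert e1 + e2 == pytest.approx(sequence_energy(codes, cmap, em))

    def test_gap_at_contact_contributes_zero_with_warning(self, em):
        cmap = _simple_map(4, [(0, 3), (1, 3)])
        codes = np.array([AA_INDEX["L"], GAP_CODE, 0, AA_INDEX["W"]], dtype=np.int8)
        with pytest.warns(UserWarning, match="gap"):
            e = sequence_energy(codes, cmap, em)
        assert e == pytest.approx(em[AA_INDEX["L"], AA_INDEX["W"]])


def _simple_map(n, pairs, chain_of=None):
    chain_of = chain_of or tuple("A" for _ in range(n))
    labels = tuple(
        "inter" if chain_of[i] != chain_of[j] else f"intra:{chain_of[i]}"
        for i, j in pairs
    )
    return ContactMap(
        n_residues=n,
        pairs=np.asarray(pairs, dtype=int).reshape(-1, 2),
        labels=labels,
        cutoff=5.0,
        min_sep=2,
        chain_of=chain_of,
        chain_pos=np.arange(n),
    )


class TestComplexEnergy:
    def test_no_inter_contacts(self, em):
        cmap = _simple_map(4, [(0, 2)], chain_of=("A", "A", "A", "B"))
        e1, e2, e12, e = complex_energy("ACD", "W", cmap, em)
        assert e12 == 0.0
        assert e == pytest.approx(e1 + e2)

    def test_rigid_mode_total_is_inter_energy(self, em, toy_complex):
        cmap = toy_complex.contact_map
        rng = np.random.default_rng(0)
        sa = rng.integers(0, 20, size=30).astype(np.int8)
        sb = rng.integers(0, 20, size=30).astype(np.int8)
        e1, e2, e12, e = complex_energy(sa, sb, cmap, em, rigid=True)
        assert e == e12
        _, _, _, e_full = complex_energy(sa, sb, cmap, em, rigid=False)
        assert e_full == pytest.approx(e1 + e2 + e12)

    def test_components_match_label_partitioned_brute_force(self, em, toy_complex):
        cmap = toy_complex.contact_map
        rng = np.random.default_rng(2)
        sa = rng.integers(0, 20, size=30).astype(np.int8)
        sb = rng.integers(0, 20, size=30).astype(np.int8)
        full = np.concatenate([sa, sb])
        sums = {"intra:A": 0.0, "intra:B": 0.0, "inter": 0.0}
        for (i, j), lb in zip(cmap.pairs, cmap.labels):
            sums[lb] += float(em[full[i], full[j]])
        e1, e2, e12, e = complex_energy(sa, sb, cmap, em)
        assert e1 == pytest.approx(sums["intra:A"])
        assert e2 == pytest.approx(sums["intra:B"])
        assert e12 == pytest.approx(sums["inter"])


class TestPairMinDistance:
    def test_residue_with_itself_is_zero(self):
        s = _point_structure([(1, 2, 3)])
        assert pair_min_distance(s, 0, 0) == 0.0

    def test_two_single_atom_residues(self):
        s = _point_structure([(0, 0, 0), (7.5, 0, 0)])
        assert pair_min_distance(s, 0, 1) == pytest.approx(7.5)

    def test_matches_brute_force_over_atom_pairs(self, toy_complex):
        s = toy_complex.structure
        i, j = 3, 17
        expected = min(
            float(np.linalg.norm(a - b))
            for a in s.residues[i].coords
            for b in s.residues[j].coords
        )
        assert pair_min_distance(s, i, j) == pytest.approx(expected)


class TestMapAlignmentToStructure:
    def _aln_from_seq(self, seq, domain="Rec"):
        codes = np.vstack([[AA_INDEX[c] for c in seq]] * 3).astype(np.int8)
        return alignment_from_codes(codes, {domain: (0, len(seq))})

    def test_identity_mapping(self):
        seq = "ACDEFGHIKL"
        s = _point_structure([(3.8 * i, 0, 0) for i in range(10)], names=list(seq))
        aln = self._aln_from_seq(seq)
        m = map_alignment_to_structure(aln, s, {"Rec": "A"})
        assert m.unmapped_columns == ()
        assert [m.column_to_residue[c][1] for c in range(10)] == list(range(1, 11))

    def test_missing_structure_residue_leaves_column_unmapped(self):
        seq = "ACDEFGHIKL"
        struct_seq = "ACDEGHIKL"  # F missing
        s = _point_structure(
            [(3.8 * i, 0, 0) for i in range(9)], names=list(struct_seq)
        )
        aln = self._aln_from_seq(seq)
        m = map_alignment_to_structure(aln, s, {"Rec": "A"})
        assert 4 in m.unmapped_columns
        assert m.column_to_residue[3][1] == 4  # E before the gap
        assert m.column_to_residue[5][1] == 5  # G after the gap

    def test_structure_insertion_matches_hand_table(self):
        seq = "ACDEFGHIKL"
        struct_seq = "ACDEFWWGHIKL"  # two-residue insertion after F
        s = _point_structure(
            [(3.8 * i, 0, 0) for i in range(12)], names=list(struct_seq)
        )
        aln = self._aln_from_seq(seq)
        m = map_alignment_to_structure(aln, s, {"Rec": "A"})
        hand = {0: 1, 1: 2, 2: 3, 3: 4, 4: 5, 5: 8, 6: 9, 7: 10, 8: 11, 9: 12}
        assert {c: rn for c, (_, rn) in m.column_to_residue.items()} == hand
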