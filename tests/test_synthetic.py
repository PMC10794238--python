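"""Synthetic MSAs, toy structures, and decoy-ensemble generators."""

import numpy as np
import pytest
from scipy import stats

from tcsevo.alphabet import AA_INDEX, GAP_CODE, N_AA
from tcsevo.conservation import coupling_conservation, position_conservation
from tcsevo.errors import (
    ConfigurationError,
    DecoyFormatError,
    GenerationError,
    SpecError,
)
from tcsevo.msa import estimate_frequencies
from tcsevo.synthetic import (
    BindingDecoySet,
    FoldingDecoySet,
    SyntheticMsaSpec,
    binding_decoys,
    export_decoys,
    folding_decoys,
    import_decoys,
    make_toy_structure,
    sample_msa,
)

UNIFORM_Q = np.full(N_AA, 1.0 / N_AA)


class TestSampleMsa:
    def test_full_dominance_recovers_closed_form_conservation(self):
        spec = SyntheticMsaSpec(
            n_seqs=400, n_cols=5, conserved={2: ("W", 1.0)}, seed=0, background=UNIFORM_Q
        )
        aln = sample_msa(spec)
        c = position_conservation(estimate_frequencies(aln, UNIFORM_Q, pseudocount=0.0))
        assert c[2] == pytest.approx(np.log(20), abs=1e-9)

    def test_perfect_correlation_recovers_coupling_closed_form(self):
        spec = SyntheticMsaSpec(
            n_seqs=3000,
            n_cols=4,
            coupled={(0, 3): ((("A", "A"), ("V", "V")), 1.0)},
            seed=1,
            background=UNIFORM_Q,
        )
        aln = sample_msa(spec)
        cm = coupling_conservation(estimate_frequencies(aln, UNIFORM_Q, pseudocount=1e-8))
        assert cm.C2[0, 3] == pytest.approx(np.log(19) / 2, abs=0.05)

    def test_null_spec_has_no_coupling_signal(self):
        spec = SyntheticMsaSpec(n_seqs=800, n_cols=10, seed=2)
        aln = sample_msa(spec)
        cm = coupling_conservation(estimate_frequencies(aln, pseudocount=1e-4))
        assert cm.offdiag_values().mean() < 0.05

    def test_gap_rate_honored(self):
        spec = SyntheticMsaSpec(n_seqs=500, n_cols=20, gap_rate=0.1, seed=3)
        aln = sample_msa(spec)
        frac = (aln.codes == GAP_CODE).mean()
        assert frac == pytest.approx(0.1, abs=0.01)

    def test_contradictory_planting_rejected(self):
        spec = SyntheticMsaSpec(
            n_seqs=10,
            n_cols=5,
            conserved={1: ("A", 0.9)},
            coupled={(1, 3): ((("A", "A"), ("V", "V")), 0.5)},
        )
        with pytest.raises(SpecError):
            sample_msa(spec)

    def test_column_reuse_across_pairs_rejected(self):
        spec = SyntheticMsaSpec(
            n_seqs=10,
            n_cols=6,
            coupled={
                (0, 2): ((("A", "A"), ("V", "V")), 0.5),
                (2, 4): ((("L", "L"), ("F", "F")), 0.5),
            },
        )
        with pytest.raises(SpecError):
            sample_msa(spec)

    def test_deterministic_in_seed(self):
        spec = SyntheticMsaSpec(n_seqs=50, n_cols=8, seed=11)
        a1, a2 = sample_msa(spec), sample_msa(spec)
        assert (a1.codes == a2.codes).all()


class TestMakeToyStructure:
    def test_min_sep_respected_and_buried_nonempty(self):
        toy = make_toy_structure(20, chains=1, seed=0)
        for (i, j), lb in zip(toy.contact_map.pairs, toy.contact_map.labels):
            if lb.startswith("intra"):
                assert j - i >= 2
        assert len(toy.buried) > 0 and len(toy.surface) > 0

    def test_buried_have_strictly_more_contacts_than_surface(self):
        toy = make_toy_structure(27, chains=1, seed=5)
        deg = np.zeros(27, dtype=int)
        np.add.at(deg, toy.contact_map.intra_pairs("A").ravel(), 1)
        assert deg[list(toy.buried)].min() > deg[list(toy.surface)].max()

    def test_two_chain_variant_has_interface(self):
        toy = make_toy_structure(30, chains=2, seed=0)
        assert len(toy.interface) >= 3
        for pos in toy.interface:
            assert (toy.contact_map.inter_pairs() == pos).any()

    def test_deterministic_in_seed(self):
        t1 = make_toy_structure(16, chains=2, seed=9)
        t2 = make_toy_structure(16, chains=2, seed=9)
        for r1, r2 in zip(t1.structure.residues, t2.structure.residues):
            assert (r1.coords == r2.coords).all()

    def test_too_small_rejected(self):
        with pytest.raises(ConfigurationError):
            make_toy_structure(4)


class TestFoldingDecoys:
    def test_contact_count_preserved(self, chain_a_map):
        ds = folding_decoys(chain_a_map, 50, seed=0)
        k = chain_a_map.pairs.shape[0]
        assert all(p.shape[0] == k for p in ds.decoy_pairs)

    def test_native_map_never_a_decoy(self, chain_a_map):
        ds = folding_decoys(chain_a_map, 50, seed=0)
        native = frozenset(map(tuple, chain_a_map.pairs.tolist()))
        for p in ds.decoy_pairs:
            assert frozenset(map(tuple, p.tolist())) != native

    def test_min_sep_respected_in_decoys(self, chain_a_map):
        ds = folding_decoys(chain_a_map, 20, seed=1)
        for p in ds.decoy_pairs:
            assert (p[:, 1] - p[:, 0] >= chain_a_map.min_sep).all()

    def test_degree_preserving_mode(self, chain_a_map):
        ds = folding_decoys(chain_a_map, 10, seed=2, mode="rewire-degree")
        deg_native = np.zeros(30, dtype=int)
        np.add.at(deg_native, chain_a_map.pairs.ravel(), 1)
        for p in ds.decoy_pairs:
            deg = np.zeros(30, dtype=int)
            np.add.at(deg, p.ravel(), 1)
            assert (deg == deg_native).all()

    def test_decoy_energies_approximately_gaussian(self, chain_a_map, em):
        """Sums of ~60 contact energies over random maps: normality should not
        be rejected at alpha = 0.01 for a fixed random sequence."""
        ds = folding_decoys(chain_a_map, 1000, seed=3)
        rng = np.random.default_rng(4)
        codes = rng.integers(0, N_AA, size=30).astype(np.int8)
        _, e_d = ds.energies(codes, em)
        _, p = stats.normaltest(e_d)
        assert p > 0.01

    def test_thread_mode_truncates_fixture_maps(self, chain_a_map):
        other = [make_toy_structure(40, chains=1, seed=s).contact_map for s in (7, 8)]
        ds = folding_decoys(chain_a_map, 2, mode="thread", fixture_maps=other)
        for p in ds.decoy_pairs:
            assert (p < 30).all()

    def test_thread_mode_with_too_few_fixtures(self, chain_a_map):
        other = [make_toy_structure(40, chains=1, seed=7).contact_map]
        with pytest.raises(GenerationError):
            folding_decoys(chain_a_map, 5, mode="thread", fixture_maps=other)


class TestBindingDecoys:
    def test_no_decoy_equals_native_inter_map(self, toy_complex):
        ds = binding_decoys(toy_complex, 50, seed=0)
        native = frozenset(map(tuple, ds.native_pairs.tolist()))
        for p in ds.decoy_pairs:
            assert frozenset(map(tuple, p.tolist())) != native

    def test_decoy_interfaces_smaller_than_native(self, toy_complex):
        ds = binding_decoys(toy_complex, 50, seed=0)
        k = ds.native_pairs.shape[0]
        assert all(p.shape[0] <= 0.75 * k for p in ds.decoy_pairs)

    def test_far_translations_give_zero_inter_energy(self, toy_complex, em):
        ds = binding_decoys(toy_complex, 200, seed=1)
        rng = np.random.default_rng(2)
        codes = rng.integers(0, N_AA, size=toy_complex.contact_map.n_residues).astype(np.int8)
        _, e_d = ds.energies(codes, em)
        assert (e_d == 0.0).any()  # some poses drift out of contact range

    def test_single_chain_structure_rejected(self, toy_single):
        with pytest.raises(ConfigurationError):
            binding_decoys(toy_single, 10, seed=0)


class TestDecoyExchange:
    def test_round_trip_preserves_energies_exactly(self, chain_a_map, em, tmp_path):
        ds = folding_decoys(chain_a_map, 10, seed=5)
        path = tmp_path / "decoys.jsonl"
        export_decoys(ds, path)
        back = import_decoys(path)
        assert isinstance(back, FoldingDecoySet)
        assert back.n_decoys == 10
        rng = np.random.default_rng(6)
        codes = rng.integers(0, N_AA, size=30).astype(np.int8)
        e1n, e1d = ds.energies(codes, em)
        e2n, e2d = back.energies(codes, em)
        assert e1n == e2n
        assert (e1d == e2d).all()

    def test_three_decoys_import(self, tmp_path):
        path = tmp_path / "d.jsonl"
        path.write_text(
            '{"schema": "tcsevo-decoys/1", "kind": "binding", "n_residues": 6, "native": [[0, 4]]}\n'
            '{"pairs": [[0, 5]]}\n{"pairs": []}\n{"pairs": [[1, 4], [2, 5]]}\n'
        )
        ds = import_decoys(path)
        assert isinstance(ds, BindingDecoySet)
        assert ds.n_decoys == 3

    def test_malformed_row_reports_line_number(self, tmp_path):
        path = tmp_path / "d.jsonl"
        path.write_text(
            '{"schema": "tcsevo-decoys/1", "kind": "folding", "n_residues": 6, "native": [[0, 4]]}\n'
            '{"pairs": [[0, 5]]}\nnot json\n'
        )
        with pytest.raises(DecoyFormatError, match=":3:"):
            import_decoys(path)

    def test_unknown_schema_rejected(self, tmp_path):
        path = tmp_path / "d.jsonl"
        path.write_text('{"schema": "other/9"}\n{"pairs": []}\n')
        with pytest.raises(DecoyFormatError):
            import_decoys(path)
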