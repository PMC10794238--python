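"""Residue-level frustration: oracle equivalence, profiles, deltas."""

import numpy as np
import pytest

from tcsevo.alphabet import AA_INDEX, N_AA
from tcsevo.errors import (
    ConfigurationError,
    DegenerateDecoyError,
    InputError,
    NoContactError,
    UndefinedCorrelationError,
)
from tcsevo.frustration import (
    FrustrationProfile,
    ensemble_frustration_profile,
    frustration_delta,
    frustration_index,
    frustration_index_exact,
    interface_enrichment_test,
    profile_correlation,
)
from tcsevo.structure import ContactMap


def _chain_map(n, pairs):
    return ContactMap(
        n_residues=n,
        pairs=np.asarray(pairs, dtype=int).reshape(-1, 2),
        labels=tuple("intra:A" for _ in pairs),
        cutoff=5.0,
        min_sep=2,
        chain_of=tuple("A" for _ in range(n)),
        chain_pos=np.arange(n),
    )


def _exhaustive_f(codes, pos, cmap, em, weights):
    """Independent enumeration oracle: closed-form mean/std over identities."""
    partners = []
    for i, j in cmap.pairs:
        if i == pos:
            partners.append(j)
        elif j == pos:
            partners.append(i)
    energies = []
    for x in range(N_AA):
        e = 0.0
        for p in partners:
            e += float(em[x, codes[p]])
        energies.append(e)
    mean = sum(w * e for w, e in zip(weights, energies))
    var = sum(w * (e - mean) ** 2 for w, e in zip(weights, energies))
    native = energies[int(codes[pos])]
    return (mean - native) / np.sqrt(var)


class TestFrustrationIndex:
    def test_zero_when_native_equals_composition_mean(self):
        # seq A C D, position 0 contacts position 1 (C) only; craft a table
        # where xi(A,C) is exactly the composition mean of {xi(A,C), xi(C,C),
        # xi(D,C)} -> F = 0
        em = np.zeros((N_AA, N_AA))
        A, C, D = AA_INDEX["A"], AA_INDEX["C"], AA_INDEX["D"]
        em[A, C] = em[C, A] = -2.0
        em[C, C] = -1.0
        em[D, C] = em[C, D] = -3.0
        cmap = _chain_map(3, [(0, 2)])
        codes = np.array([A, D, C], dtype=np.int8)  # pos 0 contacts pos 2 (C)
        f = frustration_index_exact(codes, 0, cmap, em, mode="composition")
        assert f == pytest.approx(0.0, abs=1e-12)

    def test_identical_candidate_energies_raise_degenerate(self):
        em = np.full((N_AA, N_AA), -1.0)
        cmap = _chain_map(3, [(0, 2)])
        codes = np.array([0, 1, 2], dtype=np.int8)
        with pytest.raises(DegenerateDecoyError):
            frustration_index(codes, 0, cmap, em, mode="uniform", seed=0)

    def test_position_without_contacts_raises(self, em):
        cmap = _chain_map(4, [(0, 2)])
        with pytest.raises(NoContactError):
            frustration_index("ACDE", 1, cmap, em, seed=0)

    def test_gap_in_neighborhood_raises(self, em):
        cmap = _chain_map(4, [(0, 2)])
        with pytest.raises(ConfigurationError):
            frustration_index("AC-E", 0, cmap, em, seed=0)

    @pytest.mark.parametrize("pos", [0, 5, 11, 17])
    def test_sampled_within_three_mc_standard_errors_of_exact(self, em, toy_single, pos):
        rng = np.random.default_rng(pos)
        codes = rng.integers(0, N_AA, size=20).astype(np.int8)
        cmap = toy_single.contact_map
        comp = np.bincount(codes, minlength=N_AA)[:N_AA] / codes.size
        exact = _exhaustive_f(codes, pos, cmap, em, comp)
        n = 1000
        sampled = frustration_index(codes, pos, cmap, em, n_decoys=n, seed=pos + 1)
        se = np.sqrt((1.0 + exact**2 / 2.0) / n)  # delta-method error of a z-score
        assert abs(sampled - exact) <= 3 * se

    def test_deterministic_given_seed(self, em, toy_single):
        codes = np.random.default_rng(0).integers(0, N_AA, size=20).astype(np.int8)
        f1 = frustration_index(codes, 5, toy_single.contact_map, em, seed=77)
        f2 = frustration_index(codes, 5, toy_single.contact_map, em, seed=77)
        assert f1 == f2

    def test_invariant_to_uniform_energy_shift(self, em, toy_single):
        codes = np.random.default_rng(1).integers(0, N_AA, size=20).astype(np.int8)
        f1 = frustration_index_exact(codes, 4, toy_single.contact_map, em)
        f2 = frustration_index_exact(codes, 4, toy_single.contact_map, em + 11.0)
        assert f2 == pytest.approx(f1, abs=1e-9)

    def test_exact_matches_enumeration_on_every_contacting_position(self, em, toy_single):
        codes = np.random.default_rng(2).integers(0, N_AA, size=20).astype(np.int8)
        cmap = toy_single.contact_map
        comp = np.bincount(codes, minlength=N_AA)[:N_AA] / codes.size
        touched = sorted(set(cmap.pairs.ravel().tolist()))
        for pos in touched:
            expected = _exhaustive_f(codes, pos, cmap, em, comp)
            assert frustration_index_exact(codes, pos, cmap, em) == pytest.approx(expected)


class TestEnsembleProfile:
    def test_singleton_set_equals_single_sequence_profile(self, em, toy_single):
        codes = np.random.default_rng(3).integers(0, N_AA, size=20).astype(np.int8)
        p1 = ensemble_frustration_profile([codes], toy_single.contact_map, em, seed=5)
        p2 = ensemble_frustration_profile([codes, codes], toy_single.contact_map, em, seed=5)
        assert np.allclose(p1.F, p2.F, equal_nan=True)

    def test_empty_set_rejected(self, em, toy_single):
        with pytest.raises(InputError):
            ensemble_frustration_profile([], toy_single.contact_map, em)

    def test_mean_equals_per_sequence_recomputation(self, em, toy_single):
        """The profile is the per-position average of per-sequence indices,
        recomputed here sequence by sequence with the same derived streams."""
        import zlib

        rng = np.random.default_rng(4)
        seqs = [rng.integers(0, N_AA, size=20).astype(np.int8) for _ in range(10)]
        cmap = toy_single.contact_map
        seed, nd = 9, 500
        prof = ensemble_frustration_profile(seqs, cmap, em, n_decoys=nd, seed=seed)
        pos = int(cmap.pairs[0, 0])
        vals = []
        for codes in seqs:
            crc = zlib.crc32(np.ascontiguousarray(codes).tobytes())
            g = np.random.default_rng([seed, pos, crc])
            vals.append(frustration_index(codes, pos, cmap, em, n_decoys=nd, seed=g))
        assert prof.F[pos] == pytest.approx(np.mean(vals))


def _profile(values):
    v = np.asarray(values, dtype=float)
    ones = np.ones_like(v)
    return FrustrationProfile(
        F=v, native_energy=ones, decoy_mean=ones, decoy_std=ones,
        n_decoys=100, n_sequences=ones.astype(int),
    )


class TestFrustrationDelta:
    def test_identical_profiles_classify_nothing(self):
        p = _profile([0.5, -1.0, 2.0])
        d = frustration_delta(p, p)
        assert d.less_frustrated == () and d.more_frustrated == ()

    def test_hand_built_classification(self):
        p1 = _profile([0.0, 0.0, 0.0])
        p2 = _profile([0.8, -0.9, 0.1])
        d = frustration_delta(p1, p2, threshold=0.70)
        assert d.less_frustrated == (0,)
        assert d.more_frustrated == (1,)

    def test_mismatched_positions_rejected(self):
        with pytest.raises(ConfigurationError):
            frustration_delta(_profile([0.0, 1.0]), _profile([0.0, 1.0, 2.0]))

    def test_classified_sets_partition_threshold_exceeders(self):
        rng = np.random.default_rng(8)
        p1 = _profile(rng.normal(size=40))
        p2 = _profile(rng.normal(size=40))
        d = frustration_delta(p1, p2, threshold=0.70)
        over = set(np.nonzero(np.abs(d.delta) >= 0.70)[0].tolist())
        assert set(d.less_frustrated) | set(d.more_frustrated) == over
        assert set(d.less_frustrated) & set(d.more_frustrated) == set()


class TestProfileCorrelation:
    def test_self_correlation_is_one(self):
        p = _profile([0.1, 0.5, -0.4, 1.2])
        r, _ = profile_correlation(p, p)
        assert r == pytest.approx(1.0)

    def test_negated_profile_is_minus_one(self):
        p = _profile([0.1, 0.5, -0.4, 1.2])
        r, _ = profile_correlation(p, _profile(-np.asarray([0.1, 0.5, -0.4, 1.2])))
        assert r == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        a = [0.3, -1.0, 2.0, 0.7, -0.2]
        b = [1.1, -0.5, 1.2, 0.0, 0.4]
        r, _ = profile_correlation(_profile(a), _profile(b))
        ma, mb = sum(a) / 5, sum(b) / 5
        num = sum((x - ma) * (y - mb) for x, y in zip(a, b))
        den = (
            sum((x - ma) ** 2 for x in a) * sum((y - mb) ** 2 for y in b)
        ) ** 0.5
        assert r == pytest.approx(num / den)

    def test_constant_profile_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            profile_correlation(_profile([1.0, 1.0, 1.0]), _profile([0.1, 0.2, 0.3]))

    def test_too_few_shared_positions_rejected(self):
        p1 = _profile([0.1, np.nan, np.nan, 0.4])
        p2 = _profile([0.2, 0.3, np.nan, np.nan])
        with pytest.raises(UndefinedCorrelationError):
            profile_correlation(p1, p2)


class TestInterfaceEnrichment:
    def test_strong_interface_signal_is_significant(self):
        rng = np.random.default_rng(0)
        delta = rng.normal(0, 0.1, size=30)
        iface = (2, 5, 9, 14)
        delta[list(iface)] += 2.0
        stat, p = interface_enrichment_test(delta, iface, n_permutations=2000, seed=1)
        assert stat > 1.0
        assert p < 0.01

    def test_null_signal_is_not_significant(self):
        rng = np.random.default_rng(3)
        delta = rng.normal(0, 1.0, size=200)
        stat, p = interface_enrichment_test(delta, tuple(range(0, 40)), seed=2)
        assert p > 0.05
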