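import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import acpsmo as a
from acpsmo.features import PAIRS, pair_name
from acpsmo.sequence_io import ALPHABET, RESIDUE_INDEX
from conftest import random_peptides

peptide_seq = st.text(alphabet=ALPHABET, min_size=1, max_size=50)


def vec(fv):
    return fv.values


class TestAac:
    @pytest.mark.parametrize(
        "seq, expected",
        [
            ("GG", {"G": 1.0}),
            ("ACDEFGHIKLMNPQRSTVWY", {aa: 0.05 for aa in ALPHABET}),
            ("KLLK", {"K": 0.5, "L": 0.5}),
        ],
    )
    def test_known_compositions(self, seq, expected):
        v = vec(a.aac(a.Peptide("p", seq)))
        for aa in ALPHABET:
            assert v[RESIDUE_INDEX[aa]] == pytest.approx(expected.get(aa, 0.0))

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            a.aac(a.Peptide("p", ""))

    @settings(derandomize=True, max_examples=50)
    @given(seq=peptide_seq)
    def test_sums_to_one(self, seq):
        assert vec(a.aac(a.Peptide("p", seq))).sum() == pytest.approx(1.0, abs=1e-12)


class TestN5C5:
    @pytest.mark.parametrize(
        "seq, frame",
        [
            ("ACDEFGHIKLMNPQ", "ACDEFLMNPQ"),   # 14-mer: clean N5 + C5
            ("ACDEFGHIKL", "ACDEFGHIKL"),       # 10-mer tiles exactly
            ("ACDEFGH", "ACDEFDEFGH"),          # 7-mer: ends overlap
            ("ACD", "ACDACD"),                  # shorter than 5: doubled
        ],
    )
    def test_frame_extraction(self, seq, frame):
        assert a.extract_n5c5(a.Peptide("p", seq)).sequence == frame

    def test_terminal_composition(self):
        v = vec(a.n5c5_features(a.Peptide("p", "KKKKKGGGGGGGGGGLLLLL")))
        assert v[RESIDUE_INDEX["K"]] == pytest.approx(0.5)
        assert v[RESIDUE_INDEX["L"]] == pytest.approx(0.5)

    def test_ten_mer_equals_whole_peptide_aac(self):
        p = a.Peptide("p", "ACDEFGHIKL")
        assert np.allclose(vec(a.n5c5_features(p)), vec(a.aac(p)))

    @settings(derandomize=True, max_examples=50)
    @given(seq=peptide_seq)
    def test_sums_to_one(self, seq):
        assert vec(a.n5c5_features(a.Peptide("p", seq))).sum() == pytest.approx(1.0, abs=1e-12)


class TestPositionalFrequency:
    def test_identical_peptides_give_one_hot_rows(self):
        pset = a.PeptideSet([a.Peptide(f"p{i}", "KLAKLAKKLA") for i in range(4)])
        M = a.positional_frequency(pset)
        assert M.shape == (10, 20)
        assert np.allclose(M.sum(axis=1), 1.0)
        assert set(np.unique(M)) == {0.0, 1.0}

    def test_difference_of_set_with_itself_is_zero(self):
        rng = np.random.default_rng(31)
        pset = random_peptides(rng, 20)
        assert np.allclose(a.positional_difference(pset, pset), 0.0)

    def test_matches_brute_force_tally(self):
        rng = np.random.default_rng(33)
        pset = random_peptides(rng, 100, min_len=5, max_len=50)
        M = a.positional_frequency(pset)
        frames = [a.extract_n5c5(p).sequence for p in pset]
        for i in range(10):
            contributors = [f for f in frames if len(f) > i]
            for j, aa in enumerate(ALPHABET):
                expected = (
                    sum(f[i] == aa for f in contributors) / len(contributors)
                    if contributors
                    else 0.0
                )
                assert M[i, j] == pytest.approx(expected)


class TestKSpace:
    @pytest.mark.parametrize(
        "seq, k, expected_pairs",
        [
            ("KAK", 0, {"KA": 0.5, "AK": 0.5}),
            ("KAK", 1, {"KK": 1.0}),
            ("KKKK", 0, {"KK": 1.0}),
        ],
    )
    def test_known_pair_frequencies(self, seq, k, expected_pairs):
        v = vec(a.kspace_features(a.Peptide("p", seq), k))
        for p, freq in expected_pairs.items():
            assert v[PAIRS.index(p)] == pytest.approx(freq)
        assert v.sum() == pytest.approx(1.0)

    @settings(derandomize=True, max_examples=60)
    @given(seq=peptide_seq, k=st.integers(min_value=0, max_value=6))
    def test_pair_count_is_length_minus_k_minus_one(self, seq, k):
        p = a.Peptide("p", seq)
        v = vec(a.kspace_features(p, k))
        n_pairs = max(len(seq) - k - 1, 0)
        if n_pairs == 0:
            assert np.all(v == 0.0)
        else:
            assert v.sum() == pytest.approx(1.0, abs=1e-12)
            tbl = a.kspace_table(a.PeptideSet([p]), k)
            assert tbl.total_pairs == n_pairs
            assert tbl.counts.sum() == n_pairs

    def test_pair_naming_uses_x_spacers(self):
        assert pair_name(0, "AK") == "AK"
        assert pair_name(3, "KK") == "KXXXK"


class TestTopDifferentialPairs:
    def test_maximally_contrasting_singletons(self):
        pos = a.PeptideSet([a.Peptide(f"p{i}", "KK") for i in range(3)])
        neg = a.PeptideSet([a.Peptide(f"n{i}", "GG") for i in range(3)])
        top = a.top_differential_pairs(pos, neg, k_max=0, n=2)
        assert {name for name, _ in top} == {"KK", "GG"}
        signs = dict(top)
        assert signs["KK"] > 0 and signs["GG"] < 0

    def test_identical_sets_all_zero(self):
        rng = np.random.default_rng(41)
        pset = random_peptides(rng, 10)
        top = a.top_differential_pairs(pset, pset, k_max=1, n=5)
        assert all(d == 0.0 for _, d in top)

    def test_agrees_with_brute_force_enumeration(self):
        rng = np.random.default_rng(43)
        pos = random_peptides(rng, 30, prefix="p")
        neg = random_peptides(rng, 30, prefix="n")
        k_max = 2
        rows = []
        for k in range(k_max + 1):
            fp = a.kspace_table(pos, k).frequencies
            fn = a.kspace_table(neg, k).frequencies
            for j, pr in enumerate(PAIRS):
                rows.append((pair_name(k, pr), fp[j] - fn[j]))
        rows.sort(key=lambda r: (-abs(r[1]), r[0]))
        assert a.top_differential_pairs(pos, neg, k_max, n=10) == [
            (nm, pytest.approx(d)) for nm, d in rows[:10]
        ]


class TestPssm:
    def test_conserved_column_score(self):
        # 5 copies of KKK, uniform background, pseudocount 1:
        # q = 5.05/6, score = log2(q / 0.05)
        aln = a.PeptideSet([a.Peptide(f"p{i}", "KKK") for i in range(5)])
        pssm = a.build_pssm(aln, pseudocount=1.0)
        q = (5 + 1 * 0.05) / 6
        expected = np.log2(q / 0.05)
        k = RESIDUE_INDEX["K"]
        assert pssm.matrix[:, k] == pytest.approx(np.full(3, expected))
        assert expected == pytest.approx(4.073, abs=5e-4)

    def test_background_distributed_alignment_scores_zero(self):
        # one of each residue per column, empirical = uniform background
        seqs = ["".join(ALPHABET[(i + j) % 20] for j in range(4)) for i in range(20)]
        aln = a.PeptideSet([a.Peptide(f"p{i}", s) for i, s in enumerate(seqs)])
        pssm = a.build_pssm(aln, pseudocount=0.0)
        assert np.allclose(pssm.matrix, 0.0, atol=1e-12)

    def test_single_sequence_pseudocount_zero_floors_absent_cells(self):
        aln = a.PeptideSet([a.Peptide("p", "KA")])
        pssm = a.build_pssm(aln, pseudocount=0.0)
        k = RESIDUE_INDEX["K"]
        assert pssm.matrix[0, k] == pytest.approx(np.log2(1 / 0.05))
        off = np.delete(pssm.matrix[0], k)
        assert np.all(off == -10.0)

    def test_unequal_lengths_and_bad_background_rejected(self):
        with pytest.raises(ValueError, match="length"):
            a.build_pssm(a.PeptideSet([a.Peptide("a", "KK"), a.Peptide("b", "KKK")]))
        with pytest.raises(ValueError):
            a.build_pssm(
                a.PeptideSet([a.Peptide("a", "KK")]),
                background=np.r_[0.0, np.full(19, 1 / 19)],
            )


class TestPssmFeatures:
    def test_zero_matrix_gives_zero_vector(self):
        pssm = a.Pssm(np.zeros((10, 20)), a.uniform_background(), 1.0, 1)
        v = vec(a.pssm_features(a.Peptide("p", "KLAKLAKKLA"), pssm))
        assert np.all(v == 0.0)

    def test_identity_like_matrix_marks_present_residues(self):
        seq = "KLAKLAKKLA"
        m = np.zeros((10, 20))
        for i, ch in enumerate(seq):
            m[i, RESIDUE_INDEX[ch]] = 1.0
        pssm = a.Pssm(m, a.uniform_background(), 1.0, 1)
        v = vec(a.pssm_features(a.Peptide("p", seq), pssm)).reshape(20, 20)
        for r in set(seq):
            assert v[RESIDUE_INDEX[r], RESIDUE_INDEX[r]] == pytest.approx(1.0)
        for r in set(ALPHABET) - set(seq):
            assert np.all(v[RESIDUE_INDEX[r]] == 0.0)

    def test_matches_brute_force_accumulation(self):
        rng = np.random.default_rng(47)
        seq = "".join(rng.choice(list(ALPHABET), 10))
        m = rng.normal(size=(10, 20))
        pssm = a.Pssm(m, a.uniform_background(), 1.0, 3)
        v = vec(a.pssm_features(a.Peptide("p", seq), pssm)).reshape(20, 20)
        for r in range(20):
            positions = [i for i, ch in enumerate(seq) if RESIDUE_INDEX[ch] == r]
            if not positions:
                assert np.all(v[r] == 0.0)
            else:
                assert v[r] == pytest.approx(m[positions].mean(axis=0))


class TestHybridAndEncode:
    def test_hybrid_dimensions(self):
        p = a.Peptide("p", "KLAKLAKKLAGG")
        aac_k0 = a.hybridize([a.aac(p), a.kspace_features(p, 0)])
        assert len(aac_k0.values) == 420
        triple = a.hybridize([a.aac(p), a.n5c5_features(p), a.kspace_features(p, 0)])
        assert len(triple.values) == 440
        single = a.hybridize([a.aac(p)])
        assert np.array_equal(single.values, a.aac(p).values)

    def test_mixed_peptides_rejected(self):
        with pytest.raises(a.FeatureMismatchError):
            a.hybridize([a.aac(a.Peptide("p", "KK")), a.aac(a.Peptide("q", "GG"))])

    def test_encode_matches_manual_hybrid(self):
        p = a.Peptide("p", "KLAKLAKKLAGG")
        spec = a.FeatureSpec(("AAC", "N5C5", "KSPACE"), k_values=(0, 1))
        manual = np.concatenate(
            [
                a.aac(p).values,
                a.n5c5_features(p).values,
                a.kspace_features(p, 0).values,
                a.kspace_features(p, 1).values,
            ]
        )
        assert np.array_equal(a.encode(p, spec).values, manual)
        assert len(spec.feature_names) == len(manual)

    def test_encoders_are_pure(self):
        p = a.Peptide("p", "KLAKLAKKLA")
        spec = a.FeatureSpec(("AAC", "KSPACE"), k_values=(0,))
        assert np.array_equal(a.encode(p, spec).values, a.encode(p, spec).values)

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            a.FeatureSpec(("KSPACE",))  # k_values missing
        with pytest.raises(ValueError):
            a.FeatureSpec(("PSSM",))  # pssm missing
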