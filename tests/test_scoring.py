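"""Score-model loading and column homogeneity."""

import numpy as np
import pytest

from varcog.scoring import (
    AMINO_ACIDS,
    SCORED,
    SKIPPED_ALL_GAP,
    SKIPPED_SINGULAR,
    ColumnView,
    DegenerateColumnError,
    FamilyAlignment,
    MatrixFormatError,
    ScoreModel,
    alignment_homogeneity_profile,
    alignment_passes_filter,
    column_consensus,
    column_homogeneity,
    load_background_frequencies,
    load_score_matrix,
)

from oracles import oracle_consensus, oracle_homogeneity


def random_column(rng, n_max=12, gap_prob=0.2):
    n = rng.integers(2, n_max + 1)
    residues = [
        "-" if rng.random() < gap_prob else AMINO_ACIDS[rng.integers(20)]
        for _ in range(n)
    ]
    if sum(r != "-" for r in residues) < 2:  # keep the column scorable
        residues[0], residues[1] = "A", "W"
    return ColumnView(residues=residues, weights=[1.0 / n] * n)


class TestScoreModel:
    def test_builtin_blosum62_values(self, model):
        assert model.score("W", "W") == 11
        assert model.score("A", "A") == 4

    def test_symmetry(self, model):
        assert model.score("D", "K") == model.score("K", "D")
        assert np.array_equal(model.matrix, model.matrix.T)

    def test_ncbi_text_round_trip(self, model, tmp_path):
        from Bio.Align import substitution_matrices

        path = tmp_path / "blosum62.txt"
        path.write_text(str(substitution_matrices.load("BLOSUM62")))
        loaded = load_score_matrix(path)
        assert np.array_equal(loaded.matrix, model.matrix)
        assert loaded.metadata["matrix"] == str(path)

    def test_asymmetric_matrix_rejected(self, model):
        bad = model.matrix.copy()
        bad[0, 1] += 1
        with pytest.raises(MatrixFormatError, match="symmetric"):
            ScoreModel(matrix=bad, background=model.background)

    def test_scaled_frequency_table_normalized_with_warning(self, tmp_path):
        path = tmp_path / "freqs.tsv"
        path.write_text(
            "".join(f"{aa}\t{2.0 / 20}\n" for aa in AMINO_ACIDS)
        )
        with pytest.warns(UserWarning, match="renormaliz"):
            freqs, _ = load_background_frequencies(path)
        assert freqs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_background_positive_and_unit_sum(self, model):
        assert np.all(model.background > 0)
        assert model.background.sum() == pytest.approx(1.0, abs=1e-9)


class TestConsensus:
    def test_invariant_column_self_consensus(self, model):
        col = ColumnView(residues=["A"] * 5, weights=[0.2] * 5)
        c, q_c = column_consensus(col, model)
        assert c == "A"
        assert q_c == model.score("A", "A")

    def test_brute_force_enumeration_oracle(self, model, score_dict, rng):
        for _ in range(200):
            col = random_column(rng)
            c, q_c = column_consensus(col, model)
            oc, oq = oracle_consensus(col.residues, col.weights, score_dict)
            assert c == oc
            assert q_c == pytest.approx(oq, abs=1e-12)

    def test_tie_breaks_alphabetically(self, model):
        # Symmetric two-residue column under a score-matrix symmetry: with a
        # toy matrix where I and L are interchangeable, Q_I == Q_L exactly.
        toy = model.matrix.copy()
        i, l = AMINO_ACIDS.index("I"), AMINO_ACIDS.index("L")
        toy[i, :] = toy[l, :] = (model.matrix[i, :] + model.matrix[l, :]) / 2
        toy[:, i] = toy[:, l] = toy[i, :]
        toy[i, i] = toy[l, l] = toy[i, l]
        toy_model = ScoreModel(matrix=toy, background=model.background)
        col = ColumnView(residues=["I", "L"], weights=[0.5, 0.5])
        c, _ = column_consensus(col, toy_model)
        assert c == "I"  # first of the tied pair in alphabetical order


class TestHomogeneity:
    def test_invariant_column_is_exactly_one(self, model):
        for aa in "WACDY":
            col = ColumnView(residues=[aa] * 8, weights=[1 / 8] * 8)
            assert column_homogeneity(col, model) == 1.0

    def test_clamped_at_zero(self, model):
        # C/W mixtures score poorly against every consensus: Q_c < Q_R here.
        col = ColumnView(
            residues=list("CWCWCWCW"), weights=[1 / 8] * 8
        )
        h = column_homogeneity(col, model)
        oracle = oracle_homogeneity(
            list("CWCWCWCW"), [1 / 8] * 8,
            {a: {b: model.matrix[i, j] for j, b in enumerate(AMINO_ACIDS)}
             for i, a in enumerate(AMINO_ACIDS)},
            {a: model.background[i] for i, a in enumerate(AMINO_ACIDS)},
            clamp=False,
        )
        if oracle <= 0:
            assert h == 0.0
        else:
            assert h == pytest.approx(oracle, abs=1e-12)

    def test_two_residue_column_matches_hand_arithmetic(
        self, model, score_dict, freq_dict
    ):
        col = ColumnView(residues=["D"] * 4 + ["K"] * 4, weights=[1 / 8] * 8)
        h = column_homogeneity(col, model)
        expected = oracle_homogeneity(col.residues, col.weights, score_dict, freq_dict)
        assert h == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("m", [1, 3, 5, 7])
    def test_two_residue_mixtures_vs_oracle(self, model, score_dict, freq_dict, m):
        n = 8
        col = ColumnView(residues=["A"] * m + ["V"] * (n - m), weights=[1 / n] * n)
        assert column_homogeneity(col, model) == pytest.approx(
            oracle_homogeneity(col.residues, col.weights, score_dict, freq_dict),
            abs=1e-12,
        )

    def test_fuzz_bounds_and_oracle(self, model, score_dict, freq_dict, rng):
        for _ in range(300):
            col = random_column(rng)
            h = column_homogeneity(col, model)
            assert 0.0 <= h <= 1.0
            expected = oracle_homogeneity(
                col.residues, col.weights, score_dict, freq_dict
            )
            assert h == pytest.approx(expected, abs=1e-12)
            unclamped = oracle_homogeneity(
                col.residues, col.weights, score_dict, freq_dict, clamp=False
            )
            assert unclamped <= 1.0 + 1e-12

    def test_row_permutation_invariance(self, model, rng):
        col = random_column(rng)
        h = column_homogeneity(col, model)
        perm = rng.permutation(len(col.residues))
        col2 = ColumnView(
            residues=[col.residues[i] for i in perm],
            weights=[col.weights[i] for i in perm],
        )
        assert column_homogeneity(col2, model) == pytest.approx(h, abs=1e-14)

    def test_row_duplication_invariance(self, model, rng):
        col = random_column(rng)
        h = column_homogeneity(col, model)
        doubled = ColumnView(
            residues=list(col.residues) * 2,
            weights=[w / 2 for w in col.weights] * 2,
        )
        assert column_homogeneity(doubled, model) == pytest.approx(h, abs=1e-12)

    def test_all_gap_column_raises(self, model):
        col = ColumnView(residues=["-", "-"], weights=[0.5, 0.5])
        with pytest.raises(DegenerateColumnError):
            column_homogeneity(col, model)

    def test_ambiguous_residues_treated_as_gaps(self, model):
        plain = ColumnView(residues=["A", "A", "V"], weights=[1 / 3] * 3)
        with_x = ColumnView(residues=["A", "A", "V", "X"], weights=[1 / 4] * 4)
        assert column_homogeneity(with_x, model) == pytest.approx(
            column_homogeneity(plain, model), abs=1e-12
        )


def make_alignment(seqs, family_id="fam"):
    return FamilyAlignment(
        family_id=family_id,
        rows=[(f"s{i}", f"g{i}", s) for i, s in enumerate(seqs)],
    )


class TestFilter:
    def test_duplicates_collapse(self):
        aln = make_alignment(["ACDEF" * 20] * 8)
        ok, n_seq, _ = alignment_passes_filter(aln)
        assert n_seq == 1
        assert not ok

    def test_seven_distinct_sequences_fail(self, rng):
        seqs = [
            "".join(rng.choice(list(AMINO_ACIDS), 100)) for _ in range(7)
        ]
        ok, n_seq, n_col = alignment_passes_filter(make_alignment(seqs))
        assert n_seq == 7
        assert n_col == 100
        assert not ok

    def test_ten_distinct_sequences_pass(self, rng):
        seqs = ["".join(rng.choice(list(AMINO_ACIDS), 100)) for _ in range(10)]
        ok, _, _ = alignment_passes_filter(make_alignment(seqs))
        assert ok

    def test_singular_insertion_columns_not_informative(self):
        # Column 0 has residues from one sequence only -> excluded.
        seqs = ["A" + "CDEF" * 15, "-" + "CDEF" * 15] + [
            "-" + "CDEV" * 15,
            "-" + "CDEW" * 15,
        ]
        _, _, n_col = alignment_passes_filter(make_alignment(seqs))
        assert n_col == 60

    def test_gap_only_sequences_dedup_on_ungapped_string(self):
        aln = make_alignment(["AC-DE", "ACD-E"])  # same ungapped string
        _, n_seq, _ = alignment_passes_filter(aln)
        assert n_seq == 1


class TestProfile:
    def test_identical_sequences_give_all_ones(self):
        aln = make_alignment(["ACDEFGHIKL"] * 8)
        profile = alignment_homogeneity_profile(
            aln, model=load_score_matrix(), require_filter=False
        )
        assert np.all(profile.scored == 1.0)
        assert all(m == SCORED for m in profile.column_mask)

    def test_singular_and_all_gap_columns_masked(self, model):
        aln = make_alignment(["A-C", "A--", "A--"])
        profile = alignment_homogeneity_profile(aln, model, require_filter=False)
        assert profile.column_mask == [SCORED, SKIPPED_ALL_GAP, SKIPPED_SINGULAR]
        assert np.isnan(profile.h[1]) and np.isnan(profile.h[2])

    def test_filter_enforced_unless_overridden(self, model):
        aln = make_alignment(["ACDEF"] * 8)
        with pytest.raises(ValueError, match="inclusion filter"):
            alignment_homogeneity_profile(aln, model)

    def test_external_weights_must_sum_to_one(self, model):
        aln = make_alignment(["ACDEF", "ACDEW"])
        with pytest.raises(ValueError, match="sum to 1"):
            alignment_homogeneity_profile(
                aln, model, weights=[0.9, 0.9], require_filter=False
            )
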