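"""k-mer featurization: extraction, vocabulary, frequencies, scaling, PCA."""

import numpy as np
import pytest
import scipy.linalg
from hypothesis import given, settings
from hypothesis import strategies as st

from mgfdta.errors import EmptyInputError, InvalidParameterError
from mgfdta.kmer import (ProteinKmerFeaturizer, apply_scaler, build_vocabulary,
                         extract_kmers, fit_pca, fit_scaler, frequency_matrix,
                         frequency_vector, project)

CORPUS = ["MATSK", "MATTE", "CATSE"]


@pytest.mark.parametrize("seq,k,expected", [
    ("MATSK", 3, ["MAT", "ATS", "TSK"]),
    ("CATSE", 3, ["CAT", "ATS", "TSE"]),
    ("MATTE", 3, ["MAT", "ATT", "TTE"]),
    ("AB", 3, []),
    ("AAAA", 3, ["AAA", "AAA"]),
    ("ACD", 1, ["A", "C", "D"]),
])
def test_sliding_window_extraction(seq, k, expected):
    assert extract_kmers(seq, k) == expected


def test_extraction_rejects_nonpositive_window():
    with pytest.raises(InvalidParameterError):
        extract_kmers("MATSK", 0)


@given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", max_size=40),
       st.integers(1, 5))
@settings(max_examples=100, deadline=None)
def test_extraction_count_and_reconstruction(seq, k):
    frags = extract_kmers(seq, k)
    assert len(frags) == max(0, len(seq) - k + 1)
    if frags:
        assert "".join(f[0] for f in frags[:-1]) + frags[-1] == seq


class TestVocabulary:
    def test_three_sequence_corpus_retains_seven_kmers(self):
        vocab = build_vocabulary(CORPUS, 3, 7)
        assert vocab.kmers == ("MAT", "ATS", "TSK", "ATT", "TTE", "CAT", "TSE")
        assert len(vocab) == 7

    def test_single_repeated_kmer(self):
        vocab = build_vocabulary(["AAAA"], 3, 10)
        assert vocab.kmers == ("AAA",)

    def test_cap_keeps_most_frequent_with_first_occurrence_ties(self):
        # MAT occurs twice (brute-force count); all others once
        vocab = build_vocabulary(CORPUS, 3, 2)
        assert vocab.kmers[0] == "MAT"
        assert vocab.kmers[1] == "ATS"  # first once-occurring k-mer seen
        assert len(vocab) == 2

    def test_empty_corpus_rejected(self):
        with pytest.raises(EmptyInputError):
            build_vocabulary(["AB"], 3, 5)

    def test_determinism(self):
        a = build_vocabulary(CORPUS, 3, 7)
        b = build_vocabulary(list(CORPUS), 3, 7)
        assert a.kmers == b.kmers


class TestFrequencyVectors:
    def test_printed_vectors_at_three_decimals(self):
        vocab = build_vocabulary(CORPUS, 3, 7)
        np.testing.assert_array_almost_equal(
            frequency_vector("MATSK", vocab),
            [0.333, 0.333, 0.333, 0, 0, 0, 0], decimal=3)
        np.testing.assert_array_almost_equal(
            frequency_vector("MATTE", vocab),
            [0.333, 0, 0, 0.333, 0.333, 0, 0], decimal=3)
        np.testing.assert_array_almost_equal(
            frequency_vector("CATSE", vocab),
            [0, 0.333, 0, 0, 0, 0.333, 0.333], decimal=3)

    def test_short_sequence_gives_zero_vector(self):
        vocab = build_vocabulary(CORPUS, 3, 7)
        assert frequency_vector("QQ", vocab).sum() == 0.0

    def test_row_sum_bounded_by_in_vocabulary_share(self):
        vocab = build_vocabulary(CORPUS, 3, 2)
        v = frequency_vector("MATSK", vocab)  # MAT, ATS in vocab; TSK not
        assert np.isclose(v.sum(), 2 / 3)
        assert np.all((0 <= v) & (v <= 1))

    def test_relative_frequencies_remove_length_bias(self):
        # duplicating every sequence of the corpus leaves each row unchanged:
        # relative frequencies do not depend on corpus composition or length
        vocab = build_vocabulary(CORPUS, 3, 7)
        m1 = frequency_matrix(CORPUS, vocab)
        m2 = frequency_matrix(CORPUS + CORPUS, vocab)
        np.testing.assert_allclose(m2[: len(CORPUS)], m1)
        np.testing.assert_allclose(m2[len(CORPUS):], m1)


class TestScaler:
    def test_two_point_column_standardizes_to_unit_values(self):
        scaler = fit_scaler(np.array([[0.2], [0.4]]))
        z = apply_scaler(np.array([[0.2], [0.4]]), scaler)
        np.testing.assert_allclose(z[:, 0], [-1, 1])
        assert np.isclose(scaler.stds[0], 0.1, atol=1e-12)

    def test_constant_column_maps_to_zero(self):
        mat = np.full((3, 1), 0.3)
        z = apply_scaler(mat, fit_scaler(mat))
        np.testing.assert_array_equal(z, np.zeros((3, 1)))

    def test_fitted_columns_have_zero_mean(self, rng):
        mat = rng.random((12, 5))
        z = apply_scaler(mat, fit_scaler(mat))
        np.testing.assert_allclose(z.mean(axis=0), 0, atol=1e-9)

    def test_idempotent_on_standardized_data(self, rng):
        mat = rng.standard_normal((10, 4))
        z = apply_scaler(mat, fit_scaler(mat))
        z2 = apply_scaler(z, fit_scaler(z))
        np.testing.assert_allclose(z2, z, atol=1e-9)

    def test_single_row_warns_and_forces_unit_std(self):
        with pytest.warns(UserWarning):
            scaler = fit_scaler(np.array([[1.0, 2.0]]))
        np.testing.assert_array_equal(scaler.stds, [1, 1])


class TestPCA:
    def test_matches_dense_covariance_eigendecomposition(self, rng):
        """Oracle: eigh of C = Z'Z/(n-1), compared up to sign."""
        for _ in range(5):
            n, p = int(rng.integers(8, 20)), int(rng.integers(3, 15))
            mat = rng.standard_normal((n, p))
            z = apply_scaler(mat, fit_scaler(mat))
            proj = fit_pca(z, out_dim=min(n - 1, p))
            cov = z.T @ z / (n - 1)
            evals, evecs = scipy.linalg.eigh(cov)
            evals, evecs = evals[::-1], evecs[:, ::-1]
            np.testing.assert_allclose(proj.eigenvalues,
                                       evals[: proj.out_dim], atol=1e-6)
            for j in range(proj.out_dim):
                dot = abs(evecs[:, j] @ proj.components[:, j])
                assert dot == pytest.approx(1.0, abs=1e-6)

    def test_projected_column_variance_equals_eigenvalue(self, rng):
        mat = rng.standard_normal((15, 6))
        z = apply_scaler(mat, fit_scaler(mat))
        proj = fit_pca(z, out_dim=4)
        reduced = project(z, proj)
        np.testing.assert_allclose(reduced.var(axis=0, ddof=1),
                                   proj.eigenvalues[:4], atol=1e-6)

    def test_rank_one_data_keeps_all_variance_in_first_component(self):
        t = np.linspace(-1, 1, 9)
        z = np.column_stack([t, t])  # points on the line y = x
        proj = fit_pca(z, out_dim=1)
        full = fit_pca(z, out_dim=2)
        assert full.eigenvalues[1] == pytest.approx(0, abs=1e-12)
        reduced = project(z, proj)
        # total variance of both columns ends up in the single component
        assert np.var(reduced, ddof=1) == pytest.approx(
            2 * np.var(t, ddof=1), rel=1e-9)

    def test_full_rank_reconstruction(self, rng):
        mat = rng.standard_normal((20, 5))
        z = apply_scaler(mat, fit_scaler(mat))
        proj = fit_pca(z, out_dim=5)
        recon = project(z, proj) @ proj.components.T
        np.testing.assert_allclose(recon, z, atol=1e-8)

    def test_out_dim_clamped_with_warning(self, rng):
        z = rng.standard_normal((5, 3))
        with pytest.warns(UserWarning):
            proj = fit_pca(z, out_dim=10)
        assert proj.out_dim == 3

    def test_sign_convention(self, rng):
        z = rng.standard_normal((10, 6))
        proj = fit_pca(z, out_dim=4)
        for j in range(4):
            col = proj.components[:, j]
            assert col[np.abs(col).argmax()] > 0


def test_pipeline_determinism_and_roundtrip(tmp_path, rng):
    seqs = ["".join(rng.choice(list("ACDEFGHIK"), 30)) for _ in range(12)]
    a = ProteinKmerFeaturizer(k=3, vocab_size=100, pca_dim=5).fit(seqs)
    b = ProteinKmerFeaturizer(k=3, vocab_size=100, pca_dim=5).fit(seqs)
    assert a.vocab.kmers == b.vocab.kmers
    np.testing.assert_array_equal(a.transform(seqs), b.transform(seqs))

    a.save(tmp_path / "arc.npz")
    c = ProteinKmerFeaturizer.load(tmp_path / "arc.npz")
    np.testing.assert_array_equal(c.transform(seqs), a.transform(seqs))
    assert c.provenance["fitted_on"] == "train"
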