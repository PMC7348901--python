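"""Projector construction and null-space source recovery."""

import numpy as np
import pytest
from scipy.linalg import subspace_angles

from nsfecg.errors import (
    DegenerateInputError,
    DimensionalityError,
    NumericalRankError,
    ParameterError,
)
from nsfecg.nsitm import ItmResult, compute_itm, label_sources, null_space_extract
from nsfecg.preprocess import denoise
from nsfecg.synth import MixtureSpec, build_mixture, fetal_spec, generate_source, maternal_spec


def _eig_oracle_nullspace(W: np.ndarray, rtol: float = 1e-6) -> np.ndarray:
    """Brute-force oracle: eigenvectors of W with eigenvalue ~ 1 (columns)."""
    evals, evecs = np.linalg.eigh(W)
    return evecs[:, np.abs(evals - 1.0) < rtol]


class TestComputeItm:
    def test_hand_rank_one_projector(self):
        x = np.array([[1.0, -1.0, 0.0, 0.0]])
        itm = compute_itm(x)
        expected = x.T @ x / 2.0
        np.testing.assert_allclose(itm.W, expected, atol=1e-9)
        np.testing.assert_allclose(itm.W @ itm.W, itm.W, atol=1e-12)
        assert abs(np.trace(itm.W) - 1.0) < 1e-9

    def test_trace_equals_channel_count(self, rng):
        Xp = rng.standard_normal((3, 50))
        itm = compute_itm(Xp)
        assert abs(np.trace(itm.W) - 3.0) < 1e-8

    def test_orthonormal_rows_give_gram_projector(self):
        # zero-mean orthonormal rows => Cx = I/N cancels the 1/N: W = Xp' Xp
        raw = np.random.default_rng(5).standard_normal((40, 2))
        q, _ = np.linalg.qr(raw - raw.mean(axis=0))
        Xp = q.T
        itm = compute_itm(Xp)
        np.testing.assert_allclose(itm.W, Xp.T @ Xp, atol=1e-9)

    def test_symmetry_and_eigenvalue_split(self, rng):
        Xp = rng.standard_normal((4, 120))
        itm = compute_itm(Xp)
        assert np.linalg.norm(itm.W - itm.W.T) < 1e-10
        evals = np.linalg.eigvalsh(itm.W)
        near_one = np.sum(np.abs(evals - 1.0) < 1e-6)
        near_zero = np.sum(np.abs(evals) < 1e-6)
        assert near_one == 4 and near_zero == 120 - 4

    def test_q_singular_values_are_zero_or_one(self, rng):
        Xp = rng.standard_normal((3, 80))
        itm = compute_itm(Xp)
        sv = np.sort(np.linalg.svd(itm.Q, compute_uv=False))
        assert np.allclose(sv[:3], 0.0, atol=1e-7)
        assert np.allclose(sv[3:], 1.0, atol=1e-7)
        np.testing.assert_allclose(
            np.sort(itm.singular_values), sv, atol=1e-7
        )

    def test_zero_data_raises_with_condition_number(self):
        with pytest.raises(NumericalRankError) as err:
            compute_itm(np.zeros((2, 50)))
        assert err.value.condition_number == np.inf

    def test_rank_deficient_data_truncates_to_numerical_rank(self):
        # duplicated channel: rank 1 of 2 -> projector of trace 1
        base = np.sin(np.linspace(0, 20, 80))
        itm = compute_itm(np.vstack([base, 2.0 * base]))
        assert itm.nullspace_dim == 1
        assert abs(np.trace(itm.W) - 1.0) < 1e-8
        np.testing.assert_allclose(itm.W @ itm.W, itm.W, atol=1e-10)

    def test_memory_guard_on_large_n(self):
        with pytest.raises(ParameterError, match="window"):
            compute_itm(np.zeros((2, 20001)))


class TestNullSpaceExtract:
    def test_matches_eigendecomposition_oracle(self, rng):
        for _ in range(5):
            m = int(rng.integers(2, 6))
            n = int(rng.integers(50, 200))
            Xp = rng.standard_normal((m, n))
            itm = compute_itm(Xp)
            Y = null_space_extract(itm, itm.nullspace_dim).Y
            oracle = _eig_oracle_nullspace(itm.W)
            angles = subspace_angles(Y.T, oracle)
            assert np.max(angles) < 1e-6

    def test_full_null_space_is_orthonormal_and_annihilated(self, rng):
        Xp = rng.standard_normal((4, 100))
        itm = compute_itm(Xp)
        src = null_space_extract(itm, itm.nullspace_dim)
        np.testing.assert_allclose(src.Y @ src.Y.T, np.eye(4), atol=1e-8)
        assert np.linalg.norm(itm.Q @ src.Y.T) < 1e-6

    def test_orthogonal_rows_recovered_as_same_plane(self):
        raw = np.random.default_rng(2).standard_normal((60, 2))
        q, _ = np.linalg.qr(raw - raw.mean(axis=0))  # zero-mean orthonormal cols
        Xp = (q * [2.0, 1.0]).T   # two orthogonal rows, distinct power
        itm = compute_itm(Xp)
        Y = null_space_extract(itm, 2).Y
        assert np.max(subspace_angles(Y.T, Xp.T)) < 1e-8

    def test_svd_native_spans_same_nullspace(self, rng):
        Xp = rng.standard_normal((3, 60))
        itm = compute_itm(Xp)
        a = null_space_extract(itm, 3, order_by="xp_spectrum").Y
        b = null_space_extract(itm, 3, order_by="svd_native").Y
        assert np.max(subspace_angles(a.T, b.T)) < 1e-6

    def test_noiseless_mixture_recovers_both_sources(self):
        mecg = generate_source(maternal_spec(seed=21))
        fecg = 0.3 * generate_source(fetal_spec(seed=22))
        S = np.vstack([mecg, fecg])
        A = np.array([[1.0, 0.4], [0.8, -0.5], [-0.6, 0.7], [1.2, 0.1]])
        rec = build_mixture(S, MixtureSpec(A=A), fs=250)
        Xp = denoise(rec).X
        Y = null_space_extract(compute_itm(Xp), 2).Y
        for s in S:
            best = max(abs(np.corrcoef(y, s)[0, 1]) for y in Y)
            assert best >= 0.95

    def test_requested_dimension_bounds(self, rng):
        itm = compute_itm(rng.standard_normal((2, 50)))
        with pytest.raises(DimensionalityError):
            null_space_extract(itm, 3)

    def test_degenerate_identity_projector_rejected(self):
        n = 10
        itm = ItmResult(
            W=np.eye(n),
            singular_values=np.zeros(n),
            Vq=np.eye(n),
            nullspace_dim=n,
        )
        with pytest.raises(DegenerateInputError):
            null_space_extract(itm, 2)


class TestLabelSources:
    def test_rate_rule_assigns_fetal_to_faster_row(self):
        mecg = generate_source(maternal_spec(seed=1))
        fecg = generate_source(fetal_spec(seed=2))
        from nsfecg.nsitm import ExtractedSources

        src = ExtractedSources(
            Y=np.vstack([mecg, fecg]) / np.linalg.norm([mecg, fecg], axis=1, keepdims=True),
            labels=["unassigned", "unassigned"],
        )
        labelled = label_sources(src, 250.0)
        assert labelled.labels == ["mecg", "fecg_raw"]
        assert labelled.rates_bpm[1] > labelled.rates_bpm[0]

    def test_single_row_rejected(self):
        from nsfecg.nsitm import ExtractedSources

        src = ExtractedSources(Y=np.ones((1, 500)), labels=["unassigned"])
        with pytest.raises(ParameterError):
            label_sources(src, 250.0)

    def test_end_to_end_labels_match_truth(self, noisy_record):
        Xp = denoise(noisy_record).X
        src = label_sources(null_space_extract(compute_itm(Xp), 2), noisy_record.fs)
        mecg, fecg = noisy_record.truth.S
        assert abs(np.corrcoef(src.row("fecg_raw"), fecg)[0, 1]) > abs(
            np.corrcoef(src.row("fecg_raw"), mecg)[0, 1]
        )
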