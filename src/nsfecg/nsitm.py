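"""Null-space idempotent-transformation-matrix (NSITM) source recovery.

The separation operator is the N x N orthogonal projector W onto the row
space of the preprocessed data Xp,

    W = (1/N) Xp' Cx^{-1} Xp,      Cx = (1/N) Xp Xp',

optionally ridge-regularised.  Because the true source waveforms satisfy
Y = Y W (each sample of a source is reproduced by the projector), they lie
in the null space of Q = W - I_N, which equals W's eigenvalue-1 eigenspace,
i.e. exactly the row space of Xp.  The recovered waveforms are an
orthonormal basis of an L-dimensional subspace of null(Q), read off the
right-singular-vector matrix of Q.

With the singular values of Q sorted strictly descending, the null-space
directions occupy the last columns of Vq, internally ordered by ascending
data variance - so the last L columns are the L dominant-variance
directions (maternal first from the end, then the weaker fetal component).
This is the default ``order_by="xp_spectrum"`` rule; ``"svd_native"`` runs a
full SVD of Q instead (O(N^3), intended for small-N cross-checks), taking
the last L columns of whatever basis LAPACK returns for the degenerate
null space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    DegenerateInputError,
    DimensionalityError,
    LabelingError,
    NumericalRankError,
    ParameterError,
)

__all__ = ["ItmResult", "ExtractedSources", "compute_itm", "null_space_extract", "label_sources"]

#: refuse to form W above this many samples (W is N x N dense)
MAX_SAMPLES = 20000


@dataclass
class ItmResult:
    """The projector W with the SVD structure of Q = W - I_N.

    ``singular_values`` holds all N singular values of Q descending;
    ``Vq`` the matching right-singular vectors (columns).  The null space of
    Q occupies the last ``nullspace_dim`` columns, ordered by ascending
    variance of the data restricted to each direction.
    """

    W: np.ndarray
    singular_values: np.ndarray
    Vq: np.ndarray
    nullspace_dim: int
    xp_singular_values: np.ndarray = field(default=None)  # type: ignore[assignment]
    condition_number: float = 1.0

    @property
    def Q(self) -> np.ndarray:
        """Separation matrix Q = W - I_N (materialised on demand)."""
        return self.W - np.eye(self.W.shape[0])

    @property
    def n_samples(self) -> int:
        return self.W.shape[0]

    def idempotency_error(self) -> float:
        """Frobenius norm of W@W - W, computed through the low-rank factors."""
        B = self.Vq[:, self.n_samples - self.nullspace_dim :]
        f = 1.0 - self.singular_values[self.n_samples - self.nullspace_dim :]
        # W = B F B' with B orthonormal => ||W^2 - W||_F = ||F G F - F||_F,
        # G = B'B (identity up to rounding)
        F = np.diag(f)
        G = B.T @ B
        return float(np.linalg.norm(F @ G @ F - F))


@dataclass
class ExtractedSources:
    """L recovered unit-norm waveforms with role labels.

    ``basis_indices`` records which columns of Vq each row was taken from.
    """

    Y: np.ndarray
    labels: list[str]
    basis_indices: list[int] = field(default_factory=list)
    rates_bpm: list[float] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def n_sources(self) -> int:
        return self.Y.shape[0]

    def row(self, label: str) -> np.ndarray:
        for i, lab in enumerate(self.labels):
            if lab == label:
                return self.Y[i]
        raise KeyError(f"no source labelled {label!r}")


def compute_itm(
    Xp: np.ndarray,
    ridge_scale: float = 1e-10,
    rank_rtol: float = 1e-8,
) -> ItmResult:
    """Build the idempotent transformation matrix from preprocessed data.

    ``Xp`` is M x N with zero-mean rows (re-centred here if not).  The ridge
    term lambda = ridge_scale * trace(Cx)/M guards near-singular Cx, and
    directions whose singular value falls below ``rank_rtol`` times the
    largest are truncated: the projector then spans the numerical row space
    only (rank-deficient data, e.g. a noiseless mixture of L < M sources,
    is the normal case, not an error).  A matrix with no usable direction
    at all raises :class:`NumericalRankError`.
    """
    Xp = np.atleast_2d(np.asarray(Xp, dtype=float))
    m, n = Xp.shape
    if n <= m:
        raise ParameterError(f"need N > M, got Xp of shape {m}x{n}")
    if n > MAX_SAMPLES:
        raise ParameterError(
            f"N={n} exceeds the {MAX_SAMPLES}-sample guard for the dense N x N "
            "projector; process the record in windows"
        )
    Xp = Xp - Xp.mean(axis=1, keepdims=True)
    # Economy SVD of the data; Cx = U diag(sv^2/N) U'.
    _, sv, Vt = np.linalg.svd(Xp, full_matrices=False)
    if sv[0] == 0.0:
        raise NumericalRankError(
            "Xp is identically zero: the covariance is singular beyond "
            "regularization",
            condition_number=np.inf,
        )
    rank = int(np.sum(sv > rank_rtol * sv[0]))
    cond = (sv[0] / sv[rank - 1]) ** 2
    sv_r = sv[:rank]
    s = sv_r**2 / n                    # retained eigenvalues of Cx
    lam = ridge_scale * s.sum() / m
    f = s / (s + lam)                  # shrinkage of each row-space direction
    V1 = Vt.T[:, :rank]                # N x rank, columns by descending data variance
    W = (V1 * f) @ V1.T
    # Q = W - I has singular value 1 on the orthogonal complement
    # (mult N-rank) and 1 - f_i ~ 0 on the row-space directions.  Descending
    # order puts the complement first and the row space last, ascending in
    # data variance.
    sigma_q = np.concatenate([np.ones(n - rank), (1.0 - f)[::-1]])
    complement = np.linalg.qr(V1, mode="complete")[0][:, rank:]
    Vq = np.concatenate([complement, V1[:, ::-1]], axis=1)
    null_dim = int(np.sum(sigma_q <= max(rank_rtol, np.max(1.0 - f) * (1 + 1e-12))))
    return ItmResult(
        W=W,
        singular_values=sigma_q,
        Vq=Vq,
        nullspace_dim=null_dim,
        xp_singular_values=sv_r,
        condition_number=float(cond),
    )


def null_space_extract(
    itm: ItmResult, L: int, order_by: str = "xp_spectrum"
) -> ExtractedSources:
    """Recover L unit-norm waveforms from the null space of Q.

    ``order_by="xp_spectrum"`` takes the last L columns of the deterministic
    Vq built by :func:`compute_itm` (the L dominant data-variance directions
    of the null space); ``"svd_native"`` recomputes a full SVD of Q and takes
    the last L right-singular vectors as returned by LAPACK.
    """
    n = itm.n_samples
    if itm.nullspace_dim >= n:
        raise DegenerateInputError(
            "W is (numerically) the identity: the null space of Q is the whole "
            "space and carries no separation information"
        )
    if L < 1 or L > itm.nullspace_dim:
        raise DimensionalityError(
            f"requested L={L} sources but the null space has dimension "
            f"{itm.nullspace_dim}"
        )
    if order_by == "xp_spectrum":
        cols = list(range(n - L, n))
        basis = itm.Vq[:, cols]
        # row 0 = dominant-variance direction (the maternal component on
        # typical abdominal mixtures), then progressively weaker directions
        Y = basis.T[::-1]
        indices = cols[::-1]
    elif order_by == "svd_native":
        _, _, Vt = np.linalg.svd(itm.Q)
        Y = Vt[n - L :][::-1]
        indices = list(range(n - 1, n - L - 1, -1))
    else:
        raise ParameterError(f"unknown order_by rule {order_by!r}")
    Y = Y / np.linalg.norm(Y, axis=1, keepdims=True)
    return ExtractedSources(
        Y=np.ascontiguousarray(Y),
        labels=["unassigned"] * L,
        basis_indices=list(indices),
    )


def _dominant_frequency(x: np.ndarray, fs: float) -> float:
    spec = np.abs(np.fft.rfft(x - x.mean())) ** 2
    freqs = np.fft.rfftfreq(len(x), d=1.0 / fs)
    spec[0] = 0.0
    return float(freqs[int(np.argmax(spec))])


def label_sources(sources: ExtractedSources, fs: float) -> ExtractedSources:
    """Assign fecg_raw/mecg labels by estimated beat rate.

    The fetal heart beats faster than the maternal heart, so the row with the
    highest estimated rate is labelled ``fecg_raw`` and the remaining rows
    ``mecg``.  Near-ties are broken by dominant spectral frequency.  Requires
    at least two rows.
    """
    from .peaks import heart_rates, pan_tompkins  # deferred: peaks imports nothing back

    if sources.n_sources < 2:
        raise ParameterError("label_sources needs at least 2 extracted rows")
    rates = []
    for row in sources.Y:
        try:
            idx = pan_tompkins(row, fs, mode="fetal")
            rates.append(heart_rates(idx, fs).mean_rate_bpm if len(idx) >= 2 else np.nan)
        except Exception:
            rates.append(np.nan)
    rates = np.asarray(rates, dtype=float)
    if np.all(np.isnan(rates)):
        raise LabelingError("rate estimation failed on every extracted row")
    order = np.argsort(np.nan_to_num(rates, nan=-1.0))
    top, runner = order[-1], order[-2]
    if (
        np.isfinite(rates[top])
        and np.isfinite(rates[runner])
        and abs(rates[top] - rates[runner]) < 0.5
    ):
        # spectral tie-break: the fetal trace has the higher dominant frequency
        if _dominant_frequency(sources.Y[runner], fs) > _dominant_frequency(
            sources.Y[top], fs
        ):
            top = runner
    labels = ["mecg"] * sources.n_sources
    labels[int(top)] = "fecg_raw"
    sources.labels = labels
    sources.rates_bpm = [float(r) for r in rates]
    return sources
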