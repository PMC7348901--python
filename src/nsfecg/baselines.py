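"""Comparison extractors: PCA whitening, FastICA, and the parallel
linear-predictor (PLP) filter.

All three return :class:`~nsfecg.nsitm.ExtractedSources` with unit-norm
rows, so the evaluation harness treats every method identically.

PCA recovers uncorrelated components from the whitening transform
Cx^{-1/2} Xp; the L dominant-variance components are returned by default
(on abdominal mixtures the maternal and fetal subspace carries the most
variance, while the minor components are noise).

FastICA maximises non-Gaussianity of the whitened components
(scikit-learn's fixed-point implementation, log-cosh contrast, symmetric
decorrelation).  Gaussian-only inputs are non-identifiable; they are
detected by near-zero excess kurtosis and flagged, with components still
returned.

PLP extracts temporally predictable sources from the whitened data Z: each
predictor vector y_m = w_m' Z is driven by gradient descent on its one-step
linear prediction error E_r(n) = y_m(n) - c y_m(n-1) (the AR(1) coefficient
c is refit every iteration), with deflation across the L predictors so they
converge to distinct sources.  The relative (natural) gradient step keeps
mu_y dimensionless.  The most predictable (smoothest) source - the maternal
ECG on abdominal mixtures - is extracted first.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import kurtosis
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .errors import DivergenceError, NumericalRankError, ParameterError
from .nsitm import ExtractedSources

__all__ = ["PlpConfig", "pca_extract", "fastica_extract", "plp_extract", "whiten"]


def whiten(Xp: np.ndarray, rank_rtol: float = 1e-10) -> np.ndarray:
    """Whitened rows Z = Cx^{-1/2} Xp with zero-variance directions dropped.

    Rows of Z are uncorrelated with unit sample variance, ordered by
    descending variance of the underlying principal direction.
    """
    Xp = np.atleast_2d(np.asarray(Xp, dtype=float))
    Xp = Xp - Xp.mean(axis=1, keepdims=True)
    n = Xp.shape[1]
    Cx = Xp @ Xp.T / n
    evals, evecs = np.linalg.eigh(Cx)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if evals[0] <= 0:
        raise NumericalRankError("covariance matrix has no positive eigenvalues")
    keep = evals > rank_rtol * evals[0]
    return (evecs[:, keep] / np.sqrt(evals[keep])).T @ Xp


def _unit_rows(Y: np.ndarray) -> np.ndarray:
    return Y / np.linalg.norm(Y, axis=1, keepdims=True)


def pca_extract(Xp: np.ndarray, L: int, select: str = "major") -> ExtractedSources:
    """L whitened principal components of Xp (mutually uncorrelated rows).

    ``select="major"`` returns the dominant-variance components (default),
    ``"minor"`` the smallest-variance ones.
    """
    Z = whiten(Xp)
    if L < 1 or L > Z.shape[0]:
        raise NumericalRankError(
            f"requested L={L} components but the whitened data has rank {Z.shape[0]}"
        )
    rows = Z[:L] if select == "major" else Z[-L:]
    if select not in ("major", "minor"):
        raise ParameterError(f"select must be 'major' or 'minor', got {select!r}")
    return ExtractedSources(
        Y=_unit_rows(rows.copy()),
        labels=["unassigned"] * L,
        basis_indices=list(range(L)) if select == "major" else list(range(Z.shape[0] - L, Z.shape[0])),
    )


def fastica_extract(Xp: np.ndarray, L: int, seed: int = 0) -> ExtractedSources:
    """L independent components via fixed-point ICA (log-cosh contrast)."""
    Xp = np.atleast_2d(np.asarray(Xp, dtype=float))
    flags: list[str] = []
    # identifiability: ICA needs at most one Gaussian source
    Z = whiten(Xp)
    if np.all(np.abs(kurtosis(Z, axis=1)) < 0.1):
        flags.append("inputs look Gaussian: independent components are not identifiable")
    ica = FastICA(
        n_components=L,
        fun="logcosh",
        max_iter=200,
        tol=1e-6,
        whiten="unit-variance",
        random_state=seed,
    )
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        Y = ica.fit_transform(Xp.T).T
    for w in caught:
        if issubclass(w.category, ConvergenceWarning):
            flags.append("FastICA did not converge in 200 iterations; best iterate returned")
    return ExtractedSources(
        Y=_unit_rows(Y),
        labels=["unassigned"] * L,
        basis_indices=list(range(L)),
        warnings=flags,
    )


@dataclass(frozen=True)
class PlpConfig:
    """Gradient-descent settings of the PLP extractor."""

    mu_y: float = 0.01
    max_iters: int = 500
    tol: float = 1e-8
    seed: int = 0
    init: str = "random"  # "random" | "canonical" (m-th whitened channel)

    def validate(self) -> None:
        if self.mu_y < 0:
            raise ParameterError(f"mu_y must be >= 0, got {self.mu_y}")
        if self.max_iters < 1:
            raise ParameterError(f"max_iters must be >= 1, got {self.max_iters}")
        if self.init not in ("random", "canonical"):
            raise ParameterError(f"init must be 'random' or 'canonical', got {self.init}")


def _prediction_error(y: np.ndarray) -> tuple[np.ndarray, float]:
    """One-step AR(1) prediction error of y and the fitted coefficient."""
    denom = float(y @ y)
    c = float(y[1:] @ y[:-1]) / denom if denom > 0 else 0.0
    e = y.copy()
    e[1:] -= c * y[:-1]
    e[0] = 0.0
    return e, c


def plp_extract(Xp: np.ndarray, L: int, config: PlpConfig | None = None) -> ExtractedSources:
    """Extract L temporally predictable sources by parallel linear prediction.

    Each predictor minimises its one-step prediction error over unit-norm
    combinations of the whitened channels; deflation keeps the L predictors
    mutually orthogonal in the whitened space.  Raises
    :class:`DivergenceError` when the objective grows for 10 consecutive
    iterations.
    """
    config = config or PlpConfig()
    config.validate()
    Z = whiten(Xp)
    m_eff, n = Z.shape
    if L < 1 or L > m_eff:
        raise NumericalRankError(
            f"requested L={L} sources but whitened data has rank {m_eff}"
        )
    rng = np.random.default_rng(config.seed)
    W = np.zeros((L, m_eff))
    for m in range(L):
        if config.init == "random":
            w = rng.standard_normal(m_eff)
        else:
            w = np.zeros(m_eff)
            w[m] = 1.0
        if m > 0:  # deflate against already-extracted predictors
            w -= W[:m].T @ (W[:m] @ w)
        w /= np.linalg.norm(w)
        grow_streak = 0
        last_step = 0.0
        for _ in range(config.max_iters):
            if config.mu_y == 0.0:
                break
            y = w @ Z
            e, c = _prediction_error(y)
            j = float(e @ e) / n
            # relative-gradient step on the prediction-error power; the
            # shifted term is the chain-rule contribution of y(n-1)
            g = (Z @ e - c * (Z[:, :-1] @ e[1:])) * (2.0 / n)
            g_t = g - (w @ g) * w        # tangent component on the unit sphere
            if j <= 0:
                break
            delta = (config.mu_y / j) * g_t
            if m > 0:
                delta -= W[:m].T @ (W[:m] @ delta)
            step = float(np.linalg.norm(delta))
            # divergence watch: the update norm keeps growing, or each step
            # overshoots the whole unit sphere the weights live on
            if step > last_step * (1.0 + 1e-12) or step > 2.0:
                grow_streak += 1
                if grow_streak >= 10 and step > 2.0:
                    raise DivergenceError(
                        f"PLP update diverged (update norm {step:.2e} after "
                        f"{grow_streak} growing iterations at mu_y={config.mu_y})"
                    )
            else:
                grow_streak = 0
            last_step = step
            if step < config.tol:
                break
            w = w - delta
            if m > 0:
                w -= W[:m].T @ (W[:m] @ w)
            w /= np.linalg.norm(w)
        W[m] = w
    return ExtractedSources(
        Y=_unit_rows(W @ Z),
        labels=["unassigned"] * L,
        basis_indices=list(range(L)),
    )
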