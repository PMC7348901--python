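"""Evaluation metrics for source separation and R-peak detection.

Separation quality (ground truth required, i.e. simulation only):

* SPI, the similarity performance index
  ``(1/L) sum_i 10 log10(<y,y><s,s>/<y,s>^2 - 1)`` - more negative means a
  better match (0 dB corresponds to squared cosine 0.5).
* The BSS-eval orthogonal decomposition of an estimate into
  ``s_target + e_interf + e_noise + e_artif`` with the energy-ratio scores
  SIR, SAR and SDR.
* qSNR, ``10 log10(sum shat^2 / sum (s - shat)^2)`` after least-squares
  amplitude alignment of the estimate onto the truth.

Detection quality: greedy one-to-one peak matching within a tolerance
window (+-50 ms by default, the PhysioNet Challenge 2013 convention) gives
TP/FP/FN counts, from which SE = TP/(TP+FN), ACC = TP/(TP+FN+FP) and
PPV = TP/(TP+FP) percentages follow.

Because blind separation leaves permutation and sign undetermined,
:func:`align_sources` finds the optimal assignment (Hungarian algorithm on
the absolute correlation matrix) and sign before any waveform metric is
computed.  Unbounded dB values are capped at +-300 so reports stay finite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .errors import InsufficientDataError, ParameterError, UnavailableMetricError

__all__ = [
    "DB_CAP",
    "BssDecomposition",
    "DetectionCounts",
    "SeparationReport",
    "align_sources",
    "spi",
    "bss_eval",
    "qsnr",
    "match_peaks",
    "detection_stats",
]

DB_CAP = 300.0


def _db(num: float, den: float) -> float:
    """10 log10(num/den) with +-DB_CAP guards."""
    if num <= 0.0:
        return -DB_CAP
    if den <= 0.0:
        return DB_CAP
    return float(np.clip(10.0 * np.log10(num / den), -DB_CAP, DB_CAP))


# ---------------------------------------------------------------------------
# alignment

@dataclass
class Alignment:
    """Permutation/sign map from estimate rows to truth rows."""

    permutation: np.ndarray   # estimate row i matches truth row permutation[i]
    signs: np.ndarray
    corr: np.ndarray          # |correlation| of each matched pair


def align_sources(Y: np.ndarray, S: np.ndarray) -> tuple[np.ndarray, Alignment]:
    """Optimally permute and sign-flip estimate rows to match truth rows.

    Maximises the total absolute correlation via the Hungarian assignment;
    returns the aligned copy of Y (rows reordered to truth order, signs
    fixed) and the alignment record.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    S = np.atleast_2d(np.asarray(S, dtype=float))
    if Y.shape[1] != S.shape[1]:
        raise ParameterError("estimate and truth must have the same sample count")
    Yc = Y - Y.mean(axis=1, keepdims=True)
    Sc = S - S.mean(axis=1, keepdims=True)
    num = Yc @ Sc.T
    denom = np.outer(np.linalg.norm(Yc, axis=1), np.linalg.norm(Sc, axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(denom > 0, num / denom, 0.0)
    rows, cols = linear_sum_assignment(-np.abs(corr))
    k = min(Y.shape[0], S.shape[0])
    perm = np.empty(Y.shape[0], dtype=int)
    signs = np.ones(Y.shape[0])
    matched_corr = np.zeros(Y.shape[0])
    aligned = np.zeros((k, Y.shape[1]))
    for r, c in zip(rows, cols):
        perm[r] = c
        signs[r] = 1.0 if corr[r, c] >= 0 else -1.0
        matched_corr[r] = abs(corr[r, c])
        if c < k:
            aligned[c] = signs[r] * Y[r]
    return aligned, Alignment(permutation=perm, signs=signs, corr=matched_corr)


# ---------------------------------------------------------------------------
# waveform metrics

def spi(Y: np.ndarray, S: np.ndarray) -> float:
    """Similarity performance index in dB (rows must be pre-aligned)."""
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    S = np.atleast_2d(np.asarray(S, dtype=float))
    if Y.shape != S.shape:
        raise ParameterError(f"shape mismatch: {Y.shape} vs {S.shape}")
    terms = []
    for y, s in zip(Y, S):
        yy, ss, ys = float(y @ y), float(s @ s), float(y @ s)
        if yy == 0.0 or ss == 0.0:
            raise ParameterError("SPI is undefined for zero-power rows")
        if ys == 0.0:
            terms.append(DB_CAP)       # orthogonal: no similarity at all
            continue
        arg = yy * ss / ys**2 - 1.0
        terms.append(_db(arg, 1.0) if arg > 0 else -DB_CAP)
    return float(np.mean(terms))


@dataclass
class BssDecomposition:
    """Orthogonal split of an estimate; the four parts sum to the estimate."""

    s_target: np.ndarray
    e_interf: np.ndarray
    e_noise: np.ndarray
    e_artif: np.ndarray

    def total(self) -> np.ndarray:
        return self.s_target + self.e_interf + self.e_noise + self.e_artif


def _project_onto_rows(y: np.ndarray, basis: np.ndarray) -> np.ndarray:
    coef, *_ = np.linalg.lstsq(basis.T, y, rcond=None)
    return coef @ basis


def bss_eval(
    y: np.ndarray,
    S: np.ndarray,
    noise: np.ndarray | None = None,
    target_index: int | None = None,
) -> tuple[float, float, float, BssDecomposition]:
    """BSS-eval scores (SIR, SAR, SDR) of one estimated waveform.

    ``S`` holds all true sources (rows); the matched source is
    ``target_index`` or, if omitted, the row with the largest absolute
    correlation.  ``noise`` rows extend the projection space for the
    noise term.  Requires ground truth - raises
    :class:`UnavailableMetricError` when ``S`` is None/empty.
    """
    if S is None or np.size(S) == 0:
        raise UnavailableMetricError(
            "BSS-eval requires the true sources; only simulated records carry them"
        )
    y = np.asarray(y, dtype=float).ravel()
    S = np.atleast_2d(np.asarray(S, dtype=float))
    if S.shape[1] != len(y):
        raise ParameterError("sources and estimate must share the sample count")
    if target_index is None:
        corrs = [abs(np.corrcoef(y, s)[0, 1]) for s in S]
        target_index = int(np.argmax(corrs))
    s = S[target_index]
    s_target = (float(y @ s) / float(s @ s)) * s
    p_s = _project_onto_rows(y, S)
    e_interf = p_s - s_target
    if noise is not None and np.size(noise) > 0:
        basis = np.vstack([S, np.atleast_2d(noise)])
        p_sn = _project_onto_rows(y, basis)
    else:
        p_sn = p_s
    e_noise = p_sn - p_s
    e_artif = y - p_sn
    sir = _db(float(s_target @ s_target), float(e_interf @ e_interf))
    dist = s_target + e_interf + e_noise
    sar = _db(float(dist @ dist), float(e_artif @ e_artif))
    err = e_interf + e_noise + e_artif
    sdr = _db(float(s_target @ s_target), float(err @ err))
    return sir, sar, sdr, BssDecomposition(s_target, e_interf, e_noise, e_artif)


def qsnr(
    s_true: np.ndarray,
    s_hat: np.ndarray,
    align_amplitude: bool = True,
    numerator: str = "estimate",
) -> float:
    """Quality SNR of an extracted waveform against its ground truth, dB.

    ``numerator="estimate"`` uses the estimate's power on top (the printed
    form); ``"conventional"`` uses the truth's power.  Amplitude alignment
    least-squares-scales the estimate onto the truth first.
    """
    s_true = np.asarray(s_true, dtype=float).ravel()
    s_hat = np.asarray(s_hat, dtype=float).ravel()
    if len(s_true) != len(s_hat):
        raise ParameterError("qsnr requires equal-length waveforms")
    if numerator not in ("estimate", "conventional"):
        raise ParameterError(f"unknown numerator rule {numerator!r}")
    if align_amplitude:
        denom = float(s_hat @ s_hat)
        if denom > 0:
            s_hat = (float(s_true @ s_hat) / denom) * s_hat
    resid = s_true - s_hat
    num = float(s_hat @ s_hat) if numerator == "estimate" else float(s_true @ s_true)
    return _db(num, float(resid @ resid))


# ---------------------------------------------------------------------------
# detection metrics

@dataclass
class DetectionCounts:
    """TP/FP/FN of peak detection under a matching tolerance."""

    TP: int
    FP: int
    FN: int
    tolerance_ms: float = 50.0

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.FN) < 0:
            raise ParameterError("detection counts must be non-negative")


def match_peaks(
    detected: np.ndarray,
    reference: np.ndarray,
    tolerance_ms: float = 50.0,
    fs: float = 1000.0,
) -> DetectionCounts:
    """Greedy one-to-one nearest matching of detections to reference peaks.

    Candidate pairs within +-tolerance are accepted closest-first, each peak
    used at most once.  Matched pairs are TP, leftover detections FP,
    leftover references FN.
    """
    det = np.asarray(detected, dtype=float).ravel()
    ref = np.asarray(reference, dtype=float).ravel()
    if np.any(np.diff(det) < 0) or np.any(np.diff(ref) < 0):
        raise ParameterError("peak index lists must be sorted")
    tol = tolerance_ms * fs / 1000.0
    pairs = [
        (abs(d - r), i, j)
        for i, d in enumerate(det)
        for j, r in enumerate(ref)
        if abs(d - r) <= tol
    ]
    pairs.sort()
    used_d: set[int] = set()
    used_r: set[int] = set()
    tp = 0
    for _, i, j in pairs:
        if i not in used_d and j not in used_r:
            used_d.add(i)
            used_r.add(j)
            tp += 1
    return DetectionCounts(
        TP=tp, FP=len(det) - tp, FN=len(ref) - tp, tolerance_ms=tolerance_ms
    )


def detection_stats(counts: DetectionCounts) -> tuple[float, float, float]:
    """(SE, ACC, PPV) percentages from TP/FP/FN counts."""
    if counts.TP + counts.FN == 0 or counts.TP + counts.FP == 0:
        raise InsufficientDataError(
            "detection statistics undefined: a denominator is zero "
            f"(TP={counts.TP}, FP={counts.FP}, FN={counts.FN})"
        )
    se = 100.0 * counts.TP / (counts.TP + counts.FN)
    acc = 100.0 * counts.TP / (counts.TP + counts.FN + counts.FP)
    ppv = 100.0 * counts.TP / (counts.TP + counts.FP)
    return se, acc, ppv


# ---------------------------------------------------------------------------
# aggregate report

@dataclass
class SeparationReport:
    """All quality figures of one extraction run."""

    spi_db: float
    sir_db: float
    sar_db: float
    sdr_db: float
    qsnr_db: float
    se_pct: float | None = None
    acc_pct: float | None = None
    ppv_pct: float | None = None
    alignment: Alignment | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("se_pct", "acc_pct", "ppv_pct"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 100.0:
                raise ParameterError(f"{name} out of [0, 100]: {v}")

    def to_dict(self) -> dict:
        d = {
            "spi_db": self.spi_db,
            "sir_db": self.sir_db,
            "sar_db": self.sar_db,
            "sdr_db": self.sdr_db,
            "qsnr_db": self.qsnr_db,
            "se_pct": self.se_pct,
            "acc_pct": self.acc_pct,
            "ppv_pct": self.ppv_pct,
        }
        d.update(self.extras)
        return d


def separation_report(
    Y: np.ndarray,
    S: np.ndarray,
    noise: np.ndarray | None = None,
    detection: DetectionCounts | None = None,
) -> SeparationReport:
    """Align estimates to truth and compute every waveform metric.

    SIR/SAR/SDR and qSNR are reported for the fetal source when the truth
    has the conventional (maternal, fetal) row order, i.e. for the
    last-matched row; SPI averages over all matched rows.
    """
    aligned, alignment = align_sources(Y, S)
    k = aligned.shape[0]
    spi_db = spi(aligned, S[:k])
    fetal_row = k - 1
    sir, sar, sdr, _ = bss_eval(aligned[fetal_row], S, noise, target_index=fetal_row)
    q = qsnr(S[fetal_row], aligned[fetal_row])
    se = acc = ppv = None
    if detection is not None:
        se, acc, ppv = detection_stats(detection)
    return SeparationReport(
        spi_db=spi_db,
        sir_db=sir,
        sar_db=sar,
        sdr_db=sdr,
        qsnr_db=q,
        se_pct=se,
        acc_pct=acc,
        ppv_pct=ppv,
        alignment=alignment,
    )
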