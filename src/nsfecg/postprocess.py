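"""Maternal-beat removal from the raw fetal trace.

After null-space extraction the raw FECG may still contain maternal R peaks
(the maternal source dominates the mixture).  Contaminating maternal peaks
split fetal RR intervals, which simultaneously inflates the per-interval
fetal heart rate (an extra peak midway doubles the local rate) and its
variance.  The control logic therefore activates removal only when BOTH the
FHR variance exceeds ``max_var`` AND the FHR exceeds ``max_fhr`` (180 bpm by
default, the physiological ceiling around mid-gestation).

Removal multiplies the raw FECG by a gain profile h(n): unity everywhere
except in a window of half-width U around each maternal R peak, where the
gain follows the valley-shaped coefficients

    a_r = 0.46 - 0.46 cos(2 pi r / (2U + 1)),   r in [-U, U],

which are exactly zero at the peak centre and rise towards the window edge.
Overlapping windows combine by pointwise minimum (deepest attenuation
wins); windows are truncated at the record boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InsufficientDataError, ParameterError

__all__ = [
    "ControlConfig",
    "CombFilter",
    "control_decision",
    "acf_window_coeffs",
    "default_halfwidth",
    "build_acf",
    "remove_mecg",
]


@dataclass(frozen=True)
class ControlConfig:
    """Thresholds of the removal-activation rule.

    ``max_var`` of 1-5 is the useful range; ``fhr_stat`` selects whether the
    rate clause tests the mean FHR (default) or any single interval rate.
    """

    max_fhr_bpm: float = 180.0
    max_var: float = 3.0
    fhr_stat: str = "mean"  # "mean" | "any"

    def validate(self) -> None:
        if self.max_fhr_bpm <= 0:
            raise ParameterError(f"max_fhr_bpm must be positive, got {self.max_fhr_bpm}")
        if self.max_var <= 0:
            raise ParameterError(f"max_var must be positive, got {self.max_var}")
        if self.fhr_stat not in ("mean", "any"):
            raise ParameterError(f"fhr_stat must be 'mean' or 'any', got {self.fhr_stat}")


def control_decision(fhr_vector: np.ndarray, config: ControlConfig | None = None) -> bool:
    """True iff maternal contamination is indicated by the FHR vector.

    Activates when var(FHR) > max_var AND the FHR statistic (mean by
    default) exceeds max_fhr.
    """
    config = config or ControlConfig()
    config.validate()
    v = np.asarray(fhr_vector, dtype=float).ravel()
    if len(v) < 2:
        raise InsufficientDataError(
            f"control decision needs >= 2 FHR values, got {len(v)}"
        )
    var = float(np.var(v, ddof=1))  # sample variance (MATLAB-style var)
    stat = float(np.mean(v)) if config.fhr_stat == "mean" else float(np.max(v))
    return var > config.max_var and stat > config.max_fhr_bpm


@dataclass
class CombFilter:
    """Length-N gain vector with valley windows at the maternal peaks."""

    U: int
    centers: np.ndarray
    h: np.ndarray
    window_coeffs: np.ndarray  # a_r for r = -U..U

    @property
    def n_samples(self) -> int:
        return len(self.h)


def acf_window_coeffs(U: int, variant: str = "as_printed") -> np.ndarray:
    """Window gains a_r, r = -U..U.

    ``as_printed`` uses 0.46 - 0.46 cos(2 pi r/(2U+1)) (zero gain at the
    centre); ``complement`` uses the complement of a standard Hamming
    window, 1 - (0.54 + 0.46 cos(2 pi r/(2U+1))), clipped to [0, 1].
    """
    if U < 1:
        raise ParameterError(f"comb half-width U must be >= 1, got {U}")
    r = np.arange(-U, U + 1)
    if variant == "as_printed":
        a = 0.46 - 0.46 * np.cos(2.0 * np.pi * r / (2 * U + 1))
    elif variant == "complement":
        a = 1.0 - (0.54 + 0.46 * np.cos(2.0 * np.pi * r / (2 * U + 1)))
    else:
        raise ParameterError(f"unknown comb window variant {variant!r}")
    return np.clip(a, 0.0, 1.0)


def default_halfwidth(fs: float) -> int:
    """Half-width giving a 21-sample window at fs = 1 kHz, scaled with fs.

    The recommended total length is 20-45 samples at 1 kHz; shorter windows
    risk leaving maternal energy, longer ones eat into nearby fetal beats.
    """
    return max(1, int(round(10.0 * fs / 1000.0)))


def build_acf(
    p1: np.ndarray, U: int, N: int, variant: str = "as_printed"
) -> CombFilter:
    """Assemble the comb gain vector for maternal peaks ``p1`` (empty allowed)."""
    if N < 1:
        raise ParameterError(f"record length N must be >= 1, got {N}")
    coeffs = acf_window_coeffs(U, variant)
    centers = np.asarray(p1, dtype=int).ravel()
    h = np.ones(N)
    for p in centers:
        if p < 0 or p >= N:
            raise ParameterError(f"maternal peak index {p} outside record of length {N}")
        lo = max(0, p - U)
        hi = min(N, p + U + 1)
        seg = coeffs[lo - (p - U) : (hi - (p - U))]
        h[lo:hi] = np.minimum(h[lo:hi], seg)
    return CombFilter(U=U, centers=centers, h=h, window_coeffs=coeffs)


def remove_mecg(raw_fecg: np.ndarray, comb: CombFilter) -> np.ndarray:
    """Pointwise product of the raw FECG with the comb gain profile."""
    x = np.asarray(raw_fecg, dtype=float).ravel()
    if len(x) != comb.n_samples:
        raise ParameterError(
            f"raw FECG has {len(x)} samples but the comb was built for "
            f"{comb.n_samples}"
        )
    return x * comb.h
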