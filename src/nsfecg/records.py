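"""In-memory containers for multichannel ECG recordings.

The central object is :class:`MultichannelRecord`: a channels x samples
matrix ``X`` with its sampling frequency and a per-channel role tag
(abdominal / thoracic / reference / unknown).  Simulated records carry the
ground-truth source matrix ``S`` (fetal and maternal waveforms), the noise
that was added, and the true R-peak sample indices, so every downstream
stage can be scored against truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError

CHANNEL_ROLES = ("abdominal", "thoracic", "reference", "unknown")


@dataclass
class RecordTruth:
    """Ground truth attached to a simulated record."""

    S: np.ndarray                       # L x N source matrix (row 0 = maternal, 1 = fetal by convention)
    noise: np.ndarray | None = None     # M x N additive noise actually injected
    source_labels: tuple[str, ...] = ("mecg", "fecg")
    peak_indices: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_sources(self) -> int:
        return self.S.shape[0]


@dataclass
class MultichannelRecord:
    """A channels x samples ECG recording.

    Invariants: ``X`` is 2-D with more samples than channels; all channels
    share ``fs``; if truth is present its row count is the source count.
    """

    X: np.ndarray
    fs: float
    channel_roles: tuple[str, ...] | None = None
    truth: RecordTruth | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ParameterError("X must be a 2-D channels x samples matrix")
        if self.fs <= 0:
            raise ParameterError(f"fs must be positive, got {self.fs}")
        m, n = self.X.shape
        if n <= m:
            raise ParameterError(
                f"expected more samples than channels (channels x samples), got {m}x{n}"
            )
        if self.channel_roles is None:
            self.channel_roles = ("unknown",) * m
        self.channel_roles = tuple(self.channel_roles)
        if len(self.channel_roles) != m:
            raise ParameterError(
                f"channel_roles has {len(self.channel_roles)} entries for {m} channels"
            )
        for role in self.channel_roles:
            if role not in CHANNEL_ROLES:
                raise ParameterError(f"unknown channel role {role!r}")

    @property
    def n_channels(self) -> int:
        return self.X.shape[0]

    @property
    def n_samples(self) -> int:
        return self.X.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def with_signal(self, X: np.ndarray) -> "MultichannelRecord":
        """Copy of the record with a new signal matrix (same fs/roles/truth)."""
        return MultichannelRecord(
            X=np.asarray(X, dtype=float),
            fs=self.fs,
            channel_roles=self.channel_roles,
            truth=self.truth,
        )
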