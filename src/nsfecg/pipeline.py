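"""The full extraction pipeline and its run manifest.

One call to :func:`run_pipeline` executes, in order: channel-wise denoising,
source extraction (NSITM by default, or one of the baseline extractors),
fetal/maternal labelling by beat rate, maternal R-peak detection and MHR,
fetal R-peak detection on the raw fetal trace and the per-interval FHR
vector, the contamination control decision, and - only when activated -
adaptive comb filtering of the maternal beats out of the raw fetal trace.
When the control logic stays off, the clean FECG is bit-identical to the
raw FECG.

Every run produces a :class:`RunManifest` capturing the resolved
configuration, an input fingerprint and all decisions taken, so a run can
be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from .baselines import PlpConfig, fastica_extract, pca_extract, plp_extract
from .errors import InsufficientDataError, ParameterError
from .nsitm import ExtractedSources, compute_itm, label_sources, null_space_extract
from .peaks import PeakSet, heart_rates, pan_tompkins
from .postprocess import ControlConfig, build_acf, control_decision, default_halfwidth, remove_mecg
from .preprocess import FilterBankConfig, denoise
from .records import MultichannelRecord

__all__ = ["PipelineConfig", "PipelineResult", "RunManifest", "run_pipeline", "extract_sources"]

SOFTWARE_VERSION = "nsfecg 0.1.0"

METHODS = ("nsitm", "pca", "fastica", "plp")


@dataclass(frozen=True)
class PipelineConfig:
    """Resolved parameters of one extraction run."""

    method: str = "nsitm"
    n_sources: int = 2
    filters: FilterBankConfig = field(default_factory=FilterBankConfig)
    control: ControlConfig = field(default_factory=ControlConfig)
    order_by: str = "xp_spectrum"          # nsitm null-space ordering
    acf_halfwidth: int | None = None       # None -> scaled from fs
    acf_variant: str = "as_printed"
    plp: PlpConfig = field(default_factory=PlpConfig)
    seed: int = 0                          # fastica/plp initialisation

    def validate(self) -> None:
        if self.method not in METHODS:
            raise ParameterError(f"unknown extraction method {self.method!r}")
        if self.n_sources < 2:
            raise ParameterError("pipeline needs n_sources >= 2 (fetal + maternal)")


@dataclass
class RunManifest:
    """Everything needed to reproduce a run bit-identically."""

    method: str
    config_snapshot: dict
    input_fingerprint: str
    decisions: dict
    software_version: str = SOFTWARE_VERSION

    def to_json(self, **kwargs) -> str:
        return json.dumps(dataclasses.asdict(self), default=_jsonable, **kwargs)


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"not JSON-serialisable: {type(obj)}")


@dataclass
class PipelineResult:
    clean_fecg: np.ndarray
    raw_fecg: np.ndarray
    mecg: np.ndarray
    maternal_peaks: PeakSet | None
    fetal_peaks: PeakSet | None          # on the raw fetal trace
    fetal_peaks_clean: PeakSet | None    # re-detected after comb filtering
    control_active: bool
    sources: ExtractedSources
    manifest: RunManifest

    @property
    def fhr_bpm(self) -> float | None:
        ps = self.fetal_peaks_clean if self.control_active else self.fetal_peaks
        return None if ps is None else ps.mean_rate_bpm

    @property
    def mhr_bpm(self) -> float | None:
        return None if self.maternal_peaks is None else self.maternal_peaks.mean_rate_bpm


def _fingerprint(record: MultichannelRecord) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(record.X).tobytes())
    h.update(str(record.fs).encode())
    return h.hexdigest()


def extract_sources(
    Xp: np.ndarray, fs: float, config: PipelineConfig
) -> ExtractedSources:
    """Dispatch to the configured extractor and label the rows by rate."""
    if config.method == "nsitm":
        itm = compute_itm(Xp)
        src = null_space_extract(itm, config.n_sources, order_by=config.order_by)
    elif config.method == "pca":
        src = pca_extract(Xp, config.n_sources)
    elif config.method == "fastica":
        src = fastica_extract(Xp, config.n_sources, seed=config.seed)
    elif config.method == "plp":
        src = plp_extract(Xp, config.n_sources, dataclasses.replace(config.plp, seed=config.seed))
    else:  # pragma: no cover - validated upstream
        raise ParameterError(config.method)
    return label_sources(src, fs)


def _try_peaks(x: np.ndarray, fs: float, mode: str) -> PeakSet | None:
    try:
        idx = pan_tompkins(x, fs, mode=mode)
        return heart_rates(idx, fs) if len(idx) >= 2 else None
    except InsufficientDataError:
        return None


def run_pipeline(
    record: MultichannelRecord, config: PipelineConfig | None = None
) -> PipelineResult:
    """Run the complete extraction on a record (needs >= 2 channels)."""
    config = config or PipelineConfig()
    config.validate()
    if record.n_channels < 2:
        raise ParameterError(
            f"pipeline needs at least 2 channels, record has {record.n_channels}"
        )

    preprocessed = denoise(record, config.filters)
    sources = extract_sources(preprocessed.X, record.fs, config)
    raw_fecg = sources.row("fecg_raw")
    mecg = sources.row("mecg")

    maternal_peaks = _try_peaks(mecg, record.fs, "maternal")
    fetal_peaks = _try_peaks(raw_fecg, record.fs, "fetal")

    active = False
    if fetal_peaks is not None and len(fetal_peaks.rates_bpm) >= 2:
        active = control_decision(fetal_peaks.rates_bpm, config.control)
    halfwidth = (
        config.acf_halfwidth
        if config.acf_halfwidth is not None
        else default_halfwidth(record.fs)
    )
    fetal_peaks_clean = None
    if active and maternal_peaks is not None:
        comb = build_acf(
            maternal_peaks.indices, halfwidth, record.n_samples, config.acf_variant
        )
        clean_fecg = remove_mecg(raw_fecg, comb)
        fetal_peaks_clean = _try_peaks(clean_fecg, record.fs, "fetal")
        n_suppressed = len(maternal_peaks.indices)
    else:
        active = active and maternal_peaks is not None
        clean_fecg = raw_fecg
        n_suppressed = 0

    manifest = RunManifest(
        method=config.method,
        config_snapshot=dataclasses.asdict(config),
        input_fingerprint=_fingerprint(record),
        decisions={
            "control_active": bool(active),
            "acf_halfwidth": int(halfwidth),
            "n_suppressed_peaks": int(n_suppressed),
            "basis_indices": list(sources.basis_indices),
            "labels": list(sources.labels),
            "estimated_rates_bpm": list(sources.rates_bpm),
            "extractor_warnings": list(sources.warnings),
        },
    )
    return PipelineResult(
        clean_fecg=clean_fecg,
        raw_fecg=raw_fecg,
        mecg=mecg,
        maternal_peaks=maternal_peaks,
        fetal_peaks=fetal_peaks,
        fetal_peaks_clean=fetal_peaks_clean,
        control_active=bool(active),
        sources=sources,
        manifest=manifest,
    )
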