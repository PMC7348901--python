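# nsfecg — null-space fetal ECG extraction

Non-invasive fetal electrocardiography records a mixture on the mother's
abdomen: the loud maternal ECG (MECG), the much weaker fetal ECG (FECG),
and noise.  Because the two ECGs overlap in frequency, plain filtering
cannot split them and the problem is treated as blind source separation of
the linear mixing model

    X = A S,        X ∈ R^{M×N},  A ∈ R^{M×L},  S ∈ R^{L×N},  L ≤ M < N,

with `M` recorded channels, `L` unknown sources and `N` samples.  `nsfecg`
is a toolbox for clinicians' engineers and biomedical-signal researchers
who want a deterministic, reproducible FECG extractor plus the standard
baselines and evaluation metrics in one place.

## The method

The core extractor builds the **idempotent transformation matrix**

    W = (1/N) · Xpᵀ Cx⁻¹ Xp,      Cx = (1/N) · Xp Xpᵀ,

from the band-pass/notch-denoised recording `Xp`: the orthogonal projector
onto the row space of the data (W² = W, Wᵀ = W, trace W = rank Xp).  Any
source waveform satisfies `y = y W`, so the sources live in the null space
of `Q = W − I_N`, i.e. in W's eigenvalue-1 eigenspace.  An SVD of `Q`
exposes that null space in the last columns of its right-singular-vector
matrix `Vq`; the last `L` columns (the dominant data-variance directions —
maternal first, then the weaker fetal component) are the recovered
waveforms.

Because the maternal source dominates the mixture, maternal R peaks can
survive in the raw fetal trace.  A Pan–Tompkins detector measures the
maternal (MHR) and fetal (FHR) heart rates from the inter-peak intervals
(`rate = 60·fs/Δp`); when the FHR vector shows both `var(FHR) > maxvar`
and `FHR > maxFHR` (defaults 3 and 180 bpm — contaminating peaks split RR
intervals and inflate both) an **adaptive comb filter** is applied: a gain
profile that is 1 everywhere except in a window of half-width `U` around
each maternal peak, where

    a_r = 0.46 − 0.46·cos(2πr / (2U+1)),   r ∈ [−U, U],

so the gain is exactly 0 at every maternal R peak.

Alongside the null-space method the package ships PCA-whitening, FastICA
and parallel-linear-predictor (PLP) extractors behind the same interface,
a synthetic abdominal-mixture simulator with full ground truth, and the
evaluation suite: SPI, BSS-eval SIR/SAR/SDR, qSNR, and SE/ACC/PPV peak-
detection statistics.

## Worked example

```python
import numpy as np
from nsfecg import PipelineConfig, run_pipeline, simulate_record
from nsfecg.metrics import separation_report

record = simulate_record(n_abdominal=5, n_thoracic=2, fmsnr_db=-10.0,
                         channel_snr_db=12.0, seed=7)
result = run_pipeline(record, PipelineConfig(method="nsitm"))

print(f"maternal heart rate : {result.mhr_bpm:6.1f} bpm")
print(f"fetal heart rate    : {result.fhr_bpm:6.1f} bpm")
print(f"comb filter applied : {result.control_active}")

report = separation_report(
    np.vstack([result.mecg, result.clean_fecg]),
    record.truth.S, noise=record.truth.noise)
for key in ("spi_db", "sir_db", "sar_db", "sdr_db", "qsnr_db"):
    print(f"{key:8s}: {report.to_dict()[key]:7.2f}")
corr = abs(np.corrcoef(result.clean_fecg, record.truth.S[1])[0, 1])
print(f"fetal waveform |corr| vs truth: {corr:.3f}")
```

prints

```
maternal heart rate :   79.5 bpm
fetal heart rate    :  140.0 bpm
comb filter applied : False
spi_db  :  -12.73
sir_db  :   19.40
sar_db  :   15.90
sdr_db  :   10.03
qsnr_db :   10.03
fetal waveform |corr| vs truth: 0.954
```

The simulated mother beats at 80 bpm and the fetus at 140 bpm; both rates
are recovered to a fraction of a beat per minute.  The negative SPI says
the extracted and true waveforms are close (more negative = more similar;
0 dB corresponds to a squared cosine of only 0.5), SIR ≈ 19 dB means the
maternal interference left in the fetal estimate is fifty-fold below the
fetal signal, and the extraction is clean enough that the control logic
left the comb filter off.  On this record the simulation kept the fetal
source 10 dB below maternal (`fmsnr_db=-10`) with a mixture-to-noise
ratio of 12 dB.

A command-line interface mirrors the library:

```sh
fecg simulate --out rec.csv --seed 7
fecg extract rec.csv --fs 250 --method nsitm --out-prefix run
fecg detect-peaks rec.csv --fs 250 --mode maternal --out peaks.csv
fecg evaluate --estimates est.csv --truth rec_truth.csv --out report.json
fecg bench --seed 0 --out sweep.json
```

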