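"""ECG preparation: normalization, artifact filtering, R-peak detection,
plus a synthetic ECG generator emulating archival single-lead recordings
(128 or 360 Hz, gain 200 adu/mV, baselines 0 or 1024) so classifier
training needs no download.  An optional WFDB reader is isolated behind
one function and requires the ``wfdb`` package.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal as sps
from scipy.ndimage import maximum_filter1d, uniform_filter1d

from .errors import InvalidArgumentError

log = logging.getLogger(__name__)

# Butterworth artifact-removal cascade (all stages 4th order):
LOWPASS_CUTOFF_HZ = 30.0       # removes muscle tremor (30-300 Hz)
BANDSTOP_HZ = (48.0, 52.0)     # suppresses 50 Hz mains interference
HIGHPASS_CUTOFF_HZ = 0.8       # removes baseline wander (0-0.8 Hz)
REFRACTORY_S = 0.2             # minimum spacing between R peaks


class BeatLabel(str, enum.Enum):
    NORMAL = "normal"
    ARRHYTHMIA = "arrhythmia"
    UNKNOWN = "unknown"


@dataclass
class ECGRecord:
    """A normalized single-lead ECG trace in mV.

    ``truth_beat_times`` is populated by the synthetic generator only.
    """

    samples: np.ndarray  # mV
    rate: float  # Hz
    gain: float = 200.0  # adu/mV
    baseline: float = 0.0  # adu
    subject_meta: tuple[int, int] = (0, 0)  # (age yr, gender code)
    label: BeatLabel = BeatLabel.UNKNOWN
    truth_beat_times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.rate <= 0:
            raise InvalidArgumentError("rate must be positive")
        if len(self.samples) < 2 * self.rate:
            raise InvalidArgumentError("record must be at least 2 s long")
        if np.max(np.abs(self.samples)) > 10.0:
            raise InvalidArgumentError(
                "normalized ECG amplitude exceeds +/-10 mV"
            )

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.rate

    @property
    def duration(self) -> float:
        return len(self.samples) / self.rate


def normalize_record(
    raw: np.ndarray, gain: float, baseline: float
) -> np.ndarray:
    """(raw - baseline) / gain: archival integer units (adu) to mV."""
    if gain == 0:
        raise InvalidArgumentError("gain must be nonzero")
    return (np.asarray(raw, dtype=float) - baseline) / gain


def denormalize_record(
    mv: np.ndarray, gain: float, baseline: float
) -> np.ndarray:
    """Inverse of :func:`normalize_record` (exact round trip)."""
    return np.asarray(mv, dtype=float) * gain + baseline


def remove_artifacts(record: ECGRecord) -> ECGRecord:
    """Cascade of low-pass 30 Hz, band-stop 48-52 Hz and high-pass 0.8 Hz.

    All stages are 4th-order Butterworth filters applied forward-backward
    (zero phase), preserving length and R-peak timing.  A stage whose band
    edge would sit at or beyond Nyquist is skipped with a logged warning.
    """
    x = record.samples
    nyq = record.rate / 2.0
    if LOWPASS_CUTOFF_HZ < nyq * 0.95:
        sos = sps.butter(4, LOWPASS_CUTOFF_HZ, "lowpass", fs=record.rate, output="sos")
        x = sps.sosfiltfilt(sos, x)
    else:
        log.warning("low-pass stage skipped: rate %.0f Hz too low", record.rate)
    if BANDSTOP_HZ[1] < nyq * 0.95:
        sos = sps.butter(4, BANDSTOP_HZ, "bandstop", fs=record.rate, output="sos")
        x = sps.sosfiltfilt(sos, x)
    else:
        log.warning("band-stop stage skipped: rate %.0f Hz too low", record.rate)
    sos = sps.butter(4, HIGHPASS_CUTOFF_HZ, "highpass", fs=record.rate, output="sos")
    x = sps.sosfiltfilt(sos, x)
    return ECGRecord(
        samples=np.clip(x, -10.0, 10.0),
        rate=record.rate,
        gain=record.gain,
        baseline=record.baseline,
        subject_meta=record.subject_meta,
        label=record.label,
        truth_beat_times=record.truth_beat_times,
    )


def detect_r_peaks(record: ECGRecord) -> np.ndarray:
    """R-peak times (s) via squared-derivative energy with adaptive threshold.

    The rectified slope energy (first difference squared, smoothed with a
    150 ms moving average) is compared against 0.5x its rolling 2 s
    maximum; candidate peaks must clear that threshold and respect a 0.2 s
    refractory period.  Each candidate is then refined to the extremum of
    |ECG| within +/-75 ms, which makes detection robust to polarity
    inversion.
    """
    x = record.samples
    rate = record.rate
    energy = np.gradient(x) ** 2
    smooth = uniform_filter1d(energy, size=max(int(round(0.15 * rate)), 1))
    rolling_max = maximum_filter1d(smooth, size=max(int(round(2.0 * rate)), 1))
    floor = 1e-12 * (np.max(smooth) if np.max(smooth) > 0 else 1.0)
    threshold = np.maximum(0.5 * rolling_max, floor)
    idx, _ = sps.find_peaks(smooth, distance=max(int(round(REFRACTORY_S * rate)), 1))
    idx = idx[smooth[idx] >= threshold[idx]]
    if len(idx) == 0:
        return np.empty(0)
    # refine to the local |ECG| extremum
    half = int(round(0.075 * rate))
    refined = []
    absx = np.abs(x - np.median(x))
    for i in idx:
        lo, hi = max(i - half, 0), min(i + half + 1, len(x))
        refined.append(lo + int(np.argmax(absx[lo:hi])))
    refined = np.unique(refined)
    # enforce refractory after refinement
    out = [refined[0]]
    for i in refined[1:]:
        if i - out[-1] >= REFRACTORY_S * rate:
            out.append(i)
        elif absx[i] > absx[out[-1]]:
            out[-1] = i
    return np.asarray(out) / rate


# ---------------------------------------------------------------------------
# synthetic ECG generation
# ---------------------------------------------------------------------------

# Gaussian bump morphology per beat: (amplitude mV, width s, offset as a
# fraction of the local RR interval relative to the R peak)
_MORPHOLOGY = (
    (0.12, 0.040, -0.20),  # P
    (-0.10, 0.015, -0.040),  # Q
    (1.20, 0.012, 0.0),  # R
    (-0.20, 0.015, 0.040),  # S
    (0.30, 0.060, 0.30),  # T
)


def simulate_ecg(
    rr_sequence: Sequence[float],
    rate: float = 128.0,
    gain: float = 200.0,
    baseline: float = 0.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
    subject_meta: tuple[int, int] = (0, 0),
    label: BeatLabel = BeatLabel.UNKNOWN,
) -> ECGRecord:
    """Synthetic P-QRS-T-like record driven by an RR-interval sequence.

    Each beat is a sum of Gaussian bumps (P, Q, R, S, T) positioned
    relative to the R peak at the cumulative RR times; amplitudes are
    stored in raw adu using ``gain``/``baseline`` and normalized back so
    the quantization of the archival format is exercised.  The true R-peak
    times are attached as ``truth_beat_times``.
    """
    rr = np.asarray(rr_sequence, dtype=float)
    if np.any(rr < 0.3) or np.any(rr > 2.0):
        raise InvalidArgumentError("rr values must lie within [0.3, 2.0] s")
    beat_times = 0.3 + np.concatenate([[0.0], np.cumsum(rr)])[:-1]
    duration = 0.3 + float(np.sum(rr)) + 0.3
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    mv = np.zeros(n)
    for i, bt in enumerate(beat_times):
        local_rr = rr[min(i, len(rr) - 1)]
        for amp, width, frac in _MORPHOLOGY:
            centre = bt + frac * local_rr
            mv += amp * np.exp(-0.5 * ((t - centre) / width) ** 2)
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        mv += rng.normal(0.0, noise_sd, n)
    raw = np.rint(denormalize_record(mv, gain, baseline))
    return ECGRecord(
        samples=normalize_record(raw, gain, baseline),
        rate=rate,
        gain=gain,
        baseline=baseline,
        subject_meta=subject_meta,
        label=label,
        truth_beat_times=beat_times,
    )


def read_wfdb_record(record_name: str, label: BeatLabel = BeatLabel.UNKNOWN) -> ECGRecord:
    """Read a WFDB-format (.hea/.dat) record; requires the optional ``wfdb``
    package and locally downloaded files."""
    try:
        import wfdb  # type: ignore
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "reading WFDB records requires the optional 'wfdb' package "
            "(pip install radarvitals[wfdb])"
        ) from exc
    rec = wfdb.rdrecord(record_name)  # pragma: no cover
    raw = rec.adc()[:, 0]  # pragma: no cover
    gain = float(rec.adc_gain[0])  # pragma: no cover
    baseline = float(rec.baseline[0])  # pragma: no cover
    return ECGRecord(  # pragma: no cover
        samples=normalize_record(raw, gain, baseline),
        rate=float(rec.fs),
        gain=gain,
        baseline=baseline,
        label=label,
    )
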