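"""Signal filtering, beat detection, segmentation and template construction.

The processing chain applied identically to contact PPG and (resampled) iPPG
signals: a zero-phase fifth-order Butterworth bandpass (0.4-8 Hz), detection
of beats at the steepest ascent of the pulse, segmentation of each beat over
``[t_i - 0.45*BBI~, t_i + BBI~]`` where ``BBI~`` is the median beat-to-beat
interval of the analysis window, quality filtering by mean pairwise
correlation, and ensemble averaging with linear detrending into one beat
template per window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy import signal as sps

from .signals import SampledSignal

__all__ = [
    "BeatDetectionSet",
    "BeatTemplate",
    "NoBeatsError",
    "NoTemplateError",
    "bandpass",
    "detect_beats",
    "segment_beats",
    "filter_segments",
    "build_template",
    "extract_interval",
    "interval_starts",
]

PRE_FRACTION = 0.45   # segment extends 0.45*BBI~ before the detection point
CORR_THRESHOLD = 0.3  # discard segments with lower mean pairwise correlation


class NoBeatsError(RuntimeError):
    """Fewer than two beats detected in a window."""


class NoTemplateError(RuntimeError):
    """All beat segments were discarded; no template can be built."""


@dataclass(frozen=True)
class BeatDetectionSet:
    """Steepest-ascent detection points and the window's median BBI."""

    times: np.ndarray       # detection instants, s (absolute, on signal.times)
    median_bbi: float       # s

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise ValueError("detection times must be strictly increasing")


@dataclass(frozen=True)
class BeatTemplate:
    """Ensemble-averaged, detrended beat over [-0.45*BBI~, +BBI~]."""

    values: np.ndarray
    fs: float
    median_bbi: float
    n_beats_used: int
    mean_pairwise_corr: float

    @property
    def times(self) -> np.ndarray:
        """Time axis anchored at the detection point (t = 0)."""
        n = np.asarray(self.values).size
        return np.arange(n) / self.fs - PRE_FRACTION * self.median_bbi


def bandpass(signal: SampledSignal, low: float = 0.4, high: float = 8.0,
             order: int = 5) -> SampledSignal:
    """Zero-phase Butterworth bandpass.

    The filter is designed as a single fifth-order bandpass and applied
    forward-backward (``filtfilt``), preserving pulse morphology at the cost
    of squaring the magnitude response.  The -3 dB points at the cut-off
    frequencies therefore hold for the designed single-pass filter.
    """
    if signal.fs <= 2 * high:
        raise ValueError(
            f"sampling rate {signal.fs} Hz too low for a {high} Hz cut-off")
    sos = sps.butter(order, [low, high], btype="bandpass", output="sos",
                     fs=signal.fs)
    padlen = min(signal.n - 1, 3 * int(signal.fs / low))
    if signal.n < 16:
        raise ValueError("signal too short to filter")
    filtered = sps.sosfiltfilt(sos, signal.values, padlen=padlen)
    return signal.with_values(filtered)


def butter_sos(low: float = 0.4, high: float = 8.0, order: int = 5,
               fs: float = 2000.0):
    """The designed single-pass filter, exposed for response checks."""
    return sps.butter(order, [low, high], btype="bandpass", output="sos", fs=fs)


def detect_beats(signal: SampledSignal, *, threshold_fraction: float = 0.5,
                 refractory_fraction: float = 0.3) -> BeatDetectionSet:
    """Detect beats at the steepest ascent of the filtered pulse wave.

    Detection points are local maxima of the first difference that exceed an
    adaptive threshold (``threshold_fraction`` of the rolling derivative
    amplitude over a 2 s neighbourhood), separated by a refractory period.
    The refractory period is bootstrapped from the dominant period of the
    signal's autocorrelation, then detections yield the window's median BBI.
    """
    y = signal.values
    fs = signal.fs
    if signal.duration < 2.0:
        raise NoBeatsError("window shorter than 2 s")
    d = np.gradient(y) * fs
    if np.ptp(d) <= 0 or not np.isfinite(d).any():
        raise NoBeatsError("flat signal, no beats")

    # bootstrap the beat period from the autocorrelation (0.25-2.5 s lags)
    yc = y - y.mean()
    ac = sps.correlate(yc, yc, mode="full")[yc.size - 1:]
    lo, hi = int(0.25 * fs), min(int(2.5 * fs), ac.size - 1)
    if hi <= lo:
        raise NoBeatsError("window too short to estimate a beat period")
    period = (lo + int(np.argmax(ac[lo:hi]))) / fs
    refractory = max(int(refractory_fraction * period * fs), 1)

    win = max(int(2.0 * fs), 3)
    rolling_max = ndimage.maximum_filter1d(d, size=win, mode="nearest")
    peaks, _ = sps.find_peaks(d, distance=refractory)
    peaks = peaks[d[peaks] >= threshold_fraction * rolling_max[peaks]]
    if peaks.size < 2:
        raise NoBeatsError("fewer than two beats detected")
    times = signal.t0 + peaks / fs
    median_bbi = float(np.median(np.diff(times)))
    return BeatDetectionSet(times=times, median_bbi=median_bbi)


def segment_beats(signal: SampledSignal,
                  detections: BeatDetectionSet) -> list[np.ndarray]:
    """Cut one fixed-length segment per detection.

    Each segment spans ``[t_i - 0.45*BBI~, t_i + BBI~]``; detections whose
    window would leave the signal are dropped.  Segments may overlap.
    """
    fs = signal.fs
    bbi = detections.median_bbi
    n_seg = int(round(1.45 * bbi * fs)) + 1
    n_pre = int(round(PRE_FRACTION * bbi * fs))
    segments = []
    for t_i in detections.times:
        i_det = int(round((t_i - signal.t0) * fs))
        i0 = i_det - n_pre
        if i0 < 0 or i0 + n_seg > signal.n:
            continue  # boundary detection, window underflow/overflow
        segments.append(signal.values[i0 : i0 + n_seg].copy())
    return segments


def filter_segments(segments: list[np.ndarray],
                    corr_threshold: float = CORR_THRESHOLD
                    ) -> tuple[list[np.ndarray], float]:
    """Quality-filter segments by mean pairwise Pearson correlation.

    Each segment is correlated with every other; segments whose mean
    correlation falls below ``corr_threshold`` are discarded.  Returns the
    kept segments and the overall mean pairwise correlation of the kept set
    (1.0 when only one segment survives).

    Raises
    ------
    NoTemplateError
        if every segment is discarded.
    """
    if len(segments) < 2:
        raise NoTemplateError("need at least two segments to correlate")
    mat = np.asarray(segments)
    sd = mat.std(axis=1)
    if np.any(sd == 0):
        # constant segments have undefined correlation; treat as corr 0
        keep_nonflat = sd > 0
        if keep_nonflat.sum() < 2:
            raise NoTemplateError("segments are constant")
    n = mat.shape[0]
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(mat)
    corr = np.where(np.isfinite(corr), corr, 0.0)  # undefined pairs count as 0
    np.fill_diagonal(corr, 0.0)
    mean_corr = corr.sum(axis=1) / (n - 1)
    keep = mean_corr >= corr_threshold
    if not keep.any():
        raise NoTemplateError(
            "all beat segments discarded by the correlation rule")
    kept = [segments[i] for i in np.flatnonzero(keep)]
    k = keep.sum()
    if k >= 2:
        sub = corr[np.ix_(keep, keep)]
        overall = float(sub.sum() / (k * (k - 1)))
    else:
        overall = 1.0
    return kept, overall


def build_template(kept: list[np.ndarray], fs: float, median_bbi: float,
                   mean_pairwise_corr: float) -> BeatTemplate:
    """Ensemble-average kept segments and remove the linear trend.

    The pointwise mean is computed across segments, then the least-squares
    straight line fitted to the averaged waveform is subtracted.
    """
    if not kept:
        raise NoTemplateError("no segments to average")
    mean = np.mean(np.asarray(kept), axis=0)
    x = np.arange(mean.size, dtype=float)
    slope, intercept = np.polyfit(x, mean, 1)
    detrended = mean - (slope * x + intercept)
    return BeatTemplate(values=detrended, fs=fs, median_bbi=median_bbi,
                        n_beats_used=len(kept),
                        mean_pairwise_corr=mean_pairwise_corr)


def make_template(window: SampledSignal) -> BeatTemplate:
    """Full template construction for one analysis window.

    detect -> segment -> correlation filter -> ensemble average + detrend.
    """
    detections = detect_beats(window)
    segments = segment_beats(window, detections)
    kept, overall = filter_segments(segments)
    return build_template(kept, window.fs, detections.median_bbi, overall)


# ---------------------------------------------------------------------------
# Analysis intervals
# ---------------------------------------------------------------------------

INTERVALS = ("BL", "ST1", "ST2")
INTERVAL_OFFSETS = {"BL": -30.0, "ST1": 20.0, "ST2": 40.0}
INTERVAL_DURATION = 10.0


def interval_starts(t_cpt: float) -> dict[str, float]:
    """Start times of the three 10 s analysis windows around immersion:
    baseline at ``t_cpt - 30 s``, stimulation windows at ``t_cpt + 20 s``
    and ``t_cpt + 40 s``."""
    return {name: t_cpt + off for name, off in INTERVAL_OFFSETS.items()}


def extract_interval(signal: SampledSignal, start: float,
                     duration: float = INTERVAL_DURATION) -> SampledSignal:
    """Extract one analysis window; errors if it leaves the record."""
    return signal.slice_time(start, duration)
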