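"""ECG preprocessing: denoising, QRS detection, RR extraction and cleaning.

The processing chain mirrors standard ambulatory-HRV practice: a median-filter
baseline estimate is subtracted and the residual smoothed with a short moving
average; R peaks are found with a difference-threshold detector
(differentiate -> square -> moving-window integrate -> adaptive threshold);
successive R-peak times yield the RR tachogram, which is screened for
artifacts with a moving-median / scaled-MAD rule and repaired by linear
interpolation between surrounding normal intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

#: per-interval quality flags
FLAG_NORMAL = "normal"
FLAG_OUTLIER = "outlier_replaced"

# MAD -> sigma for Gaussian data, the convention used by moving-median
# outlier screens (Matlab filloutliers' "movmedian" method).
MAD_SCALE = 1.4826


@dataclass(frozen=True)
class ECGRecord:
    """Single-lead sampled ECG.

    Parameters
    ----------
    samples : voltage series in microvolts.
    fs : sampling frequency, Hz (study hardware: 256 Hz).
    annotations : optional ground-truth beat times in seconds (used by the
        synthetic generator and by detector-validation code).
    channel_label : free-text lead name.
    """

    samples: np.ndarray
    fs: float
    annotations: np.ndarray | None = None
    channel_label: str = "ECG"

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if not self.fs > 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if not np.all(np.isfinite(samples)):
            raise ValueError("ECG samples must be finite")
        if self.annotations is not None:
            ann = np.asarray(self.annotations, dtype=float)
            object.__setattr__(self, "annotations", ann)
            if ann.size and np.any(np.diff(ann) <= 0):
                raise ValueError("annotations must be strictly increasing")
            if ann.size and (ann[0] < 0 or ann[-1] > self.duration):
                raise ValueError("annotations must lie within the record span")

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return len(self.samples) / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.fs


@dataclass(frozen=True)
class RRSeries:
    """Ordered beat times (s) and normal-to-normal intervals (ms).

    ``intervals[i]`` spans ``beat_times[i] .. beat_times[i+1]``.  For a series
    that has not been artifact-repaired (all flags ``normal``) the intervals
    are exactly the successive beat-time differences; after cleaning,
    interpolated intervals no longer match raw beat times, which is why
    consistency is only enforced on fully-normal series.
    """

    beat_times: np.ndarray
    intervals: np.ndarray
    flags: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        bt = np.asarray(self.beat_times, dtype=float)
        iv = np.asarray(self.intervals, dtype=float)
        object.__setattr__(self, "beat_times", bt)
        object.__setattr__(self, "intervals", iv)
        if self.flags is None:
            object.__setattr__(self, "flags", np.full(iv.shape, FLAG_NORMAL, dtype=object))
        else:
            fl = np.asarray(self.flags, dtype=object)
            object.__setattr__(self, "flags", fl)
            if fl.shape != iv.shape:
                raise ValueError("flags must align with intervals")
        if len(iv) != len(bt) - 1:
            raise ValueError("need len(intervals) == len(beat_times) - 1")
        if np.any(np.diff(bt) <= 0):
            raise ValueError("beat times must be strictly increasing")
        if np.any(iv <= 0):
            raise ValueError("all RR intervals must be positive")
        if np.all(self.flags == FLAG_NORMAL):
            expected = np.diff(bt) * 1000.0
            if not np.allclose(iv, expected, rtol=1e-9, atol=1e-6):
                raise ValueError("intervals inconsistent with beat times")

    @property
    def n_intervals(self) -> int:
        return len(self.intervals)

    @property
    def span(self) -> float:
        """Time covered by the series, seconds."""
        return float(self.beat_times[-1] - self.beat_times[0])


def _odd_window_samples(window_ms: float, fs: float) -> int:
    n = max(1, int(round(window_ms / 1000.0 * fs)))
    return n if n % 2 == 1 else n + 1


def denoise(record: ECGRecord, median_window_ms: float = 600.0,
            ma_window_ms: float = 20.0) -> ECGRecord:
    """Remove baseline wander and high-frequency noise.

    Baseline (drift, electrode artifact) is estimated with a median filter
    wide enough not to track the QRS complex and subtracted; powerline and
    EMG noise are attenuated with a short centered moving average.  Edges are
    handled by reflection; length and sampling rate are preserved.
    """
    x = record.samples
    n_med = _odd_window_samples(median_window_ms, record.fs)
    n_ma = _odd_window_samples(ma_window_ms, record.fs)
    if max(n_med, n_ma) > len(x):
        raise ValueError("filter window longer than the record")
    baseline = ndimage.median_filter(x, size=n_med, mode="reflect")
    detrended = x - baseline
    kernel = np.ones(n_ma) / n_ma
    padded = np.pad(detrended, n_ma // 2, mode="reflect")
    smoothed = np.convolve(padded, kernel, mode="valid")
    return replace(record, samples=smoothed)


def detect_qrs(record: ECGRecord, threshold_fraction: float = 0.4,
               refractory_ms: float = 250.0,
               integration_window_ms: float = 120.0) -> np.ndarray:
    """Difference-threshold QRS detection; returns beat times in seconds.

    The signal is differentiated, squared and integrated over a short moving
    window; an adaptive threshold follows a decaying running peak of the
    integrated signal, so detection is invariant to overall amplitude
    scaling.  Within each supra-threshold region the beat time is the argmax
    of the input signal.  Beats closer than the refractory period are merged,
    keeping the one with the larger integrated response.
    """
    x = record.samples
    fs = record.fs
    if record.duration < 2.0:
        raise ValueError("record shorter than 2 s")
    if np.std(x) == 0:
        logger.warning("flat-line ECG: no beats detected")
        return np.array([])

    diff = np.diff(x)
    sq = diff * diff
    n_int = max(1, int(round(integration_window_ms / 1000.0 * fs)))
    integ = np.convolve(sq, np.ones(n_int) / n_int, mode="same")

    # running peak with ~2 s exponential decay
    decay = float(np.exp(-1.0 / (2.0 * fs)))
    peak = float(np.max(integ[: int(2 * fs)]))
    thresh = np.empty_like(integ)
    p = peak
    for i in range(len(integ)):
        v = integ[i]
        p = v if v > p else p * decay
        thresh[i] = p
    above = integ > threshold_fraction * thresh

    # contiguous supra-threshold regions
    padded = np.concatenate(([False], above, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)  # exclusive

    half = n_int // 2
    cands: list[tuple[int, float]] = []
    for s, e in zip(starts, ends):
        lo = max(0, s - half)
        hi = min(len(x), e + 1)
        idx = lo + int(np.argmax(x[lo:hi]))
        strength = float(np.max(integ[s:e]))
        cands.append((idx, strength))

    # refractory enforcement
    refr = refractory_ms / 1000.0 * fs
    kept: list[tuple[int, float]] = []
    for idx, strength in sorted(cands):
        if kept and idx - kept[-1][0] < refr:
            if strength > kept[-1][1]:
                kept[-1] = (idx, strength)
        else:
            kept.append((idx, strength))
    return np.array([i / fs for i, _ in kept])


def extract_rr(beat_times: np.ndarray) -> RRSeries:
    """Successive beat-time differences as an RR series (ms)."""
    bt = np.asarray(beat_times, dtype=float)
    if len(bt) < 2:
        raise ValueError("need at least 2 beats to form RR intervals")
    if np.any(np.diff(bt) <= 0):
        raise ValueError("beat times must be strictly increasing")
    return RRSeries(beat_times=bt, intervals=np.diff(bt) * 1000.0)


def _moving_median_mad(x: np.ndarray, window: int) -> tuple[np.ndarray, np.ndarray]:
    n = len(x)
    half = window // 2
    med = np.empty(n)
    mad = np.empty(n)
    for i in range(n):
        w = x[max(0, i - half): min(n, i + half + 1)]
        m = np.median(w)
        med[i] = m
        mad[i] = np.median(np.abs(w - m))
    return med, mad


def clean_rr(rr: RRSeries, window: int = 11, n_mad: float = 3.0,
             bounds_ms: tuple[float, float] = (250.0, 2000.0),
             max_iter: int = 5) -> RRSeries:
    """Screen RR outliers and repair them by linear interpolation.

    An interval is an outlier if it deviates from the moving median of its
    ``window``-beat neighborhood by more than ``n_mad`` scaled MADs, or falls
    outside the physiological bounds.  Outliers are replaced by linear
    interpolation between the nearest normal neighbors (nearest-value
    extension at the edges).  The screen-and-repair pass is iterated to
    convergence (clustered artifacts inflate the local MAD and can mask each
    other on a single pass).  Beat times are kept as detected; only the
    interval values and flags change.
    """
    x = rr.intervals.copy()
    if len(x) < 3:
        raise ValueError("need at least 3 intervals to screen outliers")
    flags = rr.flags.copy()
    idx = np.arange(len(x))
    for _ in range(max_iter):
        med, mad = _moving_median_mad(x, window)
        out = np.abs(x - med) > n_mad * MAD_SCALE * mad
        out |= (x < bounds_ms[0]) | (x > bounds_ms[1])
        if out.all():
            raise ValueError("all intervals flagged as outliers; "
                             "nothing to interpolate from")
        if not out.any():
            break
        x[out] = np.interp(idx[out], idx[~out], x[~out])
        flags = np.where(out, FLAG_OUTLIER, flags).astype(object)
    return RRSeries(rr.beat_times.copy(), x, flags)


def ecg_to_rr(record: ECGRecord, median_window_ms: float = 600.0,
              ma_window_ms: float = 20.0, threshold_fraction: float = 0.4,
              refractory_ms: float = 250.0, clean: bool = True,
              window: int = 11, n_mad: float = 3.0) -> RRSeries:
    """Full chain: denoise -> detect QRS -> extract RR -> clean."""
    denoised = denoise(record, median_window_ms, ma_window_ms)
    beats = detect_qrs(denoised, threshold_fraction, refractory_ms)
    rr = extract_rr(beats)
    if clean and rr.n_intervals >= 3:
        rr = clean_rr(rr, window=window, n_mad=n_mad)
    return rr
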