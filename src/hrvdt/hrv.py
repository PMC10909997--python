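"""HRV feature extraction: time-domain indices and AR-spectrum band powers.

Time domain: meanHR, SDNN, NN50, pNN50, RMSSD over the normal-to-normal
intervals of one recording window.  Frequency domain: the tachogram is
mean-removed, cubic-interpolated to an even 4 Hz grid, fitted with a Burg
autoregressive model, and the AR power spectral density is integrated over
the conventional VLF (0.003-0.040 Hz), LF (0.040-0.150 Hz) and HF
(0.150-0.400 Hz) bands; normalized powers and the LF/HF ratio follow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from statsmodels.regression.linear_model import burg

from .ecg import RRSeries

VLF_BAND = (0.003, 0.040)
LF_BAND = (0.040, 0.150)
HF_BAND = (0.150, 0.400)

#: column order used by every writer, mirroring the study's feature labels
FEATURE_COLUMNS = ("meanHR", "SDNN", "NN50", "pNN50", "RMSSD",
                   "aVLF", "aLF", "aHF", "aTotal", "LF_HF", "nLF", "nHF")


@dataclass(frozen=True)
class HRVTimeFeatures:
    meanHR: float   # beats/min, mean of instantaneous 60000/RR
    SDNN: float     # ms, sample SD of NN intervals
    NN50: int       # successive differences > 50 ms
    pNN50: float    # %, NN50 / (n - 1) * 100
    RMSSD: float    # ms, RMS of successive differences

    def __post_init__(self):
        if self.SDNN < 0 or self.RMSSD < 0:
            raise ValueError("SDNN and RMSSD must be non-negative")
        if not 0 <= self.pNN50 <= 100:
            raise ValueError("pNN50 must be a percentage")


@dataclass(frozen=True)
class HRVFreqFeatures:
    """Band powers in ms^2 plus derived ratios.

    ``LF_HF`` is NaN when HF is zero (undefined, not infinite).  The
    constructor enforces the algebraic identities Total = VLF + LF + HF and
    nLF + nHF = 1.
    """

    VLF: float
    LF: float
    HF: float
    Total: float
    LF_HF: float
    nLF: float
    nHF: float

    def __post_init__(self):
        if min(self.VLF, self.LF, self.HF) < 0:
            raise ValueError("band powers must be non-negative")
        if self.Total > 0 and abs(self.Total - (self.VLF + self.LF + self.HF)) > 1e-6 * self.Total:
            raise ValueError("Total must equal VLF + LF + HF")
        if self.LF + self.HF > 0 and abs(self.nLF + self.nHF - 1.0) > 1e-9:
            raise ValueError("nLF + nHF must equal 1")


@dataclass(frozen=True)
class PowerSpectrum:
    frequencies: np.ndarray   # Hz, covers [0, resample_fs / 2]
    density: np.ndarray       # one-sided PSD, ms^2/Hz
    ar_order: int
    resample_fs: float

    def __post_init__(self):
        f = np.asarray(self.frequencies, dtype=float)
        d = np.asarray(self.density, dtype=float)
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "density", d)
        if np.any(d < 0):
            raise ValueError("AR spectral density must be non-negative")
        if f[0] > 0 or f[-1] < self.resample_fs / 2 - 1e-9:
            raise ValueError("frequency grid must cover [0, fs/2]")


@dataclass(frozen=True)
class HRVConfig:
    """Spectral-analysis settings; defaults suit 5-min recording windows."""

    ar_order: int = 16
    resample_fs: float = 4.0
    n_freq: int = 2049           # PSD grid points on [0, fs/2]
    select_order_aic: bool = False
    max_aic_order: int = 32
    mean_hr_instantaneous: bool = True


def time_domain(rr: RRSeries) -> HRVTimeFeatures:
    """The five time-domain indices over one window.

    meanHR averages the instantaneous rate 60000/RR_i (set
    ``mean_hr_instantaneous=False`` in :class:`HRVConfig` and use
    :func:`hrv_features` for the 60000/mean(RR) convention); SDNN uses the
    sample (n-1) denominator; NN50 counts strict exceedances of 50 ms.
    """
    x = rr.intervals
    if len(x) < 2:
        raise ValueError("need at least 2 intervals")
    diffs = np.abs(np.diff(x))
    nn50 = int(np.sum(diffs > 50.0))
    return HRVTimeFeatures(
        meanHR=float(np.mean(60000.0 / x)),
        SDNN=float(np.std(x, ddof=1)),
        NN50=nn50,
        pNN50=100.0 * nn50 / len(diffs),
        RMSSD=float(np.sqrt(np.mean(np.diff(x) ** 2))),
    )


def resample_tachogram(rr: RRSeries, fs: float = 4.0) -> np.ndarray:
    """Cubic-interpolate the tachogram to an even grid; mean removed."""
    t = rr.beat_times[1:]          # interval i is attributed to its end beat
    x = rr.intervals
    if len(x) < 4:
        raise ValueError("need at least 4 intervals to interpolate")
    spline = CubicSpline(t, x)
    grid = np.arange(t[0], t[-1], 1.0 / fs)
    y = spline(grid)
    return y - np.mean(y)


def ar_spectrum(rr: RRSeries, ar_order: int = 16, resample_fs: float = 4.0,
                n_freq: int = 2049, min_span_s: float = 60.0) -> PowerSpectrum:
    """Burg autoregressive PSD of the evenly-resampled tachogram.

    The one-sided density integrates to the AR innovation-implied process
    variance, which tracks the resampled series variance (the usual AR
    power normalization).  A zero-variance input returns an all-zero
    spectrum rather than failing the fit.
    """
    if rr.span < min_span_s:
        raise ValueError(
            f"series spans {rr.span:.1f} s; need >= {min_span_s:.0f} s for spectral analysis")
    y = resample_tachogram(rr, resample_fs)
    if ar_order >= len(y) / 2:
        raise ValueError("ar_order must be below half the resampled length")
    freqs = np.linspace(0.0, resample_fs / 2, n_freq)
    if np.var(y) < 1e-12:
        return PowerSpectrum(freqs, np.zeros_like(freqs), ar_order, resample_fs)
    try:
        rho, sigma2 = burg(y, order=ar_order, demean=False)
    except Exception as exc:  # singular normal equations etc.
        raise RuntimeError(f"AR fit failed at the Burg stage: {exc}") from exc
    # one-sided PSD: sigma2 / fs / |1 - sum rho_k z^-k|^2, doubled for f > 0
    k = np.arange(1, ar_order + 1)
    z = np.exp(-2j * math.pi * np.outer(freqs / resample_fs, k))
    denom = np.abs(1.0 - z @ rho) ** 2
    if np.any(denom < 1e-300):
        raise RuntimeError("AR fit unstable: spectral denominator vanishes")
    psd = 2.0 * sigma2 / resample_fs / denom
    return PowerSpectrum(freqs, psd, ar_order, resample_fs)


def select_ar_order_aic(rr: RRSeries, resample_fs: float = 4.0,
                        max_order: int = 32) -> int:
    """AIC-minimizing Burg order for the resampled tachogram."""
    y = resample_tachogram(rr, resample_fs)
    n = len(y)
    best, best_aic = 1, np.inf
    for p in range(1, max_order + 1):
        _, sigma2 = burg(y, order=p, demean=False)
        aic = n * np.log(sigma2) + 2 * p
        if aic < best_aic:
            best, best_aic = p, aic
    return best


def _band_integral(freqs: np.ndarray, density: np.ndarray,
                   lo: float, hi: float) -> float:
    """Trapezoidal integral over [lo, hi] with interpolated edge points."""
    inside = (freqs > lo) & (freqs < hi)
    f = np.concatenate(([lo], freqs[inside], [hi]))
    d = np.concatenate(([np.interp(lo, freqs, density)], density[inside],
                        [np.interp(hi, freqs, density)]))
    return float(np.trapezoid(d, f))


def band_powers(spec: PowerSpectrum) -> HRVFreqFeatures:
    """Integrate the PSD over the VLF/LF/HF bands and form the ratios."""
    if spec.frequencies[-1] < HF_BAND[1]:
        raise ValueError("spectrum grid must span at least [0, 0.4] Hz")
    vlf = _band_integral(spec.frequencies, spec.density, *VLF_BAND)
    lf = _band_integral(spec.frequencies, spec.density, *LF_BAND)
    hf = _band_integral(spec.frequencies, spec.density, *HF_BAND)
    total = vlf + lf + hf
    lf_hf = lf / hf if hf > 0 else float("nan")
    if lf + hf > 0:
        nlf = lf / (lf + hf)
        nhf = hf / (lf + hf)
    else:
        nlf = nhf = float("nan")
    return HRVFreqFeatures(VLF=vlf, LF=lf, HF=hf, Total=total,
                           LF_HF=lf_hf, nLF=nlf, nHF=nhf)


def hrv_features(rr: RRSeries, config: HRVConfig = HRVConfig()
                 ) -> tuple[HRVTimeFeatures, HRVFreqFeatures]:
    """Complete feature bundle for one recording window."""
    td = time_domain(rr)
    if not config.mean_hr_instantaneous:
        td = HRVTimeFeatures(meanHR=60000.0 / float(np.mean(rr.intervals)),
                             SDNN=td.SDNN, NN50=td.NN50, pNN50=td.pNN50,
                             RMSSD=td.RMSSD)
    order = (select_ar_order_aic(rr, config.resample_fs, config.max_aic_order)
             if config.select_order_aic else config.ar_order)
    spec = ar_spectrum(rr, order, config.resample_fs, config.n_freq)
    return td, band_powers(spec)


def features_as_dict(td: HRVTimeFeatures, fd: HRVFreqFeatures) -> dict[str, float]:
    """Flatten the two bundles using the study's column labels."""
    return {"meanHR": td.meanHR, "SDNN": td.SDNN, "NN50": td.NN50,
            "pNN50": td.pNN50, "RMSSD": td.RMSSD,
            "aVLF": fd.VLF, "aLF": fd.LF, "aHF": fd.HF, "aTotal": fd.Total,
            "LF_HF": fd.LF_HF, "nLF": fd.nLF, "nHF": fd.nHF}
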