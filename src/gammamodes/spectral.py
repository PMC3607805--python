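"""Multitaper spectral estimation, band-pass filtering and Hilbert phase.

Power spectra are estimated with the multitaper (Thomson) method: each
500 ms data window is multiplied by K = 5 orthogonal Slepian (DPSS) tapers
of time-bandwidth product NW = 3, zero-padded to 512 samples, Fourier
transformed, and the squared magnitudes are averaged over tapers, sliding
windows and trials,

    S(f) = (1/N) sum_n s_n(f),   s_n(f) = (1/K) sum_k |X_{n,k}(f)|^2 .

K = 2 NW - 1 uses the tapers with near-unit energy concentration, and the
resolution half-bandwidth is NW / T = 6 Hz for the default 0.5 s window.
Signals are assumed sampled at 1 kHz (the analysis binning of the
simulator), so the 512-point padding slightly oversamples the frequency
axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.fft import rfft, rfftfreq
from scipy.signal import butter, filtfilt, hilbert, lfilter
from scipy.signal.windows import dpss

__all__ = [
    "SpectrumConfig",
    "PowerSpectrumEstimate",
    "PhaseTrace",
    "multitaper_psd",
    "bandpass",
    "hilbert_phase",
    "spectral_peak",
    "GAMMA_BAND",
]

#: Gamma frequency band (Hz).
GAMMA_BAND = (30.0, 90.0)


@dataclass(frozen=True)
class SpectrumConfig:
    """Multitaper estimator settings.

    ``window_overlap_ms`` is the overlap between consecutive windows; the
    hop is therefore ``window_ms - window_overlap_ms`` (450 ms under the
    defaults).
    """

    window_ms: float = 500.0
    window_overlap_ms: float = 50.0
    n_tapers: int = 5
    nw: float = 3.0
    pad_samples: int = 512
    fs_hz: float = 1000.0

    def __post_init__(self) -> None:
        if self.n_tapers > 2 * self.nw - 1:
            raise ValueError("require K <= 2*NW - 1 for well-concentrated tapers")
        if self.pad_samples < self.window_samples:
            raise ValueError("pad length must be >= window length")

    @property
    def window_samples(self) -> int:
        return int(round(self.window_ms * self.fs_hz / 1000.0))

    @property
    def hop_samples(self) -> int:
        return int(round((self.window_ms - self.window_overlap_ms) * self.fs_hz / 1000.0))

    @property
    def half_bandwidth_hz(self) -> float:
        """Spectral resolution half-bandwidth NW / T in Hz."""
        return self.nw / (self.window_ms / 1000.0)


@dataclass
class PowerSpectrumEstimate:
    """Trial-averaged multitaper power spectral density.

    ``psd`` is one-sided in signal-units^2 per Hz; ``trial_psd`` holds the
    per-trial estimates s_n(f) whose arithmetic mean is ``psd``.
    """

    freqs: np.ndarray
    psd: np.ndarray
    trial_psd: np.ndarray
    half_bandwidth_hz: float
    config: SpectrumConfig


@dataclass
class PhaseTrace:
    """Instantaneous phase of a band-limited signal.

    Convention: phase 0 at signal maxima, pi at troughs (the angle of the
    analytic signal of the band-passed trace).
    """

    t: np.ndarray
    phase: np.ndarray
    band: tuple
    fs_hz: float

    def at(self, times: np.ndarray) -> np.ndarray:
        """Phase at arbitrary times by interpolating the unwrapped phase."""
        unwrapped = np.unwrap(self.phase)
        return np.mod(np.interp(times, self.t, unwrapped), 2.0 * np.pi)


def _segment_starts(n: int, cfg: SpectrumConfig) -> np.ndarray:
    win, hop = cfg.window_samples, cfg.hop_samples
    if n < win:
        raise ValueError("trace shorter than one analysis window")
    return np.arange(0, n - win + 1, hop)


def multitaper_psd(traces, config: SpectrumConfig | None = None) -> PowerSpectrumEstimate:
    """Multitaper PSD averaged over tapers, sliding windows and trials.

    ``traces`` is one trace or a sequence of per-trial traces sampled at
    ``config.fs_hz``.  The mean is removed per window; tapers have unit
    energy so that the integrated PSD of a white signal matches its
    variance (one-sided scaling 2/fs away from DC/Nyquist).
    """
    cfg = config or SpectrumConfig()
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    win = cfg.window_samples
    tapers = dpss(win, cfg.nw, cfg.n_tapers)           # (K, win), unit energy
    freqs = rfftfreq(cfg.pad_samples, 1.0 / cfg.fs_hz)
    scale = np.full(len(freqs), 2.0 / cfg.fs_hz)
    scale[0] = 1.0 / cfg.fs_hz
    if cfg.pad_samples % 2 == 0:
        scale[-1] = 1.0 / cfg.fs_hz
    trial_psd = np.zeros((traces.shape[0], len(freqs)))
    for n, trace in enumerate(traces):
        starts = _segment_starts(len(trace), cfg)
        acc = np.zeros(len(freqs))
        for s in starts:
            seg = trace[s : s + win]
            seg = seg - seg.mean()
            spec = rfft(tapers * seg[None, :], n=cfg.pad_samples, axis=1)
            acc += (np.abs(spec) ** 2).mean(axis=0)
        trial_psd[n] = scale * acc / len(starts)
    return PowerSpectrumEstimate(
        freqs, trial_psd.mean(axis=0), trial_psd, cfg.half_bandwidth_hz, cfg
    )


def bandpass(
    trace: np.ndarray,
    center_hz: float,
    half_width_hz: float = 5.0,
    order: int = 4,
    fs_hz: float = 1000.0,
    zero_phase: bool = True,
) -> np.ndarray:
    """Butterworth band-pass around ``center_hz``.

    Zero-phase (forward-backward) application by default so that filtering
    does not displace spike-phase relations; ``zero_phase=False`` gives the
    plain one-pass filter with its group delay.
    """
    lo, hi = center_hz - half_width_hz, center_hz + half_width_hz
    nyq = fs_hz / 2.0
    if not 0 < lo < hi < nyq:
        raise ValueError("band must lie strictly inside (0, Nyquist)")
    b, a = butter(order, [lo / nyq, hi / nyq], btype="bandpass")
    trace = np.asarray(trace, dtype=float)
    if zero_phase:
        return filtfilt(b, a, trace)
    return lfilter(b, a, trace)


def hilbert_phase(
    filtered: np.ndarray,
    fs_hz: float = 1000.0,
    band: tuple = (0.0, 0.0),
) -> PhaseTrace:
    """Instantaneous phase of a band-limited trace via the analytic signal.

    Phase 0 corresponds to local maxima of the trace and pi to troughs.
    """
    analytic = hilbert(np.asarray(filtered, dtype=float) - np.mean(filtered))
    phase = np.mod(np.angle(analytic), 2.0 * np.pi)
    t = np.arange(len(filtered)) * 1000.0 / fs_hz
    return PhaseTrace(t, phase, band, fs_hz)


@dataclass
class SpectralPeak:
    """Result of band-limited peak detection."""

    freq_hz: float
    power: float
    has_peak: bool
    trend_ratio: float


def _log_trend(freqs, psd, band, fit_lo=(10.0, None), fit_hi=(None, 200.0)):
    """Power-law trend fitted in log-log space on the band's flanks."""
    lo_band, hi_band = band
    lo_lo = fit_lo[0]
    hi_hi = min(fit_hi[1], freqs.max())
    mask = (
        ((freqs >= lo_lo) & (freqs < lo_band))
        | ((freqs > hi_band) & (freqs <= hi_hi))
    ) & (psd > 0)
    if mask.sum() < 4:
        return None
    x, y = np.log(freqs[mask]), np.log(psd[mask])
    slope, intercept = np.polyfit(x, y, 1)
    return lambda f: np.exp(intercept + slope * np.log(f))


#: Peak must exceed the fitted 1/f^a flank trend by this factor to count.
PEAK_TREND_FACTOR = 2.0


def spectral_peak(
    spectrum: PowerSpectrumEstimate,
    band: tuple = GAMMA_BAND,
    trend_factor: float = PEAK_TREND_FACTOR,
) -> SpectralPeak:
    """Arg-max of the PSD within ``band``, with a no-peak flag.

    The band maximum only counts as an oscillatory peak when it is a local
    maximum interior to the band and exceeds, by ``trend_factor``, a
    power-law trend fitted to the spectrum's flanks; otherwise the band
    maximum merely rides the 1/f-like background.
    """
    freqs, psd = spectrum.freqs, spectrum.psd
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    if not np.any(in_band):
        raise ValueError("band outside the frequency grid")
    idx = np.nonzero(in_band)[0]
    i_max = idx[np.argmax(psd[idx])]
    f_pk, p_pk = float(freqs[i_max]), float(psd[i_max])
    interior = idx[0] < i_max < idx[-1]
    local_max = (
        interior and psd[i_max] >= psd[i_max - 1] and psd[i_max] >= psd[i_max + 1]
    )
    trend = _log_trend(freqs, psd, band)
    ratio = p_pk / trend(f_pk) if trend is not None else np.inf
    return SpectralPeak(f_pk, p_pk, bool(local_max and ratio > trend_factor), float(ratio))
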