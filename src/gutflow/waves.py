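"""Oscillation-wave detection and the strength / gross / frequency metrics.

A "wave" is one crest with its following trough. Contraction strength on a
channel (Ps on pressure, Ls on longitudinal position, EWs on a diameter
channel, Vs on volume) is the algebraic sum of the crest-to-trough amplitudes
of the detected waves divided by their number. The gross level (Pg, Lg, EWg,
Vg) is the plain arithmetic mean of the trace over an interval, and its
change between adjacent intervals.

Detection is deliberately simple and oracle-checkable: strict local extrema
on the (optionally smoothed) trace, with sub-threshold ripples merged into
their neighbours by repeatedly deleting the adjacent extremum pair of
smallest height difference until every remaining swing is at least
``min_amplitude``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .errors import ParameterError
from .recording import TimeSeriesChannel

#: channel-family default minimum crest-to-trough amplitude
MIN_AMPLITUDE_DEFAULTS = {
    "pressure": 0.03,      # cmH2O, the low-amplitude noise floor
    "ew1": 0.02, "ew2": 0.02, "ew3": 0.02, "ew4": 0.02,   # mm
    "longitudinal": 0.02,  # mm
    "volume": 0.5,         # mm3, no printed value; configurable
}

#: smoothing window (s) applied before extremum detection on fast channels
SMOOTH_WINDOW_FAST = 0.15
#: sampling intervals at or below this are "fast" and get smoothed by default
FAST_DT = 0.01


@dataclass(frozen=True)
class Wave:
    """One detected oscillation on a channel."""

    channel_id: str
    crest_time: float
    crest_value: float
    trough_time: float
    trough_value: float
    wavelength: float | None = None  # crest-to-next-crest, s; None for the last wave

    @property
    def amplitude(self) -> float:
        return self.crest_value - self.trough_value


@dataclass(frozen=True)
class AmplitudeClass:
    """Pressure-wave amplitude classes: low in [low_min, high_min), high above."""

    low_min: float = 0.03   # cmH2O
    high_min: float = 0.2   # cmH2O

    def __post_init__(self):
        if not (0 <= self.low_min < self.high_min):
            raise ParameterError("require 0 <= low_min < high_min")

    def label(self, amplitude: float) -> str:
        if amplitude >= self.high_min:
            return "high"
        if amplitude >= self.low_min:
            return "low"
        return "sub"


@dataclass(frozen=True)
class StrengthMetrics:
    """Per-window wave-amplitude summary (houses Ps/Ls/EWs/Vs)."""

    channel_id: str
    S: float
    n_waves: int
    frequency_hz: float


@dataclass(frozen=True)
class GrossMetrics:
    """Within-interval mean level and its change from the previous interval."""

    channel_id: str
    G_mean: float
    G_delta: float | None = None


@dataclass(frozen=True)
class SpectrumFit:
    """Amplitude spectrum above a high-pass cutoff with an Exp3P2 envelope fit.

    The envelope model is ``a * exp(b*f + c*f**2)`` fitted to the spectrum
    points at or above ``amp_threshold``.
    """

    frequencies: np.ndarray
    amplitudes: np.ndarray
    hp_cutoff: float
    amp_threshold: float
    peak_frequency: float
    fit_params: tuple[float, float, float] | None

    @property
    def fit_available(self) -> bool:
        return self.fit_params is not None

    def envelope(self, f: np.ndarray) -> np.ndarray:
        if self.fit_params is None:
            raise ParameterError("envelope fit unavailable")
        a, b, c = self.fit_params
        return a * np.exp(b * np.asarray(f) + c * np.asarray(f) ** 2)

    @property
    def fit_peak_frequency(self) -> float:
        """Mode of the fitted envelope (finite only when it opens downward)."""
        if self.fit_params is None:
            raise ParameterError("envelope fit unavailable")
        a, b, c = self.fit_params
        if c >= 0:
            return math.nan
        return -b / (2 * c)


# ---------------------------------------------------------------------------
# extremum detection
# ---------------------------------------------------------------------------


def _alternating_extrema(y: np.ndarray) -> list[tuple[int, float, str]]:
    """Strict local extrema as (index, value, 'max'|'min'), alternating.

    Plateaus count once, at their first sample. Endpoints are not extrema
    (a wave needs both its crest and trough strictly inside the window).
    """
    # collapse runs of equal values, keeping the first index of each run
    keep = np.empty(y.size, dtype=bool)
    keep[0] = True
    np.not_equal(y[1:], y[:-1], out=keep[1:])
    idx = np.flatnonzero(keep)
    z = y[idx]
    if z.size < 3:
        return []
    d = np.sign(np.diff(z))
    flips = np.flatnonzero(d[1:] != d[:-1]) + 1
    return [
        (int(idx[i]), float(z[i]), "max" if d[i - 1] > 0 else "min") for i in flips
    ]


def _merge_ripples(ext: list[tuple[int, float, str]],
                   min_amplitude: float) -> list[tuple[int, float, str]]:
    """Delete adjacent extremum pairs of height difference < min_amplitude.

    Repeatedly removes the (leftmost) adjacent pair with the smallest height
    difference while that difference is below threshold; removing a pair from
    an alternating sequence keeps it alternating, so small ripples collapse
    into the surrounding larger swing.
    """
    ext = list(ext)
    while len(ext) >= 2:
        diffs = [abs(ext[i + 1][1] - ext[i][1]) for i in range(len(ext) - 1)]
        j = int(np.argmin(diffs))
        if diffs[j] >= min_amplitude:
            break
        del ext[j:j + 2]
    return ext


def _smooth(y: np.ndarray, width: int) -> np.ndarray:
    """Centered moving average with edge truncation."""
    if width <= 1:
        return y
    kernel = np.ones(width)
    return np.convolve(y, kernel, mode="same") / np.convolve(
        np.ones_like(y), kernel, mode="same"
    )


def detect_waves(channel: TimeSeriesChannel,
                 window: tuple[float, float] | None = None,
                 min_amplitude: float | None = None,
                 smooth_window: float | None = None) -> list[Wave]:
    """Detect crest/trough waves on a channel within a time window.

    Parameters
    ----------
    window : (start, end) or None
        Analysis window, seconds, half-open; defaults to the whole channel.
    min_amplitude : float
        Ripples with crest-to-trough swing below this are merged away.
        Defaults per channel family (pressure 0.03 cmH2O, mm channels
        0.02 mm, volume 0.5 mm3).
    smooth_window : float or None
        Moving-average width in seconds applied before detection. By default
        0.15 s on fast channels (dt <= 10 ms); none on video-rate channels.

    Returns
    -------
    list of :class:`Wave`, ordered by crest time. Each wave pairs a crest
    with its *following* trough; half-waves at the window edges are dropped.
    """
    if min_amplitude is None:
        min_amplitude = MIN_AMPLITUDE_DEFAULTS[channel.channel_id]
    if min_amplitude < 0:
        raise ParameterError("min_amplitude must be >= 0")
    if window is None:
        window = (channel.t0, channel.end)
    t, y = channel.slice(*window)
    if smooth_window is None and channel.dt <= FAST_DT:
        smooth_window = SMOOTH_WINDOW_FAST
    if smooth_window:
        y = _smooth(y, max(1, int(round(smooth_window / channel.dt))))

    ext = _merge_ripples(_alternating_extrema(y), min_amplitude)

    crests = [(i, e) for i, e in enumerate(ext) if e[2] == "max"]
    waves = []
    for i, (ci, cv, _) in crests:
        if i + 1 >= len(ext):
            break  # crest without a following trough inside the window
        ti, tv, kind = ext[i + 1]
        assert kind == "min"
        if cv - tv < min_amplitude:
            continue  # inverted swing across a trend; not a wave
        waves.append(
            Wave(channel_id=channel.channel_id,
                 crest_time=float(t[ci]), crest_value=cv,
                 trough_time=float(t[ti]), trough_value=tv)
        )
    # crest-to-crest wavelengths
    out = []
    for k, w in enumerate(waves):
        wl = waves[k + 1].crest_time - w.crest_time if k + 1 < len(waves) else None
        out.append(Wave(w.channel_id, w.crest_time, w.crest_value,
                        w.trough_time, w.trough_value, wl))
    return out


def strength(channel: TimeSeriesChannel,
             window: tuple[float, float] | None = None,
             min_amplitude: float | None = None,
             smooth_window: float | None = None) -> StrengthMetrics:
    """Mean crest-to-trough amplitude (S) and counting frequency in a window.

    S is the algebraic sum of the individual wave amplitudes divided by the
    number of waves; the counting frequency is the number of waves divided by
    the window length. Both are 0 when no wave is detected.
    """
    if window is None:
        window = (channel.t0, channel.end)
    waves = detect_waves(channel, window, min_amplitude, smooth_window)
    duration = window[1] - window[0]
    if not waves:
        return StrengthMetrics(channel.channel_id, 0.0, 0, 0.0)
    amps = [w.amplitude for w in waves]
    return StrengthMetrics(
        channel_id=channel.channel_id,
        S=float(sum(amps) / len(amps)),
        n_waves=len(waves),
        frequency_hz=len(waves) / duration,
    )


def gross(channel: TimeSeriesChannel,
          interval: tuple[float, float],
          previous_interval: tuple[float, float] | None = None) -> GrossMetrics:
    """Mean level over an interval, and its change from a previous interval."""
    if not (interval[1] > interval[0]):
        raise ParameterError("zero-length interval")
    _, y = channel.slice(*interval)
    g = float(np.mean(y))
    delta = None
    if previous_interval is not None:
        if not (previous_interval[1] > previous_interval[0]):
            raise ParameterError("zero-length previous interval")
        if previous_interval[0] >= interval[0]:
            raise ParameterError("previous interval must start earlier")
        _, yp = channel.slice(*previous_interval)
        delta = g - float(np.mean(yp))
    return GrossMetrics(channel.channel_id, g, delta)


def normalize_longitudinal(channel: TimeSeriesChannel) -> TimeSeriesChannel:
    """Shift a longitudinal trace so its minimum is zero.

    Baseline position depends on where the pattern tracker was placed, so
    traces are compared after subtracting the smallest recorded value.
    """
    if channel.channel_id != "longitudinal":
        raise ParameterError("normalize_longitudinal expects the longitudinal channel")
    return TimeSeriesChannel(
        channel_id=channel.channel_id, t0=channel.t0, dt=channel.dt,
        values=channel.values - channel.values.min(),
    )


def classify_amplitudes(waves: list[Wave],
                        classes: AmplitudeClass | None = None) -> list[str]:
    """Label each wave 'low', 'high' or 'sub' by its crest-to-trough amplitude."""
    classes = classes or AmplitudeClass()
    return [classes.label(w.amplitude) for w in waves]


# ---------------------------------------------------------------------------
# spectral estimate
# ---------------------------------------------------------------------------


def fft_spectrum(channel: TimeSeriesChannel,
                 window: tuple[float, float] | None = None,
                 hp_cutoff: float = 0.2,
                 amp_threshold: float = 0.02,
                 min_fit_points: int = 5) -> SpectrumFit:
    """Amplitude spectrum of a trace with an Exp3P2 envelope fit.

    The trace is mean-subtracted, Hann-windowed and zero-padded to four times
    the next power of two (interpolating the spectral grid). The high-pass is
    implemented by discarding bins below ``hp_cutoff``; the amplitude scale is
    calibrated so a pure sine of amplitude A peaks at ~A. The envelope
    ``a*exp(b*f + c*f**2)`` is fitted by nonlinear least squares to the bins
    at or above ``amp_threshold``, seeded from a quadratic regression of the
    log amplitudes; with fewer than ``min_fit_points`` usable bins (or a
    failed fit) the fit is flagged unavailable and the spectrum returned.
    """
    if window is None:
        window = (channel.t0, channel.end)
    if window[1] - window[0] < 20:
        raise ParameterError("spectral window must be at least 20 s")
    _, y = channel.slice(*window)
    y = y - np.mean(y)
    n = y.size
    taper = np.hanning(n)
    nfft = 4 * (1 << int(math.ceil(math.log2(n))))
    amp = np.abs(np.fft.rfft(y * taper, n=nfft)) * 2.0 / taper.sum()
    freqs = np.fft.rfftfreq(nfft, d=channel.dt)
    mask = freqs >= hp_cutoff
    freqs, amp = freqs[mask], amp[mask]
    if freqs.size == 0:
        raise ParameterError("no spectral bins above the high-pass cutoff")
    peak = float(freqs[int(np.argmax(amp))])

    fit_params = None
    sel = amp >= amp_threshold
    if int(sel.sum()) >= min_fit_points:
        f_fit, a_fit = freqs[sel], amp[sel]
        coef = np.polyfit(f_fit, np.log(a_fit), 2)  # c f^2 + b f + log a
        p0 = (float(np.exp(coef[2])), float(coef[1]), float(coef[0]))
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(
                    lambda f, a, b, c: a * np.exp(b * f + c * f * f),
                    f_fit, a_fit, p0=p0, maxfev=10000,
                )
            if np.all(np.isfinite(popt)):
                fit_params = (float(popt[0]), float(popt[1]), float(popt[2]))
        except RuntimeError:
            fit_params = None  # non-convergence is reported, never defaulted

    return SpectrumFit(
        frequencies=freqs, amplitudes=amp, hp_cutoff=hp_cutoff,
        amp_threshold=amp_threshold, peak_frequency=peak, fit_params=fit_params,
    )
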