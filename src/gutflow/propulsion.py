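"""Anterograde / retrograde / segmental classification of diameter changes.

Works on pairs of edge-width channels sampled on one 50 ms grid. Contraction
is a diameter *decrease*. For every time step both one-step backward
differences are examined:

* proximal contracting while distal relaxes -> **anterograde** (content is
  pushed aborally, the distal segment distends to receive it);
* distal contracting while proximal relaxes -> **retrograde**;
* both moving the same way -> **segmental**, with its inclination set by
  which tracker changes less: a smaller distal decrease leans forward, a
  smaller distal increase leans backward.

The signed amplitude is ``(d_dist - d_prox) / 2`` mm per step, positive for
anterograde and negative for retrograde by construction, and equal to the
segmental inclination in the same-sign branch. A propagation call requires
*both* derivatives to exceed the noise floor: a step where only one tracker
moves carries no directional evidence and is skipped. Summed over the three
adjacent tracker pairs and normalized per slow-wave cycle this yields the
"net amplitude": > 0 net anterograde, < 0 net retrograde.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .recording import TimeSeriesChannel

KINDS = ("anterograde", "retrograde", "segmental",
         "segmental_forward", "segmental_backward")

#: default per-step noise floor, mm per 50 ms step
NOISE_FLOOR_MM = 0.005

SEGMENTAL_KINDS = frozenset({"segmental", "segmental_forward", "segmental_backward"})


@dataclass(frozen=True)
class PropulsionEvent:
    time: float
    pair: tuple[str, str]  # (proximal id, distal id)
    kind: str
    signed_amplitude: float  # mm; > 0 anterograde, < 0 retrograde

    def __post_init__(self):
        if self.kind == "anterograde" and not self.signed_amplitude > 0:
            raise ParameterError("anterograde events must carry a positive amplitude")
        if self.kind == "retrograde" and not self.signed_amplitude < 0:
            raise ParameterError("retrograde events must carry a negative amplitude")


@dataclass(frozen=True)
class NetAmplitude:
    value: float  # mm (per cycle or per minute, see normalization)
    window: tuple[float, float]
    direction: str  # anterograde | retrograde | balanced
    n_events: int = 0


def classify_pair(proximal: TimeSeriesChannel,
                  distal: TimeSeriesChannel,
                  window: tuple[float, float] | None = None,
                  noise_floor: float = NOISE_FLOOR_MM) -> list[PropulsionEvent]:
    """Per-step propagation events between one proximal/distal tracker pair.

    Both channels must share the same grid. Steps where either derivative is
    below ``noise_floor`` in magnitude emit no event.
    """
    if (proximal.dt != distal.dt or abs(proximal.t0 - distal.t0) > 1e-9
            or proximal.n != distal.n):
        raise ParameterError("proximal and distal channels must share one grid")
    if window is None:
        window = (proximal.t0, proximal.end)
    t, yp = proximal.slice(*window)
    _, yd = distal.slice(*window)
    dp = np.diff(yp)
    dd = np.diff(yd)
    ts = t[1:]
    active = (np.abs(dp) >= noise_floor) & (np.abs(dd) >= noise_floor)
    pair = (proximal.channel_id, distal.channel_id)
    events = []
    for i in np.flatnonzero(active):
        a, b = dp[i], dd[i]
        amp = (b - a) / 2.0
        if a < 0 < b:
            kind = "anterograde"
        elif b < 0 < a:
            kind = "retrograde"
        elif amp > 0:
            kind = "segmental_forward"
        elif amp < 0:
            kind = "segmental_backward"
        else:
            kind = "segmental"  # identical magnitudes: no inclination
        events.append(PropulsionEvent(float(ts[i]), pair, kind, float(amp)))
    return events


def classify_recording(rec, window=None,
                       noise_floor: float = NOISE_FLOOR_MM) -> list[PropulsionEvent]:
    """Events from the three adjacent tracker pairs (1-2, 2-3, 3-4), merged."""
    events = []
    for prox, dist in (("ew1", "ew2"), ("ew2", "ew3"), ("ew3", "ew4")):
        events.extend(classify_pair(rec.channel(prox), rec.channel(dist),
                                    window, noise_floor))
    events.sort(key=lambda e: (e.time, e.pair))
    return events


def net_amplitude(events: list[PropulsionEvent],
                  window: tuple[float, float],
                  normalization: str = "per_cycle",
                  cycle_period: float = 1.0 / 0.7) -> NetAmplitude:
    """Signed aggregate of event amplitudes over a window.

    With ``normalization='per_cycle'`` (default) the amplitude sum is divided
    by the number of slow-wave cycles in the window (``cycle_period`` s per
    cycle), yielding mm-per-cycle values; ``'per_minute'`` divides by the
    window length in minutes instead.
    """
    if not (window[1] > window[0]):
        raise ParameterError("empty window")
    duration = window[1] - window[0]
    in_win = [e for e in events if window[0] <= e.time < window[1]]
    total = sum(e.signed_amplitude for e in in_win)
    if normalization == "per_cycle":
        divisor = duration / cycle_period
    elif normalization == "per_minute":
        divisor = duration / 60.0
    else:
        raise ParameterError(f"unknown normalization {normalization!r}")
    value = total / divisor if divisor > 0 else 0.0
    if not in_win:
        value = 0.0
    direction = ("anterograde" if value > 0
                 else "retrograde" if value < 0 else "balanced")
    return NetAmplitude(value=value, window=window, direction=direction,
                        n_events=len(in_win))
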