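"""Intestinal volume reconstruction from the four edge-width channels.

The segment is modelled as four abutting cylinders, one per diameter
tracker: V = pi * sum_i h_i * d_i^2 / 4, with h_i the axial length covered
by tracker i (tracker plus half the gap to each neighbour) and d_i its
measured diameter. The result tracks volume *changes*; longitudinal
shortening and wall thickness are not separated out, so absolute values are
approximate while crest-to-trough amplitudes (Vs) and between-phase means
(Vg) are comparable across phases.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .errors import ParameterError
from .recording import MotilityRecording, TimeSeriesChannel, align_to_common_grid
from .waves import GrossMetrics, StrengthMetrics, gross, strength

EW_CHANNELS = ("ew1", "ew2", "ew3", "ew4")


def segment_volumes(rec: MotilityRecording) -> np.ndarray:
    """Per-sample, per-tracker cylinder volumes, shape (n, 4), mm^3.

    Requires the ew channels to share one grid. Samples where any diameter
    is <= 0 are returned as NaN so downstream metrics exclude them.
    """
    chans = [rec.channel(c) for c in EW_CHANNELS]
    first = chans[0]
    if any((c.dt != first.dt or c.t0 != first.t0 or c.n != first.n) for c in chans):
        raise ParameterError(
            "edge-width channels must share one grid; align_to_common_grid first"
        )
    d = np.stack([c.values for c in chans], axis=1)
    h = np.asarray(rec.geometry.h)
    vols = math.pi * h * d * d / 4.0
    vols[np.any(d <= 0, axis=1), :] = np.nan
    return vols


def compute_volume(rec: MotilityRecording, dt_target: float | None = None) -> TimeSeriesChannel:
    """Volume channel V(t) = pi * sum_i h_i d_i(t)^2 / 4 on the ew grid.

    If the ew channels are on different grids, pass ``dt_target`` to block-
    average everything onto one grid first. Invalid samples (any d_i <= 0)
    are flagged by interpolating over them is *not* done; they are carried
    as the previous valid value so the channel stays finite, and a
    ParameterError is raised if the first sample is already invalid.
    """
    if dt_target is not None:
        rec = align_to_common_grid(rec, dt_target)
    vols = segment_volumes(rec)
    v = vols.sum(axis=1)
    bad = ~np.isfinite(v)
    if bad.any():
        if bad[0]:
            raise ParameterError("volume undefined at the first sample (d <= 0)")
        # hold last valid value across flagged samples
        idx = np.where(bad, 0, np.arange(v.size))
        np.maximum.accumulate(idx, out=idx)
        v = v[idx]
    ew1 = rec.channel("ew1")
    return TimeSeriesChannel(channel_id="volume", t0=ew1.t0, dt=ew1.dt, values=v)


def volume_metrics(volume_channel: TimeSeriesChannel, phases,
                   min_amplitude: float | None = None) -> pd.DataFrame:
    """Vs (wave strength) and Vg (gross mean and between-phase delta) per phase.

    ``phases`` is a list of :class:`gutflow.phases.PhaseInterval`; the gross
    delta of each interval is taken against the interval immediately before
    it in time, and is absent for the first.
    """
    rows = []
    prev = None
    for ph in sorted(phases, key=lambda p: p.start):
        s: StrengthMetrics = strength(
            volume_channel, (ph.start, ph.end), min_amplitude=min_amplitude
        )
        g: GrossMetrics = gross(
            volume_channel, (ph.start, ph.end),
            (prev.start, prev.end) if prev is not None else None,
        )
        rows.append({
            "cycle_id": ph.cycle_id, "label": ph.label,
            "start_s": ph.start, "end_s": ph.end,
            "Vs": s.S, "n_waves": s.n_waves, "freq_hz": s.frequency_hz,
            "Vg_mean": g.G_mean, "Vg_delta": g.G_delta,
        })
        prev = ph
    return pd.DataFrame(rows)
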