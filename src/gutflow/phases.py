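"""Segmentation of the pressure trace into B / N / D / A phases.

Each high-amplitude pressure episode anchors one cycle:

* **D** ("during") — a maximal run of high-amplitude waves (crest-to-trough
  >= ``high_threshold``); runs closer than ``gap_merge`` wavelengths merge.
* **N** ("near") — the interval of rapidly rising wave amplitude leading into
  D: the terminal run of waves whose amplitude envelope exceeds
  ``rise_factor`` times the trailing baseline of the preceding quiet span.
* **A** ("after") — from the end of D until the envelope falls back below
  that same baseline threshold (or the next cycle's N onset, whichever is
  first).
* **B** ("before") — whatever remains between the previous cycle's A and the
  N onset.

Boundaries are driven by the pressure-amplitude envelope alone (a moving
median of wave amplitudes), which makes the rule deterministic and invariant
to constant pressure offsets; longitudinal criteria are reported as
supporting per-phase metrics, not used for boundaries. Intervals are
half-open [start, end) and tile the analysed window exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError
from .recording import MotilityRecording, align_to_common_grid
from .volume import compute_volume
from .waves import (MIN_AMPLITUDE_DEFAULTS, Wave, detect_waves, gross,
                    normalize_longitudinal, strength)

PHASE_ORDER = ("B", "N", "D", "A")


@dataclass(frozen=True)
class PhaseInterval:
    """One labelled [start, end) interval of a cycle."""

    label: str
    start: float
    end: float
    cycle_id: int
    partial: bool = False

    def __post_init__(self):
        if self.label not in PHASE_ORDER:
            raise ParameterError(f"unknown phase label {self.label!r}")
        if not (self.end > self.start):
            raise ParameterError("phase interval must have positive duration")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class SegmentationConfig:
    high_threshold: float = 0.2   # cmH2O, crest-to-trough; D-phase waves
    low_floor: float = 0.03       # cmH2O, detection floor
    envelope_window: float = 5.0  # s, moving-median span for the envelope
    rise_factor: float = 1.5      # N starts where envelope > rise_factor * baseline
    gap_merge: float = 2.0        # wavelengths; closer D runs merge

    def __post_init__(self):
        if not (self.high_threshold > self.low_floor > 0):
            raise ParameterError("require high_threshold > low_floor > 0")
        if not (self.rise_factor > 1):
            raise ParameterError("rise_factor must exceed 1")


def _envelope(waves: list[Wave], half_window: float) -> np.ndarray:
    """Moving median of wave amplitudes over crest times +- half_window."""
    t = np.array([w.crest_time for w in waves])
    a = np.array([w.amplitude for w in waves])
    env = np.empty_like(a)
    for i, ti in enumerate(t):
        env[i] = np.median(a[(t >= ti - half_window) & (t <= ti + half_window)])
    return env


def _mean_wavelength(waves: list[Wave]) -> float:
    gaps = [w.wavelength for w in waves if w.wavelength is not None]
    if not gaps:
        return 1.0 / 0.7  # nominal slow-wave period when only one wave exists
    return float(np.median(gaps))


def segment_phases(rec: MotilityRecording,
                   cfg: SegmentationConfig | None = None,
                   window: tuple[float, float] | None = None) -> list[PhaseInterval]:
    """Partition the recording's window into B->N->D->A intervals per cycle.

    Returns an empty list (with a warning) when no high-amplitude wave is
    present, i.e. no cycle exists. A leading B and a trailing interval cut
    by the recording edge are flagged ``partial``.
    """
    cfg = cfg or SegmentationConfig()
    pressure = rec.channel("pressure")
    if window is None:
        window = rec.common_window()
    w_start, w_end = window
    waves = detect_waves(pressure, window, min_amplitude=cfg.low_floor)
    amps = np.array([w.amplitude for w in waves])
    high = np.flatnonzero(amps >= cfg.high_threshold) if waves else np.array([], int)
    if high.size == 0:
        warnings.warn("no high-amplitude pressure wave in the window: no cycle")
        return []

    lam = _mean_wavelength(waves)
    env = _envelope(waves, cfg.envelope_window / 2)
    crest_t = np.array([w.crest_time for w in waves])

    # --- D runs: consecutive high waves; merge runs with short gaps --------
    runs: list[list[int]] = [[int(high[0])]]
    for i in high[1:]:
        # gap from the end (trough) of the last high wave to the next crest
        gap = crest_t[i] - waves[runs[-1][-1]].trough_time
        if gap < cfg.gap_merge * lam:
            runs[-1].append(int(i))
        else:
            runs.append([int(i)])

    def onset(i: int) -> float:
        """Start of wave i: trough of the previous wave, else half a period back."""
        if i > 0:
            return max(w_start, waves[i - 1].trough_time)
        return max(w_start, waves[i].crest_time - lam / 2)

    d_bounds = [(onset(r[0]), min(w_end, waves[r[-1]].trough_time)) for r in runs]

    # --- per cycle, in time order: N onset by envelope rise over the -------
    # trailing-B baseline, then A end where the envelope returns below that
    # same threshold (bounded by the next D onset, clamped to the next N).
    n_starts: list[float] = []
    thresholds: list[float] = []
    a_ends: list[float] = []
    for k, (d_start, d_end) in enumerate(d_bounds):
        region_start = a_ends[k - 1] if k > 0 else w_start
        region = [i for i in range(len(waves))
                  if region_start <= crest_t[i] < d_start]
        if not region:
            n_start = max(region_start, d_start - lam)
            thr = cfg.rise_factor * cfg.low_floor
        else:
            n_start = d_start
            thr = cfg.rise_factor * cfg.low_floor
            for _ in range(5):  # fixed point: baseline over the B span only
                base_idx = [i for i in region if crest_t[i] < n_start] or region
                baseline = float(np.median(env[base_idx]))
                thr = cfg.rise_factor * baseline
                j = len(region)
                while j > 0 and env[region[j - 1]] > thr:
                    j -= 1
                if j == len(region):      # no terminal rise: minimal N
                    new_start = max(region_start, d_start - lam)
                elif j == 0:              # whole region rising: N covers it
                    new_start = region_start
                else:
                    new_start = 0.5 * (crest_t[region[j - 1]] + crest_t[region[j]])
                if abs(new_start - n_start) < 1e-9:
                    n_start = new_start
                    break
                n_start = new_start
        n_start = min(n_start, d_start - 1e-9)
        if k > 0 and a_ends[k - 1] > n_start:
            a_ends[k - 1] = n_start  # previous A ran into this cycle's rise
        n_starts.append(n_start)
        thresholds.append(thr)

        limit = d_bounds[k + 1][0] if k + 1 < len(d_bounds) else w_end
        after = [i for i in range(len(waves)) if d_end <= crest_t[i] < limit]
        a_end = None
        for j, i in enumerate(after):
            if env[i] < thr:
                prev_t = crest_t[after[j - 1]] if j > 0 else d_end
                a_end = 0.5 * (prev_t + crest_t[i])
                break
        if a_end is None:
            a_end = limit if after else min(limit, d_end + lam)
        a_ends.append(a_end if a_end > d_end else d_end + 1e-9)

    # --- assemble contiguous intervals -------------------------------------
    intervals: list[PhaseInterval] = []
    for k, ((d_start, d_end), n_start, a_end) in enumerate(
            zip(d_bounds, n_starts, a_ends)):
        b_start = a_ends[k - 1] if k > 0 else w_start
        a_end = min(a_end, w_end)
        if n_start > b_start + 1e-12:
            intervals.append(PhaseInterval("B", b_start, n_start, k,
                                           partial=(k == 0)))
        if d_start > n_start + 1e-12:
            intervals.append(PhaseInterval("N", max(n_start, b_start), d_start, k))
        intervals.append(PhaseInterval("D", d_start, d_end, k))
        if a_end > d_end + 1e-12:
            last = k + 1 == len(d_bounds)
            partial = last and a_end >= w_end - 1e-9 and env[-1] >= thresholds[k]
            intervals.append(PhaseInterval("A", d_end, a_end, k, partial=partial))
    # trailing span after the final A belongs to the (incomplete) next cycle
    tail_start = intervals[-1].end
    if tail_start < w_end - 1e-9:
        intervals.append(PhaseInterval("B", tail_start, w_end,
                                       len(d_bounds), partial=True))
    return intervals


def phase_of(t: float, phases: list[PhaseInterval]) -> PhaseInterval | None:
    """The unique half-open interval containing t, or None."""
    for ph in phases:
        if ph.start <= t < ph.end:
            return ph
    return None


#: metric-family name -> channel id
FAMILIES = {
    "ilp": "pressure",
    "lm": "longitudinal",
    "ew1": "ew1",
    "ew4": "ew4",
    "volume": "volume",
}


def phase_metrics(rec: MotilityRecording,
                  phases: list[PhaseInterval],
                  dt_target: float = 0.05,
                  min_amplitudes: dict[str, float] | None = None) -> pd.DataFrame:
    """Per-phase strength, gross, frequency and duration metrics.

    For every interval and every channel family (ILP, LM, EW1, EW4, volume)
    the table holds the wave strength S (Ps/Ls/EW1s/EW4s/Vs), wave count and
    counting frequency, the gross mean G (Pg per phase), and the gross delta
    against the immediately preceding interval (Lg, EW1g, EW4g, Vg between
    adjacent phases). The longitudinal channel is min-normalized first.
    S is reported as NaN ("unavailable") for intervals shorter than one mean
    wavelength of the channel.
    """
    if not phases:
        raise ParameterError("phase list is empty")
    min_amplitudes = {**MIN_AMPLITUDE_DEFAULTS, **(min_amplitudes or {})}
    aligned = align_to_common_grid(rec, dt_target)
    if "volume" not in aligned.channels:
        aligned = aligned.with_channel(compute_volume(aligned))
    channels = {
        "ilp": rec.channel("pressure"),  # native rate for wave detection
        "lm": normalize_longitudinal(aligned.channel("longitudinal")),
        "ew1": aligned.channel("ew1"),
        "ew4": aligned.channel("ew4"),
        "volume": aligned.channel("volume"),
    }
    ordered = sorted(phases, key=lambda p: p.start)
    total = sum(p.duration for p in ordered)
    lam = {}
    for fam, ch in channels.items():
        ws = detect_waves(ch, min_amplitude=min_amplitudes[FAMILIES[fam]])
        lam[fam] = _mean_wavelength(ws)

    rows = []
    for idx, ph in enumerate(ordered):
        row = {
            "cycle_id": ph.cycle_id, "label": ph.label,
            "start_s": ph.start, "end_s": ph.end,
            "duration_s": ph.duration, "duration_frac": ph.duration / total,
            "partial": ph.partial,
        }
        prev = ordered[idx - 1] if idx > 0 else None
        for fam, ch in channels.items():
            iv = (max(ph.start, ch.t0), min(ph.end, ch.end))
            if not iv[1] > iv[0]:
                row.update({f"{fam}_S": np.nan, f"{fam}_n_waves": 0,
                            f"{fam}_freq_hz": np.nan, f"{fam}_G_mean": np.nan,
                            f"{fam}_G_delta": np.nan})
                continue
            if ph.duration < lam[fam]:
                s_val, n_waves, freq = np.nan, 0, np.nan  # too short to hold a wave
            else:
                sm = strength(ch, iv, min_amplitude=min_amplitudes[FAMILIES[fam]])
                s_val, n_waves, freq = sm.S, sm.n_waves, sm.frequency_hz
            piv = None
            if prev is not None:
                piv = (max(prev.start, ch.t0), min(prev.end, ch.end))
                piv = piv if piv[1] > piv[0] else None
            g = gross(ch, iv, piv)
            row[f"{fam}_S"] = s_val
            row[f"{fam}_n_waves"] = n_waves
            row[f"{fam}_freq_hz"] = freq
            row[f"{fam}_G_mean"] = g.G_mean
            row[f"{fam}_G_delta"] = np.nan if g.G_delta is None else g.G_delta
        rows.append(row)
    return pd.DataFrame(rows)
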