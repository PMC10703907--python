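"""Droplet-discharge (DD) analysis: durations, D/Ds, groups, flow balance.

A discharge's duration D is the interval since the previous discharge
(minutes). Dividing by the tubing-only standard duration Ds removes
pump/tubing variation: D/Ds near 1 means flow indistinguishable from the
empty tubing. Discharges are grouped by the phase containing the drop
instant and the normalized duration:

* ``S_D`` — short (D/Ds below the long threshold) during the D phase;
* ``L_D`` — long during the D phase;
* ``L_A`` — long during the A phase;
* everything else (short-in-A, B/N-phase drops, the first drop, boundary
  straddlers) is ``excluded`` but still counted in the denominator of the
  group shares.

The long threshold defaults to D/Ds = 0.98, the lower edge of the observed
long-discharge range.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace

from .errors import ParameterError
from .phases import PhaseInterval, phase_of
from .recording import DropEvent, MotilityRecording

GROUPS = ("S_D", "L_A", "L_D", "excluded")

#: default D/Ds boundary between short and long discharges
LONG_THRESHOLD = 0.98


@dataclass(frozen=True)
class DischargeEvent:
    """One droplet discharge with its duration metrics and group label."""

    time: float                    # s
    volume: float                  # microliters
    duration_D: float | None       # min since the previous discharge
    d_over_ds: float | None        # duration_D / Ds
    flow_ml_min: float | None      # volume / duration
    phase_label: str | None = None
    cycle_id: int | None = None
    group: str | None = None
    straddle: bool = False


def discharge_durations(drops: list[DropEvent], Ds: float) -> list[DischargeEvent]:
    """Per-drop duration, D/Ds and instantaneous flow rate.

    ``Ds`` is the tubing-only standard duration in minutes. The first drop
    has no preceding interval and carries None metrics.
    """
    if not Ds > 0:
        raise ParameterError("standard duration Ds must be > 0")
    if len(drops) < 2:
        raise ParameterError("need at least two drop events")
    events = []
    prev = None
    for d in drops:
        if prev is None:
            events.append(DischargeEvent(d.time, d.volume, None, None, None))
        else:
            dur_min = (d.time - prev.time) / 60.0
            if not dur_min > 0:
                raise ParameterError("drop events must be strictly increasing")
            events.append(DischargeEvent(
                time=d.time, volume=d.volume, duration_D=dur_min,
                d_over_ds=dur_min / Ds,
                flow_ml_min=(d.volume / 1000.0) / dur_min,
            ))
        prev = d
    return events


def assign_group(phase_label: str | None, d_over_ds: float | None,
                 long_threshold: float = LONG_THRESHOLD,
                 straddle: bool = False) -> str:
    """Pure grouping rule from (phase, D/Ds, straddle flag)."""
    if straddle or phase_label is None or d_over_ds is None:
        return "excluded"
    long = d_over_ds >= long_threshold
    if phase_label == "D":
        return "L_D" if long else "S_D"
    if phase_label == "A" and long:
        return "L_A"
    return "excluded"  # short-in-A, or B/N-phase discharge


def classify_discharges(events: list[DischargeEvent],
                        phases: list[PhaseInterval],
                        long_threshold: float = LONG_THRESHOLD,
                        boundary_tol: float = 0.0) -> list[DischargeEvent]:
    """Attach phase labels and group labels to discharge events.

    A discharge whose drop instant lies within ``boundary_tol`` seconds of
    its cycle's D->A boundary cannot be attributed to either phase with
    confidence; it is flagged ``straddle`` and excluded (default tolerance 0
    disables the check).
    """
    d_ends = {ph.cycle_id: ph.end for ph in phases if ph.label == "D"}
    out = []
    for ev in events:
        ph = phase_of(ev.time, phases)
        label = ph.label if ph is not None else None
        cycle = ph.cycle_id if ph is not None else None
        straddle = False
        if ph is not None and boundary_tol > 0 and cycle in d_ends:
            straddle = abs(ev.time - d_ends[cycle]) <= boundary_tol
        group = assign_group(label, ev.d_over_ds, long_threshold, straddle)
        out.append(replace(ev, phase_label=label, cycle_id=cycle,
                           group=group, straddle=straddle))
    return out


def group_shares(events: list[DischargeEvent]) -> dict:
    """Counts and percentages per group, against *all* recorded discharges.

    Percentages use the total recorded discharge count (excluded ones
    included) as the denominator, so 18 short-in-D discharges out of 48
    recorded give 37.5 %.
    """
    if not events:
        return {"total": 0, "groups": {}}
    counts = Counter(ev.group or "excluded" for ev in events)
    total = len(events)
    return {
        "total": total,
        "groups": {
            g: {"count": counts.get(g, 0),
                "percent": 100.0 * counts.get(g, 0) / total}
            for g in GROUPS
        },
    }


@dataclass(frozen=True)
class FlowSummary:
    mean_flow: float   # ml/min over the window
    inflow: float      # ml delivered over the window
    outflow: float     # ml discharged over the window
    net_balance: float # outflow - inflow, ml
    state: str         # secretory | absorptive | neutral


def flow_balance(rec: MotilityRecording,
                 window: tuple[float, float],
                 inflow_rate: float | None = None,
                 dead_band_frac: float = 0.01) -> FlowSummary:
    """Inflow/outflow balance over a window (secretion vs absorption).

    Outflow is the summed drop volume inside the window; inflow is the pump
    rate times the window length. A net balance within ``dead_band_frac`` of
    the inflow counts as neutral.
    """
    if inflow_rate is None:
        inflow_rate = rec.inflow_rate
    start, end = window
    if not end > start:
        raise ParameterError("empty window")
    minutes = (end - start) / 60.0
    outflow = sum(d.volume for d in rec.drops if start <= d.time < end) / 1000.0
    inflow = inflow_rate * minutes
    net = outflow - inflow
    if abs(net) <= dead_band_frac * inflow:
        state = "neutral"
    elif net > 0:
        state = "secretory"
    else:
        state = "absorptive"
    return FlowSummary(mean_flow=outflow / minutes if minutes else 0.0,
                       inflow=inflow, outflow=outflow, net_balance=net,
                       state=state)
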