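"""Synthetic motility recordings with known ground truth.

The generator emulates the channels of an ex vivo jejunal recording so every
analysis stage is testable without instruments:

* pressure at 2 ms: afterload + a slow-wave sinusoid whose crest-to-trough
  amplitude follows a scripted B/N/D/A block structure, plus white noise;
* longitudinal position at 50 ms: baseline + amplitude-scripted sinusoid;
* edge-width diameters at 50 ms: a baseline minus a raised-cosine
  constriction pulse once per slow-wave cycle. EW2..EW4 are EW1 delayed by
  k * ``lag_per_tracker``. The default lag is (1 - w/2) slow-wave cycles
  (w = pulse width in cycles), which makes the distal tracker re-dilate
  while the proximal one constricts -- the receptive-relaxation pattern of
  propulsive peristalsis -- so a positive lag yields anterograde-dominated
  classification and a negative lag its mirror image;
* drop events driven by accumulated outflow, modulated by phase so
  discharges cluster in D and A, or placed explicitly by a discharge script.

Identical seeds give bit-identical output. Waves are sinusoids/raised
cosines rather than physiological shapes; all downstream metrics depend
only on crest/trough/frequency structure, so this is sufficient for
testing, not a claim about tissue biophysics.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigError
from .recording import (DropEvent, MotilityRecording, SegmentGeometry,
                        TimeSeriesChannel, write_recording)

#: one scripted block: (label, duration s, pressure amp cmH2O,
#: longitudinal amp mm, edge-width amp mm); amplitudes are crest-to-trough
PhaseBlock = tuple[str, float, float, float, float]

DEFAULT_PHASE_SCRIPT: tuple[PhaseBlock, ...] = (
    ("B", 25.0, 0.08, 0.5, 0.22),
    ("N", 10.0, 0.15, 0.9, 0.26),
    ("D", 40.0, 0.60, 1.1, 0.14),
    ("A", 15.0, 0.15, 0.6, 0.23),
)

#: relative outflow weight per phase label (scaled to match the pump inflow
#: on average): discharge is concentrated in D and A
DEFAULT_OUTFLOW_WEIGHTS = {"B": 0.3, "N": 0.5, "D": 2.0, "A": 1.2}


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    duration: float = 270.0            # s; default holds three 90 s cycles
    slow_wave_hz: float = 0.70
    phase_script: tuple[PhaseBlock, ...] = DEFAULT_PHASE_SCRIPT
    lag_per_tracker: float | None = None   # s; None -> (1 - w/2) cycles
    bump_width: float = 0.3                # constriction pulse width, cycles
    baseline_diameter: float = 3.0         # mm
    longitudinal_baseline: float = 5.0     # mm
    noise_sd: dict = field(default_factory=lambda: {
        "pressure": 0.005, "longitudinal": 0.01, "ew": 0.001})
    afterload: float = 1.5                 # cmH2O
    inflow_rate: float = 0.065             # ml/min
    ul_per_drop: float = 50.0
    Ds_min: float = 0.77
    total_length: float = 45.0             # mm
    outflow_weights: dict = field(
        default_factory=lambda: dict(DEFAULT_OUTFLOW_WEIGHTS))
    discharge_script: tuple[tuple[float, str], ...] | None = None
    dt_pressure: float = 0.002
    dt_video: float = 0.05

    def __post_init__(self):
        if not (0.3 < self.slow_wave_hz < 1.2):
            raise ConfigError("slow_wave_hz must lie in (0.3, 1.2)")
        if not self.phase_script:
            raise ConfigError("phase script must not be empty")
        for label, dur, pa, la, ea in self.phase_script:
            if not dur > 0:
                raise ConfigError("phase block durations must be > 0")
            if min(pa, la, ea) < 0:
                raise ConfigError("phase block amplitudes must be >= 0")
        if not (0 < self.bump_width < 1):
            raise ConfigError("bump_width must lie in (0, 1) cycles")
        if not self.duration > 0:
            raise ConfigError("duration must be > 0")

    @property
    def lag_s(self) -> float:
        if self.lag_per_tracker is not None:
            return self.lag_per_tracker
        return (1.0 - self.bump_width / 2.0) / self.slow_wave_hz

    @property
    def cycle_duration(self) -> float:
        return sum(b[1] for b in self.phase_script)


@dataclass(frozen=True)
class GroundTruth:
    """Scripted truth recorded alongside a simulated recording."""

    boundaries: tuple[tuple[str, float, float], ...]  # (label, start, end)
    slow_wave_hz: float
    lag_s: float
    cycle_duration: float
    phase_script: tuple[PhaseBlock, ...]
    drop_intents: tuple[tuple[float, str | None], ...]  # (time, intent/phase)

    def phase_at(self, t: float) -> str | None:
        for label, start, end in self.boundaries:
            if start <= t < end:
                return label
        return None


def _tile_script(script, duration):
    """Scripted (label, start, end) blocks tiled over [0, duration)."""
    out = []
    t = 0.0
    while t < duration - 1e-9:
        for label, dur, *_ in script:
            end = min(t + dur, duration)
            if end > t:
                out.append((label, t, end))
            t = end
            if t >= duration - 1e-9:
                break
    return tuple(out)


def _block_amplitude(script, boundaries, times, which):
    """Per-sample scripted amplitude (which: 2 pressure, 3 longi, 4 ew)."""
    amp_of = {label: blk[which] for blk, label in
              zip(script, [b[0] for b in script])}
    edges = np.array([b[1] for b in boundaries] + [boundaries[-1][2]])
    labels = [b[0] for b in boundaries]
    idx = np.clip(np.searchsorted(edges, times, side="right") - 1,
                  0, len(labels) - 1)
    amps = np.array([amp_of[lab] for lab in labels])
    return amps[idx]


def _bump(phase_frac: np.ndarray, width: float) -> np.ndarray:
    """Raised-cosine constriction pulse on the cycle fraction in [0, 1)."""
    theta = np.mod(phase_frac, 1.0)
    out = np.zeros_like(theta)
    inside = theta < width
    out[inside] = np.sin(np.pi * theta[inside] / width) ** 2
    return out


def simulate(cfg: SimConfig) -> tuple[MotilityRecording, GroundTruth]:
    """Generate one recording plus its ground truth. Deterministic per seed."""
    rng = np.random.default_rng(cfg.seed)
    f = cfg.slow_wave_hz
    boundaries = _tile_script(cfg.phase_script, cfg.duration)

    # pressure, 2 ms
    tp = np.arange(0.0, cfg.duration, cfg.dt_pressure)
    amp_p = _block_amplitude(cfg.phase_script, boundaries, tp, 2)
    pressure = (cfg.afterload + 0.5 * amp_p * np.sin(2 * np.pi * f * tp)
                + rng.normal(0, cfg.noise_sd["pressure"], tp.size))

    # video-rate channels, 50 ms
    tv = np.arange(0.0, cfg.duration, cfg.dt_video)
    amp_l = _block_amplitude(cfg.phase_script, boundaries, tv, 3)
    longitudinal = (cfg.longitudinal_baseline
                    + 0.5 * amp_l * np.sin(2 * np.pi * f * tv)
                    + rng.normal(0, cfg.noise_sd["longitudinal"], tv.size))

    channels = {
        "pressure": TimeSeriesChannel("pressure", 0.0, cfg.dt_pressure, pressure),
        "longitudinal": TimeSeriesChannel("longitudinal", 0.0, cfg.dt_video,
                                          longitudinal),
    }
    for k in range(4):
        shifted = tv - k * cfg.lag_s
        amp_e = _block_amplitude(cfg.phase_script, boundaries,
                                 np.clip(shifted, 0.0, cfg.duration), 4)
        ew = (cfg.baseline_diameter
              - amp_e * _bump(f * shifted, cfg.bump_width)
              + rng.normal(0, cfg.noise_sd["ew"], tv.size))
        channels[f"ew{k + 1}"] = TimeSeriesChannel(f"ew{k + 1}", 0.0,
                                                   cfg.dt_video, ew)

    drops, intents = _make_drops(cfg, boundaries, tv)
    rec = MotilityRecording(
        channels=channels,
        geometry=SegmentGeometry.uniform(cfg.total_length),
        drops=drops,
        afterload=cfg.afterload,
        standard_duration_Ds=cfg.Ds_min,
        inflow_rate=cfg.inflow_rate,
    )
    truth = GroundTruth(
        boundaries=boundaries, slow_wave_hz=f, lag_s=cfg.lag_s,
        cycle_duration=cfg.cycle_duration, phase_script=cfg.phase_script,
        drop_intents=intents,
    )
    return rec, truth


def _make_drops(cfg: SimConfig, boundaries, tv):
    if cfg.discharge_script is not None:
        max_w = max(cfg.outflow_weights.values()) if cfg.outflow_weights else 1.0
        peak_ul_per_s = max_w * cfg.inflow_rate * 1000.0 / 60.0
        prev = 0.0
        drops, intents = [], []
        for t, intent in cfg.discharge_script:
            if not (0 < t <= cfg.duration):
                raise ConfigError(f"scripted discharge at {t} s outside recording")
            if t <= prev:
                raise ConfigError("scripted discharges must be strictly increasing")
            if peak_ul_per_s * t < cfg.ul_per_drop * (len(drops) + 1):
                raise ConfigError(
                    f"scripted discharge at {t} s before enough outflow accumulates"
                )
            drops.append(DropEvent(float(t), cfg.ul_per_drop))
            intents.append((float(t), intent))
            prev = t
        return drops, tuple(intents)

    # outflow proportional to the phase weight, scaled to the pump inflow
    labels = np.array([b[0] for b in boundaries])
    edges = np.array([b[1] for b in boundaries] + [boundaries[-1][2]])
    idx = np.clip(np.searchsorted(edges, tv, side="right") - 1, 0,
                  len(labels) - 1)
    w = np.array([cfg.outflow_weights.get(lab, 1.0) for lab in labels])[idx]
    rate = cfg.inflow_rate * w / w.mean()            # ml/min per sample
    ul_per_step = rate * 1000.0 / 60.0 * cfg.dt_video
    acc = 0.0
    drops, intents = [], []
    for t, du in zip(tv, ul_per_step):
        acc += du
        if acc >= cfg.ul_per_drop:
            acc -= cfg.ul_per_drop
            drops.append(DropEvent(float(t), cfg.ul_per_drop))
            intents.append((float(t), labels[idx[np.searchsorted(tv, t)]]))
    return drops, tuple(intents)


# ---------------------------------------------------------------------------
# fixture suite
# ---------------------------------------------------------------------------


def fixture_configs(base_seed: int = 0) -> dict[str, SimConfig]:
    """The named battery of simulation configs used by the on-disk fixtures."""
    tone_script = (("D", 120.0, 0.5, 1.0, 0.2),)
    no_noise = {"pressure": 0.0, "longitudinal": 0.0, "ew": 0.0}
    cycle = DEFAULT_PHASE_SCRIPT
    return {
        "noiseless_tone": SimConfig(seed=base_seed, duration=120.0,
                                    phase_script=tone_script, noise_sd=no_noise),
        "noisy_cycles_a": SimConfig(seed=base_seed + 1),
        "noisy_cycles_b": SimConfig(seed=base_seed + 2),
        "anterograde": SimConfig(seed=base_seed + 3, duration=120.0,
                                 phase_script=tone_script),
        "retrograde": SimConfig(seed=base_seed + 4, duration=120.0,
                                phase_script=tone_script,
                                lag_per_tracker=-SimConfig().lag_s),
        "segmental": SimConfig(seed=base_seed + 5, duration=120.0,
                               phase_script=tone_script, lag_per_tracker=0.0),
        "discharge_sd": SimConfig(seed=base_seed + 6, discharge_script=(
            (40.0, "first"), (70.0, "S_D"), (130.0, "L_D"), (160.0, "S_D"),
            (220.0, "L_D"), (250.0, "S_D"))),
        "discharge_la": SimConfig(seed=base_seed + 7, discharge_script=(
            (80.0, "L_A"), (170.0, "L_A"), (260.0, "L_A"))),
        "discharge_ld": SimConfig(seed=base_seed + 8, discharge_script=(
            (70.0, "L_D"), (160.0, "L_D"), (250.0, "L_D"))),
    }


def make_fixture_suite(out_dir: str | Path, base_seed: int = 0) -> Path:
    """Write the fixture battery as CSV/JSON recordings with ground truth.

    Returns the manifest path. Re-running with the same seed rewrites
    byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {}
    for name, cfg in fixture_configs(base_seed).items():
        rec, truth = simulate(cfg)
        fdir = out_dir / name
        cfg_path = write_recording(rec, fdir, stem=name)
        truth_path = fdir / f"{name}_truth.json"
        with open(truth_path, "w") as fh:
            json.dump(asdict(truth), fh, indent=1)
        manifest[name] = {
            "config": str(cfg_path.relative_to(out_dir)),
            "truth": str(truth_path.relative_to(out_dir)),
            "seed": cfg.seed,
        }
    mpath = out_dir / "manifest.json"
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return mpath
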