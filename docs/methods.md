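# Methods

This note documents the models, algorithms and defaults behind gutflow, the
choices made where the design was genuinely open, and what the synthetic
recordings do and do not establish about real tissue data.

## Data model

A recording holds uniformly sampled channels — intraluminal pressure (ILP,
cmH₂O, default 2 ms interval), four edge-width diameters EW₁–EW₄ and one
longitudinal-position channel (mm, 50 ms) — plus segment geometry (four
per-tracker axial lengths hᵢ covering tracker + half-gaps), drop events
(time, μl) and scalars: afterload (1.5 cmH₂O), tubing-only standard
discharge duration Ds (min) and pump inflow rate (ml/min). Time is seconds
internally; minutes appear only in discharge/flow outputs. Missing samples
are never interpolated: a timestamp gap beyond 2·dt fails validation,
because every metric below assumes a uniform grid. Cross-channel analyses
run on a common 50 ms grid obtained by within-bin block averaging (which
preserves channel means and sub-10 Hz spectral content); upsampling is
refused. Wave detection runs on native rates.

## Wave detection and S/G metrics

Crest/trough detection uses strict local extrema on the (optionally
smoothed) trace. Plateaus count once, at their first sample. Sub-threshold
ripple is removed by a pairwise merge: repeatedly delete the adjacent
extremum pair with the smallest height difference while that difference is
below `min_amplitude`; deleting a pair from an alternating sequence keeps
it alternating, so ripples collapse into the surrounding swing. A wave is a
crest paired with its *following* trough (the pairing direction is a
convention; the alternative — preceding trough — gives the same amplitudes
on symmetric oscillations and is trivially obtained by shifting the
pairing). Half-waves at window edges are discarded. The rule is simple
enough to be re-implemented exhaustively, and the test suite checks exact
(1e-9) agreement against such an independent oracle.

Defaults: `min_amplitude` 0.03 cmH₂O on pressure (the boundary below which
deflections are treated as noise rather than low-amplitude waves), 0.02 mm
on the mm channels (the spectral amplitude threshold, reused), 0.5 mm³ on
volume (no established value; configurable). Fast channels (dt ≤ 10 ms) get
a 0.15 s moving-average pre-smooth; video-rate channels none.

Strength S is the mean crest-to-trough amplitude over a window (0 with no
waves); this houses Ps, Ls, EW₁s/EW₄s and Vs depending on the channel. The
counting frequency is waves per window length — biased low by up to one
wave per window on short windows, which matters for sub-15 s phases and is
why per-phase S is reported "unavailable" (NaN) for intervals shorter than
one mean wavelength. Gross G is the plain arithmetic mean over an interval;
its between-phase difference (current minus previous) houses Pg changes,
Lg, EWg and Vg. Longitudinal traces are min-normalized (subtract the
smallest recorded value) before analysis so different tracker placements
compare.

The amplitude spectrum mean-subtracts, Hann-windows and zero-pads the
trace to 4× the next power of two; the high-pass is implemented by
discarding bins below the 0.2 Hz cutoff (no filter type is prescribed by
the source procedure, and bin-discarding is exact for a one-sided amplitude
spectrum). Scale is calibrated so a sine of amplitude A peaks near A. The
Exp3P2 envelope a·exp(b·f + c·f²) is fitted by nonlinear least squares to
bins at/above the amplitude threshold, seeded by quadratic regression of
the log-amplitudes; fewer than 5 usable bins or non-convergence flags the
fit unavailable — never silently defaulted.

## Phase segmentation (B/N/D/A)

The four phases are defined narratively in terms of Ps, Ls and Lg; for a
deterministic, testable rule the segmentation here uses only the
pressure-amplitude envelope (moving median of wave amplitudes over a 5 s
window), with the longitudinal criteria reported as supporting metrics
rather than boundary drivers:

* **D** — maximal runs of waves with amplitude ≥ 0.2 cmH₂O; runs whose gap
  (last trough to next high crest) is under 2 mean wavelengths merge. The
  run is extended to the preceding trough at its start.
* **N** — the terminal contiguous run of waves before D whose envelope
  exceeds 1.5× the trailing-B baseline (median envelope over the B span; a
  2-pass fixed point resolves the circularity of "baseline over B" before N
  is known). With no detectable rise, N is one wavelength.
* **A** — from D's end until the envelope returns below that cycle's
  threshold, clamped by the next cycle's N onset.
* **B** — the remainder back to the previous A.

Intervals are half-open [start, end), tile the analysed window exactly, and
a leading B or trailing interval cut by the recording edge is flagged
`partial`. How B of one cycle is delimited from A of the previous when
cycles abut is not externally defined; the envelope-return rule is this
module's convention and the flag makes it auditable. Segmentation is
invariant to constant pressure offsets (amplitudes, not levels, drive it).
On scripted synthetic cycles every boundary is recovered within one slow-
wave wavelength — the natural resolution limit of a wave-based envelope.

## Volume

V(t) = π Σᵢ hᵢ dᵢ(t)²/4, four abutting cylinders. hᵢ defaults to
total_length/4 when per-tracker lengths are absent, and is held constant in
time (whether it should shorten with longitudinal contraction is left
open; holding it constant keeps Vs/Vg interpretable as diameter-driven).
Samples with dᵢ ≤ 0 are flagged invalid and carried as the previous valid
value. The result mixes circular- and longitudinal-muscle contributions,
so it is a volume-*change* signal, not an absolute lumen volume.

## Propulsion classification and net amplitude

On the 50 ms grid, one-step backward differences of a proximal/distal
channel pair are compared: (−,+) anterograde, (+,−) retrograde, same-sign
segmental, with segmental inclination from which tracker changes less. The
signed amplitude is (Δdist − Δprox)/2 for every kind — positive exactly for
anterograde, negative for retrograde, and equal to the inclination in the
segmental branch — which makes swap-antisymmetry exact by construction.

A propagation call requires **both** derivatives above the noise floor
(default 0.005 mm/step). This is deliberate: a step where only one tracker
moves carries no evidence about propagation direction, and for any periodic
wave shape a one-sided rule produces exactly equal anterograde and
retrograde counts by time-shift symmetry, drowning genuine directionality.
Requiring bilateral evidence restricts events to the propulsive strokes,
where proximal constriction coincides with distal movement.

Net amplitude sums the signed amplitudes over all three adjacent pairs and
divides by the number of slow-wave cycles in the window (`per_cycle`,
default, giving mm-scale per-phase values) or by minutes (`per_minute`);
the divisor in "sum of amplitudes by time" is not externally fixed, so it
is configurable. Sign > 0 means net anterograde, < 0 net retrograde.

## Discharge analysis

Duration D = inter-drop interval (min); the first drop carries none.
D/Ds normalizes by the tubing-only standard duration and is invariant to
consistent time-unit rescaling. Groups: D-phase drops are S_D below the
long threshold and L_D at/above it; A-phase drops at/above threshold are
L_A; short-in-A, B/N-phase, first and straddling drops are excluded but
stay in the share denominator (18 of 48 ⇒ 37.5 %). The long threshold
defaults to D/Ds = 0.98, the lower edge of the observed long-discharge
range; it is a config knob, not a fitted constant. A drop within
`boundary_tol` (default 0 = disabled) of its cycle's D→A boundary is
flagged `straddle` and excluded, mirroring the census practice of dropping
discharges attributable to both phases. Note the published census counts
(18+19+8 grouped + 4 removed) overshoot the stated 48 total by one; the
implementation simply reports whatever the data yield.

Flow balance over a window: outflow = Σ drop volumes, inflow = pump rate ×
duration; net > 0 secretory, < 0 absorptive, with a ±1 % dead band
declared neutral to avoid labelling rounding noise.

## Reports and statistics

Tables are tidy frames of mean ± SEM and n per (group, metric, phase or
transition) cell, with SEM absent at n = 1 and empty cells omitted with a
warning. The battery per stratum: Shapiro–Wilk per sample; one-way ANOVA
with pairwise t tests Bonferroni-corrected over the within-stratum family
(all pairs, e.g. 6 for four phases); Kruskal–Wallis with pairwise
Mann–Whitney. Normality rejections are flagged but both batteries still
run — the two axes of comparison each use their conventional battery
rather than conditioning on the flag. Compact letters come from a greedy
deterministic insert/absorb pass over the non-significant pairs. The test
suite calibrates the wiring: under the null the rejection fraction across
500 seeded replicates is ~5 %, and a 3×SD shift at n = 20 is detected in
≥ 95 % of replicates — wiring checks, not claims about the tests.

## Synthetic recordings

The generator scripts one cycle as four blocks (label, duration,
crest-to-trough pressure amplitude, longitudinal amplitude, EW amplitude)
tiled over the recording. Defaults: 0.70 Hz slow wave; B 25 s at
0.08 cmH₂O, N 10 s at 0.15, D 40 s at 0.60, A 15 s at 0.15 (low-amplitude
phases inside the 0.03–0.2 band, D above it, and N/A clearly above the
1.5× rise threshold over B so the segmentation problem is well-posed);
pressure noise 0.005 cmH₂O, longitudinal 0.01 mm, EW 0.001 mm (machine-
vision trackers resolve ~1 μm at 20 Hz, comfortably under the 5 μm/step
classification floor); baseline diameter 3 mm, segment 45 mm; inflow
0.065 ml/min, 50 μl per drop, Ds 0.77 min.

Pressure and longitudinal channels are amplitude-modulated sinusoids. EW
channels carry one raised-cosine constriction pulse per cycle (width 0.3
cycles); EW₂–₄ are EW₁ delayed by k·lag per tracker, default lag
(1 − width/2) cycles ≈ 1.21 s (≈ 9 mm/s propagation over ~11 mm tracker
spacing). That default aligns the distal tracker's re-dilation with the
proximal constriction — the receptive-relaxation geometry of propulsive
peristalsis — which is what makes a positive lag produce anterograde-
dominant classification; a plain delayed sinusoid cannot, because its
anterograde and retrograde step counts are equal by symmetry. Drops are
emitted when accumulated outflow (inflow rate modulated by per-phase
weights, concentrated in D and A) reaches the per-drop volume, or exactly
at scripted times with a feasibility check. Identical seeds give
bit-identical recordings.

What passing on synthetic data shows: the *operational rules* are
implemented correctly and are recoverable at realistic noise. What it does
not show: that the B/N/D/A rules segment real tissue pressure the way an
expert would, that real propulsion is as cleanly lagged as the generator,
or anything about the published tissue values (those require the real
recordings and are out of scope here).

## Problem sizes

Default test recordings are 3–5 cycles (270–450 s; 135k–225k pressure
samples) — enough for three complete cycles after edge trimming, and small
enough that the whole suite runs in a couple of minutes on one core. The
acceptance script uses a five-cycle recording and reports every quantity
with the problem size it was computed at.

## Known limitations

* Boundary resolution is one slow-wave wavelength; sub-wavelength phase
  timing is not meaningful under a wave-envelope rule.
* The N/D boundary ignores the longitudinal peak/plateau criterion (exposed
  conceptually as a refinement, not implemented as a boundary driver).
* Counting frequency underestimates in short windows (edge half-waves are
  discarded); prefer the FFT peak for windows under ~30 s.
* The volume formula cannot separate circular from longitudinal
  contributions.
* Net-amplitude magnitudes depend on the chosen divisor (`per_cycle` vs
  `per_minute`); only signs and within-convention comparisons are
  meaningful.
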