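"""Aggregation into movement/strength and frequency tables, plus the group
comparison test battery.

Tables report mean +- SEM per cell, grouped by discharge group (S_D, L_A,
L_D) with gross metrics on the B->N, N->D and D->A transitions and strength/
frequency metrics per phase. The statistical battery mirrors the standard
workflow for this kind of data: Shapiro-Wilk normality per sample, one-way
ANOVA with Bonferroni-corrected pairwise t tests along one axis, and
Kruskal-Wallis with pairwise Mann-Whitney along the other, significance at
p < 0.05, with a compact letter display derived deterministically from the
pairwise significance matrix.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError

ALPHA = 0.05

STRENGTH_METRICS = {"ilp": "Ps", "lm": "Ls", "ew1": "EW1s", "ew4": "EW4s",
                    "volume": "Vs"}
GROSS_METRICS = {"ilp": "Pg", "lm": "Lg", "ew1": "EW1g", "ew4": "EW4g",
                 "volume": "Vg"}
TRANSITIONS = {"N": "B_to_N", "D": "N_to_D", "A": "D_to_A"}
PHASES = ("B", "N", "D", "A")


def _cycle_groups(events) -> dict[int, str]:
    """cycle_id -> discharge group, from classified events; excluded skipped."""
    out: dict[int, str] = {}
    for ev in events:
        if ev.group in ("S_D", "L_A", "L_D") and ev.cycle_id is not None:
            out[ev.cycle_id] = ev.group
    return out


def _cell(values: np.ndarray) -> dict:
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    n = values.size
    return {
        "mean": float(values.mean()) if n else np.nan,
        "sem": float(values.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan,
        "n": int(n),
    }


def build_tables(metrics: pd.DataFrame, events) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Movement/strength and frequency tables from per-phase metrics.

    ``metrics`` is the output of :func:`gutflow.phases.phase_metrics`;
    ``events`` the classified discharge events, which assign each cycle to a
    group. Cycles without a grouped discharge are dropped with a warning.
    Returns tidy frames with columns (group, metric, column, mean, sem, n);
    ``column`` is a transition label for gross metrics and a phase label for
    strength and frequency metrics.
    """
    groups = _cycle_groups(events)
    if not groups:
        raise ParameterError("no classified discharge events to group cycles by")
    df = metrics[~metrics["partial"]].copy()
    df["group"] = df["cycle_id"].map(groups)
    dropped = df["group"].isna().sum()
    if dropped:
        warnings.warn(f"{dropped} phase rows belong to cycles without a "
                      "grouped discharge; omitted")
    df = df.dropna(subset=["group"])

    move_rows, freq_rows = [], []
    for group, gdf in df.groupby("group", sort=True):
        for fam, gross_name in GROSS_METRICS.items():
            for phase, col in TRANSITIONS.items():
                vals = gdf.loc[gdf["label"] == phase, f"{fam}_G_delta"]
                move_rows.append({"group": group, "metric": gross_name,
                                  "column": col, **_cell(vals)})
        for fam, s_name in STRENGTH_METRICS.items():
            for phase in PHASES:
                sel = gdf["label"] == phase
                move_rows.append({"group": group, "metric": s_name,
                                  "column": phase,
                                  **_cell(gdf.loc[sel, f"{fam}_S"])})
                freq_rows.append({"group": group, "metric": f"freq_{fam}",
                                  "column": phase,
                                  **_cell(gdf.loc[sel, f"{fam}_freq_hz"])})
    movement = pd.DataFrame(move_rows)
    frequency = pd.DataFrame(freq_rows)
    for tbl in (movement, frequency):
        empty = tbl["n"] == 0
        if empty.any():
            warnings.warn(f"{int(empty.sum())} empty cells omitted from table")
    return movement[movement["n"] > 0], frequency[frequency["n"] > 0]


# ---------------------------------------------------------------------------
# test battery
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BatteryResult:
    labels: tuple[str, ...]
    shapiro_p: dict
    anova_p: float
    kruskal_p: float
    pairwise_t_p: dict      # (a, b) -> Bonferroni-adjusted p
    pairwise_mwu_p: dict    # (a, b) -> raw Mann-Whitney p
    letters: dict           # label -> compact letter display (from t tests)
    skipped: bool = False
    reason: str | None = None


def compact_letters(labels, sig: dict[tuple[str, str], bool]) -> dict[str, str]:
    """Compact letter display from a pairwise significance map.

    Labels that are *not* significantly different share a letter. The greedy
    insert rule is deterministic: labels are processed in the given order and
    joined to the first letter group they are compatible with.
    """
    def different(a, b):
        return sig.get((a, b), sig.get((b, a), False))

    groups: list[list[str]] = []
    for lab in labels:
        placed = False
        for g in groups:
            if all(not different(lab, other) for other in g):
                g.append(lab)
                placed = True
        if not placed:
            groups.append([lab])
    # drop letter groups fully contained in another (absorption)
    kept = []
    for g in groups:
        if not any(set(g) < set(h) for h in groups if h is not g):
            if set(g) not in [set(k) for k in kept]:
                kept.append(g)
    letters = {lab: "" for lab in labels}
    for letter, g in zip("abcdefghijklmnopqrstuvwxyz", kept):
        for lab in g:
            letters[lab] += letter
    return letters


def battery(samples: dict[str, np.ndarray], alpha: float = ALPHA) -> BatteryResult:
    """Run the full comparison battery on named samples.

    Requires at least two groups with n >= 3 each. Zero-variance (or too
    small) inputs skip the battery with a flag rather than erroring.
    """
    labels = tuple(samples.keys())
    arrays = {k: np.asarray(v, dtype=float) for k, v in samples.items()}
    arrays = {k: v[np.isfinite(v)] for k, v in arrays.items()}
    if len(arrays) < 2 or any(v.size < 3 for v in arrays.values()):
        return BatteryResult(labels, {}, np.nan, np.nan, {}, {}, {},
                             skipped=True, reason="need >= 2 groups with n >= 3")
    if np.ptp(np.concatenate(list(arrays.values()))) == 0:
        return BatteryResult(labels, {}, np.nan, np.nan, {}, {}, {},
                             skipped=True, reason="zero variance")

    shapiro_p = {}
    for k, v in arrays.items():
        if np.ptp(v) == 0:
            shapiro_p[k] = np.nan
        else:
            shapiro_p[k] = float(stats.shapiro(v).pvalue)

    vals = list(arrays.values())
    anova_p = float(stats.f_oneway(*vals).pvalue)
    kruskal_p = float(stats.kruskal(*vals).pvalue)

    pairs = list(itertools.combinations(labels, 2))
    m = len(pairs)
    pairwise_t, pairwise_mwu, sig = {}, {}, {}
    for a, b in pairs:
        p_t = float(stats.ttest_ind(arrays[a], arrays[b]).pvalue)
        pairwise_t[(a, b)] = min(1.0, p_t * m)  # Bonferroni over the family
        pairwise_mwu[(a, b)] = float(
            stats.mannwhitneyu(arrays[a], arrays[b],
                               alternative="two-sided").pvalue)
        sig[(a, b)] = pairwise_t[(a, b)] < alpha
    letters = compact_letters(labels, sig)
    return BatteryResult(labels, shapiro_p, anova_p, kruskal_p,
                         pairwise_t, pairwise_mwu, letters)


def compare_groups(samples: pd.DataFrame,
                   value: str = "value",
                   by: str = "group",
                   within: tuple[str, ...] = ("metric", "phase"),
                   alpha: float = ALPHA) -> pd.DataFrame:
    """Battery per stratum: compare ``by`` levels within each ``within`` cell.

    ``samples`` is tidy (one row per observation). The default compares the
    discharge groups within each metric/phase; passing ``by='phase'`` and
    ``within=('metric', 'group')`` compares phases within a group instead.
    Returns one row per stratum with p values, normality flags and letters.
    """
    for col in (value, by, *within):
        if col not in samples.columns:
            raise ParameterError(f"samples lacks required column {col!r}")
    rows = []
    for key, sub in samples.groupby(list(within), sort=True):
        key = key if isinstance(key, tuple) else (key,)
        groups = {str(g): s[value].to_numpy()
                  for g, s in sub.groupby(by, sort=True)}
        res = battery(groups, alpha=alpha)
        row = dict(zip(within, key))
        row.update({
            "skipped": res.skipped,
            "reason": res.reason,
            "anova_p": res.anova_p,
            "kruskal_p": res.kruskal_p,
            "shapiro_reject": any(p < alpha for p in res.shapiro_p.values()
                                  if np.isfinite(p)) if res.shapiro_p else False,
            "pairwise_t_p": res.pairwise_t_p,
            "pairwise_mwu_p": res.pairwise_mwu_p,
            "letters": res.letters,
        })
        rows.append(row)
    out = pd.DataFrame(rows)
    # normality rejection is flagged but both batteries are still reported
    return out
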