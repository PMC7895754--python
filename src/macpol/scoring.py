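"""Marker fold changes, M1/M2 scores, polarization maps and phenotype labels.

The M1 (M2) score at time t is the geometric mean of the panel's marker
fold changes relative to the pre-stimulus baseline; the M1/M2 score is
their ratio, which is 1 at t=0 by construction (0 after log transform).
The score formula is a replaceable strategy (``score_fn`` arguments).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from .engine import SimulationResult, SolverSettings, equilibrate, simulate
from .errors import ConfigurationError, DomainError
from .network import Network
from .protocols import DoseEvent, StimulationProtocol

#: fold-change denominator floor, as a fraction of the series maximum
BASELINE_FLOOR_FRACTION = 1e-6
#: trajectory-class threshold (log10 units)
DEFAULT_DELTA = 0.05
#: single-cell phenotype threshold (log10 units)
DEFAULT_TAU = 0.1


@dataclass
class MarkerPanel:
    m1: List[Tuple[str, str]]  # (species id, readout in {level, mRNA, production_rate})
    m2: List[Tuple[str, str]]

    def __post_init__(self):
        ids_m1 = {sid for sid, _ in self.m1}
        ids_m2 = {sid for sid, _ in self.m2}
        if ids_m1 & ids_m2:
            raise ConfigurationError(
                f"marker panels overlap: {sorted(ids_m1 & ids_m2)}"
            )

    @classmethod
    def from_dict(cls, d: dict) -> "MarkerPanel":
        return cls(
            m1=[(sid, ro) for sid, ro in d["m1"]],
            m2=[(sid, ro) for sid, ro in d["m2"]],
        )

    def swapped(self) -> "MarkerPanel":
        return MarkerPanel(m1=list(self.m2), m2=list(self.m1))

    def all_markers(self) -> List[Tuple[str, str]]:
        return list(self.m1) + list(self.m2)


@dataclass
class ScoreTrajectory:
    time_grid: np.ndarray
    m1_score: np.ndarray
    m2_score: np.ndarray
    m1m2_score: np.ndarray
    normalized: bool = True
    transform: str = "none"  # {none, log2, log10}

    def log10_m1m2(self) -> np.ndarray:
        if self.transform == "log10":
            return self.m1m2_score
        if self.transform == "none":
            return np.log10(self.m1m2_score)
        raise ConfigurationError(f"cannot take log10 of transform={self.transform!r}")

    def at(self, t: float) -> float:
        return float(np.interp(t, self.time_grid, self.log10_m1m2()))


@dataclass
class PhenotypeLabel:
    label: str  # {M1-like, M2-like, M0*}
    threshold: float


# ---------------------------------------------------------------------------
# fold changes and scores


def fold_change(
    result: SimulationResult,
    species_id: str,
    t: float,
    readout: str = "level",
    baseline: Optional[float] = None,
) -> float:
    """value(t) / value(t=0), with a floored denominator."""
    series = result.series(species_id, readout)
    if baseline is None:
        baseline = float(series[0])
    floor = BASELINE_FLOOR_FRACTION * max(float(np.max(series)), 1e-300)
    denom = max(baseline, floor)
    if denom <= 0:
        raise DomainError(f"non-positive baseline for {species_id!r}")
    return float(np.interp(t, result.times, series)) / denom


def _panel_fold_matrix(result: SimulationResult, markers) -> np.ndarray:
    """(n_times, n_markers) fold-change matrix against the t=0 column."""
    cols = []
    for sid, readout in markers:
        series = np.asarray(result.series(sid, readout), float)
        floor = BASELINE_FLOOR_FRACTION * max(float(np.max(series)), 1e-300)
        denom = max(float(series[0]), floor)
        cols.append(np.maximum(series, floor) / denom)
    return np.column_stack(cols)


def _geometric_mean(mat: np.ndarray) -> np.ndarray:
    return np.exp(np.mean(np.log(mat), axis=1))


def score_trajectory(
    result: SimulationResult,
    panel: MarkerPanel,
    transform: str = "none",
    score_fn: Callable[[np.ndarray], np.ndarray] = _geometric_mean,
) -> ScoreTrajectory:
    m1 = score_fn(_panel_fold_matrix(result, panel.m1))
    m2 = score_fn(_panel_fold_matrix(result, panel.m2))
    ratio = m1 / m2
    if transform == "log2":
        m1, m2, ratio = np.log2(m1), np.log2(m2), np.log2(ratio)
    elif transform == "log10":
        m1, m2, ratio = np.log10(m1), np.log10(m2), np.log10(ratio)
    elif transform != "none":
        raise ConfigurationError(f"unknown transform {transform!r}")
    return ScoreTrajectory(result.times, m1, m2, ratio, True, transform)


def m_scores(
    result: SimulationResult, panel: MarkerPanel, t: float
) -> Tuple[float, float, float]:
    """(m1_score, m2_score, m1m2_score) at time t (untransformed)."""
    traj = score_trajectory(result, panel)
    m1 = float(np.interp(t, traj.time_grid, traj.m1_score))
    m2 = float(np.interp(t, traj.time_grid, traj.m2_score))
    return m1, m2, m1 / m2


def score_integral(
    score: ScoreTrajectory, window: Tuple[float, float] = (0.0, 24.0)
) -> float:
    """Trapezoidal integral of the log10 M1/M2 score over the window."""
    lo, hi = window
    if score.time_grid[0] > lo or score.time_grid[-1] < hi:
        raise ConfigurationError(
            f"trajectory [{score.time_grid[0]:g}, {score.time_grid[-1]:g}] h "
            f"does not cover window [{lo:g}, {hi:g}] h"
        )
    grid = np.unique(np.concatenate([
        score.time_grid[(score.time_grid >= lo) & (score.time_grid <= hi)],
        [lo, hi],
    ]))
    vals = np.interp(grid, score.time_grid, score.log10_m1m2())
    return float(np.trapezoid(vals, grid))


# ---------------------------------------------------------------------------
# condition sets and the polarization map

SINGLE_STIMULI = ("IFNG", "TNFA", "IL1B", "IL4", "IL10", "VEGFA", "HYP")


def condition_protocol(
    condition: Sequence[str],
    dose_ng_per_ml: float = 10.0,
    hypoxia_percent: float = 2.0,
    duration: float = 48.0,
) -> StimulationProtocol:
    """Protocol for a combination of stimuli named as in :data:`SINGLE_STIMULI`."""
    events, oxygen = [], 21.0
    for stim in condition:
        if stim == "HYP":
            oxygen = hypoxia_percent
        elif stim in SINGLE_STIMULI:
            events.append(DoseEvent(0.0, f"{stim}_ext", dose_ng_per_ml, "ng/mL"))
        else:
            raise ConfigurationError(f"unknown stimulus {stim!r}")
    return StimulationProtocol(events=events, oxygen_percent=oxygen,
                               duration=duration)


def default_conditions() -> List[Tuple[str, ...]]:
    """7 single stimuli plus the 21 pairwise combinations."""
    singles = [(s,) for s in SINGLE_STIMULI]
    pairs = [tuple(c) for c in itertools.combinations(SINGLE_STIMULI, 2)]
    return singles + pairs


def polarization_map(
    network: Network,
    panel: MarkerPanel,
    conditions: Optional[List[Tuple[str, ...]]] = None,
    times: Sequence[float] = (4.0, 24.0, 48.0),
    dose_ng_per_ml: float = 10.0,
    settings: Optional[SolverSettings] = None,
    baseline_state: Optional[np.ndarray] = None,
    dose_scale: float = 1.0,
):
    """Long-format table of log2 marker fold changes per condition and time."""
    import pandas as pd

    conditions = conditions if conditions is not None else default_conditions()
    settings = settings or SolverSettings()
    if baseline_state is None:
        baseline_state = equilibrate(network, settings)
    markers = panel.all_markers()
    rows = []
    horizon = max(times)
    for cond in conditions:
        protocol = condition_protocol(cond, dose_ng_per_ml, duration=horizon)
        protocol.dose_scale = dose_scale
        result = simulate(network, protocol, settings,
                          initial_state=baseline_state.copy())
        fc = _panel_fold_matrix(result, markers)
        for t in times:
            at_t = np.array(
                [np.interp(t, result.times, fc[:, j]) for j in range(fc.shape[1])]
            )
            for j, (sid, readout) in enumerate(markers):
                rows.append({
                    "condition": "+".join(cond),
                    "marker": sid,
                    "readout": readout,
                    "time": t,
                    "log2fc": float(np.log2(at_t[j])),
                })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# classification


def classify_trajectory(score: ScoreTrajectory, delta: float = DEFAULT_DELTA) -> str:
    """{self-promoting, self-limiting, self-repolarizing, flat}.

    Rules on the log10 M1/M2 trajectory s(t):
    flat             max |s| < delta;
    self-repolarizing  both extremes exceed delta with opposite signs;
    self-limiting    |s| peaks then decays by more than 50 % toward 0;
    self-promoting   otherwise.
    """
    if score.time_grid[-1] - score.time_grid[0] < 48.0 - 1e-9:
        raise ConfigurationError("trajectory must cover at least 48 h")
    s = score.log10_m1m2()
    if float(np.max(np.abs(s))) < delta:
        return "flat"
    if float(np.max(s)) > delta and float(np.min(s)) < -delta:
        return "self-repolarizing"
    i_peak = int(np.argmax(np.abs(s)))
    peak, final = abs(float(s[i_peak])), abs(float(s[-1]))
    if i_peak < len(s) - 1 and final < 0.5 * peak:
        return "self-limiting"
    return "self-promoting"


def classify_cell(score_at_24h: float, tau: float = DEFAULT_TAU) -> PhenotypeLabel:
    if score_at_24h > tau:
        return PhenotypeLabel("M1-like", tau)
    if score_at_24h < -tau:
        return PhenotypeLabel("M2-like", tau)
    return PhenotypeLabel("M0*", tau)
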