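"""Virtual macrophage populations: re-parameterized model instances.

Heterogeneity model: independent log-normal multipliers (log10 standard
deviation ``sigma_log10``) applied to every kinetic parameter.  Cells whose
perturbed model fails to reach a resting state, or whose baseline departs
from the reference baseline by more than 20-fold for any species, are
rejected and resampled.  The whole pipeline is deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .engine import SolverSettings, equilibrate, simulate
from .errors import ConfigurationError, DomainError, MacpolError
from .network import Network
from .protocols import StimulationProtocol
from .scoring import (
    DEFAULT_TAU,
    MarkerPanel,
    ScoreTrajectory,
    classify_cell,
    score_trajectory,
)

BASELINE_WINDOW_FOLD = 20.0  # accepted baseline range vs reference, per species
MIN_ACCEPTANCE_RATE = 0.10


@dataclass
class VirtualCell:
    cell_id: int
    multipliers: Dict[str, float]
    seed: int
    accepted: bool = True
    baseline: Optional[np.ndarray] = None


def _draw_multipliers(param_ids, sigma_log10: float, rng) -> Dict[str, float]:
    logs = rng.normal(0.0, sigma_log10, size=len(param_ids))
    return {pid: float(10.0**v) for pid, v in zip(param_ids, logs)}


def generate_population(
    network: Network,
    n: int = 100,
    sigma_log10: float = 0.08,
    seed: int = 0,
    settings: Optional[SolverSettings] = None,
    equilibration_criterion: float = 1e-6,
    max_attempts_factor: int = 10,
) -> List[VirtualCell]:
    """Draw exactly ``n`` accepted virtual cells (seed-deterministic)."""
    if n < 1:
        raise DomainError("n must be >= 1")
    if sigma_log10 < 0:
        raise DomainError("sigma_log10 must be >= 0")
    settings = settings or SolverSettings()
    param_ids = [p.id for p in network.parameters]
    reference_baseline = equilibrate(network, settings, equilibration_criterion)
    lo = reference_baseline / BASELINE_WINDOW_FOLD
    hi = reference_baseline * BASELINE_WINDOW_FOLD

    root = np.random.SeedSequence(seed)
    cells: List[VirtualCell] = []
    attempts = 0
    draw = 0
    max_attempts = max_attempts_factor * n
    while len(cells) < n:
        if attempts >= max_attempts:
            rate = len(cells) / max(attempts, 1)
            raise MacpolError(
                f"acceptance rate {rate:.1%} below {MIN_ACCEPTANCE_RATE:.0%}; "
                "reduce sigma_log10"
            )
        child = np.random.SeedSequence(entropy=root.entropy, spawn_key=(draw,))
        rng = np.random.default_rng(child)
        draw += 1
        attempts += 1
        mult = _draw_multipliers(param_ids, sigma_log10, rng)
        if sigma_log10 == 0.0:
            baseline = reference_baseline
        else:
            net_i = network.scale_parameters(mult)
            try:
                baseline = equilibrate(net_i, settings, equilibration_criterion)
            except MacpolError:
                continue
            # ignore the window for species whose reference baseline is ~0
            mask = reference_baseline > 1e-9
            if np.any(baseline[mask] < lo[mask]) or np.any(baseline[mask] > hi[mask]):
                continue
        cells.append(
            VirtualCell(
                cell_id=len(cells),
                multipliers=mult,
                seed=int(child.spawn_key[0]),
                accepted=True,
                baseline=baseline.copy(),
            )
        )
    return cells


def simulate_population(
    cells: List[VirtualCell],
    network: Network,
    protocol: StimulationProtocol,
    panel: MarkerPanel,
    settings: Optional[SolverSettings] = None,
    baseline_mode: str = "shared",
) -> Tuple[List[ScoreTrajectory], ScoreTrajectory]:
    """Per-cell log10 score trajectories plus the reference-model trajectory.

    Each cell is normalized to its own t=0 value.  With the default
    ``baseline_mode="shared"`` every cell starts the experiment from the
    common unpolarized reference baseline (cell-specific kinetics then drive
    divergence, so even an unstimulated population shows a phenotype
    spectrum); ``"per_cell"`` starts each cell at its own resting state.
    """
    if baseline_mode not in ("shared", "per_cell"):
        raise ConfigurationError(f"unknown baseline_mode {baseline_mode!r}")
    settings = settings or SolverSettings()
    shared = equilibrate(network, settings) if baseline_mode == "shared" else None
    out: List[ScoreTrajectory] = []
    for cell in cells:
        if not cell.accepted:
            raise ConfigurationError(f"cell {cell.cell_id} was not accepted")
        net_i = network.scale_parameters(cell.multipliers)
        if baseline_mode == "shared":
            y0 = shared.copy()
        else:
            y0 = None if cell.baseline is None else cell.baseline.copy()
        result = simulate(net_i, protocol, settings, initial_state=y0)
        out.append(score_trajectory(result, panel, transform="log10"))
    ref_result = simulate(
        network, protocol, settings,
        initial_state=shared.copy() if shared is not None else None,
    )
    reference = score_trajectory(ref_result, panel, transform="log10")
    return out, reference


def response_fractions(
    scores: List[ScoreTrajectory], t: float = 24.0, tau: float = DEFAULT_TAU
) -> Dict[str, float]:
    """Fractions of M1-like / M2-like / M0* cells at time t."""
    if not scores:
        raise ConfigurationError("empty population")
    counts = {"M1-like": 0, "M2-like": 0, "M0*": 0}
    for s in scores:
        counts[classify_cell(s.at(t), tau).label] += 1
    n = len(scores)
    return {k: v / n for k, v in counts.items()}


def population_manifest(cells: List[VirtualCell]):
    import hashlib
    import json

    import pandas as pd

    rows = []
    for c in cells:
        digest = hashlib.sha256(
            json.dumps(c.multipliers, sort_keys=True).encode()
        ).hexdigest()[:12]
        rows.append(
            {
                "cell_id": c.cell_id,
                "seed": c.seed,
                "multipliers_hash": digest,
                "accepted": c.accepted,
            }
        )
    return pd.DataFrame(rows)
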