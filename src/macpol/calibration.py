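"""Normalization conventions, least-squares objective, fitting and bootstrap.

Fitting operates in log10-parameter space with box bounds, multi-start
local search, deterministic per seed.  The bootstrap resamples whole
datasets (block bootstrap at the dataset level) with replacement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import minimize

from .engine import SolverSettings, equilibrate, simulate
from .errors import ConfigurationError, DomainError
from .network import Network
from .protocols import StimulationProtocol

NORMALIZATION_MODES = {
    "t0",
    "max",
    "last_timepoint",
    "named_reference_timepoint",
    "named_reference_condition",
}


@dataclass
class CalibrationDataset:
    species: str
    points: List[Tuple[float, float]]  # (time h, value)
    readout: str = "level"
    condition: Optional[StimulationProtocol] = None  # None = untreated baseline
    normalization_mode: str = "t0"
    reference: Optional[float] = None  # index (timepoint mode) or value (condition mode)
    weight: float = 1.0
    name: str = ""

    def __post_init__(self):
        if not self.points:
            raise ConfigurationError("dataset needs at least one point")
        if self.normalization_mode not in NORMALIZATION_MODES:
            raise ConfigurationError(
                f"unknown normalization mode {self.normalization_mode!r}"
            )
        if self.normalization_mode.startswith("named_") and self.reference is None:
            raise ConfigurationError(
                f"mode {self.normalization_mode!r} needs a reference"
            )

    def times(self) -> np.ndarray:
        return np.array([t for t, _ in self.points], float)

    def values(self) -> np.ndarray:
        return np.array([v for _, v in self.points], float)


@dataclass
class FitResult:
    parameters: Dict[str, float]
    objective: float
    converged: bool
    seed: int
    n_starts: int
    bootstrap_replicates: Optional[List[Dict[str, float]]] = None


def normalize_series(
    values: Sequence[float],
    mode: str,
    reference: Optional[float] = None,
) -> np.ndarray:
    """Divide a series by its mode-determined reference value."""
    v = np.asarray(values, float)
    if mode == "t0":
        ref = v[0]
    elif mode == "max":
        ref = float(np.max(v))
    elif mode == "last_timepoint":
        ref = v[-1]
    elif mode == "named_reference_timepoint":
        if reference is None:
            raise ConfigurationError("reference index required")
        ref = v[int(reference)]
    elif mode == "named_reference_condition":
        if reference is None:
            raise ConfigurationError("reference value required")
        ref = float(reference)
    else:
        raise ConfigurationError(f"unknown normalization mode {mode!r}")
    if ref <= 0:
        raise DomainError(f"normalization reference must be > 0 (got {ref})")
    return v / ref


# ---------------------------------------------------------------------------
# objective


def objective(
    network: Network,
    overrides: Mapping[str, float],
    datasets: Sequence[CalibrationDataset],
    settings: Optional[SolverSettings] = None,
) -> float:
    """Weighted SSE between normalized simulation and normalized data.

    All dataset conditions share the single pre-equilibrated baseline of the
    overridden parameter vector.
    """
    settings = settings or SolverSettings()
    base_values = network.parameter_values()
    net = network.scale_parameters(
        {pid: val / base_values[pid] for pid, val in overrides.items()}
    )
    baseline = equilibrate(net, settings)
    cache: Dict[int, object] = {}
    sse = 0.0
    for ds in datasets:
        key = id(ds.condition)
        if key not in cache:
            protocol = ds.condition or StimulationProtocol(
                duration=max((max(ds.times()) for ds in datasets), default=48.0)
            )
            horizon = max(float(np.max(ds.times())), 1.0)
            if protocol.duration < horizon:
                protocol = StimulationProtocol.from_dict(protocol.to_dict())
                protocol.duration = horizon
            cache[key] = simulate(
                net, protocol, settings, initial_state=baseline.copy()
            )
        result = cache[key]
        sim = np.array(
            [result.at(ds.species, t, ds.readout) for t in ds.times()]
        )
        sim_n = normalize_series(sim, ds.normalization_mode, ds.reference)
        data_n = normalize_series(ds.values(), ds.normalization_mode, ds.reference)
        sse += ds.weight * float(np.sum((sim_n - data_n) ** 2))
    return sse


# ---------------------------------------------------------------------------
# fitting


def fit(
    network: Network,
    free_parameters: Mapping[str, Tuple[float, float]],
    datasets: Sequence[CalibrationDataset],
    budget: int = 200,
    seed: int = 0,
    n_starts: int = 4,
    settings: Optional[SolverSettings] = None,
) -> FitResult:
    """Multi-start Nelder-Mead in log10 space within box bounds."""
    settings = settings or SolverSettings()
    pids = list(free_parameters)
    if not pids:
        return FitResult(
            parameters={},
            objective=objective(network, {}, datasets, settings),
            converged=True,
            seed=seed,
            n_starts=0,
        )
    lo = np.log10([free_parameters[p][0] for p in pids])
    hi = np.log10([free_parameters[p][1] for p in pids])
    if np.any(lo >= hi):
        raise ConfigurationError("bounds must satisfy 0 < lo < hi")
    nominal = network.parameter_values()

    def unpack(x):
        return {pid: float(10.0 ** np.clip(x[j], lo[j], hi[j]))
                for j, pid in enumerate(pids)}

    evals = {"n": 0}

    def f(x):
        evals["n"] += 1
        penalty = float(np.sum(np.maximum(x - hi, 0) ** 2)
                        + np.sum(np.maximum(lo - x, 0) ** 2))
        try:
            return objective(network, unpack(x), datasets, settings) + 1e3 * penalty
        except Exception:
            return 1e12

    rng = np.random.default_rng(seed)
    starts = [np.clip(np.log10([nominal[p] for p in pids]), lo, hi)]
    for _ in range(max(n_starts - 1, 0)):
        starts.append(lo + rng.uniform(size=len(pids)) * (hi - lo))

    best_x, best_val, improved = starts[0], np.inf, False
    f0 = f(starts[0])
    for x0 in starts:
        res = minimize(
            f, x0, method="Nelder-Mead",
            options={"maxiter": budget, "xatol": 1e-6, "fatol": 1e-12},
        )
        if res.fun < best_val:
            best_val, best_x = float(res.fun), res.x
            improved = improved or res.fun < f0 - 1e-15 or res.success
    return FitResult(
        parameters=unpack(best_x),
        objective=best_val,
        converged=bool(improved),
        seed=seed,
        n_starts=len(starts),
    )


def bootstrap_uncertainty(
    network: Network,
    datasets: Sequence[CalibrationDataset],
    free_parameters: Mapping[str, Tuple[float, float]],
    n_boot: int = 20,
    seed: int = 0,
    budget: int = 150,
    n_starts: int = 2,
    settings: Optional[SolverSettings] = None,
) -> Tuple[List[Dict[str, float]], Dict[str, float]]:
    """Dataset-level block bootstrap; returns replicate fits and per-parameter CV."""
    if n_boot < 2:
        raise ConfigurationError("n_boot must be >= 2")
    rng = np.random.default_rng(seed)
    replicates: List[Dict[str, float]] = []
    for b in range(n_boot):
        idx = rng.integers(0, len(datasets), size=len(datasets))
        resampled = [datasets[i] for i in idx]
        res = fit(network, free_parameters, resampled, budget=budget,
                  seed=seed + 1000 + b, n_starts=n_starts, settings=settings)
        replicates.append(res.parameters)
    cv = {}
    for pid in free_parameters:
        vals = np.array([r[pid] for r in replicates])
        cv[pid] = float(np.std(vals) / np.mean(vals)) if np.mean(vals) > 0 else np.inf
    return replicates, cv


# ---------------------------------------------------------------------------
# synthetic fixtures


def generate_synthetic_datasets(
    network: Network,
    conditions: Sequence[Tuple[str, Optional[StimulationProtocol], str, str]],
    times: Sequence[float] = (0.0, 2.0, 4.0, 8.0, 16.0, 24.0, 48.0),
    noise_sigma_log10: float = 0.0,
    seed: int = 0,
    settings: Optional[SolverSettings] = None,
    modes: Sequence[str] = ("t0", "max", "last_timepoint"),
) -> List[CalibrationDataset]:
    """Simulate conditions and emit noisy normalized time-course datasets.

    ``conditions``: (name, protocol-or-None, species, readout) tuples.
    Multiplicative log-normal noise; a normalization mode is drawn per
    dataset; fully seed-deterministic.
    """
    settings = settings or SolverSettings()
    rng = np.random.default_rng(seed)
    baseline = equilibrate(network, settings)
    out: List[CalibrationDataset] = []
    for name, protocol, species, readout in conditions:
        proto = protocol or StimulationProtocol(duration=max(times))
        if proto.duration < max(times):
            proto = StimulationProtocol.from_dict(proto.to_dict())
            proto.duration = max(times)
        result = simulate(network, proto, settings, initial_state=baseline.copy())
        values = np.array([result.at(species, t, readout) for t in times])
        if noise_sigma_log10 > 0:
            values = values * 10.0 ** rng.normal(0.0, noise_sigma_log10,
                                                 size=values.size)
        mode = str(rng.choice(list(modes)))
        out.append(
            CalibrationDataset(
                species=species,
                readout=readout,
                condition=protocol,
                points=list(zip([float(t) for t in times],
                                [float(v) for v in values])),
                normalization_mode=mode,
                name=name,
            )
        )
    return out


def datasets_to_tsv(datasets: Sequence[CalibrationDataset], path) -> None:
    import pandas as pd

    rows = []
    for i, ds in enumerate(datasets):
        for t, v in ds.points:
            rows.append(
                {
                    "condition_id": ds.name or f"ds{i}",
                    "readout": f"{ds.species}:{ds.readout}",
                    "mode": ds.normalization_mode,
                    "time_or_dose": t,
                    "value": v,
                    "weight": ds.weight,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
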