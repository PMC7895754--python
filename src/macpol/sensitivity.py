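"""Latin-hypercube sampling, PRCC, sensitivity and intervention screens.

PRCC of parameter j against output y: rank-transform all columns and y,
regress rank(x_j) and rank(y) each on the remaining rank columns (with
intercept), and correlate the residuals.  Significance via the standard
t transform with n - p - 1 degrees of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .engine import SolverSettings, equilibrate, simulate
from .errors import ConfigurationError, DomainError
from .network import Network
from .protocols import Intervention, StimulationProtocol, apply_interventions
from .scoring import MarkerPanel, ScoreTrajectory, score_integral, score_trajectory

INFLUENCE_THRESHOLD = 0.1  # |PRCC| above this flags a parameter as influential


@dataclass
class SensitivityResult:
    parameter: str
    prcc: float
    p_value: float
    p_adjusted: float
    rank: int
    module: Optional[str] = None
    influential: bool = False


# ---------------------------------------------------------------------------
# sampling


def lhs_sample(
    ranges: Mapping[str, Tuple[float, float]],
    n: int,
    seed: int,
) -> "np.ndarray":
    """Latin-hypercube design in log10 space; one sample per stratum.

    Returns an (n, p) array of parameter values (linear scale), columns in
    the iteration order of ``ranges``.
    """
    if n < 1:
        raise DomainError("n must be >= 1")
    rng = np.random.default_rng(seed)
    cols = []
    for pid, (lo, hi) in ranges.items():
        if not (0 < lo < hi):
            raise DomainError(f"range for {pid!r} must satisfy 0 < lo < hi")
        llo, lhi = np.log10(lo), np.log10(hi)
        strata = (rng.permutation(n) + rng.uniform(size=n)) / n
        cols.append(10.0 ** (llo + strata * (lhi - llo)))
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# PRCC


def _rank(a: np.ndarray) -> np.ndarray:
    return stats.rankdata(a, axis=0) if a.ndim == 2 else stats.rankdata(a)


def _residuals(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Residual of y after least-squares regression on [1, X]."""
    A = np.column_stack([np.ones(len(y)), X]) if X.size else np.ones((len(y), 1))
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return y - A @ coef


def prcc(X: np.ndarray, y: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Partial rank correlation coefficients and two-sided p-values."""
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    n, p = X.shape
    if n != y.size:
        raise ConfigurationError("X and y size mismatch")
    if n <= p + 2:
        raise ConfigurationError(f"need n > p + 2 samples (n={n}, p={p})")
    constant = [j for j in range(p) if np.ptp(X[:, j]) == 0.0]
    if constant:
        raise ConfigurationError(f"constant design columns: {constant}")
    R = _rank(X)
    ry = _rank(y)
    # collinearity check on the rank matrix
    if np.linalg.matrix_rank(np.column_stack([np.ones(n), R])) < p + 1:
        corr = np.corrcoef(R, rowvar=False)
        pairs = [
            (i, j)
            for i in range(p)
            for j in range(i + 1, p)
            if abs(corr[i, j]) > 1 - 1e-12
        ]
        raise ConfigurationError(f"rank-deficient design; collinear columns: {pairs}")
    out = np.empty(p)
    pv = np.empty(p)
    dof = n - p - 1
    for j in range(p):
        others = np.delete(R, j, axis=1)
        rx = _residuals(R[:, j], others)
        rr = _residuals(ry, others)
        denom = np.linalg.norm(rx) * np.linalg.norm(rr)
        r = float(rx @ rr / denom) if denom > 0 else 0.0
        r = float(np.clip(r, -1.0, 1.0))
        out[j] = r
        if abs(r) >= 1.0:
            pv[j] = 0.0
        else:
            t = r * np.sqrt(dof / (1.0 - r * r))
            pv[j] = 2.0 * stats.t.sf(abs(t), dof)
    return out, pv


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    p = np.asarray(p_values, float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for i in range(m - 1, -1, -1):
        running = min(running, p[order[i]] * m / (i + 1))
        adj[order[i]] = running
    return adj


# ---------------------------------------------------------------------------
# screens


def default_ranges(
    network: Network,
    parameters: Optional[Sequence[str]] = None,
    fold: float = 10.0,
) -> Dict[str, Tuple[float, float]]:
    """Log-uniform ranges +/- ``fold`` around nominal for the chosen parameters."""
    values = network.parameter_values()
    pids = list(parameters) if parameters is not None else list(values)
    return {pid: (values[pid] / fold, values[pid] * fold) for pid in pids}


def sensitivity_screen(
    network: Network,
    protocol: Optional[StimulationProtocol] = None,
    parameters: Optional[Sequence[str]] = None,
    n: int = 200,
    seed: int = 0,
    panel: Optional[MarkerPanel] = None,
    window: Tuple[float, float] = (0.0, 24.0),
    ranges: Optional[Mapping[str, Tuple[float, float]]] = None,
    settings: Optional[SolverSettings] = None,
    metric=None,
) -> List[SensitivityResult]:
    """Rank parameters by |PRCC| against the 24-h M1/M2 score integral.

    ``metric(result) -> float`` overrides the default score-integral output;
    supplying it allows screens on networks without a marker panel.
    """
    from .engine import compile_network

    if protocol is None:
        protocol = StimulationProtocol(oxygen_percent=2.0, duration=window[1])
    settings = settings or SolverSettings()
    ranges = dict(ranges) if ranges is not None else default_ranges(network, parameters)
    pids = list(ranges)
    if n < 10 * len(pids):
        warnings.warn(
            f"n={n} is below the recommended 10x #parameters ({10 * len(pids)})",
            stacklevel=2,
        )
    if metric is None:
        if panel is None:
            raise ConfigurationError("either panel or metric must be given")

        def metric(result):
            return score_integral(score_trajectory(result, panel), window)

    X = lhs_sample(ranges, n, seed)
    cn = compile_network(network)
    modules = {
        r.law.rate_param: r.module
        for r in network.reactions
        if r.law.rate_param is not None
    }
    y = np.empty(n)
    base_values = network.parameter_values()
    for i in range(n):
        overrides = {pid: X[i, j] for j, pid in enumerate(pids)}
        net_i = network.scale_parameters(
            {pid: overrides[pid] / base_values[pid] for pid in pids}
        )
        try:
            y0 = equilibrate(net_i, settings)
            result = simulate(net_i, protocol, settings, initial_state=y0)
            y[i] = metric(result)
        except Exception:
            y[i] = np.nan
    ok = np.isfinite(y)
    if ok.sum() <= len(pids) + 2:
        raise ConfigurationError("too many failed samples for PRCC")
    vals, pv = prcc(X[ok], y[ok])
    padj = benjamini_hochberg(pv)
    order = np.argsort(-np.abs(vals))
    results = []
    for rank, j in enumerate(order, start=1):
        results.append(
            SensitivityResult(
                parameter=pids[j],
                prcc=float(vals[j]),
                p_value=float(pv[j]),
                p_adjusted=float(padj[j]),
                rank=rank,
                module=modules.get(pids[j]),
                influential=abs(vals[j]) > INFLUENCE_THRESHOLD,
            )
        )
    return results


def intervention_screen(
    network: Network,
    candidates: Mapping[str, Intervention],
    protocol: Optional[StimulationProtocol] = None,
    panel: Optional[MarkerPanel] = None,
    settings: Optional[SolverSettings] = None,
) -> Dict[str, ScoreTrajectory]:
    """Score trajectories (log10, t=0-normalized) per candidate intervention."""
    if panel is None:
        raise ConfigurationError("a marker panel is required")
    if protocol is None:
        protocol = StimulationProtocol(oxygen_percent=2.0, duration=48.0)
    settings = settings or SolverSettings()
    baseline = equilibrate(network, settings)
    out: Dict[str, ScoreTrajectory] = {}
    for name, iv in candidates.items():
        net_i = apply_interventions(network, [iv])
        result = simulate(net_i, protocol, settings, initial_state=baseline.copy())
        out[name] = score_trajectory(result, panel, transform="log10")
    return out


def results_to_frame(results: List[SensitivityResult]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "parameter": r.parameter,
                "module": r.module,
                "prcc": r.prcc,
                "p": r.p_value,
                "p_adj": r.p_adjusted,
                "rank": r.rank,
                "influential": r.influential,
            }
            for r in results
        ]
    )
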