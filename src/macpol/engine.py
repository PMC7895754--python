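"""ODE right-hand-side assembly, pre-equilibration and event-driven integration.

The right-hand side and its Jacobian are generated as Python source from the
reaction list and compiled once per network; parameter values are passed as a
vector so interventions and population re-parameterizations do not trigger
recompilation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .errors import (
    ConfigurationError,
    NonConvergenceError,
    SolverError,
    ValidationError,
)
from .network import Network, stoichiometry_matrix, validate_network

__all__ = [
    "SolverSettings",
    "SimulationResult",
    "CompiledNetwork",
    "compile_network",
    "build_rhs",
    "equilibrate",
    "simulate",
]


@dataclass
class SolverSettings:
    rel_tol: float = 1e-6
    abs_tol: Optional[float] = None  # default: 1e-9 * max initial amount
    max_step: float = np.inf
    stiff: bool = True

    def __post_init__(self):
        if self.rel_tol <= 0 or (self.abs_tol is not None and self.abs_tol <= 0):
            raise ConfigurationError("solver tolerances must be > 0")

    def resolve_abs_tol(self, y0: np.ndarray) -> float:
        if self.abs_tol is not None:
            return self.abs_tol
        scale = float(np.max(y0)) if y0.size and np.max(y0) > 0 else 1.0
        return 1e-9 * scale

    @property
    def method(self) -> str:
        return "BDF" if self.stiff else "RK45"


# ---------------------------------------------------------------------------
# compilation


def _mass_action_exprs(k_expr: str, terms: List[tuple]) -> tuple:
    """Return (rate expression, {state index: derivative expression})."""
    factors = []
    for i, st in terms:
        factors.append(f"y[{i}]" if st == 1 else f"y[{i}]**{st!r}")
    rate = "*".join([k_expr] + factors)
    derivs = {}
    for j, (i, st) in enumerate(terms):
        other = [f for m, f in enumerate(factors) if m != j]
        if st == 1:
            dterm = "*".join([k_expr] + other) if other else k_expr
        else:
            dterm = "*".join(
                [k_expr, f"{st!r}", f"y[{i}]**{st - 1!r}"] + other
            )
        derivs[i] = derivs.get(i, "0.0") + " + " + dterm
    return rate, {i: e.replace("0.0 + ", "") for i, e in derivs.items()}


class CompiledNetwork:
    """A network lowered to fast rate/RHS/Jacobian callables."""

    def __init__(self, network: Network):
        violations = validate_network(network)
        if violations:
            raise ValidationError(violations)
        self.network = network
        self.species_ids = network.species_ids()
        self.index = network.species_index()
        self.param_ids = [p.id for p in network.parameters]
        self.param_index = {pid: i for i, pid in enumerate(self.param_ids)}
        self.y0 = network.initial_state()
        self.p0 = np.array([p.value for p in network.parameters], float)
        self.S = stoichiometry_matrix(network)
        self.n_species = len(self.species_ids)
        self.n_reactions = len(network.reactions)
        self._build()

    def _build(self) -> None:
        rate_lines: List[str] = []
        jac_lines: List[str] = []
        sym_env: Dict[str, object] = {}
        for k, rxn in enumerate(self.network.reactions):
            law = rxn.law
            kx = (
                f"p[{self.param_index[law.rate_param]}]"
                if law.rate_param is not None and law.rate_param in self.param_index
                else None
            )
            if law.kind == "mass_action":
                terms = [(self.index[sid], st) for sid, st in rxn.reactants]
                expr, derivs = _mass_action_exprs(kx, terms)
            elif law.kind == "synthesis":
                expr, derivs = kx, {}
            elif law.kind == "first_order_decay":
                i = self.index[rxn.reactants[0][0]]
                expr, derivs = f"{kx}*y[{i}]", {i: kx}
            elif law.kind in ("hill_activation", "hill_inhibition", "michaelis_menten"):
                j = self.index[law.regulator]
                a = f"max(y[{j}], 0.0)"
                K = law.K
                if law.kind == "michaelis_menten":
                    expr = f"{kx}*{a}/({K!r} + {a})"
                    derivs = {j: f"{kx}*{K!r}/(({K!r} + {a})**2)"}
                else:
                    n = law.n
                    kn = K**n
                    an = f"({a})**{n!r}"
                    if law.kind == "hill_activation":
                        expr = f"{kx}*{an}/({kn!r} + {an})"
                        sgn = ""
                    else:
                        expr = f"{kx}*{kn!r}/({kn!r} + {an})"
                        sgn = "-"
                    derivs = {
                        j: f"{sgn}{kx}*{n!r}*{kn!r}*({a})**{n - 1!r}"
                        f"/(({kn!r} + {an})**2)"
                    }
            elif law.kind == "expression":
                expr, derivs = self._compile_expression(k, rxn, sym_env)
            else:  # pragma: no cover - rejected by validation
                raise ConfigurationError(f"unsupported law kind {law.kind!r}")

            rate_lines.append(f"    r[{k}] = {expr}")
            for i, dexpr in derivs.items():
                jac_lines.append(f"    dr[{k}, {i}] = {dexpr}")

        src = (
            "def _rates(y, p, r, _funcs):\n"
            + ("\n".join(rate_lines) if rate_lines else "    pass")
            + "\n    return r\n\n"
            "def _drates(y, p, dr, _funcs):\n"
            + ("\n".join(jac_lines) if jac_lines else "    pass")
            + "\n    return dr\n"
        )
        ns: Dict[str, object] = {"max": max}
        exec(compile(src, "<macpol-rhs>", "exec"), ns)
        self._src = src
        self._rates_fn = ns["_rates"]
        self._drates_fn = ns["_drates"]
        self._funcs = sym_env

    def _compile_expression(self, k, rxn, sym_env):
        import sympy as sp

        expr = sp.sympify(rxn.law.expression, rational=False)
        subs = {}
        for sym in expr.free_symbols:
            name = str(sym)
            if name in self.index:
                subs[sym] = sp.Symbol(f"__y{self.index[name]}")
            elif name in self.param_index:
                subs[sym] = sp.Symbol(f"__p{self.param_index[name]}")
            else:
                raise ConfigurationError(
                    f"reaction {rxn.id!r}: expression symbol {name!r} is neither "
                    "a species nor a parameter"
                )
        expr = expr.subs(subs)

        def lower(e) -> str:
            s = sp.printing.pycode(e)
            s = s.replace("math.", "_funcs['math'].")
            import re

            s = re.sub(r"__y(\d+)", r"y[\1]", s)
            s = re.sub(r"__p(\d+)", r"p[\1]", s)
            return s

        import math

        sym_env["math"] = math
        derivs = {}
        for sym in expr.free_symbols:
            name = str(sym)
            if name.startswith("__y"):
                derivs[int(name[3:])] = lower(sp.diff(expr, sym))
        return lower(expr), derivs

    # -- callables -------------------------------------------------------
    def rates(self, y: np.ndarray, p: Optional[np.ndarray] = None) -> np.ndarray:
        r = np.zeros(self.n_reactions)
        return self._rates_fn(y, self.p0 if p is None else p, r, self._funcs)

    def rhs(self, t: float, y: np.ndarray, p: Optional[np.ndarray] = None) -> np.ndarray:
        return self.S @ self.rates(y, p)

    def jac(self, t: float, y: np.ndarray, p: Optional[np.ndarray] = None) -> np.ndarray:
        dr = np.zeros((self.n_reactions, self.n_species))
        self._drates_fn(y, self.p0 if p is None else p, dr, self._funcs)
        return self.S @ dr


def compile_network(network: Network) -> CompiledNetwork:
    return CompiledNetwork(network)


def build_rhs(network: Network) -> Callable[[np.ndarray, float], np.ndarray]:
    """Return a derivative evaluator ``f(state, t) -> dstate/dt``.

    Refuses (raising :class:`ValidationError`) when the network is invalid.
    """
    compiled = compile_network(network)

    def f(state, t=0.0):
        return compiled.rhs(t, np.asarray(state, float))

    f.compiled = compiled  # type: ignore[attr-defined]
    return f


# ---------------------------------------------------------------------------
# pre-equilibration


def equilibrate(
    network: Network,
    settings: Optional[SolverSettings] = None,
    criterion: float = 1e-6,
    horizon: float = 500.0,
    compiled: Optional[CompiledNetwork] = None,
    p: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Integrate the unstimulated network to a resting state.

    Convergence criterion: ``max |dX/dt| / (|X| + 1) < criterion`` (per hour).
    """
    cn = compiled if compiled is not None else compile_network(network)
    settings = settings or SolverSettings()
    y = cn.y0.copy()
    atol = settings.resolve_abs_tol(y)
    t, chunk = 0.0, max(horizon / 10.0, 1.0)
    free = np.array([not s.is_constant for s in cn.network.species])

    def converged(state):
        dydt = cn.rhs(0.0, state, p)
        rel = np.abs(dydt) / (np.abs(state) + 1.0)
        return float(np.max(rel)) if rel.size else 0.0

    def polish(state):
        """Newton (Levenberg-Marquardt) refinement on the non-constant subspace.

        The residual is augmented with the stoichiometric conservation laws
        (left null space of S) so totals of conserved pools are pinned to
        their values on entry instead of drifting to a different class.
        """
        from scipy.linalg import null_space
        from scipy.optimize import root

        idx = np.where(free)[0]
        W = null_space(cn.S[idx, :].T, rcond=1e-10).T  # (k, n_free)
        scale = np.abs(state[idx]) + 1.0
        totals0 = W @ state[idx] if W.size else np.zeros(0)

        def g(x):
            full = state.copy()
            full[idx] = x
            res = cn.rhs(0.0, full, p)[idx] / scale
            if W.size:
                res = np.concatenate([res, W @ x - totals0])
            return res

        def gj(x):
            full = state.copy()
            full[idx] = x
            J = cn.jac(0.0, full, p)[np.ix_(idx, idx)] / scale[:, None]
            if W.size:
                J = np.vstack([J, W])
            return J

        try:
            sol = root(g, state[idx], jac=gj, method="lm",
                       options={"maxiter": 300})
        except Exception:
            return None
        out = state.copy()
        out[idx] = sol.x
        if np.any(out < -atol * 10):
            return None
        return np.clip(out, 0.0, None)

    def try_polish(state, worst_now):
        refined = polish(state)
        if refined is not None and converged(refined) < min(worst_now, criterion):
            return refined
        return state

    worst = converged(y)
    if worst < 1e-2:
        y = try_polish(y, worst)
        worst = converged(y)
    while worst >= criterion and t < horizon:
        sol = solve_ivp(
            lambda tt, yy: cn.rhs(tt, yy, p),
            (t, t + chunk),
            y,
            method=settings.method,
            jac=lambda tt, yy: cn.jac(tt, yy, p),
            rtol=settings.rel_tol,
            atol=atol,
            max_step=settings.max_step,
        )
        if not sol.success:
            raise SolverError(f"equilibration failed at t={sol.t[-1]:g} h: {sol.message}")
        y = sol.y[:, -1]
        t += chunk
        worst = converged(y)
        if worst < 1e-2:
            y = try_polish(y, worst)
            worst = converged(y)
    if worst >= criterion:
        dydt = cn.rhs(0.0, y, p)
        rel = np.abs(dydt) / (np.abs(y) + 1.0)
        sid = cn.species_ids[int(np.argmax(rel))]
        raise NonConvergenceError(
            f"no resting state within {horizon:g} h; worst offender {sid!r} "
            f"(relative derivative {np.max(rel):.3g}/h)"
        )
    return np.clip(y, 0.0, None)


# ---------------------------------------------------------------------------
# stimulation runs


@dataclass
class SimulationResult:
    """Time grid x species trajectories plus secreted-marker production rates."""

    times: np.ndarray
    trajectories: np.ndarray  # (n_times, n_species), clipped at 0
    species_ids: List[str]
    production_rates: Dict[str, np.ndarray]
    protocol: object = None
    baseline: Optional[np.ndarray] = None  # pre-dose equilibrated state

    def __post_init__(self):
        self._index = {sid: i for i, sid in enumerate(self.species_ids)}

    def series(self, species_id: str, readout: str = "level") -> np.ndarray:
        if readout == "production_rate":
            try:
                return self.production_rates[species_id]
            except KeyError:
                raise ConfigurationError(
                    f"no production-rate readout for {species_id!r}"
                ) from None
        if species_id not in self._index:
            raise ConfigurationError(f"unknown species {species_id!r}")
        return self.trajectories[:, self._index[species_id]]

    def at(self, species_id: str, t: float, readout: str = "level") -> float:
        return float(np.interp(t, self.times, self.series(species_id, readout)))

    def to_frame(self):
        import pandas as pd

        rows = []
        for sid in self.species_ids:
            prod = self.production_rates.get(sid)
            for i, t in enumerate(self.times):
                rows.append(
                    {
                        "time": t,
                        "species": sid,
                        "amount": self.trajectories[i, self._index[sid]],
                        "production_rate": float(prod[i]) if prod is not None else np.nan,
                    }
                )
        return pd.DataFrame(rows)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _gather_events(cn: CompiledNetwork, protocol, protocols_mod):
    """Collect (time, kind, payload); kind order breaks ties: dose < intervention."""
    events = []
    for ev in protocol.events:
        copies = protocols_mod.event_copies(ev, protocol)
        if ev.species not in cn.index:
            raise ConfigurationError(f"dose targets unknown species {ev.species!r}")
        events.append((float(ev.time), 0, (cn.index[ev.species], copies)))
    for iv in protocol.interventions:
        if iv.parameter not in cn.param_index:
            raise ConfigurationError(
                f"intervention targets unknown parameter {iv.parameter!r}"
            )
        if float(iv.onset) > 0.0:
            events.append(
                (float(iv.onset), 1, (cn.param_index[iv.parameter], iv.multiplier))
            )
    events.sort(key=lambda e: (e[0], e[1]))
    return events


def simulate(
    network: Network,
    protocol=None,
    settings: Optional[SolverSettings] = None,
    time_grid: Optional[Sequence[float]] = None,
    initial_state: Optional[np.ndarray] = None,
) -> SimulationResult:
    """Integrate ``network`` under a stimulation protocol.

    The network is pre-equilibrated (at nominal parameters, 21 % O2, no
    interventions) unless ``initial_state`` is supplied.  Integration restarts
    at every event time; dosed species jump by the dose amount.  Simultaneous
    events are applied doses first, then oxygen, then interventions.
    """
    from . import protocols as protocols_mod

    if protocol is None:
        protocol = protocols_mod.StimulationProtocol()
    settings = settings or SolverSettings()

    cn = compile_network(network)
    if initial_state is None:
        y0 = equilibrate(network, settings, compiled=cn)
    else:
        y0 = np.asarray(initial_state, float).copy()

    # oxygen enters via PHD-activity parameter scaling, applied from t=0
    run_net = protocols_mod.apply_oxygen(network, protocol.oxygen_percent)
    p = np.array([prm.value for prm in run_net.parameters], float)
    for iv in protocol.interventions:
        if iv.parameter not in cn.param_index:
            raise ConfigurationError(
                f"intervention targets unknown parameter {iv.parameter!r}"
            )
        if float(iv.onset) <= 0.0:
            p[cn.param_index[iv.parameter]] *= iv.multiplier

    duration = float(protocol.duration)
    if time_grid is None:
        n = max(int(round(duration * 5)), 10)
        time_grid = np.linspace(0.0, duration, n + 1)
    times = np.asarray(time_grid, float)
    if np.any(np.diff(times) <= 0):
        raise ConfigurationError("time grid must be strictly increasing")

    events = _gather_events(cn, protocol, protocols_mod)
    for t_ev, _, _ in events:
        if t_ev < times[0] or t_ev > times[-1]:
            raise ConfigurationError(
                f"event at t={t_ev:g} h outside the simulated window"
            )

    atol = settings.resolve_abs_tol(np.maximum(y0, cn.y0))
    y = y0.copy()
    out = np.empty((times.size, cn.n_species))
    prod_segments: List[np.ndarray] = []
    param_track = np.empty((times.size, p.size))

    # apply t=0 events before recording the first point
    i_ev = 0
    while i_ev < len(events) and events[i_ev][0] <= times[0]:
        _, kind, payload = events[i_ev]
        if kind == 0:
            y[payload[0]] += payload[1]
        else:
            p[payload[0]] *= payload[1]
        i_ev += 1

    filled = 0
    t_now = times[0]
    while filled < times.size:
        t_next = events[i_ev][0] if i_ev < len(events) else times[-1]
        t_next = min(max(t_next, t_now), times[-1])
        seg_mask = (times >= t_now - 1e-12) & (times <= t_next + 1e-12)
        seg_mask[:filled] = False
        t_eval = times[seg_mask]
        if t_next > t_now:
            sol = solve_ivp(
                lambda tt, yy: cn.rhs(tt, yy, p),
                (t_now, t_next),
                y,
                method=settings.method,
                jac=lambda tt, yy: cn.jac(tt, yy, p),
                rtol=settings.rel_tol,
                atol=atol,
                max_step=settings.max_step,
                t_eval=t_eval if t_eval.size else None,
                dense_output=False,
            )
            if not sol.success:
                raise SolverError(
                    f"integration failed at t={sol.t[-1] if sol.t.size else t_now:g} h: "
                    f"{sol.message}"
                )
            if t_eval.size:
                out[filled : filled + t_eval.size] = sol.y.T
                param_track[filled : filled + t_eval.size] = p
                filled += t_eval.size
            y = sol.y[:, -1] if sol.t.size and sol.t[-1] == t_next else y
            if sol.t.size and sol.t[-1] != t_next:  # pragma: no cover
                raise SolverError(f"integrator stopped early at t={sol.t[-1]:g} h")
        elif t_eval.size:  # event exactly on a recorded time with zero-length segment
            out[filled : filled + t_eval.size] = y
            param_track[filled : filled + t_eval.size] = p
            filled += t_eval.size
        t_now = t_next
        while i_ev < len(events) and events[i_ev][0] <= t_now + 1e-12:
            _, kind, payload = events[i_ev]
            if kind == 0:
                y[payload[0]] += payload[1]
            else:
                p[payload[0]] *= payload[1]
            i_ev += 1
        if t_now >= times[-1] and filled >= times.size:
            break
        if t_now >= times[-1]:
            out[filled:] = y
            param_track[filled:] = p
            filled = times.size

    production: Dict[str, np.ndarray] = {}
    secretion = [
        (j, r) for j, r in enumerate(network.reactions) if "secretion" in r.tags
    ]
    if secretion:
        flux = np.empty((times.size, len(secretion)))
        for i in range(times.size):
            rates = cn.rates(np.clip(out[i], 0.0, None), param_track[i])
            flux[i] = [rates[j] for j, _ in secretion]
        for col, (j, rxn) in enumerate(secretion):
            target = rxn.products[0][0] if rxn.products else rxn.id
            production[target] = flux[:, col]

    return SimulationResult(
        times=times,
        trajectories=np.clip(out, 0.0, None),
        species_ids=cn.species_ids,
        production_rates=production,
        protocol=protocol,
        baseline=y0,
    )
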