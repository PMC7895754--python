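"""Biochemical network data model and rate-law evaluation.

Amounts are dimensionless copies per cell; time is in hours.  Reversible
reactions are represented as two irreversible reactions (``kf*``/``kr*``
parameter pairs).  Catalysts appear with equal stoichiometry on both sides
of a reaction, so constant species are never net-consumed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .errors import ConfigurationError, DomainError

SPECIES_ROLES = {
    "ligand",
    "receptor",
    "complex",
    "protein",
    "phospho-protein",
    "mRNA",
    "miRNA",
    "compound",
}
COMPARTMENTS = {"extracellular", "cytoplasm", "nucleus"}
LAW_KINDS = {
    "mass_action",
    "hill_activation",
    "hill_inhibition",
    "synthesis",
    "first_order_decay",
    "michaelis_menten",
    "expression",
}
#: law kinds that require a regulator species and a half-saturation constant
_REGULATED_KINDS = {"hill_activation", "hill_inhibition", "michaelis_menten"}


@dataclass
class Species:
    id: str
    name: str = ""
    role: str = "protein"
    compartment: str = "cytoplasm"
    initial_amount: float = 0.0
    is_constant: bool = False
    secreted: bool = False

    def __post_init__(self):
        if not self.name:
            self.name = self.id


@dataclass
class Parameter:
    id: str
    value: float
    description: str = ""


@dataclass
class RateLaw:
    """One of the supported kinetic forms.

    ``mass_action``       rate = k * prod(reactant ** stoich)
    ``hill_activation``   rate = k * A**n / (K**n + A**n)
    ``hill_inhibition``   rate = k * K**n / (K**n + A**n)
    ``synthesis``         rate = k
    ``first_order_decay`` rate = k * substrate  (single reactant)
    ``michaelis_menten``  rate = k * A / (K + A)
    ``expression``        rate = arbitrary math string (import escape hatch)

    where ``k`` is the value of ``rate_param`` and ``A`` the regulator amount.
    """

    kind: str
    rate_param: Optional[str] = None
    K: Optional[float] = None
    n: Optional[float] = None
    regulator: Optional[str] = None
    expression: Optional[str] = None


@dataclass
class Reaction:
    id: str
    reactants: List[Tuple[str, float]] = field(default_factory=list)
    products: List[Tuple[str, float]] = field(default_factory=list)
    modifiers: List[str] = field(default_factory=list)
    law: RateLaw = field(default_factory=lambda: RateLaw("synthesis"))
    tags: List[str] = field(default_factory=list)
    module: Optional[str] = None

    def net_stoichiometry(self) -> Dict[str, float]:
        net: Dict[str, float] = {}
        for sid, st in self.reactants:
            net[sid] = net.get(sid, 0.0) - st
        for sid, st in self.products:
            net[sid] = net.get(sid, 0.0) + st
        return {k: v for k, v in net.items() if v != 0.0}


@dataclass
class ConservedMoiety:
    name: str
    members: List[Tuple[str, float]]  # (species id, stoichiometric weight)
    total: Optional[float] = None


@dataclass
class Network:
    species: List[Species] = field(default_factory=list)
    reactions: List[Reaction] = field(default_factory=list)
    parameters: List[Parameter] = field(default_factory=list)
    moieties: List[ConservedMoiety] = field(default_factory=list)

    # -- lookups ---------------------------------------------------------
    def species_ids(self) -> List[str]:
        return [s.id for s in self.species]

    def species_index(self) -> Dict[str, int]:
        return {s.id: i for i, s in enumerate(self.species)}

    def parameter_index(self) -> Dict[str, int]:
        return {p.id: i for i, p in enumerate(self.parameters)}

    def get_species(self, sid: str) -> Species:
        for s in self.species:
            if s.id == sid:
                return s
        raise ConfigurationError(f"unknown species {sid!r}")

    def get_parameter(self, pid: str) -> Parameter:
        for p in self.parameters:
            if p.id == pid:
                return p
        raise ConfigurationError(f"unknown parameter {pid!r}")

    def get_reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise ConfigurationError(f"unknown reaction {rid!r}")

    def parameter_values(self) -> Dict[str, float]:
        return {p.id: p.value for p in self.parameters}

    def initial_state(self) -> np.ndarray:
        return np.array([s.initial_amount for s in self.species], float)

    def copy(self) -> "Network":
        import copy as _copy

        return _copy.deepcopy(self)

    def scale_parameters(self, factors: Mapping[str, float]) -> "Network":
        """Return a copy with the listed parameter values multiplied."""
        out = self.copy()
        idx = {p.id: p for p in out.parameters}
        for pid, f in factors.items():
            if pid not in idx:
                raise ConfigurationError(f"unknown parameter {pid!r}")
            idx[pid].value *= f
        return out


# ---------------------------------------------------------------------------
# rate evaluation


def evaluate_rate(
    law: RateLaw,
    amounts: Mapping[str, float],
    reaction: Reaction,
    parameters: Mapping[str, float],
) -> float:
    """Evaluate one reaction rate (copies/hour) at the given amounts."""
    for sid, _ in reaction.reactants:
        a = amounts.get(sid)
        if a is None:
            raise ConfigurationError(
                f"reaction {reaction.id!r}: reactant {sid!r} missing from state"
            )
        if a < 0:
            raise DomainError(f"negative amount for {sid!r}: {a}")

    if law.kind == "expression":
        env = dict(parameters)
        env.update(amounts)
        from .io import _eval_expression  # deferred to avoid cycle

        return float(_eval_expression(law.expression, env))

    k = parameters.get(law.rate_param)
    if k is None:
        raise ConfigurationError(
            f"reaction {reaction.id!r}: unknown rate parameter {law.rate_param!r}"
        )

    if law.kind == "mass_action":
        rate = k
        for sid, st in reaction.reactants:
            rate *= amounts[sid] ** st
        return rate
    if law.kind == "synthesis":
        return k
    if law.kind == "first_order_decay":
        if len(reaction.reactants) != 1:
            raise ConfigurationError(
                f"reaction {reaction.id!r}: first_order_decay needs one reactant"
            )
        return k * amounts[reaction.reactants[0][0]]
    if law.kind in _REGULATED_KINDS:
        if law.regulator is None or law.regulator not in amounts:
            raise ConfigurationError(
                f"reaction {reaction.id!r}: regulator {law.regulator!r} missing"
            )
        a = amounts[law.regulator]
        if a < 0:
            raise DomainError(f"negative amount for {law.regulator!r}: {a}")
        K = law.K
        if law.kind == "michaelis_menten":
            return k * a / (K + a)
        n = law.n
        an, kn = a**n, K**n
        if law.kind == "hill_activation":
            return k * an / (kn + an)
        return k * kn / (kn + an)
    raise ConfigurationError(f"unknown rate-law kind {law.kind!r}")


# ---------------------------------------------------------------------------
# validation


def _check_law(rxn: Reaction, pids, sids, out: List[str]) -> None:
    law = rxn.law
    if law.kind not in LAW_KINDS:
        out.append(f"reaction {rxn.id}: unknown law kind {law.kind!r}")
        return
    if law.kind == "expression":
        if not law.expression:
            out.append(f"reaction {rxn.id}: expression law without expression")
        return
    if law.rate_param is None or law.rate_param not in pids:
        out.append(f"reaction {rxn.id}: unresolved rate parameter {law.rate_param!r}")
    if law.kind in _REGULATED_KINDS:
        if law.regulator is None or law.regulator not in sids:
            out.append(f"reaction {rxn.id}: unresolved regulator {law.regulator!r}")
        if law.K is None or law.K <= 0:
            out.append(f"reaction {rxn.id}: K must be > 0")
        if law.kind != "michaelis_menten" and (law.n is None or law.n < 1):
            out.append(f"reaction {rxn.id}: Hill coefficient must be >= 1")
    if law.kind == "first_order_decay" and len(rxn.reactants) != 1:
        out.append(f"reaction {rxn.id}: first_order_decay needs exactly one reactant")


def validate_network(network: Network) -> List[str]:
    """Return a list of violation messages (empty when the network is valid)."""
    out: List[str] = []
    sids = set()
    for s in network.species:
        if s.id in sids:
            out.append(f"duplicate species id {s.id}")
        sids.add(s.id)
        if s.role not in SPECIES_ROLES:
            out.append(f"species {s.id}: unknown role {s.role!r}")
        if s.compartment not in COMPARTMENTS:
            out.append(f"species {s.id}: unknown compartment {s.compartment!r}")
        if s.initial_amount < 0:
            out.append(f"species {s.id}: negative initial amount")

    pids = set()
    for p in network.parameters:
        if p.id in pids:
            out.append(f"duplicate parameter id {p.id}")
        pids.add(p.id)
        if p.value <= 0:
            out.append(f"parameter {p.id}: value must be > 0 (got {p.value})")

    rids = set()
    constant = {s.id for s in network.species if s.is_constant}
    for r in network.reactions:
        if r.id in rids:
            out.append(f"duplicate reaction id {r.id}")
        rids.add(r.id)
        if not r.reactants and not r.products:
            out.append(f"reaction {r.id}: no reactants and no products")
        for sid, st in r.reactants + r.products:
            if sid not in sids:
                out.append(f"reaction {r.id}: unknown species {sid!r}")
            if st < 1:
                out.append(f"reaction {r.id}: stoichiometry < 1 for {sid!r}")
        for sid in r.modifiers:
            if sid not in sids:
                out.append(f"reaction {r.id}: unknown modifier {sid!r}")
        for sid, net in r.net_stoichiometry().items():
            if sid in constant and net < 0:
                out.append(
                    f"reaction {r.id}: constant species {sid!r} net-consumed"
                )
        _check_law(r, pids, sids, out)

    # conserved moieties: stoichiometric sum invariant under every reaction
    for m in network.moieties:
        weights = dict(m.members)
        for sid in weights:
            if sid not in sids:
                out.append(f"moiety {m.name}: unknown species {sid!r}")
        for r in network.reactions:
            change = sum(
                weights.get(sid, 0.0) * net
                for sid, net in r.net_stoichiometry().items()
            )
            if abs(change) > 1e-12:
                out.append(
                    f"moiety {m.name}: not invariant under reaction {r.id}"
                    f" (net change {change:g})"
                )
    return out


def conserved_totals(
    network: Network, state: Mapping[str, float]
) -> Dict[str, float]:
    """Weighted totals of each declared conserved moiety at the given state."""
    out = {}
    for m in network.moieties:
        try:
            out[m.name] = sum(w * state[sid] for sid, w in m.members)
        except KeyError as e:
            raise ConfigurationError(
                f"moiety {m.name}: state missing species {e.args[0]!r}"
            ) from None
    return out


def stoichiometry_matrix(network: Network) -> np.ndarray:
    """Dense net-stoichiometry matrix (species x reactions).

    Rows of constant (clamped) species are zeroed so that the product with a
    rate vector is directly the state derivative.
    """
    idx = network.species_index()
    S = np.zeros((len(network.species), len(network.reactions)))
    for j, r in enumerate(network.reactions):
        for sid, net in r.net_stoichiometry().items():
            S[idx[sid], j] = net
    for i, s in enumerate(network.species):
        if s.is_constant:
            S[i, :] = 0.0
    return S
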