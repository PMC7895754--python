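"""Stimulation protocols: doses, oxygen, interventions, HSS variants.

Doses are instantaneous additions ("bolus") to extracellular species,
converted from mass concentrations to copies per cell with a configurable
medium volume per cell.  Oxygen enters the kinetics only through linear
scaling of PHD-mediated HIF-hydroxylation rate parameters (reactions tagged
``phd_hydroxylation``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional

from .errors import ConfigurationError, DomainError
from .network import Network

AVOGADRO = 6.02214076e23

#: molecular weights (Da) of the shipped ligands; sources in README
DEFAULT_MOLECULAR_WEIGHTS: Dict[str, float] = {
    "IFNG_ext": 34000.0,   # biologically active homodimer
    "TNFA_ext": 17350.0,   # monomer mass, dosed as monomer equivalents
    "IL1B_ext": 17400.0,
    "IL4_ext": 15000.0,
    "IL10_ext": 37000.0,   # homodimer
    "VEGFA_ext": 38700.0,  # VEGF165 homodimer
    "VEGFB_ext": 38700.0,
}

#: default medium volume per cell (mL); ~1e6 cells/mL culture
DEFAULT_MEDIUM_VOLUME_ML = 1e-6

DOSE_UNITS = {"ng/mL", "pg/mL", "copies"}


@dataclass
class DoseEvent:
    time: float
    species: str
    dose: float
    units: str = "ng/mL"

    def __post_init__(self):
        if self.units not in DOSE_UNITS:
            raise ConfigurationError(f"unknown dose units {self.units!r}")
        if self.time < 0:
            raise DomainError("event time must be >= 0")
        if self.dose < 0:
            raise DomainError("dose must be >= 0")


@dataclass
class Intervention:
    parameter: str
    multiplier: float
    onset: float = 0.0

    def __post_init__(self):
        if self.multiplier <= 0:
            raise DomainError("intervention multiplier must be > 0")


@dataclass
class StimulationProtocol:
    events: List[DoseEvent] = field(default_factory=list)
    oxygen_percent: float = 21.0
    duration: float = 48.0
    dose_scale: float = 1.0
    interventions: List[Intervention] = field(default_factory=list)
    medium_volume_ml: float = DEFAULT_MEDIUM_VOLUME_ML
    molecular_weights: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if not (0.0 < self.oxygen_percent <= 21.0):
            raise DomainError("oxygen_percent must be in (0, 21]")
        for ev in self.events:
            if ev.time > self.duration:
                raise ConfigurationError(
                    f"event at t={ev.time:g} h exceeds duration {self.duration:g} h"
                )

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "StimulationProtocol":
        d = dict(d)
        d["events"] = [DoseEvent(**e) for e in d.get("events", [])]
        d["interventions"] = [Intervention(**i) for i in d.get("interventions", [])]
        return cls(**d)

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "StimulationProtocol":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# conversions and transformations


def dose_to_copies(
    dose_ng_per_ml: float,
    molecular_weight: float,
    medium_volume_per_cell_ml: float = DEFAULT_MEDIUM_VOLUME_ML,
) -> float:
    """Convert a ng/mL dose to copies per cell.

    copies = dose[g/mL] / MW[g/mol] * N_A * volume[mL]
    """
    if dose_ng_per_ml < 0:
        raise DomainError("dose must be >= 0")
    if molecular_weight <= 0 or medium_volume_per_cell_ml <= 0:
        raise DomainError("molecular weight and volume must be > 0")
    grams_per_ml = dose_ng_per_ml * 1e-9
    return grams_per_ml / molecular_weight * AVOGADRO * medium_volume_per_cell_ml


def event_copies(event: DoseEvent, protocol: StimulationProtocol) -> float:
    """Effective copies-per-cell added by one dose event (dose_scale applied)."""
    dose = event.dose * protocol.dose_scale
    if event.units == "copies":
        return dose
    if event.units == "pg/mL":
        dose = dose * 1e-3  # -> ng/mL
    mw = protocol.molecular_weights.get(
        event.species, DEFAULT_MOLECULAR_WEIGHTS.get(event.species)
    )
    if mw is None:
        raise ConfigurationError(
            f"no molecular weight known for {event.species!r}; dose in copies "
            "or add it to protocol.molecular_weights"
        )
    return dose_to_copies(dose, mw, protocol.medium_volume_ml)


def oxygen_scale_factor(oxygen_percent: float) -> float:
    """Linear PHD-activity scaling: 21 % (normoxia) -> 1.0."""
    if not (0.0 < oxygen_percent <= 21.0):
        raise DomainError("oxygen_percent must be in (0, 21]")
    return oxygen_percent / 21.0


def _scale_tagged(network: Network, tags, factor: float) -> Network:
    params = set()
    for r in network.reactions:
        if any(t in r.tags for t in tags) and r.law.rate_param is not None:
            params.add(r.law.rate_param)
    if factor == 1.0 or not params:
        return network.copy()
    return network.scale_parameters({pid: factor for pid in params})


def apply_oxygen(network: Network, oxygen_percent: float) -> Network:
    """Return a copy with PHD-hydroxylation rate parameters scaled by %O2/21."""
    return _scale_tagged(
        network, ("phd_hydroxylation",), oxygen_scale_factor(oxygen_percent)
    )


def apply_interventions(network: Network, interventions) -> Network:
    """Pure transformation multiplying the targeted parameter values."""
    factors: Dict[str, float] = {}
    for iv in interventions:
        factors[iv.parameter] = factors.get(iv.parameter, 1.0) * iv.multiplier
    return network.scale_parameters(factors)


def hss_variant(network: Network, synthesis_scale: float) -> Network:
    """Scale all transcription/translation rate parameters (HSS surrogate).

    Combined with 2 % O2 this represents hypoxia plus globally reduced
    protein and RNA synthesis.
    """
    if not (0.0 < synthesis_scale <= 1.0):
        raise DomainError("synthesis_scale must be in (0, 1]")
    tagged = [
        r
        for r in network.reactions
        if "transcription" in r.tags or "translation" in r.tags
    ]
    if not tagged:
        raise ConfigurationError(
            "network has no reactions tagged transcription/translation"
        )
    return _scale_tagged(network, ("transcription", "translation"), synthesis_scale)


def in_vivo_scaling(protocol: StimulationProtocol) -> StimulationProtocol:
    """100-fold dose dilution (ng/mL -> high pg/mL range); multiplicative."""
    import copy as _copy

    out = _copy.deepcopy(protocol)
    out.dose_scale = protocol.dose_scale * 0.01
    return out
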