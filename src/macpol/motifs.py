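"""Small analytically tractable networks used as fixtures and oracles.

These are first-class, tested constructors: engine correctness is checked
against their closed-form solutions, sensitivity screens against their
known input-output structure, and calibration against their recoverable
(or deliberately degenerate) parameterizations.
"""

from __future__ import annotations

import numpy as np

from .network import (
    ConservedMoiety,
    Network,
    Parameter,
    RateLaw,
    Reaction,
    Species,
)


def closed_binding_network(
    kf: float = 1e-3, kr: float = 0.5, l0: float = 500.0, r0: float = 100.0
) -> Network:
    """L + R <-> LR with no synthesis/decay; both totals are conserved."""
    return Network(
        species=[
            Species("L", role="ligand", compartment="extracellular",
                    initial_amount=l0),
            Species("R", role="receptor", initial_amount=r0),
            Species("LR", role="complex", initial_amount=0.0),
        ],
        parameters=[Parameter("kf1", kf), Parameter("kr1", kr)],
        reactions=[
            Reaction("bind", [("L", 1.0), ("R", 1.0)], [("LR", 1.0)],
                     law=RateLaw("mass_action", rate_param="kf1")),
            Reaction("unbind", [("LR", 1.0)], [("L", 1.0), ("R", 1.0)],
                     law=RateLaw("first_order_decay", rate_param="kr1")),
        ],
        moieties=[
            ConservedMoiety("R_total", [("R", 1.0), ("LR", 1.0)], r0),
            ConservedMoiety("L_total", [("L", 1.0), ("LR", 1.0)], l0),
        ],
    )


def receptor_cycle_network(r0: float = 1e4, l0: float = 1e6) -> Network:
    """Closed receptor trafficking cycle: bind, internalize, recycle.

    Total receptor (R + LR + Ri) is conserved; ligand is consumed on
    internalization, so only the receptor moiety is declared.
    """
    return Network(
        species=[
            Species("L", role="ligand", compartment="extracellular",
                    initial_amount=l0),
            Species("R", role="receptor", initial_amount=r0),
            Species("LR", role="complex", initial_amount=0.0),
            Species("Ri", role="receptor", initial_amount=0.0),
        ],
        parameters=[
            Parameter("kf1", 1e-6),
            Parameter("kr1", 0.1),
            Parameter("ki", 0.5),
            Parameter("krec", 0.3),
        ],
        reactions=[
            Reaction("bind", [("L", 1.0), ("R", 1.0)], [("LR", 1.0)],
                     law=RateLaw("mass_action", rate_param="kf1")),
            Reaction("unbind", [("LR", 1.0)], [("L", 1.0), ("R", 1.0)],
                     law=RateLaw("first_order_decay", rate_param="kr1")),
            Reaction("internalize", [("LR", 1.0)], [("Ri", 1.0)],
                     law=RateLaw("first_order_decay", rate_param="ki")),
            Reaction("recycle", [("Ri", 1.0)], [("R", 1.0)],
                     law=RateLaw("first_order_decay", rate_param="krec")),
        ],
        moieties=[
            ConservedMoiety("R_total",
                            [("R", 1.0), ("LR", 1.0), ("Ri", 1.0)], r0),
        ],
    )


def irreversible_binding_network(
    k: float = 1e-3, a0: float = 300.0, b0: float = 200.0
) -> Network:
    """A + B -> C, second-order; has the textbook closed-form solution."""
    return Network(
        species=[
            Species("A", initial_amount=a0),
            Species("B", initial_amount=b0),
            Species("C", role="complex", initial_amount=0.0),
        ],
        parameters=[Parameter("k1", k)],
        reactions=[
            Reaction("bind", [("A", 1.0), ("B", 1.0)], [("C", 1.0)],
                     law=RateLaw("mass_action", rate_param="k1")),
        ],
        moieties=[
            ConservedMoiety("A_total", [("A", 1.0), ("C", 1.0)], a0),
            ConservedMoiety("B_total", [("B", 1.0), ("C", 1.0)], b0),
        ],
    )


def bimolecular_solution(t, k: float, a0: float, b0: float) -> np.ndarray:
    """Exact C(t) for A + B -> C with rate k*A*B."""
    t = np.asarray(t, float)
    if abs(a0 - b0) < 1e-12:
        return a0 - a0 / (1.0 + a0 * k * t)
    e = np.exp((b0 - a0) * k * t)
    return a0 * b0 * (e - 1.0) / (b0 * e - a0)


def synthesis_decay_network(ks: float = 100.0, kd: float = 0.2,
                            x0: float = 0.0) -> Network:
    """0 -> X -> 0 with steady state ks/kd."""
    return Network(
        species=[Species("X", initial_amount=x0)],
        parameters=[Parameter("ks", ks), Parameter("kd", kd)],
        reactions=[
            Reaction("syn", [], [("X", 1.0)],
                     law=RateLaw("synthesis", rate_param="ks"),
                     tags=["translation"]),
            Reaction("dec", [("X", 1.0)], [],
                     law=RateLaw("first_order_decay", rate_param="kd")),
        ],
    )


def isomerization_network(kf: float = 1.0, kr: float = 1.0,
                          a0: float = 100.0) -> Network:
    """A <-> B; symmetric rates give the A = B = a0/2 equilibrium."""
    return Network(
        species=[Species("A", initial_amount=a0), Species("B", initial_amount=0.0)],
        parameters=[Parameter("kf1", kf), Parameter("kr1", kr)],
        reactions=[
            Reaction("fwd", [("A", 1.0)], [("B", 1.0)],
                     law=RateLaw("first_order_decay", rate_param="kf1")),
            Reaction("rev", [("B", 1.0)], [("A", 1.0)],
                     law=RateLaw("first_order_decay", rate_param="kr1")),
        ],
        moieties=[ConservedMoiety("AB_total", [("A", 1.0), ("B", 1.0)], a0)],
    )


def sensitivity_motif() -> Network:
    """Three-parameter motif where only ``k_synth`` controls the output O.

    ``k_da``/``k_db`` govern a decoy species D that never feeds O.
    """
    return Network(
        species=[
            Species("O", initial_amount=0.0),
            Species("D", initial_amount=0.0),
        ],
        parameters=[
            Parameter("k_synth", 50.0),
            Parameter("k_out", 0.5),
            Parameter("k_da", 20.0),
            Parameter("k_db", 0.2),
        ],
        reactions=[
            Reaction("o_syn", [], [("O", 1.0)],
                     law=RateLaw("synthesis", rate_param="k_synth")),
            Reaction("o_dec", [("O", 1.0)], [],
                     law=RateLaw("first_order_decay", rate_param="k_out")),
            Reaction("d_syn", [], [("D", 1.0)],
                     law=RateLaw("synthesis", rate_param="k_da")),
            Reaction("d_dec", [("D", 1.0)], [],
                     law=RateLaw("first_order_decay", rate_param="k_db")),
        ],
    )


def stimulus_response_motif(kv: float = 80.0, kx: float = 0.3,
                            kl: float = 0.1) -> Network:
    """Dose-driven induction motif used for parameter-recovery studies.

    L decays with ``k_l``; X is synthesized under Hill control of L
    (``k_v``) and decays with ``k_x``.  A bolus of L gives a pulse of X
    whose amplitude and relaxation identify ``k_v`` and ``k_x``.
    """
    return Network(
        species=[
            Species("L", role="ligand", compartment="extracellular",
                    initial_amount=0.0),
            Species("X", initial_amount=0.0),
        ],
        parameters=[
            Parameter("k_v", kv),
            Parameter("k_x", kx),
            Parameter("k_l", kl),
        ],
        reactions=[
            Reaction("induce", [], [("X", 1.0)],
                     law=RateLaw("hill_activation", rate_param="k_v",
                                 K=500.0, n=2.0, regulator="L")),
            Reaction("x_dec", [("X", 1.0)], [],
                     law=RateLaw("first_order_decay", rate_param="k_x")),
            Reaction("l_dec", [("L", 1.0)], [],
                     law=RateLaw("first_order_decay", rate_param="k_l")),
        ],
    )


def degenerate_pair_motif(k1: float = 5.0, k2: float = 2.0) -> Network:
    """Only the product ``k1 * k2`` is constrained by steady-state data on Y.

    X has fast fixed turnover, so Y's steady state is (k1/kx) * k2 / ky.
    """
    return Network(
        species=[Species("X", initial_amount=0.0), Species("Y", initial_amount=0.0)],
        parameters=[
            Parameter("k1", k1),
            Parameter("k2", k2),
            Parameter("k_x", 1.0),
            Parameter("k_y", 0.5),
        ],
        reactions=[
            Reaction("x_syn", [], [("X", 1.0)],
                     law=RateLaw("synthesis", rate_param="k1")),
            Reaction("x_dec", [("X", 1.0)], [],
                     law=RateLaw("first_order_decay", rate_param="k_x")),
            Reaction("y_syn", [("X", 1.0)], [("X", 1.0), ("Y", 1.0)],
                     law=RateLaw("mass_action", rate_param="k2")),
            Reaction("y_dec", [("Y", 1.0)], [],
                     law=RateLaw("first_order_decay", rate_param="k_y")),
        ],
    )
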