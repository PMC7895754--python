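import numpy as np
import pytest

from macpol.engine import (
    SolverSettings,
    build_rhs,
    compile_network,
    equilibrate,
    simulate,
)
from macpol.errors import ConfigurationError, NonConvergenceError, ValidationError
from macpol.motifs import (
    bimolecular_solution,
    closed_binding_network,
    irreversible_binding_network,
    isomerization_network,
    receptor_cycle_network,
    synthesis_decay_network,
)
from macpol.network import (
    Network,
    Parameter,
    RateLaw,
    Reaction,
    Species,
    conserved_totals,
)
from macpol.protocols import DoseEvent, Intervention, StimulationProtocol


class TestBuildRhs:
    def test_simple_conversion(self):
        net = Network(
            species=[Species("A", initial_amount=10), Species("B")],
            parameters=[Parameter("k", 1.0)],
            reactions=[Reaction("c", [("A", 1.0)], [("B", 1.0)],
                                law=RateLaw("first_order_decay", rate_param="k"))],
        )
        f = build_rhs(net)
        dy = f([10.0, 0.0], 0.0)
        assert dy == pytest.approx([-10.0, 10.0])

    def test_constant_species_zero_derivative(self):
        net = Network(
            species=[Species("O2", initial_amount=21, is_constant=True),
                     Species("X")],
            parameters=[Parameter("k", 2.0)],
            reactions=[
                Reaction("use", [("O2", 1.0)], [("X", 1.0), ("O2", 1.0)],
                         law=RateLaw("mass_action", rate_param="k")),
            ],
        )
        f = build_rhs(net)
        dy = f([21.0, 0.0], 0.0)
        assert dy[0] == 0.0
        assert dy[1] == pytest.approx(42.0)

    def test_invalid_network_refused_with_report(self):
        net = closed_binding_network()
        net.reactions[0].reactants.append(("GHOST", 1.0))
        with pytest.raises(ValidationError) as exc:
            build_rhs(net)
        assert any("GHOST" in v for v in exc.value.violations)

    def test_random_network_matches_flux_bookkeeping_oracle(self):
        # brute-force oracle: evaluate each reaction's rate with the slow
        # dictionary-based evaluator and sum net stoichiometries by hand
        from macpol.network import evaluate_rate

        rng = np.random.default_rng(7)
        species = [Species(f"S{i}", initial_amount=rng.uniform(1, 100))
                   for i in range(6)]
        params = [Parameter(f"k{j}", rng.uniform(0.1, 2.0)) for j in range(10)]
        kinds = ["mass_action", "synthesis", "first_order_decay",
                 "hill_activation", "hill_inhibition"]
        reactions = []
        for j in range(10):
            kind = kinds[j % len(kinds)]
            a, b = rng.choice(6, size=2, replace=False)
            if kind == "mass_action":
                rxn = Reaction(f"r{j}", [(f"S{a}", 1.0), (f"S{b}", 1.0)],
                               [(f"S{(a + 1) % 6}", 1.0)],
                               law=RateLaw(kind, rate_param=f"k{j}"))
            elif kind == "synthesis":
                rxn = Reaction(f"r{j}", [], [(f"S{a}", 1.0)],
                               law=RateLaw(kind, rate_param=f"k{j}"))
            elif kind == "first_order_decay":
                rxn = Reaction(f"r{j}", [(f"S{a}", 1.0)], [],
                               law=RateLaw(kind, rate_param=f"k{j}"))
            else:
                rxn = Reaction(f"r{j}", [], [(f"S{a}", 1.0)],
                               law=RateLaw(kind, rate_param=f"k{j}", K=50.0,
                                           n=1.5, regulator=f"S{b}"))
            reactions.append(rxn)
        net = Network(species=species, parameters=params, reactions=reactions)

        state = rng.uniform(0.5, 80.0, size=6)
        amounts = {f"S{i}": state[i] for i in range(6)}
        pvals = {p.id: p.value for p in params}
        expected = np.zeros(6)
        for rxn in reactions:
            rate = evaluate_rate(rxn.law, amounts, rxn, pvals)
            for sid, stoich in rxn.net_stoichiometry().items():
                expected[int(sid[1:])] += stoich * rate

        f = build_rhs(net)
        assert f(state, 0.0) == pytest.approx(expected, rel=1e-12)

    def test_analytic_jacobian_matches_finite_differences(self):
        net = receptor_cycle_network()
        cn = compile_network(net)
        y = np.array([1e5, 5e3, 2e3, 1e3])
        J = cn.jac(0.0, y)
        eps = 1e-4
        for j in range(4):
            yp, ym = y.copy(), y.copy()
            yp[j] += eps * max(y[j], 1.0)
            ym[j] -= eps * max(y[j], 1.0)
            col = (cn.rhs(0.0, yp) - cn.rhs(0.0, ym)) / (yp[j] - ym[j])
            assert J[:, j] == pytest.approx(col, rel=1e-5, abs=1e-6)


class TestEquilibrate:
    def test_symmetric_isomerization(self):
        net = isomerization_network(kf=1.0, kr=1.0, a0=100.0)
        state = equilibrate(net)
        assert state == pytest.approx([50.0, 50.0], rel=1e-6)

    def test_synthesis_decay_closed_form(self):
        net = synthesis_decay_network(ks=120.0, kd=0.4)
        state = equilibrate(net)
        assert state[0] == pytest.approx(300.0, rel=1e-6)

    def test_nonconvergence_names_offender(self):
        # pure accumulation never reaches steady state
        net = Network(
            species=[Species("GROW")],
            parameters=[Parameter("k", 5.0)],
            reactions=[Reaction("syn", [], [("GROW", 1.0)],
                                law=RateLaw("synthesis", rate_param="k"))],
        )
        with pytest.raises(NonConvergenceError, match="GROW"):
            equilibrate(net, horizon=10.0)

    def test_reference_baseline_scores_are_unity(self, reference_net, baseline,
                                                 panel, settings):
        from macpol.scoring import m_scores

        proto = StimulationProtocol(duration=24.0)
        result = simulate(reference_net, proto, settings,
                          initial_state=baseline.copy())
        m1, m2, ratio = m_scores(result, panel, 24.0)
        assert m1 == pytest.approx(1.0, abs=5e-3)
        assert m2 == pytest.approx(1.0, abs=5e-3)
        assert ratio == pytest.approx(1.0, abs=5e-3)


class TestSimulate:
    def test_zero_event_protocol_is_flat(self):
        net = synthesis_decay_network(ks=100.0, kd=0.2)
        y0 = equilibrate(net)
        result = simulate(net, StimulationProtocol(duration=48.0),
                          initial_state=y0)
        assert np.ptp(result.series("X")) < 1e-6 * y0[0]

    def test_bimolecular_binding_matches_closed_form(self):
        k, a0, b0 = 2e-3, 300.0, 180.0
        net = irreversible_binding_network(k=k, a0=a0, b0=b0)
        grid = np.linspace(0.0, 10.0, 101)
        settings = SolverSettings(rel_tol=1e-10, abs_tol=1e-12)
        result = simulate(net, StimulationProtocol(duration=10.0),
                          settings=settings, time_grid=grid,
                          initial_state=net.initial_state())
        expected = bimolecular_solution(grid, k, a0, b0)
        assert result.series("C") == pytest.approx(expected, rel=1e-6, abs=1e-6)

    def test_dosed_species_jumps_by_dose(self):
        net = closed_binding_network(l0=0.0, r0=100.0)
        proto = StimulationProtocol(
            events=[DoseEvent(0.0, "L", 500.0, "copies")], duration=5.0
        )
        result = simulate(net, proto, initial_state=net.initial_state())
        assert result.series("L")[0] == pytest.approx(500.0)

    def test_moiety_conservation_along_trajectory(self):
        net = receptor_cycle_network()
        proto = StimulationProtocol(
            events=[DoseEvent(0.0, "L", 1e6, "copies")], duration=48.0
        )
        result = simulate(net, proto, initial_state=net.initial_state())
        idx = {s: i for i, s in enumerate(result.species_ids)}
        totals = [
            conserved_totals(net, {s: result.trajectories[i, idx[s]]
                                   for s in idx})["R_total"]
            for i in range(len(result.times))
        ]
        totals = np.asarray(totals)
        assert np.max(np.abs(totals - totals[0])) < 1e-8 * totals[0]

    def test_mid_run_intervention_changes_dynamics(self):
        net = synthesis_decay_network(ks=100.0, kd=0.5)
        proto = StimulationProtocol(
            duration=40.0,
            interventions=[Intervention("ks", 2.0, onset=20.0)],
        )
        y0 = equilibrate(net)
        result = simulate(net, proto, initial_state=y0)
        assert result.at("X", 19.0) == pytest.approx(200.0, rel=1e-4)
        assert result.at("X", 40.0) == pytest.approx(400.0, rel=1e-3)

    def test_event_outside_window_rejected(self):
        net = synthesis_decay_network()
        proto = StimulationProtocol(duration=48.0,
                                    events=[DoseEvent(10.0, "X", 5.0, "copies")])
        with pytest.raises(ConfigurationError):
            simulate(net, proto, time_grid=np.linspace(0, 5, 10),
                     initial_state=net.initial_state())

    def test_grid_invariance_on_reference(self, reference_net, baseline):
        # halving rel_tol changes 24-h endpoints by < 0.1 %
        proto = StimulationProtocol(oxygen_percent=2.0, duration=24.0)
        a = simulate(reference_net, proto, SolverSettings(rel_tol=1e-6),
                     initial_state=baseline.copy())
        b = simulate(reference_net, proto, SolverSettings(rel_tol=5e-7),
                     initial_state=baseline.copy())
        ya, yb = a.trajectories[-1], b.trajectories[-1]
        scale = np.abs(ya) + 1e-6 * np.max(ya)
        assert np.max(np.abs(ya - yb) / scale) < 1e-3

    def test_nonnegativity_on_reference(self, reference_net, baseline, settings):
        proto = StimulationProtocol(
            events=[DoseEvent(0.0, "IFNG_ext", 10.0, "ng/mL")], duration=48.0
        )
        result = simulate(reference_net, proto, settings,
                          initial_state=baseline.copy())
        assert np.all(result.trajectories >= 0.0)

    def test_production_rates_cover_secreted_markers(self, reference_net,
                                                     baseline, settings):
        result = simulate(reference_net, StimulationProtocol(duration=4.0),
                          settings, initial_state=baseline.copy())
        for sid in ("TNFA_ext", "IL1B_ext", "IFNG_ext", "IL10_ext",
                    "VEGFA_ext", "IL12_ext", "CXCL9_ext", "IL1RA_ext"):
            assert sid in result.production_rates
            assert np.all(result.production_rates[sid] >= 0.0)


def test_result_tsv_roundtrip(tmp_path):
    import pandas as pd

    net = synthesis_decay_network()
    result = simulate(net, StimulationProtocol(duration=2.0),
                      initial_state=net.initial_state())
    out = tmp_path / "traj.tsv"
    result.write_tsv(out)
    df = pd.read_csv(out, sep="\t")
    assert set(df.columns) == {"time", "species", "amount", "production_rate"}
    assert (df.species == "X").any()
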