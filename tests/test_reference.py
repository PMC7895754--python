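import numpy as np
import pytest

from macpol.engine import equilibrate, simulate
from macpol.network import validate_network
from macpol.protocols import DoseEvent, StimulationProtocol
from macpol.reference import (
    TARGETED_INTERVENTIONS,
    PATHWAY_MODULES,
    build_reference_network,
    directional_response_suite,
    pathway_modules,
)

SECRETED_MARKERS = ("TNFA", "IL1B", "IFNG", "IL10", "VEGFA", "IL12", "CXCL9",
                    "IL1RA")
RECEPTOR_LIGANDS = ("TNFA", "IL1B", "IFNG", "IL10", "VEGFA")


class TestTopology:
    def test_validates_cleanly(self, reference_net):
        assert validate_network(reference_net) == []

    def test_exactly_seven_pathway_modules(self, reference_doc):
        mods = pathway_modules(reference_doc)
        assert set(mods) == set(PATHWAY_MODULES)
        assert len(mods) == 7
        for m in mods.values():
            assert m.reaction_ids

    def test_modules_cover_every_reaction_exactly_once(self, reference_doc):
        mods = pathway_modules(reference_doc)
        covered = [rid for m in mods.values() for rid in m.reaction_ids]
        assert sorted(covered) == sorted(
            r.id for r in reference_doc.network.reactions
        )

    def test_eight_secreted_markers_have_secretion_reactions(self,
                                                            reference_net):
        secretion_products = {
            r.products[0][0]
            for r in reference_net.reactions
            if "secretion" in r.tags
        }
        for marker in SECRETED_MARKERS:
            assert f"{marker}_ext" in secretion_products

    def test_autocrine_loops_closed_for_receptor_ligands(self, reference_net):
        # secreted ligand feeds back onto its own receptor pathway
        for lig in RECEPTOR_LIGANDS:
            ext = f"{lig}_ext"
            binds = [
                r for r in reference_net.reactions
                if (ext, 1.0) in r.reactants and r.id.endswith("_bind")
            ]
            secretes = [
                r for r in reference_net.reactions
                if "secretion" in r.tags and r.products[0][0] == ext
            ]
            assert binds and secretes, lig

    def test_receptor_modules_complete(self, reference_net):
        rids = {r.id for r in reference_net.reactions}
        for lig in ("ifng", "tnfa", "il1b", "il4", "il10", "vegfa"):
            for stage in ("bind", "unbind", "c_act", "internalize", "recycle",
                          "ri_deg", "r_syn", "r_deg"):
                assert f"{lig}_{stage}" in rids, (lig, stage)

    def test_vegf_isoforms_compete_for_receptor(self, reference_net):
        r = reference_net.get_reaction("vegfb_bind")
        assert ("R_VEGFA", 1.0) in r.reactants
        assert ("VEGFB_ext", 1.0) in r.reactants

    def test_intervention_parameters_exist(self, reference_net):
        pids = {p.id for p in reference_net.parameters}
        for name, (pid, _) in TARGETED_INTERVENTIONS.items():
            assert pid in pids, name

    def test_marker_panel_resolvable(self, reference_doc, panel,
                                     reference_net, settings, baseline):
        result = simulate(reference_net, StimulationProtocol(duration=2.0),
                          settings, initial_state=baseline.copy())
        for sid, readout in panel.all_markers():
            series = result.series(sid, readout)
            assert np.all(series > 0)


@pytest.fixture(scope="module")
def suite(reference_doc, settings):
    return directional_response_suite(reference_doc, settings)


class TestDirectionalSuite:
    def test_all_directions_pass(self, suite):
        failed = suite[~suite.passed]
        assert failed.empty, failed.to_string()

    def test_covers_all_stimuli(self, suite):
        assert {"IFNG", "TNFA", "IL1B", "IL4", "IL10", "HYP",
                "HYP+miR93-OE"} <= set(suite.stimulus)

    def test_ifng_inos_up(self, suite):
        row = suite[(suite.stimulus == "IFNG") & (suite.target == "INOS")]
        assert float(row.fold_change.iloc[0]) > 1.0

    def test_il10_represses_vegf_while_ifng_promotes(self, suite):
        il10 = suite[(suite.stimulus == "IL10") &
                     (suite.target == "VEGFA_ext")].fold_change.iloc[0]
        ifng = suite[(suite.stimulus == "IFNG") &
                     (suite.target == "VEGFA_ext")].fold_change.iloc[0]
        assert il10 < 1.0 < ifng

    def test_hypoxia_induces_both_arg1_and_il1b(self, suite):
        hyp = suite[suite.stimulus == "HYP"].set_index("target")
        assert hyp.loc["ARG1", "fold_change"] > 1.0
        assert hyp.loc["IL1B_ext", "fold_change"] > 1.0


class TestFeedbackProperties:
    def test_removing_a20_feedback_raises_peak_nfkb(self, reference_net,
                                                    settings, baseline):
        proto = StimulationProtocol(
            events=[DoseEvent(0.0, "TNFA_ext", 10.0, "ng/mL")], duration=24.0
        )
        with_fb = simulate(reference_net, proto, settings,
                           initial_state=baseline.copy())
        no_a20 = reference_net.scale_parameters({"k_ikka_off_a20": 1e-12})
        base2 = equilibrate(no_a20, settings)
        without = simulate(no_a20, proto, settings, initial_state=base2)
        peak = lambda r: float(np.max(r.series("NFKBn")))
        assert peak(without) > peak(with_fb)

    def test_il4_pretreatment_blunts_ifng_irf1(self, reference_net, settings,
                                               baseline):
        ifng_at_24 = DoseEvent(24.0, "IFNG_ext", 10.0, "ng/mL")
        plain = simulate(
            reference_net,
            StimulationProtocol(events=[ifng_at_24], duration=48.0),
            settings, initial_state=baseline.copy(),
        )
        pretreated = simulate(
            reference_net,
            StimulationProtocol(
                events=[DoseEvent(0.0, "IL4_ext", 10.0, "ng/mL"), ifng_at_24],
                duration=48.0,
            ),
            settings, initial_state=baseline.copy(),
        )
        window = plain.times >= 24.0
        peak_plain = float(np.max(plain.series("IRF1")[window]))
        peak_pre = float(np.max(pretreated.series("IRF1")[window]))
        assert peak_pre < peak_plain

    def test_stat6_targeting_lowers_score_under_hypoxia(self, reference_net,
                                                        panel, score_at,
                                                        settings, baseline):
        from macpol.scoring import score_trajectory

        hyp_score = score_at(("HYP",))
        pid, mult = TARGETED_INTERVENTIONS["STAT6*"]
        net = reference_net.scale_parameters({pid: mult})
        result = simulate(net,
                          StimulationProtocol(oxygen_percent=2.0, duration=48.0),
                          settings, initial_state=baseline.copy())
        stat6_score = score_trajectory(result, panel, transform="log10").at(24.0)
        assert stat6_score < hyp_score


def test_overrides_applied():
    doc = build_reference_network({"parameter_overrides": {"kf3": 0.123}})
    assert doc.network.get_parameter("kf3").value == 0.123


def test_unknown_override_rejected():
    from macpol.errors import ConfigurationError

    with pytest.raises(ConfigurationError):
        build_reference_network({"parameter_overrides": {"nope": 1.0}})


def test_shipped_fixture_matches_builder(reference_doc):
    # the data files are regenerated whenever the nominal parameterization
    # changes; drift between them and the builder is a packaging bug
    import importlib.resources as resources

    from macpol.io import network_from_dict
    import json

    with resources.files("macpol").joinpath(
            "data/reference_model.json").open() as fh:
        shipped = network_from_dict(json.load(fh))
    assert shipped.network.parameter_values() == \
        reference_doc.network.parameter_values()
    assert len(shipped.network.reactions) == len(reference_doc.network.reactions)
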