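import numpy as np
import pytest

from macpol.engine import SimulationResult
from macpol.errors import ConfigurationError
from macpol.scoring import (
    MarkerPanel,
    ScoreTrajectory,
    classify_cell,
    classify_trajectory,
    condition_protocol,
    default_conditions,
    fold_change,
    m_scores,
    polarization_map,
    score_integral,
    score_trajectory,
)


def _result(times, series: dict, production=None):
    ids = list(series)
    traj = np.column_stack([np.asarray(series[s], float) for s in ids])
    return SimulationResult(
        times=np.asarray(times, float),
        trajectories=traj,
        species_ids=ids,
        production_rates=production or {},
    )


def _score(times, values):
    v = np.asarray(values, float)
    return ScoreTrajectory(np.asarray(times, float), np.abs(v), np.ones_like(v),
                           v, transform="log10")


class TestFoldChange:
    def test_t0_is_one(self):
        r = _result([0, 1, 2], {"X": [5, 10, 20]})
        assert fold_change(r, "X", 0.0) == pytest.approx(1.0)

    def test_constant_trajectory(self):
        r = _result([0, 1, 2], {"X": [7, 7, 7]})
        for t in (0.0, 1.0, 2.0):
            assert fold_change(r, "X", t) == pytest.approx(1.0)

    def test_doubling(self):
        r = _result([0, 1], {"X": [5, 10]})
        assert fold_change(r, "X", 1.0) == pytest.approx(2.0)

    def test_baseline_floor_prevents_blowup(self):
        r = _result([0, 1], {"X": [0.0, 100.0]})
        assert np.isfinite(fold_change(r, "X", 1.0))


class TestMScores:
    def test_all_unity(self):
        r = _result([0, 1], {"A": [1, 1], "B": [2, 2], "C": [3, 3],
                             "D": [4, 4]})
        panel = MarkerPanel(m1=[("A", "level"), ("B", "level")],
                            m2=[("C", "level"), ("D", "level")])
        assert m_scores(r, panel, 1.0) == pytest.approx((1.0, 1.0, 1.0))

    def test_geometric_mean_hand_computation(self):
        # M1 markers x4, M2 markers x1 -> ratio 4, log10 ~ 0.602
        r = _result([0, 1], {"A": [1, 4], "B": [2, 8], "C": [3, 3],
                             "D": [4, 4]})
        panel = MarkerPanel(m1=[("A", "level"), ("B", "level")],
                            m2=[("C", "level"), ("D", "level")])
        m1, m2, ratio = m_scores(r, panel, 1.0)
        assert m1 == pytest.approx(4.0)
        assert m2 == pytest.approx(1.0)
        assert np.log10(ratio) == pytest.approx(0.602, abs=1e-3)

    def test_swapping_panels_inverts_score(self):
        rng = np.random.default_rng(3)
        vals = rng.uniform(0.5, 5.0, size=(2, 4))
        vals[0] = 1.0
        r = _result([0, 1], {k: vals[:, i] for i, k in enumerate("ABCD")})
        panel = MarkerPanel(m1=[("A", "level"), ("B", "level")],
                            m2=[("C", "level"), ("D", "level")])
        _, _, ratio = m_scores(r, panel, 1.0)
        _, _, inv = m_scores(r, panel.swapped(), 1.0)
        assert ratio * inv == pytest.approx(1.0, rel=1e-12)

    def test_invariance_to_marker_order_and_unit_rescaling(self):
        rng = np.random.default_rng(5)
        vals = rng.uniform(0.5, 5.0, size=(3, 4))
        series = {k: vals[:, i] for i, k in enumerate("ABCD")}
        r1 = _result([0, 1, 2], series)
        panel = MarkerPanel(m1=[("A", "level"), ("B", "level")],
                            m2=[("C", "level"), ("D", "level")])
        reordered = MarkerPanel(m1=[("B", "level"), ("A", "level")],
                                m2=[("D", "level"), ("C", "level")])
        rescaled = dict(series)
        rescaled["A"] = series["A"] * 1e3  # unit change of one marker
        r2 = _result([0, 1, 2], rescaled)
        s1 = m_scores(r1, panel, 2.0)
        assert m_scores(r1, reordered, 2.0) == pytest.approx(s1)
        assert m_scores(r2, panel, 2.0) == pytest.approx(s1)

    def test_overlapping_panels_rejected(self):
        with pytest.raises(ConfigurationError):
            MarkerPanel(m1=[("A", "level")], m2=[("A", "level")])

    def test_reference_signs_ifng_vs_il4(self, score_at):
        assert score_at(("IFNG",)) > 0.0
        assert score_at(("IL4",)) < 0.0


class TestScoreIntegral:
    def test_flat_zero(self):
        s = _score([0, 12, 24], [0, 0, 0])
        assert score_integral(s) == 0.0

    def test_constant_log_score(self):
        s = _score(np.linspace(0, 24, 25), np.full(25, 0.3))
        assert score_integral(s, (0.0, 24.0)) == pytest.approx(7.2)

    def test_agreement_with_refined_quadrature(self):
        t = np.linspace(0, 24, 49)
        vals = np.sin(t / 5.0) * 0.4
        coarse = score_integral(_score(t, vals))
        t_fine = np.linspace(0, 24, 481)
        fine = np.trapezoid(np.interp(t_fine, t, vals), t_fine)
        assert coarse == pytest.approx(fine, rel=1e-4)

    def test_window_not_covered(self):
        with pytest.raises(ConfigurationError):
            score_integral(_score([0, 10], [0, 1]), (0.0, 24.0))


class TestClassification:
    def test_monotone_increasing_self_promoting(self):
        t = np.linspace(0, 48, 49)
        assert classify_trajectory(_score(t, 0.01 * t)) == "self-promoting"

    def test_flat(self):
        t = np.linspace(0, 48, 49)
        assert classify_trajectory(_score(t, np.full(49, 0.01))) == "flat"

    def test_sign_change_self_repolarizing(self):
        t = np.linspace(0, 48, 49)
        vals = 0.1 * np.sin(2 * np.pi * (t + 6) / 96.0)
        vals = np.where(t < 24, 0.1, -0.1)
        assert classify_trajectory(_score(t, vals)) == "self-repolarizing"

    def test_peak_and_decay_self_limiting(self):
        t = np.linspace(0, 48, 49)
        vals = 0.4 * np.exp(-((t - 8) / 10.0) ** 2)
        assert classify_trajectory(_score(t, vals)) == "self-limiting"

    def test_short_trajectory_rejected(self):
        with pytest.raises(ConfigurationError):
            classify_trajectory(_score([0, 24], [0, 1]))

    def test_classify_cell_thresholds(self):
        assert classify_cell(0.0).label == "M0*"
        assert classify_cell(0.2, tau=0.1).label == "M1-like"
        assert classify_cell(-0.2, tau=0.1).label == "M2-like"
        assert classify_cell(0.09, tau=0.1).label == "M0*"

    def test_ifng_plus_il4_repolarizes(self, run_condition, panel):
        traj = score_trajectory(run_condition(("IFNG", "IL4")), panel,
                                transform="log10")
        assert classify_trajectory(traj) == "self-repolarizing"


class TestConditions:
    def test_28_conditions(self):
        conds = default_conditions()
        assert len(conds) == 28
        assert len([c for c in conds if len(c) == 1]) == 7
        assert len([c for c in conds if len(c) == 2]) == 21

    def test_condition_protocol_hypoxia(self):
        proto = condition_protocol(("IFNG", "HYP"))
        assert proto.oxygen_percent == 2.0
        assert proto.events[0].species == "IFNG_ext"

    def test_unknown_stimulus(self):
        with pytest.raises(ConfigurationError):
            condition_protocol(("LPS",))


@pytest.fixture(scope="module")
def small_map(reference_net, panel, baseline, settings):
    conds = [("IFNG",), ("IL4",), ("TNFA",)]
    return polarization_map(reference_net, panel, conditions=conds,
                            settings=settings, baseline_state=baseline)


class TestPolarizationMap:
    def test_shape(self, small_map, panel):
        assert len(small_map) == 3 * len(panel.all_markers()) * 3
        assert set(small_map.time) == {4.0, 24.0, 48.0}

    def test_deterministic(self, reference_net, panel, baseline, settings,
                           small_map):
        again = polarization_map(reference_net, panel,
                                 conditions=[("IFNG",), ("IL4",), ("TNFA",)],
                                 settings=settings, baseline_state=baseline)
        assert np.array_equal(small_map.log2fc.values, again.log2fc.values)

    def test_tnfa_induces_m1_and_m2_markers(self, small_map, panel):
        # non-mutually-exclusive induction at 24 h
        at24 = small_map[(small_map.condition == "TNFA") &
                         (small_map.time == 24.0)]
        m1_ids = {sid for sid, _ in panel.m1}
        m2_ids = {sid for sid, _ in panel.m2}
        assert (at24[at24.marker.isin(m1_ids)].log2fc > 0).any()
        assert (at24[at24.marker.isin(m2_ids)].log2fc > 0).any()
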