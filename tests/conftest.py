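import numpy as np
import pytest

from macpol.engine import SolverSettings, equilibrate, simulate
from macpol.reference import build_reference_network, default_marker_panel_dict
from macpol.scoring import MarkerPanel, condition_protocol, score_trajectory


@pytest.fixture(scope="session")
def reference_doc():
    return build_reference_network()


@pytest.fixture(scope="session")
def reference_net(reference_doc):
    return reference_doc.network


@pytest.fixture(scope="session")
def settings():
    return SolverSettings()


@pytest.fixture(scope="session")
def baseline(reference_net, settings):
    return equilibrate(reference_net, settings)


@pytest.fixture(scope="session")
def panel():
    return MarkerPanel.from_dict(default_marker_panel_dict())


@pytest.fixture(scope="session")
def run_condition(reference_net, settings, baseline):
    """Simulate one named stimulus combination from the shared baseline."""

    def _run(cond, dose_scale=1.0, duration=48.0):
        proto = condition_protocol(cond, duration=duration)
        proto.dose_scale = dose_scale
        return simulate(reference_net, proto, settings,
                        initial_state=baseline.copy())

    return _run


@pytest.fixture(scope="session")
def score_at(run_condition, panel):
    def _score(cond, t=24.0, dose_scale=1.0):
        traj = score_trajectory(run_condition(cond, dose_scale), panel,
                                transform="log10")
        return traj.at(t)

    return _score
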