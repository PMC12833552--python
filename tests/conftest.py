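import numpy as np
import pytest

from gluebridge import forge


@pytest.fixture(scope="session")
def holo_model():
    """Default glue-bound (holo) interface: more, stronger planted bridges."""
    spec = forge.paper_like_scenario("holo")
    return forge.build_interface_topology(spec)


@pytest.fixture(scope="session")
def holo_run(holo_model):
    """A rendered holo replica (400 frames, default noise) with its manifest."""
    spec = holo_model.spec
    manifest = forge.simulate_bridge_schedule(spec.bridges, 400, seed=91)
    traj = forge.render_trajectory(holo_model, manifest)
    return holo_model, manifest, traj


@pytest.fixture
def rng():
    return np.random.default_rng(20250930)
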