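import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_clips():
    """A small phantom dataset shared across tests."""
    from cscseg.phantom import make_clips
    return make_clips(32, 999)


@pytest.fixture(scope="session")
def desk_results(small_clips):
    """A quickly fitted desk-scale CSC model (full pipeline sans backbone),
    used for interface-level inference tests; trained once per session."""
    from cscseg.model import CSCConfig, CSCModel
    cfg = CSCConfig.desk(use_backbone=False, epochs_phase1=3, epochs_phase2=12,
                         checkpoint_interval=4)
    return CSCModel(small_clips, cfg).fit(seed=0)


@pytest.fixture(scope="session")
def trained_crop_model(small_clips):
    """A crop + U-net model trained long enough to segment its own training
    clips well; used for accuracy-dependent inference tests."""
    from cscseg.model import CSCConfig, CSCModel
    cfg = CSCConfig.desk(use_ed=False, use_backbone=False, epochs_phase2=80,
                         checkpoint_interval=16)
    return CSCModel(small_clips, cfg).fit(seed=0)
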