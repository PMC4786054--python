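import numpy as np
import pytest

from ptccd.cascade import derive_noise_budget
from ptccd.config import DetectorConfig
from ptccd.experiments import EnsembleSpec, run_spot_ensemble


@pytest.fixture(scope="session")
def cfg() -> DetectorConfig:
    return DetectorConfig()


@pytest.fixture(scope="session")
def budget(cfg):
    return derive_noise_budget(cfg.cascade_params())


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture(scope="session")
def zone_a_ensemble(cfg):
    """The zone-A spot ensemble (raw + corrected pipelines) shared by the
    statistical validation tests.  Expensive: built once per session."""
    spec = EnsembleSpec(n_replicates=10_000, zone="A", seed=20260927)
    return run_spot_ensemble(spec, pipeline="both", cfg=cfg)


def combined_3se(*ses: float) -> float:
    return 3.0 * float(np.sqrt(sum(s * s for s in ses)))
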