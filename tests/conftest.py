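import numpy as np
import pytest

from smartscan import AcquisitionParams, RescanPlan
from smartscan.quality import logistic_curve


@pytest.fixture
def defaults():
    """The reference operating point (Table-of-defaults parameters)."""
    return AcquisitionParams()


@pytest.fixture
def curve():
    return logistic_curve()


@pytest.fixture
def toy_pipeline_params():
    """Hand-traceable instance where the parallel equation underestimates:
    compute idles at the section boundary, then backlogs."""
    return AcquisitionParams(
        n_sections=2,
        n_tiles=2,
        t_section_s=100.0,
        t_tile_s=0.0,
        t_fast_s=10.0,
        t_compute_s=50.0,
        t_slow_s=0.0,
        t_trad_s=1.0,
    )


def random_params(rng: np.random.Generator, **overrides) -> AcquisitionParams:
    """Random valid parameter draw for property tests."""
    fields = dict(
        quality_standard=float(rng.uniform(0, 1)),
        n_tiles=int(rng.integers(1, 7)),
        n_sections=int(rng.integers(1, 6)),
        t_trad_s=float(rng.uniform(0, 50)),
        t_fast_s=float(rng.uniform(0, 50)),
        t_slow_s=float(rng.uniform(0, 50)),
        t_compute_s=float(rng.uniform(0, 50)),
        t_tile_s=float(rng.uniform(0, 50)),
        t_section_s=float(rng.uniform(0, 50)),
    )
    fields.update(overrides)
    return AcquisitionParams(**fields)


def random_plan(rng: np.random.Generator) -> RescanPlan:
    return RescanPlan(float(rng.uniform(0, 1)))
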