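import numpy as np
import pytest

from hepatexture.estimators import ESTIMATOR_IDS, EstimatorVector
from hepatexture.phantom import (PhantomSpec, TextureParams,
                                 default_two_class_spec)
from hepatexture.protocols import Protocol


def make_vector(protocol=Protocol.SSFSE_T2, **named):
    """An EstimatorVector with given ids set and every other id = 0."""
    values = {eid: 0.0 for eid in ESTIMATOR_IDS}
    values.update(named)
    return EstimatorVector(values=values, protocol=protocol)


@pytest.fixture(scope="session")
def small_spec():
    """A light-weight phantom spec for fast unit tests."""
    return default_two_class_spec(n_per_class=(2, 2), seed=7,
                                  rows=64, cols=64, n_slices=2)


@pytest.fixture(scope="session")
def quiet_textures():
    """One protocol, no noise / bias / vessels: constant parenchyma."""
    tex = {Protocol.SSFSE_T2: TextureParams(base=500.0, noise_sd=0.0,
                                            skew=0.0, bias_amp=0.0,
                                            vessel_density=0.0)}
    return PhantomSpec(n_per_class=(1, 1), class_textures=(tex, tex),
                       rows=64, cols=64, n_slices=1, seed=0)


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory, small_spec):
    """A generated 2+2 phantom cohort on disk, shared across tests."""
    from hepatexture.phantom import generate_cohort
    out = tmp_path_factory.mktemp("cohort")
    return generate_cohort(small_spec, out)


def rng(seed=0):
    return np.random.default_rng(seed)
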