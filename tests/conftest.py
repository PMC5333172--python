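import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from regevo.expression import ModelParams, TimeGrid
from regevo.synthetic import (
    default_locus_specs,
    default_tf_specs,
    make_genotype,
    make_pwms,
    make_tf_profiles,
    make_wildtype,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tf_specs():
    return default_tf_specs()


@pytest.fixture(scope="session")
def pwms(tf_specs):
    return make_pwms(tf_specs, 42)


@pytest.fixture(scope="session")
def small_world(tf_specs, pwms):
    """A small but complete model system: 4 x 600 bp loci, 12 nuclei,
    coarse time grid.  Used by unit tests that need a real genotype."""
    loci = default_locus_specs(length=600, n_planted=6)
    genotype = make_genotype(loci, pwms, rng_seed=7)
    profiles = make_tf_profiles(12)
    params = ModelParams.default(tf_specs=tf_specs).set_reference_energies(pwms)
    grid = TimeGrid(t_end=3.0, dt=0.02, obs_times=np.arange(0.5, 3.01, 0.5))
    U, annotation = make_wildtype(genotype, params, pwms, profiles, grid)
    return {
        "tf_specs": tf_specs,
        "pwms": pwms,
        "genotype": genotype,
        "profiles": profiles,
        "params": params,
        "grid": grid,
        "U": U,
        "annotation": annotation,
    }
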