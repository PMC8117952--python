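import numpy as np
import pytest

from mbfseg.core import Condition, SliceLocation
from mbfseg.phantom import PhantomConfig, generate_phantom

SLICES = (SliceLocation.BASE, SliceLocation.MID, SliceLocation.APEX)


def dice(a, b) -> float:
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    return 2.0 * (a & b).sum() / (a.sum() + b.sum())


def study_dicts(study):
    """(rest_series, stress_series, rest_maps, stress_maps) by slice."""
    rest = {loc: study.series[(loc, Condition.REST)] for loc in SLICES}
    stress = {loc: study.series[(loc, Condition.STRESS)] for loc in SLICES}
    rmaps = {loc: study.maps[(loc, Condition.REST)] for loc in SLICES}
    smaps = {loc: study.maps[(loc, Condition.STRESS)] for loc in SLICES}
    return rest, stress, rmaps, smaps


@pytest.fixture(scope="session")
def noiseless_study():
    return generate_phantom(PhantomConfig(noise_sd=0.0, mbf_noise_sd=0.0,
                                          rng_seed=1))


@pytest.fixture(scope="session")
def noisy_study():
    """Default study conditions: series SNR 10, map SNR 8."""
    return generate_phantom(PhantomConfig(rng_seed=2))
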