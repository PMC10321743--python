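import logging
import warnings

import numpy as np
import pytest

from spider2d import field_data as fd
from spider2d import synthetic_fields as sf
from spider2d import pipeline

logging.getLogger("spider2d").setLevel(logging.ERROR)
warnings.filterwarnings("ignore", message="subdomain extent")
warnings.filterwarnings("ignore", message="feature matrix has fewer rows")


def small_grid(n=24, nt=24, **kw):
    return sf.default_grid(n=n, nt=nt, **kw)


@pytest.fixture(scope="session")
def probes():
    return pipeline.default_probes(seed=7)


@pytest.fixture(scope="session")
def eq3_clean():
    """Clean cellular-flow fixture with evolving director (64^3)."""

    fields, truth = sf.make_fixture("eq3", seed=1)
    return fields, truth


@pytest.fixture(scope="session")
def eq3_nondim(eq3_clean):
    fields, truth = eq3_clean
    nf, scales = fd.nondimensionalize(fields)
    return nf, scales, truth


@pytest.fixture(scope="session")
def eq9_clean():
    fields, truth = sf.make_fixture("eq9", seed=1)
    return fields, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
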