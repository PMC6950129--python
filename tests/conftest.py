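import numpy as np
import pytest

import pbsource as pb


@pytest.fixture(scope="session")
def case_inputs():
    """The bundled case-study end-members and 32 soil samples."""
    return pb.load_case_study_inputs()


@pytest.fixture(scope="session")
def case_sources(case_inputs):
    return case_inputs[0]


@pytest.fixture(scope="session")
def case_samples(case_inputs):
    return case_inputs[1]


@pytest.fixture()
def rng():
    return np.random.default_rng(20260923)


def random_source_set(rng, n, spread=0.02):
    """Independent generator of plausible end-members for oracle tests
    (does not go through pbsource.synthetic)."""
    anchor = np.log([38.2, 15.55, 18.15])
    ratios = np.exp(anchor + spread * rng.standard_normal((n, 3)))
    return pb.SourceSet(
        tuple(f"src{i}" for i in range(n)),
        tuple(pb.RatioTriple(*row, pb.Parameterization.REF_204) for row in ratios),
    )
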