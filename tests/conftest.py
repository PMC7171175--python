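import hypothesis
import numpy as np
import pytest

hypothesis.settings.register_profile(
    "deterministic", derandomize=True, deadline=None, max_examples=50
)
hypothesis.settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def quick_fit_opts():
    """Reduced sampler settings for fast smoke fits in unit tests."""
    return dict(walkers=32, tune=400, draws=200, min_ess=50.0, retry=False)


@pytest.fixture(scope="session")
def dox_viability_fit():
    """Viability-only posterior on a growth-dominant synthetic assay."""
    from growthdeath.identifiability import fit_viability_only
    from growthdeath.synthetic import fixture_truth, generate_viability_assay

    doses = tuple((640 * 0.5 ** np.arange(12))[::-1].round(4))
    truth = fixture_truth("DOX-like", seed=11, doses=doses)
    assay = generate_viability_assay(truth)
    return truth, assay, fit_viability_only(assay, seed=21)
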