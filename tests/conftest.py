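import pytest
from hypothesis import HealthCheck, settings

import capturedkit as ck

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def medan():
    return ck.load_medan_fixture()


@pytest.fixture(scope="session")
def medan_matrix(medan):
    profiles = [ck.score_species(t, abundance_mode="medan_compat") for t in medan.traits]
    return ck.build_score_matrix(profiles)


@pytest.fixture(scope="session")
def medan_report(medan, medan_matrix):
    return ck.analyze(medan_matrix, medan.counts, k=2, pca_mode="correlation")
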