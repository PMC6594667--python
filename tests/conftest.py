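import copy

import pytest
from hypothesis import settings

from iccm_dqa import SyntheticConfig, generate, load_system_map

settings.register_profile("deterministic", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("deterministic")


# a 4-level chain (community -> facility -> district -> national HIS)
# with 2 facilities and 5 CHWs, small enough to hand-check every metric
SMALL_SYSTEM_CONFIG = {
    "levels": [
        {"id": "community", "name": "Community", "rank": 0, "role": "community"},
        {"id": "facility", "name": "Facility", "rank": 1, "role": "facility"},
        {"id": "district", "name": "District", "rank": 2, "role": "intermediate"},
        {"id": "national", "name": "National HIS", "rank": 3, "role": "terminal"},
    ],
    "sites": [
        {"id": "national", "level": "national"},
        {"id": "d1", "level": "district", "parents": ["national"]},
        {"id": "f1", "level": "facility", "parents": ["d1"], "n_chws": 3},
        {"id": "f2", "level": "facility", "parents": ["d1"], "n_chws": 2},
        {"id": "c1", "level": "community", "parents": ["f1"]},
        {"id": "c2", "level": "community", "parents": ["f1"]},
        {"id": "c3", "level": "community", "parents": ["f1"]},
        {"id": "c4", "level": "community", "parents": ["f2"]},
        {"id": "c5", "level": "community", "parents": ["f2"]},
    ],
    "indicators": [
        {
            "id": "malaria_treated",
            "illness": "malaria",
            "register_rule": "malaria_default",
            "report_field": "malaria_treated",
        }
    ],
    "flows": [
        ["community", "facility"],
        ["facility", "district"],
        ["district", "national"],
    ],
}


def small_config() -> dict:
    return copy.deepcopy(SMALL_SYSTEM_CONFIG)


@pytest.fixture
def small_system():
    return load_system_map(small_config())


@pytest.fixture(scope="session")
def zero_error_bundle():
    return generate(SyntheticConfig.zero_error(seed=11))


@pytest.fixture(scope="session")
def noisy_bundle():
    return generate(SyntheticConfig(seed=7))
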