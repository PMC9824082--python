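"""Shared fixtures: one synthetic study build reused across the suite."""

import numpy as np
import pytest

from thermact import preprocess, synthetic_data


@pytest.fixture(scope="session")
def scene():
    return synthetic_data.SceneConfig()


@pytest.fixture(scope="session")
def coventry_records(scene):
    """The full two-layout synthetic design (480 single + 210 double records)."""
    return synthetic_data.build_coventry_like(scene, seed=0)


@pytest.fixture(scope="session")
def small8(coventry_records):
    """8-class single-subject small-layout tensor (Z=240), sensor S1."""
    recs = [r for r in coventry_records if r.n_subjects == 1 and r.layout == "small"]
    return preprocess.build_dataset(recs, "S1")


@pytest.fixture(scope="session")
def large8(coventry_records):
    """8-class single-subject large-layout tensor (Z=240), sensor S1."""
    recs = [r for r in coventry_records if r.n_subjects == 1 and r.layout == "large"]
    return preprocess.build_dataset(recs, "S1")


@pytest.fixture(scope="session")
def large15(coventry_records):
    """15-class large-layout tensor (8 single + 7 double classes, Z=450)."""
    recs = [r for r in coventry_records if r.layout == "large"]
    return preprocess.build_dataset(recs, "S1")


@pytest.fixture(scope="session")
def adl_records(scene):
    """The second-design synthetic build (9 participants x 9 activities x 3)."""
    return synthetic_data.build_infra_adl_like(scene, seed=0)


@pytest.fixture(scope="session")
def fisher15(large15):
    """Fisher canonical variables fitted once on the 15-class tensor."""
    from thermact import features

    return features.fisher_fit(large15)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def random_map(rng):
    """A generic finite 40x64 map with mild structure."""
    base = 19.0 + rng.normal(0, 0.5, size=(40, 64))
    base[:, 20:30] += 3.0
    return base
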