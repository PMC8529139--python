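import pytest

import dtameta as dm

OUTLIER_IDS = ["Taylor2008", "Lai2017"]


@pytest.fixture(scope="session")
def mir21():
    """The packaged 30-trial exosomal miR-21 study set."""
    return dm.load_fixture("liu2021_mir21")


@pytest.fixture(scope="session")
def mir21_fit(mir21):
    """Full-fixture bivariate ML fit, shared across tests."""
    return dm.fit_bivariate(mir21)


@pytest.fixture(scope="session")
def mir21_summary(mir21_fit):
    return dm.pooled_summary(mir21_fit)


@pytest.fixture(scope="session")
def mir21_excluded(mir21):
    """Refit with the two perfect-cell trials removed."""
    return dm.refit_excluding(mir21, OUTLIER_IDS)


@pytest.fixture
def toy_studies():
    """Four mid-sized heterogeneous trials for cheap fits."""
    mk = dm.Study2x2
    return dm.StudySet(
        [
            mk(study_id="a", tp=45, fn=15, fp=10, tn=50),
            mk(study_id="b", tp=30, fn=20, fp=20, tn=40),
            mk(study_id="c", tp=55, fn=5, fp=5, tn=55),
            mk(study_id="d", tp=40, fn=10, fp=15, tn=45),
        ],
        provenance="toy",
    )
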