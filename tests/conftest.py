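import datetime as dt
import io

import pytest

import seasonet as sn

FIXTURE_SEED = 1


@pytest.fixture(scope="session")
def community():
    """One default synthetic study year (records + ground truth), shared."""
    cfg = sn.CommunityConfig()
    records, truth = sn.generate_community(cfg, seed=FIXTURE_SEED)
    return cfg, records, truth


@pytest.fixture
def four_records():
    d1, d2 = dt.date(2008, 11, 3), dt.date(2008, 11, 10)
    return [
        sn.VisitRecord(d1, "P1", "B1"),
        sn.VisitRecord(d2, "P1", "B1"),
        sn.VisitRecord(d1, "P2", "B2"),
        sn.VisitRecord(d1, "P2", "B3"),
    ]


def visits_csv(text: str) -> io.StringIO:
    return io.StringIO(text.strip() + "\n")
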