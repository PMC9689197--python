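import pytest

from spinemult import (
    AgeYM,
    GrowthDatabase,
    GrowthRecord,
    Sex,
    load_packaged_table,
)


@pytest.fixture(scope="session")
def table():
    return load_packaged_table()


def make_database(curves, maturity=None, provenance="test"):
    """Build a GrowthDatabase from {(sex, percentile): {total_months: height}}."""
    records = [
        GrowthRecord(sex, label, AgeYM.from_total_months(t), h)
        for (sex, label), curve in curves.items()
        for t, h in curve.items()
    ]
    return GrowthDatabase(records, maturity_age=maturity, provenance=provenance)


@pytest.fixture
def toy_database():
    """One male P50 curve: 60 cm at 5 y, 90 cm at maturity -> M(5y) = 1.5."""
    return make_database(
        {(Sex.MALE, "P50"): {60: 60.0, 216: 90.0}},
        maturity={Sex.MALE: 216, Sex.FEMALE: 192},
    )
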