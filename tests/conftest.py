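import datetime

import pytest

from pathbroker import fixtures
from pathbroker.records import PatientRecord
from pathbroker.warehouse import Warehouse


@pytest.fixture(scope="session")
def small_spec():
    return fixtures.FixtureSpec(seed=11, n_patients=4, base_size=512,
                                wsi_levels=2)


@pytest.fixture(scope="session")
def dataset(small_spec, tmp_path_factory):
    """One small synthetic archive shared by read-only tests."""
    root = tmp_path_factory.mktemp("archive")
    return fixtures.generate_fixture_dataset(small_spec, root)


@pytest.fixture()
def warehouse(dataset):
    wf = dataset.warehouse_fixture
    wh = Warehouse()
    wh.ingest(wf.patients, wf.cases, wf.slides, wf.images, wf.reports)
    return wh


@pytest.fixture()
def jane():
    return PatientRecord(
        mrn="1482928",
        name="Jane Doe",
        birth_date=datetime.date(1970, 5, 1),
        npp_signed=True,
        protocol_enrollments={"PR-001": "consented"},
    )
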