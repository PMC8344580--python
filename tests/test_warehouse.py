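"""Warehouse ingest integrity, cohort queries and consent gating."""

import datetime

import pytest

from pathbroker import fixtures
from pathbroker.records import (
    CaseRecord,
    CohortCriteria,
    ImageRecord,
    PathologyReport,
    PatientRecord,
    SlideRecord,
)
from pathbroker.warehouse import IngestError, Warehouse


def _patient(mrn="1482928", **kw):
    kw.setdefault("name", "Jane Doe")
    kw.setdefault("birth_date", datetime.date(1970, 5, 1))
    return PatientRecord(mrn=mrn, **kw)


class TestIngest:
    def test_minimal_patient_and_case(self):
        wh = Warehouse()
        counts = wh.ingest(
            patients=[_patient()],
            cases=[CaseRecord(accession="S20-0123", mrn="1482928")],
        )
        assert counts["patients"] == 1 and counts["cases"] == 1

    def test_empty_streams_give_empty_warehouse(self):
        assert all(v == 0 for v in Warehouse().ingest().values())

    def test_dangling_image_barcode_rejected(self):
        wh = Warehouse()
        img = ImageRecord(image_id="X1", barcode="nope", file_path="/x",
                          scan_date=datetime.date(2020, 1, 1))
        with pytest.raises(IngestError, match="unknown barcode"):
            wh.ingest(patients=[_patient()], images=[img])

    def test_dangling_case_mrn_rejected(self):
        with pytest.raises(IngestError, match="unknown MRN"):
            Warehouse().ingest(cases=[CaseRecord(accession="S20-1", mrn="999999")])

    def test_duplicate_mrn_rejected(self):
        with pytest.raises(IngestError, match="duplicate"):
            Warehouse().ingest(patients=[_patient(), _patient()])

    @pytest.mark.parametrize("bad", ["X20-0123", "S2-0123", "S20_0123", "20-0123"])
    def test_accession_grammar_enforced_at_record_level(self, bad):
        with pytest.raises(ValueError):
            CaseRecord(accession=bad, mrn="1482928")

    def test_mrn_must_be_digits(self):
        with pytest.raises(ValueError):
            _patient(mrn="12a4")


class TestCohortQuery:
    def test_keyword_matches_brute_force(self, warehouse, dataset):
        """Keyword hits must equal an independent scan of every report."""
        wf = dataset.warehouse_fixture
        keyword = "carcinoma"
        expected_cases = {
            r.accession for r in wf.reports if keyword in r.text.lower()
        }
        expected_images = {
            i.image_id
            for i in wf.images
            for s in wf.slides
            if i.barcode == s.barcode and s.accession in expected_cases
        }
        hits = warehouse.query_cohort(
            CohortCriteria(report_keywords=(keyword,)))
        assert {h.image_id for h in hits} == expected_images

    def test_protocol_only_returns_all_images(self, warehouse, dataset):
        hits = warehouse.query_cohort(
            CohortCriteria(protocol_id=dataset.spec.protocol_id))
        assert len(hits) == len(dataset.warehouse_fixture.images)

    def test_date_range_excluding_everything(self, warehouse):
        hits = warehouse.query_cohort(CohortCriteria(
            date_range=(datetime.date(1990, 1, 1), datetime.date(1990, 1, 2))))
        assert hits == []

    def test_unknown_protocol_errors(self, warehouse):
        with pytest.raises(KeyError):
            warehouse.query_cohort(CohortCriteria(protocol_id="NOPE"))

    def test_conjunction_is_anti_monotone(self, warehouse, dataset):
        """Adding a criterion never enlarges the result set."""
        base = warehouse.query_cohort(
            CohortCriteria(protocol_id=dataset.spec.protocol_id))
        for extra in (
            CohortCriteria(protocol_id=dataset.spec.protocol_id,
                           stains=frozenset({"H&E"})),
            CohortCriteria(protocol_id=dataset.spec.protocol_id,
                           vendors=frozenset({"leica"})),
            CohortCriteria(protocol_id=dataset.spec.protocol_id,
                           report_keywords=("carcinoma",)),
        ):
            narrowed = warehouse.query_cohort(extra)
            assert {h.image_id for h in narrowed} <= {h.image_id for h in base}

    def test_deterministic_ordering(self, warehouse, dataset):
        crit = CohortCriteria(protocol_id=dataset.spec.protocol_id)
        a = warehouse.query_cohort(crit)
        b = warehouse.query_cohort(crit)
        assert a == b
        assert a == sorted(a, key=lambda h: (h.accession, h.image_id))

    def test_criteria_requires_at_least_one_field(self):
        with pytest.raises(ValueError):
            CohortCriteria()


class TestConsent:
    def test_consented_with_npp_included(self, warehouse, dataset, jane):
        wf = dataset.warehouse_fixture
        mrn = next(m for m, (inc, _) in wf.consent_truth.items() if inc)
        imgs = _images_of_patient(wf, mrn)
        decision = warehouse.enforce_consent(imgs, dataset.spec.protocol_id)
        assert set(decision.included) == set(imgs)

    def test_matches_brute_force_per_patient_filter(self):
        """n=50 at 60% consent: inclusion equals an independent filter."""
        spec = fixtures.FixtureSpec(seed=7, n_patients=50, consent_rate=0.6)
        wf = fixtures.generate_warehouse(spec)
        wh = Warehouse()
        wh.ingest(wf.patients, wf.cases, wf.slides, wf.images, wf.reports)
        all_images = [i.image_id for i in wf.images]
        decision = wh.enforce_consent(all_images, spec.protocol_id)

        # independent per-record filter straight off the record streams
        patients = {p.mrn: p for p in wf.patients}
        case_mrn = {c.accession: c.mrn for c in wf.cases}
        slide_acc = {s.barcode: s.accession for s in wf.slides}
        expected = [
            i.image_id for i in wf.images
            if patients[case_mrn[slide_acc[i.barcode]]].npp_signed
            and patients[case_mrn[slide_acc[i.barcode]]]
            .protocol_enrollments.get(spec.protocol_id) == "consented"
        ]
        assert list(decision.included) == expected
        assert set(decision.included) == {
            m for m in all_images
            if m in expected
        }

    def test_unknown_status_excluded_with_reason(self, warehouse, dataset):
        wf = dataset.warehouse_fixture
        for mrn, (inc, reason) in wf.consent_truth.items():
            imgs = _images_of_patient(wf, mrn)
            decision = warehouse.enforce_consent(imgs, dataset.spec.protocol_id)
            if inc:
                assert not decision.excluded
            else:
                assert {r for _, r in decision.excluded} == {reason}

    def test_idempotent(self, warehouse, dataset):
        all_images = [i.image_id for i in dataset.warehouse_fixture.images]
        once = warehouse.enforce_consent(all_images, dataset.spec.protocol_id)
        twice = warehouse.enforce_consent(once.included, dataset.spec.protocol_id)
        assert twice.included == once.included and not twice.excluded

    def test_partition(self, warehouse, dataset):
        all_images = [i.image_id for i in dataset.warehouse_fixture.images]
        d = warehouse.enforce_consent(all_images, dataset.spec.protocol_id)
        included, excluded = set(d.included), {i for i, _ in d.excluded}
        assert included | excluded == set(all_images)
        assert not included & excluded


def _images_of_patient(wf, mrn):
    accs = {c.accession for c in wf.cases if c.mrn == mrn}
    barcodes = {s.barcode for s in wf.slides if s.accession in accs}
    return [i.image_id for i in wf.images if i.barcode in barcodes]
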