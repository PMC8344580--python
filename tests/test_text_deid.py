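"""Date truncation, HID key store, and report redaction."""

import datetime
import re
from collections import Counter

import pytest

from pathbroker import fixtures, text_deid
from pathbroker.records import (
    CaseRecord,
    ImageRecord,
    PathologyReport,
    PatientRecord,
    SlideRecord,
)
from pathbroker.text_deid import (
    HIDKeyStore,
    RedactionRule,
    RedactionRuleSet,
    default_rules,
    deidentify_record,
    redact_report,
    truncate_date,
)


class TestTruncateDate:
    @pytest.mark.parametrize(
        "date,year",
        [
            (datetime.date(2020, 3, 15), "2020"),
            (datetime.date(1999, 12, 31), "1999"),
            (datetime.date(2020, 2, 29), "2020"),  # leap day
            ("2019-06-02", "2019"),
        ],
    )
    def test_truncates_to_year(self, date, year):
        assert truncate_date(date) == year

    @pytest.mark.parametrize("bad", ["06/02/19", "not a date", "", None, 42])
    def test_unparseable_never_passes_through(self, bad):
        with pytest.raises(ValueError):
            truncate_date(bad)


class TestHIDKeyStore:
    def test_idempotent(self, tmp_path):
        store = HIDKeyStore(tmp_path / "ks.jsonl")
        assert store.assign("patient", "1482928") == store.assign("patient", "1482928")

    def test_injective(self):
        store = HIDKeyStore()
        assert store.assign("case", "S20-0123") != store.assign("case", "S20-0124")

    def test_guid_hid_shares_no_4char_substring(self):
        """Independent substring scan: the HID leaks nothing of the GUID."""
        guid = "936DA01F-9ABD-4D9D-80C7-02AF85C822A8"
        hid = HIDKeyStore(key=b"\x01" * 16).assign("image", guid)
        low_guid, low_hid = guid.lower(), hid.lower()
        grams = {low_guid[i:i + 4] for i in range(len(low_guid) - 3)}
        assert not any(g in low_hid for g in grams)

    def test_family_prefixes(self):
        store = HIDKeyStore()
        assert store.assign("patient", "1").startswith("P-")
        assert store.assign("case", "S20-1").startswith("C-")
        assert store.assign("image", "g").startswith("I-")

    def test_stable_across_restart(self, tmp_path):
        path = tmp_path / "ks.jsonl"
        first = HIDKeyStore(path)
        hids = {o: first.assign("patient", o) for o in ("111111", "222222")}
        reopened = HIDKeyStore(path)
        for orig, hid in hids.items():
            assert reopened.assign("patient", orig) == hid

    def test_reidentification_round_trip(self, tmp_path):
        store = HIDKeyStore(tmp_path / "ks.jsonl")
        originals = [f"{n:07d}" for n in range(50)]
        hids = [store.assign("patient", o) for o in originals]
        assert [store.original("patient", h) for h in hids] == originals

    def test_families_disjoint(self):
        store = HIDKeyStore()
        p = store.assign("patient", "same-id")
        c = store.assign("case", "same-id")
        assert p != c

    def test_empty_original_rejected(self):
        with pytest.raises(ValueError):
            HIDKeyStore().assign("patient", "")


class TestRedaction:
    def test_worked_example(self, jane):
        r = redact_report("S20-0123 from JANE DOE on 03/15/2020", patient=jane)
        assert r.deid_text == "[ACCESSION] from [PATIENT] on [DATE-2020]"

    def test_clean_text_unchanged(self, jane):
        text = "Benign tissue without atypia."
        r = redact_report(text, patient=jane)
        assert r.deid_text == text and r.spans == ()

    def test_mrn_mid_sentence(self, jane):
        r = redact_report("Patient 1482928 was seen today.", patient=jane)
        assert "1482928" not in r.deid_text
        assert "[MRN]" in r.deid_text

    @pytest.mark.parametrize(
        "text,expect",
        [
            ("on 2020-03-15 we", "on [DATE-2020] we"),
            ("on 3/5/2020 we", "on [DATE-2020] we"),
            ("on 06/02/19 we", "on [DATE-2019] we"),
            ("on March 15, 2020 we", "on [DATE-2020] we"),
            ("seen Doe, Jane here", "seen [PATIENT] here"),
            ("seen jane doe here", "seen [PATIENT] here"),
        ],
    )
    def test_grammar_dialects(self, jane, text, expect):
        assert redact_report(text, patient=jane).deid_text == expect

    def test_spans_reconstruct_deid_text(self, jane):
        text = "S20-0123 Jane Doe 1482928 2020-01-02"
        r = redact_report(text, patient=jane)
        assert r.reconstruct(text) == r.deid_text
        starts = [s.start for s in r.spans]
        assert starts == sorted(starts)
        for a, b in zip(r.spans, r.spans[1:]):
            assert a.end <= b.start

    def test_fixed_point(self, jane):
        text = "S20-0123 from Jane Doe on 03/15/2020, MRN 1482928."
        once = redact_report(text, patient=jane)
        twice = redact_report(once.deid_text, patient=jane)
        assert twice.deid_text == once.deid_text and twice.spans == ()

    def test_year_multiset_preserved(self, jane):
        text = "Seen 03/15/2020, again 2020-06-01 and January 2, 1999."
        r = redact_report(text, patient=jane)
        before = Counter(["2020", "2020", "1999"])
        after = Counter(re.findall(r"\[DATE-(\d{4})\]", r.deid_text))
        assert after == before

    def test_placeholder_with_digits_rejected(self):
        with pytest.raises(ValueError, match="digits"):
            RedactionRuleSet(rules=(
                RedactionRule("mrn", re.compile(r"\d{6,9}"), "[MRN2]"),
            ))

    def test_empty_ruleset_rejected(self):
        with pytest.raises(ValueError):
            RedactionRuleSet(rules=())

    def test_recall_on_planted_fixture_spans(self):
        """Every planted PHI span across fixture reports is replaced."""
        spec = fixtures.FixtureSpec(seed=23, n_patients=40, phi_density=6)
        wf = fixtures.generate_warehouse(spec)
        patients = {p.mrn: p for p in wf.patients}
        case_mrn = {c.accession: c.mrn for c in wf.cases}
        total = missed = 0
        for i, rep in enumerate(wf.reports):
            pt = patients[case_mrn[rep.accession]]
            red = redact_report(rep.text, patient=pt)
            for sp in wf.report_spans[i]:
                total += 1
                covered = any(s.start <= sp.start and s.end >= sp.end
                              for s in red.spans)
                if not covered or sp.text in red.deid_text:
                    missed += 1
        assert total == 40 * 6
        assert missed == 0


class TestDeidentifyRecord:
    def test_slide_keeps_part_and_block(self):
        store = HIDKeyStore()
        slide = SlideRecord(barcode="S20-0123;2;3", accession="S20-0123",
                            part_id=2, block_id=3)
        row = deidentify_record(slide, store)
        assert row["part_id"] == 2 and row["block_id"] == 3
        assert "barcode" not in row
        assert row["case_hid"].startswith("C-")

    def test_image_scan_date_truncated_and_path_dropped(self):
        store = HIDKeyStore()
        img = ImageRecord(image_id="G1", barcode="b", file_path="/secret/x.svs",
                          scan_date=datetime.date(2019, 6, 2))
        row = deidentify_record(img, store)
        assert row["scan_year"] == "2019"
        assert "file_path" not in row and "barcode" not in row

    def test_patient_reduced_to_hid_and_birth_year(self, jane):
        row = deidentify_record(jane, HIDKeyStore())
        assert set(row) == {"patient_hid", "birth_year"}
        assert row["birth_year"] == "1970"

    def test_unknown_type_fails_closed(self):
        with pytest.raises(TypeError):
            deidentify_record({"mrn": "1"}, HIDKeyStore())
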