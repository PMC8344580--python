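"""Embedded data warehouse: ingest, cohort query, consent gating.

The warehouse combines scanned-image metadata with case, slide, report
and patient/consent information and answers research cohort requests.
Inclusion of a patient's images in a research dataset requires an
affirmative trail: a signed Notice of Privacy Practice AND "consented"
status on the requesting protocol; "unknown" excludes conservatively.

Storage is an embedded sqlite database (in-memory by default) keyed by
the platform identifiers (MRN, accession, barcode, image ID).
"""

from __future__ import annotations

import datetime
import json
import sqlite3
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .records import (
    CaseRecord,
    CohortCriteria,
    IdentifierBundle,
    ImageRecord,
    PathologyReport,
    PatientRecord,
    SlideRecord,
)

EXCLUSION_REASONS = ("npp_missing", "not_consented", "unknown_consent")

_SCHEMA = """
CREATE TABLE patients (
    mrn TEXT PRIMARY KEY, name TEXT NOT NULL, birth_date TEXT NOT NULL,
    npp_signed INTEGER NOT NULL
);
CREATE TABLE enrollments (
    mrn TEXT NOT NULL REFERENCES patients(mrn),
    protocol_id TEXT NOT NULL, status TEXT NOT NULL,
    PRIMARY KEY (mrn, protocol_id)
);
CREATE TABLE cases (
    accession TEXT PRIMARY KEY,
    mrn TEXT NOT NULL REFERENCES patients(mrn)
);
CREATE TABLE parts (
    accession TEXT NOT NULL REFERENCES cases(accession),
    part_id INTEGER NOT NULL, description TEXT NOT NULL DEFAULT '',
    PRIMARY KEY (accession, part_id)
);
CREATE TABLE slides (
    barcode TEXT PRIMARY KEY,
    accession TEXT NOT NULL, part_id INTEGER NOT NULL, block_id INTEGER NOT NULL,
    stain TEXT NOT NULL, scanner_vendor TEXT NOT NULL, scanner_model TEXT NOT NULL,
    FOREIGN KEY (accession, part_id) REFERENCES parts(accession, part_id)
);
CREATE TABLE images (
    image_id TEXT PRIMARY KEY,
    barcode TEXT NOT NULL REFERENCES slides(barcode),
    file_path TEXT NOT NULL, scan_date TEXT NOT NULL,
    quality_factor INTEGER, sequence_index INTEGER NOT NULL
);
CREATE TABLE reports (
    accession TEXT NOT NULL REFERENCES cases(accession),
    text TEXT NOT NULL, report_date TEXT NOT NULL
);
"""


class IngestError(ValueError):
    """Raised for dangling references, duplicates or grammar violations."""


@dataclass(frozen=True)
class CohortImage:
    """One image hit of a cohort query, with its linkage chain."""

    image_id: str
    barcode: str
    accession: str
    mrn: str


@dataclass(frozen=True)
class ConsentDecision:
    included: tuple[str, ...]
    excluded: tuple[tuple[str, str], ...]  # (image_id, reason)


class Warehouse:
    """Queryable store of the five record streams.

    Referential integrity (slide→case/part, image→slide, report→case,
    case→patient) is enforced at :meth:`ingest`; a dangling reference or
    duplicate primary identifier aborts the load naming the offender.
    """

    def __init__(self, path: str | Path = ":memory:"):
        self._conn = sqlite3.connect(str(path))
        self._conn.executescript(_SCHEMA)

    # -- ingest ----------------------------------------------------------

    def ingest(
        self,
        patients: Iterable[PatientRecord] = (),
        cases: Iterable[CaseRecord] = (),
        slides: Iterable[SlideRecord] = (),
        images: Iterable[ImageRecord] = (),
        reports: Iterable[PathologyReport] = (),
    ) -> dict[str, int]:
        """Load all streams, enforce integrity, return counts per type."""
        patients = list(patients)
        cases = list(cases)
        slides = list(slides)
        images = list(images)
        reports = list(reports)

        self._check_unique("patient MRN", [p.mrn for p in patients])
        self._check_unique("case accession", [c.accession for c in cases])
        self._check_unique("slide barcode", [s.barcode for s in slides])
        self._check_unique("image ID", [i.image_id for i in images])

        mrns = {p.mrn for p in patients}
        accessions = {c.accession for c in cases}
        part_keys = {(c.accession, p.part_id) for c in cases for p in c.parts}
        barcodes = {s.barcode for s in slides}
        for c in cases:
            if c.mrn not in mrns:
                raise IngestError(f"case {c.accession} references unknown MRN {c.mrn}")
        for s in slides:
            if (s.accession, s.part_id) not in part_keys:
                raise IngestError(
                    f"slide {s.barcode} references unknown part "
                    f"({s.accession}, {s.part_id})"
                )
        for i in images:
            if i.barcode not in barcodes:
                raise IngestError(f"image {i.image_id} references unknown barcode {i.barcode}")
        for r in reports:
            if r.accession not in accessions:
                raise IngestError(f"report references unknown accession {r.accession}")

        cur = self._conn
        for p in patients:
            cur.execute(
                "INSERT INTO patients VALUES (?,?,?,?)",
                (p.mrn, p.name, p.birth_date.isoformat(), int(p.npp_signed)),
            )
            for proto, status in p.protocol_enrollments.items():
                cur.execute("INSERT INTO enrollments VALUES (?,?,?)", (p.mrn, proto, status))
        for c in cases:
            cur.execute("INSERT INTO cases VALUES (?,?)", (c.accession, c.mrn))
            for part in c.parts:
                cur.execute(
                    "INSERT INTO parts VALUES (?,?,?)",
                    (c.accession, part.part_id, part.description),
                )
        for s in slides:
            cur.execute(
                "INSERT INTO slides VALUES (?,?,?,?,?,?,?)",
                (s.barcode, s.accession, s.part_id, s.block_id, s.stain,
                 s.scanner_vendor, s.scanner_model),
            )
        for i in images:
            cur.execute(
                "INSERT INTO images VALUES (?,?,?,?,?,?)",
                (i.image_id, i.barcode, i.file_path, i.scan_date.isoformat(),
                 i.quality_factor, i.sequence_index),
            )
        for r in reports:
            cur.execute(
                "INSERT INTO reports VALUES (?,?,?)",
                (r.accession, r.text, r.report_date.isoformat()),
            )
        cur.commit()
        return {
            "patients": len(patients),
            "cases": len(cases),
            "slides": len(slides),
            "images": len(images),
            "reports": len(reports),
        }

    @staticmethod
    def _check_unique(label: str, ids: Sequence[str]) -> None:
        seen: set[str] = set()
        for i in ids:
            if i in seen:
                raise IngestError(f"duplicate {label}: {i}")
            seen.add(i)

    # -- lookup helpers --------------------------------------------------

    def counts(self) -> dict[str, int]:
        out = {}
        for table in ("patients", "cases", "slides", "images", "reports"):
            out[table] = self._conn.execute(f"SELECT COUNT(*) FROM {table}").fetchone()[0]
        return out

    def patient(self, mrn: str) -> PatientRecord:
        row = self._conn.execute(
            "SELECT mrn, name, birth_date, npp_signed FROM patients WHERE mrn=?", (mrn,)
        ).fetchone()
        if row is None:
            raise KeyError(f"unknown MRN {mrn}")
        enroll = dict(
            self._conn.execute(
                "SELECT protocol_id, status FROM enrollments WHERE mrn=?", (mrn,)
            ).fetchall()
        )
        return PatientRecord(
            mrn=row[0], name=row[1], birth_date=datetime.date.fromisoformat(row[2]),
            npp_signed=bool(row[3]), protocol_enrollments=enroll,
        )

    def image(self, image_id: str) -> ImageRecord:
        row = self._conn.execute(
            "SELECT image_id, barcode, file_path, scan_date, quality_factor, "
            "sequence_index FROM images WHERE image_id=?", (image_id,)
        ).fetchone()
        if row is None:
            raise KeyError(f"unknown image {image_id}")
        return ImageRecord(
            image_id=row[0], barcode=row[1], file_path=row[2],
            scan_date=datetime.date.fromisoformat(row[3]),
            quality_factor=row[4], sequence_index=row[5],
        )

    def slide(self, barcode: str) -> SlideRecord:
        row = self._conn.execute(
            "SELECT barcode, accession, part_id, block_id, stain, scanner_vendor, "
            "scanner_model FROM slides WHERE barcode=?", (barcode,)
        ).fetchone()
        if row is None:
            raise KeyError(f"unknown barcode {barcode}")
        return SlideRecord(
            barcode=row[0], accession=row[1], part_id=row[2], block_id=row[3],
            stain=row[4], scanner_vendor=row[5], scanner_model=row[6],
        )

    def case(self, accession: str) -> CaseRecord:
        row = self._conn.execute(
            "SELECT accession, mrn FROM cases WHERE accession=?", (accession,)
        ).fetchone()
        if row is None:
            raise KeyError(f"unknown accession {accession}")
        parts = self._conn.execute(
            "SELECT part_id, description FROM parts WHERE accession=? ORDER BY part_id",
            (accession,),
        ).fetchall()
        return CaseRecord(
            accession=row[0], mrn=row[1],
            parts=tuple({"part_id": p, "description": d} for p, d in parts),
        )

    def reports_for(self, accession: str) -> list[PathologyReport]:
        rows = self._conn.execute(
            "SELECT accession, text, report_date FROM reports WHERE accession=?",
            (accession,),
        ).fetchall()
        return [
            PathologyReport(
                accession=a, text=t, report_date=datetime.date.fromisoformat(d)
            )
            for a, t, d in rows
        ]

    def known_protocols(self) -> set[str]:
        return {
            r[0]
            for r in self._conn.execute("SELECT DISTINCT protocol_id FROM enrollments")
        }

    def identifier_bundle(self, image_id: str) -> IdentifierBundle:
        """Full identifier chain for one image, for de-id verification."""
        img = self.image(image_id)
        sld = self.slide(img.barcode)
        pat = self.patient(self.case(sld.accession).mrn)
        return IdentifierBundle(
            mrn=pat.mrn, patient_name=pat.name, accession=sld.accession,
            part_id=sld.part_id, block_id=sld.block_id, barcode=sld.barcode,
            image_id=img.image_id, file_path=img.file_path,
        )

    # -- cohort query ----------------------------------------------------

    def query_cohort(self, criteria: CohortCriteria) -> list[CohortImage]:
        """Images whose linkage satisfies every stated criterion.

        Keyword matching is case-insensitive substring over the case's
        report text (a case matches when at least one of its reports
        contains all keywords).  Result is deterministically ordered by
        (accession, image_id).
        """
        if criteria.protocol_id is not None:
            if criteria.protocol_id not in self.known_protocols():
                raise KeyError(f"unknown protocol_id {criteria.protocol_id}")

        rows = self._conn.execute(
            "SELECT i.image_id, i.barcode, s.accession, c.mrn, i.scan_date, "
            "s.stain, s.scanner_vendor "
            "FROM images i JOIN slides s ON i.barcode = s.barcode "
            "JOIN cases c ON s.accession = c.accession"
        ).fetchall()

        matching_cases: Optional[set[str]] = None
        if criteria.report_keywords:
            keywords = [k.lower() for k in criteria.report_keywords]
            matching_cases = set()
            for acc, text in self._conn.execute("SELECT accession, text FROM reports"):
                low = text.lower()
                if all(k in low for k in keywords):
                    matching_cases.add(acc)

        out = []
        for image_id, barcode, accession, mrn, scan_date, stain, vendor in rows:
            if matching_cases is not None and accession not in matching_cases:
                continue
            if criteria.date_range is not None:
                d = datetime.date.fromisoformat(scan_date)
                if not criteria.date_range[0] <= d <= criteria.date_range[1]:
                    continue
            if criteria.stains is not None and stain not in criteria.stains:
                continue
            if criteria.vendors is not None and vendor not in criteria.vendors:
                continue
            out.append(CohortImage(image_id=image_id, barcode=barcode,
                                   accession=accession, mrn=mrn))
        out.sort(key=lambda r: (r.accession, r.image_id))
        return out

    # -- consent gating --------------------------------------------------

    def enforce_consent(
        self, image_ids: Iterable[str], protocol_id: str
    ) -> ConsentDecision:
        """Partition images by patient-level consent for ``protocol_id``.

        A patient's images are included iff the NPP is signed AND the
        patient's status on the protocol is "consented".  Every other
        state excludes with a reason; the filter is idempotent.
        """
        included: list[str] = []
        excluded: list[tuple[str, str]] = []
        for image_id in image_ids:
            img = self.image(image_id)
            sld = self.slide(img.barcode)
            pat = self.patient(self.case(sld.accession).mrn)
            if not pat.npp_signed:
                excluded.append((image_id, "npp_missing"))
                continue
            status = pat.protocol_enrollments.get(protocol_id, "unknown")
            if status == "consented":
                included.append(image_id)
            elif status == "declined":
                excluded.append((image_id, "not_consented"))
            else:
                excluded.append((image_id, "unknown_consent"))
        return ConsentDecision(included=tuple(included), excluded=tuple(excluded))


# -- file ingest ---------------------------------------------------------

def _load_stream(path: str | Path) -> list[dict]:
    """Read one record stream from CSV or JSON-lines (by extension)."""
    path = Path(path)
    if path.suffix.lower() in (".jsonl", ".ndjson", ".json"):
        with open(path, encoding="utf-8") as fh:
            return [json.loads(line) for line in fh if line.strip()]
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return df.to_dict("records")


def load_warehouse(
    patients: str | Path,
    cases: str | Path,
    slides: str | Path,
    images: str | Path,
    reports: str | Path,
    db_path: str | Path = ":memory:",
) -> tuple[Warehouse, dict[str, int]]:
    """Build a warehouse from one file per record type.

    CSV columns / JSON keys match the record field names.  In CSV,
    ``protocol_enrollments`` is a JSON object string and ``parts`` a
    JSON array string.
    """
    def _coerce(rows: list[dict], model):
        out = []
        for row in rows:
            row = dict(row)
            for key in ("protocol_enrollments", "parts"):
                if key in row and isinstance(row[key], str) and row[key]:
                    row[key] = json.loads(row[key])
            for key in ("quality_factor",):
                if row.get(key) == "":
                    row[key] = None
            out.append(model(**row))
        return out

    wh = Warehouse(db_path)
    counts = wh.ingest(
        patients=_coerce(_load_stream(patients), PatientRecord),
        cases=_coerce(_load_stream(cases), CaseRecord),
        slides=_coerce(_load_stream(slides), SlideRecord),
        images=_coerce(_load_stream(images), ImageRecord),
        reports=_coerce(_load_stream(reports), PathologyReport),
    )
    return wh, counts
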