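"""Safe-Harbor de-identification of structured fields and report text.

Three mechanisms, applied to every applicable field before release:

* **date truncation** — day and month removed, the year kept (Safe
  Harbor permits year-only dates);
* **HID generation** — surrogate identifiers issued per family
  (patient ← MRN, case ← accession, image ← vendor image ID), with the
  original↔HID key held by the broker, never shipped with a dataset;
* **text redaction** — regular-expression rules locate dates,
  accession numbers and MRNs in free-text reports, plus the patient's
  true name, and replace each with placeholder text.

HIDs are derived from a keyed per-family counter (not from a hash of
the original identifier), so the mapping cannot be inverted by
dictionary attack; the key store is the only link back.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import os
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

from .records import (
    CaseRecord,
    ImageRecord,
    PathologyReport,
    PatientRecord,
    SlideRecord,
)

HID_FAMILIES = {"patient": "P", "case": "C", "image": "I"}

_MONTHS = (
    "January February March April May June July August "
    "September October November December"
).split()
_MONTH_NUM = {m.lower(): i + 1 for i, m in enumerate(_MONTHS)}


# -- date truncation -----------------------------------------------------

def truncate_date(date: Union[datetime.date, str]) -> str:
    """Truncate a date to its 4-digit year string.

    Accepts a ``datetime.date`` or an ISO-format string; anything
    unparseable raises rather than passing through.
    """
    if isinstance(date, datetime.datetime):
        return f"{date.year:04d}"
    if isinstance(date, datetime.date):
        return f"{date.year:04d}"
    if isinstance(date, str):
        try:
            return f"{datetime.date.fromisoformat(date).year:04d}"
        except ValueError as exc:
            raise ValueError(f"unparseable date {date!r}") from exc
    raise ValueError(f"unparseable date {date!r}")


def _expand_two_digit_year(yy: int) -> int:
    # pivot at 50: 00-49 -> 2000s, 50-99 -> 1900s
    return 2000 + yy if yy < 50 else 1900 + yy


# -- HID key store -------------------------------------------------------

class HIDKeyStore:
    """Bidirectional original-ID ↔ HID map, partitioned by family.

    Persisted as append-only JSON-lines; the first line carries the
    store's secret key so reopening the file reproduces identical HIDs.
    ``path=None`` keeps the store in memory (tests).
    """

    def __init__(self, path: Optional[Union[str, Path]] = None,
                 key: Optional[bytes] = None):
        self.path = Path(path) if path is not None else None
        self._fwd: dict[str, dict[str, str]] = {f: {} for f in HID_FAMILIES}
        self._rev: dict[str, dict[str, str]] = {f: {} for f in HID_FAMILIES}
        self._counters: dict[str, int] = {f: 0 for f in HID_FAMILIES}
        self._key = key
        if self.path is not None and self.path.exists():
            self._load()
        if self._key is None:
            self._key = os.urandom(16)
            self._persist_header()
        elif self.path is not None and not self.path.exists():
            self._persist_header()

    def _load(self) -> None:
        with open(self.path, encoding="utf-8") as fh:
            for line in fh:
                if not line.strip():
                    continue
                rec = json.loads(line)
                if rec.get("kind") == "hidkeystore":
                    self._key = bytes.fromhex(rec["key"])
                    continue
                self._insert(rec["family"], rec["original"], rec["hid"])

    def _persist_header(self) -> None:
        if self.path is None:
            return
        if not self.path.exists() or self.path.stat().st_size == 0:
            with open(self.path, "w", encoding="utf-8") as fh:
                fh.write(json.dumps({"kind": "hidkeystore",
                                     "key": self._key.hex()}) + "\n")

    def _insert(self, family: str, original: str, hid: str) -> None:
        self._fwd[family][original] = hid
        self._rev[family][hid] = original
        self._counters[family] += 1

    def assign(self, family: str, original_id: str) -> str:
        """Issue (or recall) the HID for ``original_id``; idempotent."""
        if family not in HID_FAMILIES:
            raise KeyError(f"unknown HID family {family!r}")
        if not original_id:
            raise ValueError("original_id must be non-empty")
        existing = self._fwd[family].get(original_id)
        if existing is not None:
            return existing
        prefix = HID_FAMILIES[family]
        salt = 0
        while True:
            token = f"{family}:{self._counters[family]}:{salt}".encode()
            digest = hashlib.blake2b(token, key=self._key, digest_size=4).hexdigest()
            hid = f"{prefix}-{digest}"
            if hid not in self._rev[family]:
                break
            salt += 1
        self._insert(family, original_id, hid)
        if self.path is not None:
            try:
                with open(self.path, "a", encoding="utf-8") as fh:
                    fh.write(json.dumps({"family": family, "original": original_id,
                                         "hid": hid}) + "\n")
            except OSError as exc:
                raise OSError(f"key store {self.path} unwritable: {exc}") from exc
        return hid

    def original(self, family: str, hid: str) -> str:
        """Re-identify: recover the original identifier for a HID."""
        try:
            return self._rev[family][hid]
        except KeyError:
            raise KeyError(f"no {family} entry for HID {hid}") from None

    def entries(self, family: str) -> dict[str, str]:
        return dict(self._fwd[family])


# -- redaction rules -----------------------------------------------------

@dataclass(frozen=True)
class RedactionRule:
    category: str  # date | accession | mrn | name
    pattern: re.Pattern
    placeholder: str  # template; may contain {year}

    def render(self, match: re.Match) -> str:
        if "{year}" in self.placeholder:
            return self.placeholder.format(year=_match_year(match))
        return self.placeholder


def _match_year(match: re.Match) -> int:
    g = match.groupdict()
    if g.get("y4"):
        return int(g["y4"])
    if g.get("y2") is not None:
        return _expand_two_digit_year(int(g["y2"]))
    raise ValueError("date rule matched without a year group")


_DATE_ISO = re.compile(r"\b(?P<y4>\d{4})-\d{2}-\d{2}\b")
_DATE_SLASH = re.compile(r"\b\d{1,2}/\d{1,2}/(?:(?P<y4>\d{4})|(?P<y2>\d{2}))\b")
_DATE_WRITTEN = re.compile(
    r"\b(?:%s)\s+\d{1,2},\s*(?P<y4>\d{4})\b" % "|".join(_MONTHS), re.IGNORECASE
)
# swallows barcode-style suffixes (S20-0123-2-1) along with plain accessions
_ACCESSION_TOKEN = re.compile(r"\b[SCHRM]\d{2}-\d+(?:-[A-Za-z0-9&]+)*")
_MRN_TOKEN = re.compile(r"(?<!\d)\d{6,9}(?!\d)")


@dataclass(frozen=True)
class RedactionRuleSet:
    """Ordered redaction rules; earlier rules win overlaps.

    Placeholder templates contain no literal digits and cannot
    themselves match any rule, so redaction is a fixed point.
    """

    rules: tuple[RedactionRule, ...]

    def __post_init__(self):
        if not self.rules:
            raise ValueError("RedactionRuleSet must not be empty")
        for rule in self.rules:
            if any(ch.isdigit() for ch in rule.placeholder):
                raise ValueError(
                    f"placeholder {rule.placeholder!r} contains digits"
                )
            probe = rule.placeholder.replace("{year}", "")
            for other in self.rules:
                if other.pattern.search(probe):
                    raise ValueError(
                        f"placeholder {rule.placeholder!r} matches rule "
                        f"{other.category}"
                    )


def default_rules(patient: Optional[PatientRecord] = None) -> RedactionRuleSet:
    """The broker's default rule set, optionally with name rules.

    Date dialects covered: ISO (YYYY-MM-DD), US slash (M/D/YYYY and
    MM/DD/YY) and written month ("March 15, 2020").  MRNs are
    standalone 6–9 digit runs (over-redaction of other long numbers is
    accepted).  Name rules match the patient's given/family tokens of
    ≥3 characters, case-insensitively, in "Given Family",
    "Family, Given" and standalone order.
    """
    rules = [
        RedactionRule("date", _DATE_WRITTEN, "[DATE-{year}]"),
        RedactionRule("date", _DATE_ISO, "[DATE-{year}]"),
        RedactionRule("date", _DATE_SLASH, "[DATE-{year}]"),
        RedactionRule("accession", _ACCESSION_TOKEN, "[ACCESSION]"),
        RedactionRule("mrn", _MRN_TOKEN, "[MRN]"),
    ]
    if patient is not None:
        tokens = [t for t in {patient.given_name, patient.family_name}
                  if len(t) >= 3]
        if tokens:
            given, family = patient.given_name, patient.family_name
            if len(given) >= 3 and len(family) >= 3 and given != family:
                pair = re.compile(
                    r"\b(?:%s\s+%s|%s\s*,\s*%s)\b"
                    % tuple(map(re.escape, (given, family, family, given))),
                    re.IGNORECASE,
                )
                rules.append(RedactionRule("name", pair, "[PATIENT]"))
            alts = "|".join(re.escape(t) for t in sorted(tokens))
            single = re.compile(r"\b(?:%s)\b" % alts, re.IGNORECASE)
            rules.append(RedactionRule("name", single, "[PATIENT]"))
    return RedactionRuleSet(rules=tuple(rules))


# -- report redaction ----------------------------------------------------

@dataclass(frozen=True)
class Span:
    start: int  # offsets into the ORIGINAL text
    end: int
    category: str
    length: int
    replacement: str


@dataclass(frozen=True)
class RedactedReport:
    deid_text: str
    spans: tuple[Span, ...]
    case_hid: Optional[str] = None

    def reconstruct(self, original: str) -> str:
        """Apply the recorded spans to the original text (invariant check)."""
        out, cursor = [], 0
        for sp in self.spans:
            out.append(original[cursor:sp.start])
            out.append(sp.replacement)
            cursor = sp.end
        out.append(original[cursor:])
        return "".join(out)


def redact_report(
    text: str,
    patient: Optional[PatientRecord] = None,
    rules: Optional[RedactionRuleSet] = None,
    case_hid: Optional[str] = None,
) -> RedactedReport:
    """Replace every rule match in ``text`` with its placeholder.

    Rules are applied in priority order; an earlier rule's match
    suppresses overlapping later candidates.  Date placeholders retain
    the year.  Empty text yields empty output with zero spans.
    """
    if rules is None:
        rules = default_rules(patient)
    claimed: list[tuple[int, int]] = []
    spans: list[Span] = []
    for rule in rules.rules:
        for m in rule.pattern.finditer(text):
            s, e = m.span()
            if any(s < ce and e > cs for cs, ce in claimed):
                continue
            claimed.append((s, e))
            spans.append(Span(start=s, end=e, category=rule.category,
                              length=e - s, replacement=rule.render(m)))
    spans.sort(key=lambda sp: sp.start)
    report = RedactedReport(deid_text="", spans=tuple(spans), case_hid=case_hid)
    return RedactedReport(deid_text=report.reconstruct(text),
                          spans=tuple(spans), case_hid=case_hid)


# -- structured-record de-identification ---------------------------------

def deidentify_record(
    record: Union[PatientRecord, CaseRecord, SlideRecord, ImageRecord, PathologyReport],
    store: HIDKeyStore,
) -> dict:
    """De-identify one warehouse record into a releasable dict.

    PHI-flagged fields (MRN, accession, barcode, image ID, file path,
    names) are replaced by a HID or dropped; part/block numbers pass
    through verbatim; dates are truncated to the year.  Report text is
    NOT redacted here — run :func:`redact_report` on it separately.
    Unknown record types fail closed.
    """
    if isinstance(record, PatientRecord):
        return {
            "patient_hid": store.assign("patient", record.mrn),
            "birth_year": truncate_date(record.birth_date),
        }
    if isinstance(record, CaseRecord):
        return {
            "case_hid": store.assign("case", record.accession),
            "patient_hid": store.assign("patient", record.mrn),
            "parts": [
                {"part_id": p.part_id, "description": p.description}
                for p in record.parts
            ],
        }
    if isinstance(record, SlideRecord):
        # barcode has no HID family -> dropped entirely
        return {
            "case_hid": store.assign("case", record.accession),
            "part_id": record.part_id,
            "block_id": record.block_id,
            "stain": record.stain,
            "scanner_vendor": record.scanner_vendor,
            "scanner_model": record.scanner_model,
        }
    if isinstance(record, ImageRecord):
        # barcode and file path dropped; scan date truncated
        return {
            "image_hid": store.assign("image", record.image_id),
            "scan_year": truncate_date(record.scan_date),
            "quality_factor": record.quality_factor,
            "sequence_index": record.sequence_index,
        }
    if isinstance(record, PathologyReport):
        return {
            "case_hid": store.assign("case", record.accession),
            "report_year": truncate_date(record.report_date),
            "text": record.text,
        }
    raise TypeError(f"cannot de-identify record of type {type(record).__name__}")
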