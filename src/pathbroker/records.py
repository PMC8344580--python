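"""Structured clinical-pathology record types.

These model the identifier hierarchy of an anatomic-pathology laboratory
information system (AP-LIS): patient (MRN) → accessioned case → part →
block → glass slide (barcode) → scanned image.  Every identifier except
part and block number is treated as PHI and must be replaced or dropped
before a record leaves the broker.
"""

from __future__ import annotations

import datetime
import re
from typing import ClassVar, Literal, Optional

from pydantic import BaseModel, ConfigDict, field_validator, model_validator

#: Case accession grammar: specimen-class letter, 2-digit year, dash,
#: running number.  S=surgical, C=cytology, H=hematopathology,
#: R=research, M=molecular.
ACCESSION_RE = re.compile(r"[SCHRM]\d{2}-\d+")
_ACCESSION_FULL = re.compile(r"^[SCHRM]\d{2}-\d+$")

ConsentStatus = Literal["consented", "declined", "unknown"]
ScannerVendor = Literal["leica", "philips", "3dhistech"]


class PatientRecord(BaseModel):
    """A patient with consent facts.

    ``npp_signed`` records the signature of the Notice of Privacy
    Practice; ``protocol_enrollments`` maps research-protocol IDs to a
    synoptic consent status.
    """

    model_config = ConfigDict(frozen=True)

    mrn: str
    name: str
    birth_date: datetime.date
    npp_signed: bool = False
    protocol_enrollments: dict[str, ConsentStatus] = {}

    @field_validator("mrn")
    @classmethod
    def _mrn_digits(cls, v: str) -> str:
        if not v or not v.isdigit():
            raise ValueError(f"MRN must be a non-empty digit string, got {v!r}")
        return v

    @property
    def given_name(self) -> str:
        return self.name.split()[0]

    @property
    def family_name(self) -> str:
        return self.name.split()[-1]


class Part(BaseModel):
    model_config = ConfigDict(frozen=True)

    part_id: int
    description: str = ""

    @field_validator("part_id")
    @classmethod
    def _positive(cls, v: int) -> int:
        if v < 1:
            raise ValueError("part_id must be a positive integer")
        return v


class CaseRecord(BaseModel):
    """An accessioned case owned by one patient, split into parts."""

    model_config = ConfigDict(frozen=True)

    accession: str
    mrn: str
    parts: tuple[Part, ...] = ()

    @field_validator("accession")
    @classmethod
    def _grammar(cls, v: str) -> str:
        if not _ACCESSION_FULL.match(v):
            raise ValueError(f"accession {v!r} does not match [SCHRM]YY-N grammar")
        return v

    @model_validator(mode="after")
    def _unique_parts(self) -> "CaseRecord":
        ids = [p.part_id for p in self.parts]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate part_id in case {self.accession}")
        return self


class SlideRecord(BaseModel):
    """A barcoded glass slide cut from one block of one part."""

    model_config = ConfigDict(frozen=True)

    barcode: str
    accession: str
    part_id: int
    block_id: int
    stain: str = "H&E"
    scanner_vendor: ScannerVendor = "leica"
    scanner_model: str = ""


class ImageRecord(BaseModel):
    """One digital scan of a slide; a slide may be rescanned.

    ``quality_factor`` is the 0–100 scan-quality score some scanners
    emit (Leica does, Philips does not).  ``sequence_index`` is the
    1-based position within the scanning batch, used for periodic QC
    sampling.
    """

    model_config = ConfigDict(frozen=True)

    image_id: str
    barcode: str
    file_path: str
    scan_date: datetime.date
    quality_factor: Optional[int] = None
    sequence_index: int = 1

    @field_validator("quality_factor")
    @classmethod
    def _qf_range(cls, v: Optional[int]) -> Optional[int]:
        if v is not None and not 0 <= v <= 100:
            raise ValueError("quality_factor must be in [0, 100]")
        return v

    @field_validator("sequence_index")
    @classmethod
    def _seq_positive(cls, v: int) -> int:
        if v < 1:
            raise ValueError("sequence_index must be >= 1")
        return v


class PathologyReport(BaseModel):
    model_config = ConfigDict(frozen=True)

    accession: str
    text: str
    report_date: datetime.date


class CohortCriteria(BaseModel):
    """Conjunctive cohort filters; at least one must be present."""

    model_config = ConfigDict(frozen=True)

    report_keywords: Optional[tuple[str, ...]] = None
    date_range: Optional[tuple[datetime.date, datetime.date]] = None
    stains: Optional[frozenset[str]] = None
    vendors: Optional[frozenset[str]] = None
    protocol_id: Optional[str] = None

    @model_validator(mode="after")
    def _at_least_one(self) -> "CohortCriteria":
        if not any(
            v is not None
            for v in (
                self.report_keywords,
                self.date_range,
                self.stains,
                self.vendors,
                self.protocol_id,
            )
        ):
            raise ValueError("CohortCriteria needs at least one criterion or a protocol_id")
        if self.date_range is not None and self.date_range[0] > self.date_range[1]:
            raise ValueError("date_range start after end")
        return self


class IdentifierBundle(BaseModel):
    """The full identifier set attached to one scanned image.

    Part and block numbers are the only non-PHI identifiers; everything
    else must not survive de-identification in any byte of the output.
    """

    model_config = ConfigDict(frozen=True)

    mrn: Optional[str] = None
    patient_name: Optional[str] = None
    accession: Optional[str] = None
    part_id: Optional[int] = None
    block_id: Optional[int] = None
    barcode: Optional[str] = None
    image_id: Optional[str] = None
    file_path: Optional[str] = None

    PHI_FIELDS: ClassVar[tuple[str, ...]] = (
        "mrn",
        "patient_name",
        "accession",
        "barcode",
        "image_id",
        "file_path",
    )

    def phi_strings(self) -> list[str]:
        """All PHI identifier strings to scan output bytes for."""
        out: list[str] = []
        for field in self.PHI_FIELDS:
            v = getattr(self, field)
            if v:
                out.append(str(v))
        if self.patient_name:
            out.extend(t for t in self.patient_name.split() if len(t) >= 3)
        return out
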