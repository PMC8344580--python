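"""Synthetic fixtures with ground truth for every input family.

Emulates the three input families of a digital-pathology broker —
structured warehouse records with consent facts, free-text reports
with planted PHI, SVS-style slide files with label/macro/metadata PHI —
plus first-access logs drawn from an explicit month distribution.
Every generator records ground truth (expected consent decisions, PHI
span tables, sub-image roles and planted byte strings, the exact
generating CDF) so downstream modules can be verified end to end.

All randomness flows from ``FixtureSpec.seed``; reruns are
byte-identical.  Planted PHI is limited to the redactor's documented
grammar (three date dialects, MRNs, accessions, the patient's name in
both orders) — the generator never out-runs the redaction contract.

Pixel payloads of sub-images that survive de-identification are
constrained to channel values ≥ 140 (tissue/background) or ≤ 40
(planted dark blocks), outside the ASCII letter/digit range, so a
byte-level identifier scan of an output file can never collide with
image noise.
"""

from __future__ import annotations

import datetime
import math
import uuid
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import tifffile
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from .records import (
    CaseRecord,
    IdentifierBundle,
    ImageRecord,
    PathologyReport,
    PatientRecord,
    SlideRecord,
)
from .storage_planner import DAYS_PER_MONTH, AccessLogEntry

#: First-access month profile shaped like a busy academic slide archive:
#: half of the digitally reviewed slides are opened within a month of
#: scanning (CDF 0.51 at month 1, 0.61 at 2, 0.79 at 6, 0.91 at 12),
#: with a long 3-year tail.
DEFAULT_ACCESS_MONTH_PROBS: dict[int, float] = {
    1: 0.51,
    2: 0.10,
    **{m: 0.045 for m in range(3, 7)},
    **{m: 0.02 for m in range(7, 13)},
    **{m: 0.00375 for m in range(13, 37)},
}

_GIVEN_NAMES = (
    "Alice Bruno Carla Diego Elena Felix Greta Henry Irene Jonas "
    "Katya Lucas Marta Nadia Oscar Paula Quinn Rosa Stefan Tilda"
).split()
_FAMILY_NAMES = (
    "Abbott Becker Castillo Dvorak Eriksen Fontana Gruber Hopkins "
    "Ivanova Jensen Keller Lindqvist Moreau Novak Okafor Petrov "
    "Quintana Rossi Schmidt Tanaka"
).split()

_STAINS = ("H&E", "IHC")
_VENDOR_MODELS = {
    "leica": ("Aperio AT2", "Aperio GT450"),
    "philips": ("IntelliSite UFS",),
    "3dhistech": ("Pannoramic 1000",),
}
_DIAGNOSES = (
    "invasive ductal carcinoma",
    "basal cell carcinoma",
    "benign fibrous tissue",
    "melanoma in situ",
    "chronic inflammation",
)
_MONTH_NAMES = (
    "January February March April May June July August "
    "September October November December"
).split()


class FixtureSpec(BaseModel):
    """Knobs of the synthetic study population."""

    model_config = ConfigDict(frozen=True)

    seed: int = 0
    n_patients: int = 50
    consent_rate: float = 0.6
    npp_rate: float = 0.9
    reports_per_case: int = 1
    phi_density: int = 4
    wsi_levels: int = 3
    tile_size: int = 256
    base_size: int = 1024
    label_text: Optional[str] = None
    dark_block_fraction: float = 0.0
    access_month_probs: dict[int, float] = Field(
        default_factory=lambda: dict(DEFAULT_ACCESS_MONTH_PROBS)
    )
    never_accessed_fraction: float = 0.2
    protocol_id: str = "PR-001"

    @field_validator("base_size")
    @classmethod
    def _desk_scale(cls, v: int) -> int:
        if not 64 <= v <= 2048:
            raise ValueError("base_size must be in [64, 2048] (desk scale)")
        return v

    @model_validator(mode="after")
    def _probs_sum(self) -> "FixtureSpec":
        total = sum(self.access_month_probs.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"access month probabilities sum to {total}, not 1")
        if not 0 <= self.consent_rate <= 1:
            raise ValueError("consent_rate must be in [0, 1]")
        return self


# -- warehouse records ---------------------------------------------------

@dataclass(frozen=True)
class PlantedSpan:
    start: int
    end: int
    category: str  # date | accession | mrn | name
    text: str
    year: Optional[int] = None  # for dates


@dataclass
class WarehouseFixture:
    patients: list[PatientRecord]
    cases: list[CaseRecord]
    slides: list[SlideRecord]
    images: list[ImageRecord]
    reports: list[PathologyReport]
    consent_truth: dict[str, tuple[bool, Optional[str]]]  # mrn -> (include, reason)
    report_spans: dict[int, list[PlantedSpan]]  # index into reports
    protocol_id: str


def _stable_hash(text: str) -> int:
    return zlib.crc32(text.encode()) & 0x7FFFFFFF


def _rng(spec: FixtureSpec, stream: str) -> np.random.Generator:
    return np.random.default_rng([spec.seed, _stable_hash(stream)])


def _rand_date(rng: np.random.Generator,
               lo: datetime.date = datetime.date(2018, 1, 1),
               hi: datetime.date = datetime.date(2020, 12, 31)) -> datetime.date:
    span = (hi - lo).days
    return lo + datetime.timedelta(days=int(rng.integers(0, span + 1)))


def _format_date(rng: np.random.Generator, date: datetime.date) -> tuple[str, int]:
    """Render a date in one of the redactor's three dialects."""
    dialect = int(rng.integers(0, 4))
    if dialect == 0:
        return date.isoformat(), date.year
    if dialect == 1:
        return f"{date.month}/{date.day}/{date.year}", date.year
    if dialect == 2:
        return f"{date.month:02d}/{date.day:02d}/{date.year % 100:02d}", date.year
    return f"{_MONTH_NAMES[date.month - 1]} {date.day}, {date.year}", date.year


def generate_warehouse(spec: FixtureSpec) -> WarehouseFixture:
    """One patient → one case → 1–2 parts → one slide each → one image."""
    rng = np.random.default_rng(spec.seed)
    patients, cases, slides, images, reports = [], [], [], [], []
    consent_truth: dict[str, tuple[bool, Optional[str]]] = {}
    report_spans: dict[int, list[PlantedSpan]] = {}

    mrns = rng.choice(np.arange(1_000_000, 9_999_999), size=spec.n_patients,
                      replace=False)
    seq_counters = {v: 0 for v in _VENDOR_MODELS}

    for i in range(spec.n_patients):
        mrn = str(mrns[i])
        name = (
            f"{_GIVEN_NAMES[int(rng.integers(len(_GIVEN_NAMES)))]} "
            f"{_FAMILY_NAMES[int(rng.integers(len(_FAMILY_NAMES)))]}"
        )
        npp = bool(rng.random() < spec.npp_rate)
        consented = bool(rng.random() < spec.consent_rate)
        status = "consented" if consented else \
            ("declined" if rng.random() < 0.5 else "unknown")
        patient = PatientRecord(
            mrn=mrn, name=name,
            birth_date=_rand_date(rng, datetime.date(1940, 1, 1),
                                  datetime.date(1995, 12, 31)),
            npp_signed=npp,
            protocol_enrollments={spec.protocol_id: status},
        )
        patients.append(patient)
        if not npp:
            consent_truth[mrn] = (False, "npp_missing")
        elif status == "consented":
            consent_truth[mrn] = (True, None)
        elif status == "declined":
            consent_truth[mrn] = (False, "not_consented")
        else:
            consent_truth[mrn] = (False, "unknown_consent")

        letter = rng.choice(list("SSSSCHRM"))
        accession = f"{letter}{int(rng.integers(18, 21)):02d}-{1000 + i}"
        n_parts = int(rng.integers(1, 3))
        case = CaseRecord(
            accession=accession, mrn=mrn,
            parts=tuple(
                {"part_id": p + 1, "description": f"part {chr(65 + p)}"}
                for p in range(n_parts)
            ),
        )
        cases.append(case)

        scan_date = _rand_date(rng)
        for p in range(n_parts):
            vendor = rng.choice(list(_VENDOR_MODELS))
            model = _VENDOR_MODELS[vendor][
                int(rng.integers(len(_VENDOR_MODELS[vendor])))
            ]
            block = int(rng.integers(1, 4))
            stain = _STAINS[int(rng.integers(len(_STAINS)))]
            barcode = f"{accession};{p + 1};{block}"
            slides.append(SlideRecord(
                barcode=barcode, accession=accession, part_id=p + 1,
                block_id=block, stain=stain, scanner_vendor=vendor,
                scanner_model=model,
            ))
            seq_counters[vendor] += 1
            image_id = str(uuid.UUID(bytes=rng.bytes(16))).upper()
            qf = int(rng.integers(80, 101)) if vendor == "leica" else None
            images.append(ImageRecord(
                image_id=image_id, barcode=barcode,
                file_path=f"/archive/{vendor}/{image_id}.svs",
                scan_date=scan_date, quality_factor=qf,
                sequence_index=seq_counters[vendor],
            ))

        for _ in range(spec.reports_per_case):
            text, spans = _report_text(rng, spec, patient, accession)
            report_spans[len(reports)] = spans
            reports.append(PathologyReport(
                accession=accession, text=text,
                report_date=scan_date + datetime.timedelta(days=2),
            ))

    return WarehouseFixture(
        patients=patients, cases=cases, slides=slides, images=images,
        reports=reports, consent_truth=consent_truth,
        report_spans=report_spans, protocol_id=spec.protocol_id,
    )


def _report_text(
    rng: np.random.Generator, spec: FixtureSpec,
    patient: PatientRecord, accession: str,
) -> tuple[str, list[PlantedSpan]]:
    """Report with exactly ``phi_density`` planted, span-annotated PHI."""
    diagnosis = _DIAGNOSES[int(rng.integers(len(_DIAGNOSES)))]
    pieces = [f"FINAL DIAGNOSIS: {diagnosis}. "]
    spans: list[PlantedSpan] = []
    cursor = len(pieces[0])

    categories = ["accession", "mrn", "name", "date"]
    for k in range(spec.phi_density):
        cat = categories[k % 4]
        year: Optional[int] = None
        if cat == "accession":
            token = accession
        elif cat == "mrn":
            token = patient.mrn
        elif cat == "name":
            if rng.random() < 0.5:
                token = patient.name
            else:
                token = f"{patient.family_name}, {patient.given_name}"
        else:
            token, year = _format_date(rng, _rand_date(rng))
        lead = "Specimen reference " if cat != "name" else "Received from "
        piece = f"{lead}{token}. "
        start = cursor + len(lead)
        spans.append(PlantedSpan(start=start, end=start + len(token),
                                 category=cat, text=token, year=year))
        pieces.append(piece)
        cursor += len(piece)
    pieces.append("Microscopic sections show the findings described above.")
    return "".join(pieces), spans


# -- whole-slide images --------------------------------------------------

@dataclass(frozen=True)
class WSITruth:
    path: Path
    roles: dict[int, str]  # page index -> role
    planted_strings: tuple[str, ...]
    dark_fraction: float


def _tissue(rng: np.random.Generator, size: int) -> np.ndarray:
    """Pale procedural tissue on white; channel values kept ≥ 140."""
    img = np.full((size, size, 3), 250, dtype=np.uint8)
    from skimage.draw import disk

    for _ in range(8):
        r = int(rng.integers(size // 12, size // 4))
        cy, cx = int(rng.integers(0, size)), int(rng.integers(0, size))
        rr, cc = disk((cy, cx), r, shape=(size, size))
        color = np.array([
            int(rng.integers(200, 236)),
            int(rng.integers(160, 200)),
            int(rng.integers(180, 212)),
        ], dtype=np.uint8)
        img[rr, cc] = color
    noise = rng.integers(-8, 9, size=img.shape, dtype=np.int16)
    return np.clip(img.astype(np.int16) + noise, 140, 255).astype(np.uint8)


def _text_image(text: str, width: int, height: int,
                embed: bytes = b"") -> np.ndarray:
    """White card rendering ``text``; optionally embeds raw ASCII bytes
    into the first pixel row (so the string survives as file bytes)."""
    from PIL import Image, ImageDraw

    im = Image.new("RGB", (width, height), (255, 255, 255))
    ImageDraw.Draw(im).multiline_text((6, 6), text, fill=(0, 0, 0))
    arr = np.asarray(im).copy()
    if embed:
        flat = arr.reshape(-1)
        payload = np.frombuffer(embed, dtype=np.uint8)
        flat[: payload.size] = payload
    return arr


def generate_wsi(
    spec: FixtureSpec,
    identifiers: IdentifierBundle,
    out_path: Union[str, Path],
    dark_block_fraction: Optional[float] = None,
) -> WSITruth:
    """Write an SVS-style pyramidal TIFF with planted PHI.

    Pages: tiled pyramid levels (base first), a strip thumbnail,
    a label card (sticker text + embedded ASCII bytes) and a macro
    overview.  The base description embeds scan date, scanner ID,
    filename, barcode and operator in ``|key = value|`` form.
    """
    out_path = Path(out_path)
    if dark_block_fraction is None:
        dark_block_fraction = spec.dark_block_fraction
    rng = np.random.default_rng([spec.seed, 77, _stable_hash(identifiers.image_id or "x")])

    base = _tissue(rng, spec.base_size)
    levels = [base]
    for _ in range(max(0, spec.wsi_levels - 1)):
        levels.append(levels[-1][::2, ::2])

    step = max(1, spec.base_size // 256)
    thumb = base[::step, ::step].copy()
    actual_dark = 0.0
    if dark_block_fraction > 0:
        h, w = thumb.shape[:2]
        side = max(1, round(math.sqrt(dark_block_fraction * h * w)))
        side = min(side, h - 2, w - 2)
        thumb[2:2 + side, 2:2 + side] = 8
        actual_dark = side * side / (h * w)

    name = identifiers.patient_name or "UNKNOWN PATIENT"
    barcode = identifiers.barcode or "NO-BARCODE"
    label_text = spec.label_text or f"{name}\n{barcode}"
    scan_date_str = "06/02/19"
    scanner_id = f"SS{int(rng.integers(1000, 10000))}"
    operator = f"TECH{int(rng.integers(10, 100))}"

    label = _text_image(label_text, 256, 128,
                        embed=f"{name} {barcode}".encode())
    macro = _text_image("", 256, 192, embed=barcode.encode())
    macro[150:, :60] = 15  # sticker corner bleeding into the macro

    w = h = spec.base_size
    base_desc = (
        f"Aperio Image Library v12.0.15\n"
        f"{w}x{h} [0,0 {w}x{h}] ({spec.tile_size}x{spec.tile_size}) "
        f"-|AppMag = 20|MPP = 0.25|Date = {scan_date_str}|Time = 09:30:00"
        f"|ScanScope ID = {scanner_id}|Filename = {identifiers.image_id}"
        f"|Barcode = {barcode}|Operator = {operator}|"
    )
    label_desc = (
        f"Aperio Image Library v12.0.15\nlabel 256x128"
        f"|Barcode = {barcode}|Patient = {name}|"
    )
    macro_desc = f"Aperio Image Library v12.0.15\nmacro 256x192|Barcode = {barcode}|"

    roles: dict[int, str] = {}
    with tifffile.TiffWriter(out_path, bigtiff=False, shaped=False) as tw:
        for j, lvl in enumerate(levels):
            desc = base_desc if j == 0 else (
                f"Aperio Image Library v12.0.15\n"
                f"{lvl.shape[1]}x{lvl.shape[0]} -> level {j}|MPP = {0.25 * 2**j}|"
            )
            tw.write(lvl, tile=(spec.tile_size, spec.tile_size),
                     photometric="rgb", compression=None, description=desc)
            roles[j] = "pyramid_level"
        n = len(levels)
        tw.write(thumb, photometric="rgb", compression=None,
                 description=f"Aperio Image Library v12.0.15\n"
                             f"{thumb.shape[1]}x{thumb.shape[0]} -> reduced|")
        roles[n] = "thumbnail"
        tw.write(label, photometric="rgb", compression=None,
                 description=label_desc)
        roles[n + 1] = "label"
        tw.write(macro, photometric="rgb", compression=None,
                 description=macro_desc)
        roles[n + 2] = "macro"

    planted = [s for s in (name, barcode, identifiers.accession,
                           identifiers.image_id, scan_date_str, scanner_id,
                           operator) if s]
    planted.extend(t for t in name.split() if len(t) >= 3)
    return WSITruth(path=out_path, roles=roles,
                    planted_strings=tuple(planted),
                    dark_fraction=actual_dark)


# -- access logs ---------------------------------------------------------

@dataclass(frozen=True)
class AccessLogTruth:
    entries: list[AccessLogEntry]
    cdf: dict[int, float]  # generating CDF per month


def generate_access_log(spec: FixtureSpec, n: int) -> AccessLogTruth:
    """Draw first-access months from the spec's distribution.

    A ``never_accessed_fraction`` of entries gets no access date; the
    generating CDF (over accessed entries) is returned as ground truth.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _rng(spec, "access-log")
    months = sorted(spec.access_month_probs)
    probs = np.array([spec.access_month_probs[m] for m in months])
    probs = probs / probs.sum()
    entries = []
    for i in range(n):
        scan = _rand_date(rng, datetime.date(2018, 1, 1),
                          datetime.date(2019, 12, 31))
        if rng.random() < spec.never_accessed_fraction:
            access = None
        else:
            m = int(months[int(rng.choice(len(months), p=probs))])
            lo = (m - 1) * DAYS_PER_MONTH
            hi = m * DAYS_PER_MONTH
            days = int(math.ceil(rng.uniform(lo, hi)))
            days = max(1, min(days, math.floor(hi)))
            access = scan + datetime.timedelta(days=days)
        entries.append(AccessLogEntry(
            image_id=f"IMG{i:06d}", scan_date=scan, first_access_date=access,
        ))
    cum, cdf = 0.0, {}
    for m in months:
        cum += spec.access_month_probs[m]
        cdf[int(m)] = cum
    return AccessLogTruth(entries=entries, cdf=cdf)


# -- QC batches ----------------------------------------------------------

def generate_qc_batch(
    n: int = 100, vendor: str = "leica", seed: int = 0
) -> list[ImageRecord]:
    """Contiguous scanning batch (sequence 1..n) for one vendor."""
    rng = np.random.default_rng([seed, 13])
    out = []
    for i in range(1, n + 1):
        image_id = str(uuid.UUID(bytes=rng.bytes(16))).upper()
        out.append(ImageRecord(
            image_id=image_id, barcode=f"S19-{5000 + i};1;1",
            file_path=f"/archive/{vendor}/{image_id}.svs",
            scan_date=datetime.date(2019, 6, 2),
            quality_factor=int(rng.integers(80, 101)) if vendor == "leica" else None,
            sequence_index=i,
        ))
    return out


# -- full dataset --------------------------------------------------------

@dataclass
class FixtureDataset:
    """A complete synthetic archive: records + WSI files + ground truth."""

    spec: FixtureSpec
    warehouse_fixture: WarehouseFixture
    wsi_truths: dict[str, WSITruth]  # image_id -> truth
    root: Path

    @property
    def all_planted_strings(self) -> set[str]:
        out: set[str] = set()
        for t in self.wsi_truths.values():
            out.update(t.planted_strings)
        for spans in self.warehouse_fixture.report_spans.values():
            out.update(s.text for s in spans)
        for p in self.warehouse_fixture.patients:
            out.add(p.mrn)
            out.add(p.name)
        return out


def generate_fixture_dataset(spec: FixtureSpec, root: Union[str, Path]) -> FixtureDataset:
    """Generate records and matching WSI files under ``root/wsi``.

    Image file paths in the records point at the generated files.  If
    ``spec.dark_block_fraction > 0``, the block is planted on the
    first image only (a single simulated sticker bleed-through).
    """
    root = Path(root)
    wsi_dir = root / "wsi"
    wsi_dir.mkdir(parents=True, exist_ok=True)
    wf = generate_warehouse(spec)

    slides_by_barcode = {s.barcode: s for s in wf.slides}
    cases_by_acc = {c.accession: c for c in wf.cases}
    patients_by_mrn = {p.mrn: p for p in wf.patients}

    truths: dict[str, WSITruth] = {}
    new_images = []
    for k, img in enumerate(wf.images):
        sld = slides_by_barcode[img.barcode]
        pat = patients_by_mrn[cases_by_acc[sld.accession].mrn]
        path = wsi_dir / f"{img.image_id}.svs"
        bundle = IdentifierBundle(
            mrn=pat.mrn, patient_name=pat.name, accession=sld.accession,
            part_id=sld.part_id, block_id=sld.block_id, barcode=sld.barcode,
            image_id=img.image_id, file_path=str(path),
        )
        dark = spec.dark_block_fraction if k == 0 else 0.0
        truths[img.image_id] = generate_wsi(spec, bundle, path,
                                            dark_block_fraction=dark)
        new_images.append(img.model_copy(update={"file_path": str(path)}))
    wf.images = new_images
    return FixtureDataset(spec=spec, warehouse_fixture=wf,
                          wsi_truths=truths, root=root)
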