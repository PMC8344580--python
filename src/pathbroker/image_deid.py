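"""Whole-slide-image de-identification for an SVS-style TIFF dialect.

PHI can live in four places of a WSI: (1) the label image (sticker
photo with barcode and patient name), (2) the macro overview (may show
part of the sticker), (3) text metadata (barcode, accession, scan
dates, scanner/operator IDs), and (4) the main image when the sticker
was scanned next to the tissue.  This module handles 1–3 by byte
surgery on the container: label and macro payloads are overwritten
with zeros AND their directories unlinked from the IFD chain, and
sensitive metadata values are masked in place with equal-length ``X``
runs so no file offset shifts.  Diagnostic pixel data is never touched
(case 4 is handled by :mod:`pathbroker.phi_screen`, which excludes the
whole WSI).

Only the classic (non-Big) little/big-endian TIFF with Aperio-style
``|key = value|`` ImageDescription is supported; other dialects error
out.  Editing is never in place — output is always a new file.

`tifffile` is used to parse structure (page offsets, tags, pixel
decoding); all modifications are explicit byte patches by this module.
"""

from __future__ import annotations

import re
import shutil
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Union

import numpy as np
import tifffile

from .records import IdentifierBundle

ROLE_PYRAMID = "pyramid_level"
ROLE_THUMBNAIL = "thumbnail"
ROLE_LABEL = "label"
ROLE_MACRO = "macro"

_TIFF_TYPE_SIZES = {1: 1, 2: 1, 3: 2, 4: 4, 5: 8, 6: 1, 7: 1, 8: 2,
                    9: 4, 10: 8, 11: 4, 12: 8, 13: 4, 16: 8, 17: 8, 18: 8}
_TAG_IMAGE_DESCRIPTION = 270

#: tag/key names that scrubbing must never touch (pixel geometry and
#: spatial calibration)
GEOMETRY_KEYS = frozenset(
    k.lower()
    for k in (
        "ImageWidth", "ImageLength", "TileWidth", "TileLength", "RowsPerStrip",
        "Compression", "BitsPerSample", "SamplesPerPixel", "PhotometricInterpretation",
        "StripOffsets", "StripByteCounts", "TileOffsets", "TileByteCounts",
        "MPP", "AppMag",
    )
)

DEFAULT_SENSITIVE_KEYS = ("Date", "Time", "ScanScope ID", "Barcode",
                          "Filename", "Operator", "User")


class WSIFormatError(ValueError):
    """Unreadable, truncated or unsupported slide container."""


@dataclass(frozen=True)
class SensitiveFieldPolicy:
    """Metadata keys whose values are overwritten during scrubbing."""

    fields: tuple[str, ...] = DEFAULT_SENSITIVE_KEYS

    def __post_init__(self):
        if not self.fields:
            raise ValueError("SensitiveFieldPolicy must name at least one field")
        bad = [f for f in self.fields if f.lower() in GEOMETRY_KEYS]
        if bad:
            raise ValueError(f"policy must not name geometry keys: {bad}")


@dataclass(frozen=True)
class SubImage:
    index: int
    role: str
    width: int
    height: int
    description: str
    ifd_offset: int
    data_offsets: tuple[int, ...]
    data_bytecounts: tuple[int, ...]
    tiled: bool


@dataclass
class WSIContainer:
    """Parsed sub-image inventory of one slide file."""

    path: Path
    byteorder: str  # '<' or '>'
    sub_images: list[SubImage] = field(default_factory=list)
    dialect: str = "svs-tiff"

    def by_role(self, role: str) -> list[SubImage]:
        return [s for s in self.sub_images if s.role == role]

    @property
    def base_level(self) -> SubImage:
        return max(self.by_role(ROLE_PYRAMID), key=lambda s: s.width * s.height)

    def pixels(self, index: int) -> np.ndarray:
        with tifffile.TiffFile(self.path) as tif:
            return tif.pages[index].asarray()

    def thumbnail_pixels(self, max_side: int = 512) -> np.ndarray:
        """Dedicated thumbnail, else box-downsampled base level."""
        thumbs = self.by_role(ROLE_THUMBNAIL)
        if thumbs:
            return self.pixels(thumbs[0].index)
        from PIL import Image

        base = self.pixels(self.base_level.index)
        img = Image.fromarray(base)
        scale = max(img.size) / max_side
        if scale > 1:
            img = img.resize(
                (max(1, round(img.width / scale)), max(1, round(img.height / scale))),
                Image.BOX,
            )
        return np.asarray(img)


def read_container(path: Union[str, Path]) -> WSIContainer:
    """Parse a slide file and classify every sub-image.

    Classification: description containing the token ``label`` →
    label, ``macro`` → macro; among the remaining, the smallest
    non-tiled strip image → thumbnail; everything else is a pyramid
    level.
    """
    path = Path(path)
    try:
        tif = tifffile.TiffFile(path)
    except Exception as exc:
        size = path.stat().st_size if path.exists() else 0
        raise WSIFormatError(
            f"cannot parse {path} as TIFF (file ends at byte {size}): {exc}"
        ) from exc
    with tif:
        if tif.tiff.version != 42:
            raise WSIFormatError(
                f"{path}: unsupported TIFF variant (version {tif.tiff.version}); "
                "only classic TIFF is handled"
            )
        byteorder = tif.tiff.byteorder
        _validate_chain(path, byteorder)
        raw = []
        try:
            for i, page in enumerate(tif.pages):
                desc = (page.description or "")
                raw.append(
                    dict(
                        index=i,
                        description=desc,
                        width=int(page.imagewidth),
                        height=int(page.imagelength),
                        ifd_offset=int(page.offset),
                        data_offsets=tuple(int(o) for o in page.dataoffsets),
                        data_bytecounts=tuple(int(b) for b in page.databytecounts),
                        tiled=page.is_tiled,
                    )
                )
        except Exception as exc:
            raise WSIFormatError(
                f"{path}: truncated or corrupt directory chain near byte "
                f"{path.stat().st_size}: {exc}"
            ) from exc

    roles: dict[int, str] = {}
    plain = []
    for info in raw:
        low = info["description"].lower()
        if "label" in low:
            roles[info["index"]] = ROLE_LABEL
        elif "macro" in low:
            roles[info["index"]] = ROLE_MACRO
        else:
            plain.append(info)
    strip_pages = [p for p in plain if not p["tiled"]]
    if strip_pages and len(plain) > 1:
        thumb = min(strip_pages, key=lambda p: p["width"] * p["height"])
        roles[thumb["index"]] = ROLE_THUMBNAIL
    for info in plain:
        roles.setdefault(info["index"], ROLE_PYRAMID)

    subs = [
        SubImage(
            index=info["index"], role=roles[info["index"]], width=info["width"],
            height=info["height"], description=info["description"],
            ifd_offset=info["ifd_offset"], data_offsets=info["data_offsets"],
            data_bytecounts=info["data_bytecounts"], tiled=info["tiled"],
        )
        for info in raw
    ]
    container = WSIContainer(path=path, byteorder=byteorder, sub_images=subs)

    pyramids = container.by_role(ROLE_PYRAMID)
    if not pyramids:
        raise WSIFormatError(f"{path}: no pyramid level found")
    areas = sorted((s.width * s.height for s in pyramids), reverse=True)
    if len(areas) > 1 and areas[0] == areas[1]:
        raise WSIFormatError(f"{path}: ambiguous base pyramid level")
    for role in (ROLE_LABEL, ROLE_MACRO):
        if len(container.by_role(role)) > 1:
            raise WSIFormatError(f"{path}: more than one {role} sub-image")
    return container


def _validate_chain(path: Path, byteorder: str) -> None:
    """Bounds-check the IFD chain and payload ranges; tifffile tolerates
    truncated files by silently dropping pages, which is unsafe here."""
    buf = path.read_bytes()
    size = len(buf)
    u16, u32 = byteorder + "H", byteorder + "I"
    offset = struct.unpack_from(u32, buf, 4)[0]
    seen = set()
    while offset:
        if offset in seen:
            raise WSIFormatError(f"{path}: circular IFD chain at byte {offset}")
        seen.add(offset)
        if offset + 2 > size:
            raise WSIFormatError(
                f"{path}: directory offset {offset} beyond end of file "
                f"(byte {size})")
        n = struct.unpack_from(u16, buf, offset)[0]
        end = offset + 2 + 12 * n + 4
        if end > size:
            raise WSIFormatError(
                f"{path}: directory at byte {offset} truncated (needs {end}, "
                f"file ends at {size})")
        for k in range(n):
            entry = offset + 2 + 12 * k
            _tag, typ, count = struct.unpack_from(byteorder + "HHI", buf, entry)
            nbytes = _TIFF_TYPE_SIZES.get(typ, 1) * count
            if nbytes > 4:
                voff = struct.unpack_from(u32, buf, entry + 8)[0]
                if voff + nbytes > size:
                    raise WSIFormatError(
                        f"{path}: tag value at byte {voff} runs past end of "
                        f"file ({size})")
        offset = struct.unpack_from(u32, buf, offset + 2 + 12 * n)[0]


# -- low-level IFD surgery ----------------------------------------------

def _walk_ifds(buf: bytearray, byteorder: str) -> list[int]:
    u16 = byteorder + "H"
    u32 = byteorder + "I"
    offsets = []
    offset = struct.unpack_from(u32, buf, 4)[0]
    while offset:
        offsets.append(offset)
        n = struct.unpack_from(u16, buf, offset)[0]
        offset = struct.unpack_from(u32, buf, offset + 2 + 12 * n)[0]
    return offsets


def _zero_ifd(buf: bytearray, byteorder: str, ifd_offset: int) -> None:
    """Zero an IFD block and every out-of-line tag value it points to."""
    u16 = byteorder + "H"
    u32 = byteorder + "I"
    n = struct.unpack_from(u16, buf, ifd_offset)[0]
    for k in range(n):
        entry = ifd_offset + 2 + 12 * k
        _tag, typ, count = struct.unpack_from(byteorder + "HHI", buf, entry)
        nbytes = _TIFF_TYPE_SIZES.get(typ, 1) * count
        if nbytes > 4:
            valueoffset = struct.unpack_from(u32, buf, entry + 8)[0]
            buf[valueoffset:valueoffset + nbytes] = bytes(nbytes)
    end = ifd_offset + 2 + 12 * n + 4
    buf[ifd_offset:end] = bytes(end - ifd_offset)


def _relink(buf: bytearray, byteorder: str, ifd_offsets: list[int],
            keep: list[int]) -> None:
    """Rewrite the IFD chain to visit only the kept directories."""
    u16 = byteorder + "H"
    u32 = byteorder + "I"
    kept = [ifd_offsets[i] for i in keep]
    struct.pack_into(u32, buf, 4, kept[0] if kept else 0)
    for j, off in enumerate(kept):
        n = struct.unpack_from(u16, buf, off)[0]
        nxt = kept[j + 1] if j + 1 < len(kept) else 0
        struct.pack_into(u32, buf, off + 2 + 12 * n, nxt)


def _require_new_path(src: Path, out: Optional[Union[str, Path]]) -> Path:
    if out is None:
        out = src.with_suffix(src.suffix + ".deid")
    out = Path(out)
    if out.resolve() == src.resolve():
        raise ValueError("in-place editing refused; give a distinct output path")
    return out


# -- operations ----------------------------------------------------------

def strip_associated_images(
    container: WSIContainer, out_path: Optional[Union[str, Path]] = None
) -> WSIContainer:
    """Remove label and macro sub-images into a new file.

    Payload bytes and directory blocks of the removed sub-images are
    overwritten with zeros, and the directories are unlinked from the
    IFD chain, so neither ordinary readers nor byte scavengers recover
    them.  Pyramid and thumbnail payloads stay byte-identical.  A
    container without label/macro is copied unchanged (idempotence).
    """
    out_path = _require_new_path(container.path, out_path)
    buf = bytearray(container.path.read_bytes())
    removed = {s.index for s in container.sub_images
               if s.role in (ROLE_LABEL, ROLE_MACRO)}
    if removed:
        ifd_offsets = _walk_ifds(buf, container.byteorder)
        for sub in container.sub_images:
            if sub.index not in removed:
                continue
            for off, cnt in zip(sub.data_offsets, sub.data_bytecounts):
                buf[off:off + cnt] = bytes(cnt)
            _zero_ifd(buf, container.byteorder, sub.ifd_offset)
        keep = [i for i in range(len(ifd_offsets)) if i not in removed]
        _relink(buf, container.byteorder, ifd_offsets, keep)
    out_path.write_bytes(bytes(buf))
    return read_container(out_path)


def _masked_description(desc: bytes, keys: Iterable[str]) -> bytes:
    for key in keys:
        pattern = re.compile(
            rb"(\|\s*" + re.escape(key.encode()) + rb"\s*=\s*)([^|\x00]*?)(?=\s*(?:\||\x00|$))",
            re.IGNORECASE,
        )

        def _mask(m: re.Match) -> bytes:
            return m.group(1) + b"X" * len(m.group(2))

        desc = pattern.sub(_mask, desc)
    return desc


def scrub_metadata(
    container: WSIContainer,
    policy: SensitiveFieldPolicy = SensitiveFieldPolicy(),
    out_path: Optional[Union[str, Path]] = None,
) -> WSIContainer:
    """Mask sensitive ``|key = value|`` metadata into a new file.

    Each policy key's value is replaced by an ``X`` run of equal byte
    length, in place in the ImageDescription, so no offsets shift and
    the ``|`` structure survives.  Geometry and spatial-calibration
    keys (MPP, magnification, dimensions) are never modified.
    """
    out_path = _require_new_path(container.path, out_path)
    buf = bytearray(container.path.read_bytes())
    with tifffile.TiffFile(container.path) as tif:
        for page in tif.pages:
            tag = page.tags.get(_TAG_IMAGE_DESCRIPTION)
            if tag is None or tag.count <= 4:
                continue
            start = tag.valueoffset
            raw = bytes(buf[start:start + tag.count])
            masked = _masked_description(raw, policy.fields)
            assert len(masked) == len(raw)
            buf[start:start + tag.count] = masked
    out_path.write_bytes(bytes(buf))
    return read_container(out_path)


def deidentify_wsi(
    path: Union[str, Path],
    out_path: Union[str, Path],
    policy: SensitiveFieldPolicy = SensitiveFieldPolicy(),
) -> WSIContainer:
    """Full image de-id: strip label/macro, then scrub metadata."""
    import tempfile

    path = Path(path)
    out_path = _require_new_path(path, out_path)
    container = read_container(path)
    with tempfile.TemporaryDirectory() as tmp:
        stage = Path(tmp) / "stripped.svs"
        stripped = strip_associated_images(container, stage)
        return scrub_metadata(stripped, policy, out_path)


# -- verification --------------------------------------------------------

@dataclass(frozen=True)
class CheckResult:
    name: str
    passed: bool
    detail: str = ""


@dataclass(frozen=True)
class DeidVerification:
    checks: tuple[CheckResult, ...]

    @property
    def passed(self) -> bool:
        return all(c.passed for c in self.checks)

    def check(self, name: str) -> CheckResult:
        return next(c for c in self.checks if c.name == name)


def verify_deid(
    original_path: Union[str, Path],
    deid_path: Union[str, Path],
    identifiers: Union[IdentifierBundle, Iterable[str]],
) -> DeidVerification:
    """Acceptance gate for one de-identified slide.

    Four checks: (a) no identifier string survives anywhere in the
    output's raw bytes (case-insensitive), (b) label and macro
    sub-images are absent, (c) every pyramid level's decoded pixels
    are identical to the original's, (d) a standard TIFF reader opens
    the file.  Failures are report entries, never exceptions.
    """
    if isinstance(identifiers, IdentifierBundle):
        strings = identifiers.phi_strings()
    else:
        strings = [str(s) for s in identifiers]

    checks: list[CheckResult] = []
    data = Path(deid_path).read_bytes()
    hits = []
    for s in strings:
        if not s:
            continue
        m = re.search(re.escape(s.encode()), data, re.IGNORECASE)
        if m:
            hits.append(f"{s!r} at offset {m.start()}")
    checks.append(CheckResult("no_identifier_bytes", not hits, "; ".join(hits)))

    try:
        deid = read_container(deid_path)
        present = [r for r in (ROLE_LABEL, ROLE_MACRO) if deid.by_role(r)]
        checks.append(CheckResult("label_macro_absent", not present,
                                  ", ".join(present)))
    except WSIFormatError as exc:
        deid = None
        checks.append(CheckResult("label_macro_absent", False, str(exc)))

    if deid is not None:
        orig = read_container(original_path)
        orig_pyr = sorted(orig.by_role(ROLE_PYRAMID),
                          key=lambda s: -(s.width * s.height))
        deid_pyr = sorted(deid.by_role(ROLE_PYRAMID),
                          key=lambda s: -(s.width * s.height))
        if len(orig_pyr) != len(deid_pyr):
            checks.append(CheckResult(
                "pyramid_pixels_identical", False,
                f"{len(orig_pyr)} levels before, {len(deid_pyr)} after"))
        else:
            bad = []
            for o, d in zip(orig_pyr, deid_pyr):
                if not np.array_equal(orig.pixels(o.index), deid.pixels(d.index)):
                    bad.append(f"level {o.width}x{o.height}")
            checks.append(CheckResult("pyramid_pixels_identical", not bad,
                                      ", ".join(bad)))
    else:
        checks.append(CheckResult("pyramid_pixels_identical", False,
                                  "output unreadable"))

    try:
        tifffile.imread(deid_path, key=0)
        checks.append(CheckResult("readable_by_standard_reader", True))
    except Exception as exc:
        checks.append(CheckResult("readable_by_standard_reader", False, str(exc)))

    return DeidVerification(checks=tuple(checks))
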