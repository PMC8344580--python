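"""Post-scan quality-control triage and the rescan request queue.

The manual QC workflow, encoded as deterministic rules:

1. the macro image of every WSI is reviewed by a technician;
2. Leica scans with a scanner-issued Quality Factor below 90 get a
   detailed focus review (strict ``<``: 90 passes);
3. every Philips WSI, and every 10th Leica/3DHistech slide of a batch,
   is fully opened to verify successful scanning.

Pathologists can additionally file rescan requests with a reason
(blurriness, missing tissue, air bubbles, other); duplicate reports by
the same reporter on the same day collapse to one queue entry.
"""

from __future__ import annotations

import datetime
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Union

from .records import ImageRecord

RESCAN_REASONS = ("blurriness", "missing_tissue", "air_bubbles", "other")
QF_REVIEW_THRESHOLD = 90
PERIODIC_SAMPLE_PERIOD = 10


@dataclass(frozen=True)
class QCDisposition:
    image_id: str
    checks_triggered: frozenset[str]  # ⊆ {macro_review, quality_factor_review, full_open_check}
    outcome: str  # pass | rescan
    rescan_reason: Optional[str] = None

    def __post_init__(self):
        if self.outcome == "rescan" and self.rescan_reason is None:
            raise ValueError("rescan outcome requires a reason")


def triage(image: ImageRecord, macro_ok: bool, vendor: str,
           override_reason: Optional[str] = None) -> QCDisposition:
    """Evaluate the three QC rules for one scan.

    ``macro_ok=False`` forces a rescan, attributed to missing tissue
    unless ``override_reason`` names another category.  A Leica image
    without a quality factor violates the vendor contract and errors.
    Stateless and order-independent per image.
    """
    checks = {"macro_review"}
    if vendor == "leica":
        if image.quality_factor is None:
            raise ValueError(
                f"image {image.image_id}: Leica scans must carry a quality factor"
            )
        if image.quality_factor < QF_REVIEW_THRESHOLD:
            checks.add("quality_factor_review")
    if vendor == "philips" or (
        vendor in ("leica", "3dhistech")
        and image.sequence_index % PERIODIC_SAMPLE_PERIOD == 0
    ):
        checks.add("full_open_check")
    if macro_ok:
        outcome, reason = "pass", None
    else:
        reason = override_reason or "missing_tissue"
        if reason not in RESCAN_REASONS:
            raise ValueError(f"unknown rescan reason {reason!r}")
        outcome = "rescan"
    return QCDisposition(
        image_id=image.image_id,
        checks_triggered=frozenset(checks),
        outcome=outcome,
        rescan_reason=reason,
    )


def sample_periodic(
    images: Iterable[ImageRecord], period: int = PERIODIC_SAMPLE_PERIOD
) -> list[ImageRecord]:
    """Every ``period``-th scan of a contiguous batch (index ≡ 0 mod period)."""
    if period < 1:
        raise ValueError("period must be positive")
    return [img for img in images if img.sequence_index % period == 0]


@dataclass(frozen=True)
class RescanRequest:
    image_id: str
    reason: str
    reporter: str
    timestamp: str  # ISO datetime


class RescanQueue:
    """Persistent (JSON-lines) queue of pathologist rescan requests."""

    def __init__(self, path: Optional[Union[str, Path]] = None):
        self.path = Path(path) if path is not None else None
        self._entries: list[RescanRequest] = []
        if self.path is not None and self.path.exists():
            with open(self.path, encoding="utf-8") as fh:
                for line in fh:
                    if line.strip():
                        self._entries.append(RescanRequest(**json.loads(line)))

    def file_rescan_request(
        self,
        image_id: str,
        reason: str,
        reporter: str,
        timestamp: Optional[datetime.datetime] = None,
    ) -> Optional[RescanRequest]:
        """Append a request; same (image, reporter, reason) within one
        calendar day collapses to the existing entry (returned as None)."""
        if reason not in RESCAN_REASONS:
            raise ValueError(
                f"unknown rescan reason {reason!r}; expected one of {RESCAN_REASONS}"
            )
        ts = timestamp or datetime.datetime.now()
        day = ts.date().isoformat()
        for e in self._entries:
            if (
                e.image_id == image_id
                and e.reporter == reporter
                and e.reason == reason
                and e.timestamp[:10] == day
            ):
                return None
        entry = RescanRequest(image_id=image_id, reason=reason,
                              reporter=reporter, timestamp=ts.isoformat())
        self._entries.append(entry)
        if self.path is not None:
            with open(self.path, "a", encoding="utf-8") as fh:
                fh.write(json.dumps(entry.__dict__) + "\n")
        return entry

    @property
    def entries(self) -> list[RescanRequest]:
        return list(self._entries)
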