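"""End-to-end dataset compilation: the broker's release pipeline.

cohort query → consent gate → image de-identification + verification →
dark-region screening → record/report de-identification → manifest.

Honest-broker separation: the re-identification key store and the
audit log (which reference original identifiers) are written OUTSIDE
the export directory; nothing under ``out_dir`` carries PHI.
"""

from __future__ import annotations

import datetime
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

from . import __version__
from .image_deid import SensitiveFieldPolicy, deidentify_wsi, verify_deid
from .phi_screen import DarkRegionParams, screen_wsi
from .records import CohortCriteria
from .text_deid import HIDKeyStore, deidentify_record, redact_report
from .warehouse import Warehouse
from . import image_deid

EXCLUSION_REASONS = ("consent", "phi_screen", "deid_failure")


@dataclass
class DatasetManifest:
    request_id: str
    parameters: dict
    tool_version: str
    included: list[dict] = field(default_factory=list)
    excluded: list[dict] = field(default_factory=list)  # {image_hid, reason}

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, default=str)

    @classmethod
    def load(cls, path: Union[str, Path]) -> "DatasetManifest":
        data = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(**data)


class AuditLog:
    """Structured JSON-lines record of every broker decision."""

    def __init__(self, path: Optional[Union[str, Path]] = None):
        self.path = Path(path) if path is not None else None
        self.events: list[dict] = []

    def record(self, event: str, **details) -> None:
        entry = {"ts": datetime.datetime.now().isoformat(),
                 "event": event, **details}
        self.events.append(entry)
        if self.path is not None:
            with open(self.path, "a", encoding="utf-8") as fh:
                fh.write(json.dumps(entry, default=str) + "\n")


def compile_dataset(
    warehouse: Warehouse,
    criteria: CohortCriteria,
    keystore: HIDKeyStore,
    out_dir: Union[str, Path],
    request_id: str = "REQ-0001",
    screen_params: DarkRegionParams = DarkRegionParams(),
    policy: SensitiveFieldPolicy = SensitiveFieldPolicy(),
    audit: Optional[AuditLog] = None,
) -> tuple[DatasetManifest, int]:
    """Compile and de-identify one research dataset.

    Returns ``(manifest, n_deid_failures)``; a nonzero failure count
    means some slide could not be safely de-identified (it is excluded
    and the caller should exit nonzero).  ``criteria.protocol_id`` is
    required: release without a consented protocol is refused.
    """
    if criteria.protocol_id is None:
        raise ValueError("dataset compilation requires a protocol_id")
    out_dir = Path(out_dir)
    try:
        (out_dir / "images").mkdir(parents=True, exist_ok=True)
        (out_dir / "reports").mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out_dir}: {exc}") from exc
    audit = audit or AuditLog()

    hits = warehouse.query_cohort(criteria)
    audit.record("cohort_query", n_hits=len(hits),
                 criteria=criteria.model_dump(mode="json"))
    decision = warehouse.enforce_consent(
        [h.image_id for h in hits], criteria.protocol_id
    )
    manifest = DatasetManifest(
        request_id=request_id,
        parameters={
            "criteria": criteria.model_dump(mode="json"),
            "screen": screen_params.__dict__,
            "policy": list(policy.fields),
        },
        tool_version=__version__,
    )
    n_failures = 0

    for image_id, reason in decision.excluded:
        hid = keystore.assign("image", image_id)
        manifest.excluded.append({"image_hid": hid, "reason": "consent"})
        audit.record("consent_exclusion", image_id=image_id,
                     image_hid=hid, reason=reason)

    for image_id in decision.included:
        img = warehouse.image(image_id)
        sld = warehouse.slide(img.barcode)
        case = warehouse.case(sld.accession)
        patient = warehouse.patient(case.mrn)
        bundle = warehouse.identifier_bundle(image_id)
        image_hid = keystore.assign("image", image_id)
        case_hid = keystore.assign("case", sld.accession)
        patient_hid = keystore.assign("patient", patient.mrn)

        deid_file = out_dir / "images" / f"{image_hid}.svs"
        try:
            container = image_deid.read_container(img.file_path)
            screen = screen_wsi(container, screen_params, image_id=image_id)
            if screen.flagged:
                manifest.excluded.append(
                    {"image_hid": image_hid, "reason": "phi_screen"})
                audit.record("phi_screen_exclusion", image_id=image_id,
                             image_hid=image_hid,
                             regions=len(screen.regions))
                continue
            deidentify_wsi(img.file_path, deid_file, policy)
            verification = verify_deid(img.file_path, deid_file, bundle)
        except Exception as exc:
            n_failures += 1
            manifest.excluded.append(
                {"image_hid": image_hid, "reason": "deid_failure"})
            audit.record("deid_failure", image_id=image_id,
                         image_hid=image_hid, error=str(exc))
            deid_file.unlink(missing_ok=True)
            continue
        if not verification.passed:
            n_failures += 1
            deid_file.unlink(missing_ok=True)
            manifest.excluded.append(
                {"image_hid": image_hid, "reason": "deid_failure"})
            audit.record("deid_verify_failure", image_id=image_id,
                         image_hid=image_hid,
                         checks=[c.__dict__ for c in verification.checks])
            continue

        report_files = []
        for i, rep in enumerate(warehouse.reports_for(sld.accession)):
            redacted = redact_report(rep.text, patient=patient, case_hid=case_hid)
            name = f"{case_hid}.txt" if i == 0 else f"{case_hid}_{i}.txt"
            (out_dir / "reports" / name).write_text(redacted.deid_text,
                                                    encoding="utf-8")
            report_files.append(f"reports/{name}")

        row = deidentify_record(img, keystore)
        row.update(deidentify_record(sld, keystore))
        row.update({
            "patient_hid": patient_hid,
            "file": f"images/{deid_file.name}",
            "reports": report_files,
        })
        manifest.included.append(row)
        audit.record("included", image_id=image_id, image_hid=image_hid)

    (out_dir / "manifest.json").write_text(manifest.to_json(), encoding="utf-8")
    audit.record("manifest_written", included=len(manifest.included),
                 excluded=len(manifest.excluded), failures=n_failures)
    return manifest, n_failures
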