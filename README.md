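# pathbroker

An honest-broker toolkit for digital pathology research data.

Clinical slide archives are a rich substrate for computational
pathology, but every scanned slide is tied to a patient: the medical
record number (MRN), the case accession number, the slide barcode, the
scan dates, the label sticker photographed into the slide file itself.
An *honest broker* sits between the clinical archive and the research
world — it compiles cohorts only from patients with an affirmative
consent trail, de-identifies everything it releases, and keeps the
re-identification key on its own side of the wall.

`pathbroker` implements that broker end to end, on synthetic data:

* **warehouse** — an embedded store of patients, cases, parts/blocks,
  slides, scanned images and free-text reports; conjunctive cohort
  queries; patient-level consent gating (a signed Notice of Privacy
  Practice **and** "consented" status on the requesting protocol —
  "unknown" excludes).
* **text_deid** — HIPAA Safe-Harbor de-identification: dates truncated
  to the year; surrogate identifiers (HIDs, one family each for
  patients ← MRNs, cases ← accessions, images ← vendor image IDs)
  issued from a keyed counter with a persistent bidirectional key
  store; regular-expression redaction of dates, accessions, MRNs and
  the patient's name in report text.
* **image_deid** — whole-slide images in an SVS-style pyramidal TIFF
  dialect: the label and macro images are overwritten with zeros *and*
  unlinked from the directory chain; sensitive `|key = value|` metadata
  (scan date/time, scanner ID, barcode, filename, operator) is masked
  in place with equal-length `X` runs; diagnostic pixels are untouched
  and verified bit-identical.
* **phi_screen** — a sticker scanned next to the tissue survives in
  the main image, so thumbnails are screened for large dark connected
  components; a flagged slide is excluded from the dataset outright.
* **scan_qc** — the post-scan triage rules (macro review for every
  slide; detailed review of Leica scans with Quality Factor < 90;
  every Philips slide and every 10th Leica/3DHistech slide fully
  opened) and a deduplicating rescan-request queue.
* **storage_planner** — capacity arithmetic (1 GB/WSI × 10⁶ scans/yr
  = 1 PB/yr), cumulative first-access curves from access logs, and the
  two-tier assignment keeping recently scanned slides on flash.
* **fixtures** — seeded generators for all input families with ground
  truth: consent tables, PHI span annotations, planted identifier byte
  strings inside generated slide files, access logs from an explicit
  month distribution.

## Worked example

Generate a 5-patient synthetic archive and compile a consented,
de-identified dataset:

```bash
$ pathbroker gen-fixtures --seed 7 --n-patients 5 --base-size 512 --out arch
wrote 5 patients, 7 WSI under arch

$ pathbroker compile --archive arch --protocol PR-001 \
      --out export --broker-dir broker
{"included": 3, "excluded": 4, "deid_failures": 0}
```

Three of the seven scans belong to patients with a full consent trail
and are released; the other four are excluded with reason `consent`.
The manifest rows carry only surrogate identifiers and year-truncated
dates — part and block numbers are the only identifiers that pass
through verbatim:

```json
{
  "image_hid": "I-79248dd2",
  "scan_year": "2020",
  "case_hid": "C-202f4596",
  "part_id": 2,
  "block_id": 2,
  "stain": "H&E",
  "scanner_vendor": "philips",
  "file": "images/I-79248dd2.svs",
  "reports": ["reports/C-202f4596.txt"]
}
```

and the released report text is fully redacted, with years retained:

```
FINAL DIAGNOSIS: benign fibrous tissue. Specimen reference [ACCESSION].
Specimen reference [MRN]. Received from [PATIENT]. Specimen reference
[DATE-2019]. Microscopic sections show the findings described above.
```

The key store and audit log land in `broker/`, never in `export/`:
re-identification is possible only through the broker.

Library use mirrors the CLI — see `docs/methods.md` for the model
behind each module and `tests/` for executable examples.

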