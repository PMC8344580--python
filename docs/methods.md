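# Methods

This note documents the models, rules and numerical choices behind
`pathbroker`, what the synthetic generators emulate, and what passing
tests do and do not demonstrate about real archives.

## Data model and consent semantics

The warehouse mirrors the identifier hierarchy of an anatomic-pathology
LIS: patient (MRN, digit string) → accessioned case → part → block →
glass slide (barcode) → scanned image (vendor-scheme ID, possibly a
GUID; a slide may own several images through rescans). Case accessions
follow the grammar `[SCHRM]\d{2}-\d+` — specimen-class letter
(surgical, cytology, hematopathology, research, molecular), two-digit
year, dash, running number — and unparseable accessions are rejected at
ingest rather than passed through. Part and block numbers are the only
identifiers treated as non-PHI.

Cohort release is gated per patient: inclusion requires a signed
Notice of Privacy Practice **and** an explicit "consented" status on
the requesting protocol. "Unknown" consent excludes — the conservative
reading of an honest broker's duty; the two failure modes are reported
separately (`npp_missing`, `not_consented`, `unknown_consent`).
Consent is evaluated at request time, not snapshotted. Keyword search
over reports is case-insensitive substring matching with no stemming;
criteria are conjunctive, so adding one can only shrink a cohort.

Persistence is an embedded sqlite database (in-memory for tests);
the module surface is format-agnostic (CSV or JSON-lines per record
type).

## Safe-Harbor text de-identification

Three mechanisms, applied to every applicable field:

* **Date truncation** drops day and month, keeping the 4-digit year
  (permitted under Safe Harbor). Unparseable dates raise — a date is
  never passed through silently.
* **HID generation.** Surrogates take the form `<P|C|I>-<8 hex>`. The
  hex digits derive from a BLAKE2b keyed hash of a per-family counter
  — *not* of the original identifier — so the mapping cannot be
  inverted by hashing candidate MRNs (dictionary attack); the only
  route back is the key store, an append-only JSON-lines file whose
  header persists the store key, making HIDs stable across restarts.
* **Text redaction** applies ordered regular-expression rules; an
  earlier rule's match suppresses overlapping later candidates. Date
  dialects covered: ISO `YYYY-MM-DD`, US slash `M/D/YYYY` and
  `MM/DD/YY` (two-digit years pivot at 50), and written month
  ("March 15, 2020"). The date placeholder `[DATE-<year>]` retains the
  year. Accession tokens admit barcode-style suffixes
  (`S20-0123-2-1`), since slide barcodes embedding accessions may
  appear in report text. MRNs are standalone 6–9 digit runs; other
  long numbers will be over-redacted, which we accept — a false
  replacement is cheap, a missed MRN is not. Name rules match the
  patient's given/family tokens of ≥ 3 characters case-insensitively,
  in "Given Family", "Family, Given" and standalone order; initials
  and nicknames are out of scope. Placeholder templates contain no
  digits and cannot match any rule, which makes redaction a fixed
  point.

The redactor is a single rule-based pass; no statistical or NER
de-identification layer is included, and addresses, phone numbers and
provider names are not redacted. The recall guarantees measured by the
tests therefore hold *for PHI drawn from the documented grammar* —
exactly what the fixture generator plants — and say nothing about
free-form PHI outside it.

## Whole-slide-image de-identification

PHI occupies four places in a slide file: the label image (sticker
photo: barcode + patient name), the macro overview (may show part of
the sticker), text metadata, and — when the sticker sat close to the
tissue — the main image itself.

The first three are handled by byte surgery on a classic (non-Big)
TIFF with Aperio-style `|key = value|` ImageDescription. `tifffile`
parses structure (page offsets, tag offsets, pixel decoding); all
modification is explicit byte patching:

* **Strip**: label and macro payload ranges and their whole directory
  blocks (including out-of-line tag values such as descriptions) are
  overwritten with zeros, and the directories are unlinked from the
  IFD chain. Overwrite-*and*-unlink means neither an ordinary reader
  nor a byte scavenger recovers the sticker.
* **Scrub**: each sensitive key's value (default policy: Date, Time,
  ScanScope ID, Barcode, Filename, Operator, User) is replaced by an
  `X` run of equal byte length at its original offset, so no offsets
  shift and the `|` structure survives. Geometry and calibration keys
  (dimensions, tiling, compression, MPP, magnification) are refused by
  policy validation; microns-per-pixel is preserved exactly.
* Editing is never in place — output is always a new file. Sub-image
  classification: a description containing `label` → label, `macro` →
  macro; the smallest remaining non-tiled strip image → thumbnail;
  everything else is a pyramid level. Files with no pyramid level, an
  ambiguous base level, duplicate label/macro, or a truncated or
  BigTIFF/other-dialect structure error out with the offending byte
  offset.

Verification re-reads both files independently and asserts four
properties: no identifier byte-string survives anywhere in the output
(case-insensitive full-file scan), label/macro absent, every pyramid
level bit-identical to the original, and the file opens in a standard
reader. Failures are report entries, not exceptions, so a pipeline can
quarantine a slide rather than crash.

The fourth PHI location is handled by screening (below), and the
flagged slide is excluded whole — never cropped or inpainted.

## Dark-region screening

Thumbnail luminance is integer Rec.601 (`0.299R + 0.587G + 0.114B`);
pixels below a threshold form a mask whose connected components are
labeled (default 8-connectivity). A slide is flagged iff some
component's area fraction reaches `min_area_fraction` (`≥` at the
boundary). Defaults — threshold 60/255, minimum fraction 0.05 — are
operational choices exposed in `DarkRegionParams` and recorded in
every decision for auditability; no published quantitative definition
of "dark" exists to calibrate against. The screen prefers a dedicated
thumbnail sub-image and falls back to box-downsampling the base level
to ≤ 512 px. Screening is pure: the container is never modified.

## QC triage

The three rules are encoded exactly: macro review always;
quality-factor review iff the vendor is Leica and the scanner-issued
Quality Factor is `< 90` (strict — 90 passes); full-open check for
every Philips slide and for Leica/3DHistech slides whose batch
sequence index ≡ 0 (mod 10). "Every 10th" is interpreted as index
multiples of 10 per batch (the phase is unspecified in practice; any
fixed phase selects ⌊n/10⌋ of n contiguous scans). Philips slides
receive both macro review and the full-open check. A failed macro
review forces a rescan, auto-attributed to `missing_tissue` unless a
reporter overrides the reason — a deterministic simplification of a
human judgment. A Leica image without a quality factor violates the
vendor contract and errors. Rescan reasons are the four observed
categories (blurriness, missing tissue, air bubbles, other); duplicate
reports by the same reporter on the same calendar day collapse.

## Storage planning

Capacity is bilinear: `size_GB × scans/yr / 10⁶` PB/yr, using the
decimal convention (10⁶ GB = 1 PB) consistent with the 1 GB × 10⁶ =
1 PB arithmetic it reproduces. Access curves bin first accesses into
calendar-agnostic 30.44-day months, month 1 = (0, 1] month (same-day
access counts as month 1); only ever-accessed slides enter the
denominator, matching how slide-viewer usage is reported, while
never-accessed slides still participate in tier assignment by scan
date. The tier-1 window is the smallest month whose cumulative
fraction reaches the coverage target; an unreachable target errors,
naming the maximum attainable fraction.

## Synthetic generators

All randomness descends from a single integer seed (numpy PCG64;
sub-streams keyed by CRC32 of a stream name); reruns are
byte-identical. Defaults model a mid-size request: 50 patients, 60%
protocol consent, 90% NPP signature, one case per patient with 1–2
parts, one scan per slide, three scanner vendors in realistic model
mixes, scan dates over 2018–2020. Reports plant a configurable number
of PHI spans (default 4) drawn only from the redactor's documented
grammar, with exact span tables as ground truth.

Generated slides are desk-scale (base ≤ 2048 px, default 1024 in the
shared archives, 256–512 in the many-archive runs so the whole suite
and the acceptance script finish in seconds): uncompressed tiled
pyramid levels, a strip thumbnail, a label card rendering the sticker
text and additionally embedding its ASCII bytes in the first pixel
row (so the string exists as scannable file bytes, not just glyphs),
and a macro with a simulated sticker corner. Tissue is procedural
ellipse texture — deliberately not photorealistic. Pixel values of
surviving sub-images are constrained outside the ASCII letter/digit
byte range, so a byte-level identifier scan cannot false-positive on
image noise; this is a fixture property, not a claim about real
scanner output.

The access-log generator draws first-access months from an explicit
probability vector; the default profile puts 51% of accesses in
month 1, reaches 79% by month 6 and 91% by month 12 with a 3-year
tail, emulating a busy academic archive. A configurable fraction of
slides (default 20%) is never accessed.

What the fixtures do **not** emulate: real scanner compression (JPEG
/ JPEG2000), vendor containers other than the generic SVS/TIFF dialect
(no Philips iSyntax, no 3DHistech MRXS, no BigTIFF), OCR-able sticker
layouts, report language beyond the planted grammar, and clinical
volume. Green tests demonstrate the mechanisms — consent logic, byte
surgery, span replacement, curve recovery — under controlled inputs,
not validated performance on a hospital archive.

## Known limitations

* The redactor's recall guarantee is relative to its grammar; real
  reports contain PHI shapes (addresses, phone numbers, provider
  names, free-form dates) it does not target.
* Only the SVS-style classic-TIFF dialect is de-identified; other
  vendor formats are refused, not converted.
* The dark-region screen detects stickers by darkness alone; pale or
  translucent overlays would pass.
* HID issuance is sequential per store; merging two independently
  grown key stores is not supported.
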