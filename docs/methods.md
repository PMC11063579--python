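# Methods

This note documents the models and procedures inside `pseudoreg`, the
parameters that matter, the numerical and design choices that were
genuinely open, and what the synthetic-data tests do and do not show.

## Pseudonym scheme

A pseudonym renders as `PREFIX-SITE-BODY-CHECK`. The body is drawn
uniformly at random from a configurable alphabet (default: uppercase
alphanumerics minus I, O, 0, 1 — 32 symbols) at a configurable length
(default 6, giving 32⁶ ≈ 1.07 × 10⁹ values per scope and site). Random
rather than sequential bodies are the default because sequential counters
leak enrolment order through every exported artifact; a sequential mode
exists for migrating registries that were numbered that way.

Collision handling is bounded rejection sampling (64 draws against the set
of issued values) followed by a deterministic lexicographic scan of the
body space. The scan triggers only when the space is nearly saturated; it
guarantees termination and converts a full space into an explicit
capacity-exhausted error. Validation of the configuration warns when
`alphabet^body_length` falls below the expected registry capacity.

The check character is ISO 7064 MOD 37-2 over `prefix + site_code + body`
(values 0–9, A–Z; the check symbol may additionally be `*`). MOD 37-2 is a
pure-system scheme with radix 2 and modulus 37: it detects every
single-character substitution, and adjacent transpositions escape only
when the two characters' values satisfy a congruence that is rare in
practice (the test suite's brute-force sweep over a thousand IDs finds
none; the suite asserts ≥ 99 %). Validation reports structural defects
(wrong prefix, site, length, characters, separator) separately from a
check-character mismatch, because the latter means "a real ID was probably
mistyped" and is surfaced to users as a suspected transcription error
rather than not-found.

## Identity normalization and quality checks

All matching happens on a canonical form: NFKD decomposition with
combining marks stripped (Müller → MULLER), case folding to upper case
(ß → SS), internal whitespace collapsed, dates as ISO 8601 `YYYY-MM-DD`,
enums mapped to their configured codes. Normalization is applied to a
fixed point, making it idempotent by construction (a property test checks
this over arbitrary Unicode). ISO dates everywhere is deliberate: the
registries this package targets span countries whose local date formats
conflict in exactly the way (day/month swap) that the linkage layer has
to model as a typo.

Quality checks are total (never raise) and two-level: **errors** block
registration (missing required fields, invalid calendar dates such as
February 30th, future birth dates, enum values outside the configured
set); **warnings** flag suspicious but admissible values (age above 110
years, single-character names, placeholder strings like "XXX" or "TEST").

## Record linkage

Per-field similarities:

- text: Jaro–Winkler (prefix scale 0.1, maximum prefix 4, boost only above
  0.7), the standard choice for short name strings; half-transpositions
  are floored as in the original reference implementation;
- date: 1.0 if equal; 0.8 if the day and month are transposed or exactly
  one of year/month/day differs; 0.0 otherwise;
- enum: equality.

The aggregate is the weighted arithmetic mean over fields present in both
records (weights from the identity schema; fields missing on either side
are excluded, which redistributes their weight). Classification uses two
thresholds: `block` (default 0.98) refuses registration, `review` (default
0.85) requires an explicit audited override. The defaults follow common
identity-linkage practice: 0.98 admits only near-exact agreement, 0.85
catches one-to-two keystroke errors on realistic name lengths without
flooding staff with review candidates.

Default weights are first name 1.0, last name 1.0, date of birth 1.0, sex
0.25. Sex carries little identifying evidence (few possible values), and
keeping the non-date weights at or below this level yields the blocking
guarantee below.

### Blocking

Fuzzy search must scale to the size of a multi-year study while remaining
*exactly* equivalent to a brute-force scan — blocking that silently drops
a true match would defeat the registry's purpose. The index therefore
blocks on date-of-birth component pairs: each record is keyed under
(year, month), (year, day), (month, day), and (year, {month, day}
unordered). A candidate at or above the review threshold must have date
similarity ≥ 0.8 whenever the configured weights satisfy

    (W − w_dob) / W < review_threshold,

because even perfect agreement on every other field cannot otherwise reach
the threshold (with the defaults: 2.25/3.25 ≈ 0.69 < 0.85). Every record
pair with date similarity ≥ 0.8 — equal dates, one differing component, or
a day/month transposition — shares at least one of the four keys, so the
blocked candidate set is a superset of every possible hit. The bound is
recomputed from the live configuration at query time; if it fails, or the
query carries no parseable date of birth, search falls back to a full
scan. Records without a date of birth are always scanned. Wildcard
queries are always evaluated by full scan. The acceptance suite asserts
set-identity between blocked search and a brute-force oracle over
thousands of randomized queries, and the scaled import experiment measures
candidate comparisons per registration at sizes 10³/10⁴/10⁵ (≈ 0.23 % of
registry size, growth ratio ≈ 1.0× linear).

The inner scoring loop applies an exact branch-and-bound cutoff (cheap
fields first; a candidate is dropped once perfect similarity on its
remaining fields cannot reach the review threshold) and accumulates in a
fixed field order, so pruned and unpruned computations agree bit for bit.
Jaro–Winkler values are memoized; name pools in real cohorts are heavily
repeated, which makes bulk linkage largely cache-bound.

## Registry semantics

- **Search proof.** `register_subject` demands the result of a search run
  for *this* identity (fingerprint of the normalized values) against the
  *current* state (index version); otherwise it raises missing-search or
  stale-search. This encodes the workflow rule that the duplicate search
  is the first step of every registration.
- **Aliquots.** One pseudonym per vial; aliquot indices continue across
  registration calls per (subject, visit, sample type).
- **Audit.** Every mutating operation and every depseudonymization appends
  exactly one entry (timestamp, actor, action, target). The log is
  append-only and survives save/load.
- **Persistence.** A registry directory holds `config.yaml`, line-delimited
  JSON record files, and `meta.json` (written last, with record counts).
  Saves write-and-rename per file; a torn snapshot is detected by the
  count check and reported as corruption rather than silently loaded.
- **Locking.** Single writer via a lock file carrying holder and
  timestamp; a second writer fails naming the holder. Locks older than a
  configurable stale timeout (default 12 h) are *reported*, and takeover
  requires an explicit flag — a stale lock is never broken silently.
  Readers load a consistent snapshot of the durable state without touching
  the lock, so label printing can proceed while enrolment continues.
- **Bulk import.** `register_new` runs the full quality + linkage pipeline
  per row (against the registry and the rows already accepted from the
  same file); acceptance is all-or-nothing per row, never per file.
  `restore_with_pseudonyms` preserves pseudonyms verbatim for backup
  restore and version migration; any collision aborts the whole file with
  a row-indexed diff, since a partially restored registry is worse than a
  failed restore. Exports are deterministic (fixed column order, rows
  sorted by pseudonym) and re-importable; an export flagged as backup
  resets the reminder clock (default interval: 1 day).

## Label rendering

Sheets are laid out row-major with configurable rows × columns and a
per-payload repeat count; page count is ⌈cells / (rows·columns)⌉ with
blanks trailing on the last page. The output is a single self-contained
HTML document (inline CSS and SVG, no external references) because labels
are printed from a browser on the machine that holds the data and must
not require network access. Cell geometry is CSS and can be adapted to
label stock; no printer-driver integration is attempted.

The three symbologies are implemented at the module-matrix level:

- **DataMatrix ECC 200** (default; smallest footprint on cryotube labels):
  square symbols 10×10–26×26, ASCII encodation with digit pairing,
  253-state pad randomization, standard diagonal placement with the four
  corner cases, Reed–Solomon parity over GF(256) with primitive
  polynomial 0x12D and first root α¹.
- **QR** versions 1–3 at error-correction level M, byte mode, mask 0
  (the decoder honors any mask read from the BCH-protected format field).
- **Code 128** set B with the mandatory modulo-103 check symbol.

Each decoder is a separate read path (frame/format verification, inverse
placement or zigzag, Reed–Solomon syndrome check, de-encodation) used as
the round-trip oracle in tests; any flipped module is reported as
corruption, never misread. Decoders operate on module matrices — image
capture, deskewing, and error *correction* (as opposed to detection) are
out of scope.

## Synthetic cohorts

The generator emulates the properties of enrolment data that exercise the
linkage layer: multi-locale name pools (including diacritics) with a
Zipf-like frequency skew (heavy-tailed name frequencies are what create
chance near-matches), uniform dates of birth over 1920–2007 (days 1–28, so
every generated date is valid in every month and day/month swaps are
well-defined), and sex correlated with the first-name pool. Duplicates are
copies of earlier records with 1–`max_typos` logged edits — character
substitution, adjacent transposition, deletion, a day/month swap, or a
single-component date change — at most one edit per field and at most one
to the date of birth. Every duplicate therefore retains date similarity
≥ 0.8, matching how real duplicate enrolments look (a typo or two, not a
different person).

Originals are kept separable by construction: a sampled identity is
rejected and redrawn if it scores at or above the default review threshold
against any previously accepted original. This is what makes the
ground-truth labels meaningful — any false positive or missed duplicate
indicts the matcher, not an ambiguous cohort — and it is also what the
duplicate-free 100,000-subject import relies on.

What the fixtures do **not** model: real name-frequency distributions by
country, correlated household surnames, transliteration variants,
phonetically equivalent spellings (no Soundex/Metaphone in this version),
shared or estimated dates of birth (e.g. January 1st clustering), and
fields beyond the default four. Linkage metrics measured here (precision
and recall ≈ 1.0 at the default thresholds) are therefore an upper bound
on real-world performance; on real data the review threshold and weights
should be tuned per study, which is why both are configuration, not code.

## Problem sizes and determinism

Test and acceptance sizes were chosen to exercise the asymptotic claims on
a desk machine: 100,000 pseudonyms for collision behavior, a brute-force
substitution sweep over 1,000 IDs (~4 × 10⁵ mutations), a 5,000-identity
cohort with 5 % duplicates for linkage quality, 1,000 records × 200
queries for search equivalence, and the 100,000-subject + 100,000-biosample
import for scaling (comparisons counted at 10³/10⁴/10⁵). All randomness
flows from explicit integer seeds; cohorts and metrics are bit-identical
across runs for a fixed seed. Scaling is asserted on candidate-comparison
counts, not wall clock, which is reported but hardware-dependent.

## Known limitations

- No cryptographic or keyed derivation of pseudonyms from identity data;
  the model is registry lookup, by design (derived pseudonyms cannot be
  revoked and invite dictionary attacks on the identity space).
- No phonetic matching and no cross-site federated linkage; one registry
  is one site's mapping.
- Single-writer file locking is advisory: it assumes cooperating processes
  on a shared filesystem, not adversarial ones.
- The symbology decoders verify and reject; they do not correct. A
  damaged-but-correctable physical label is handled by the scanner's own
  decoder in practice.
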