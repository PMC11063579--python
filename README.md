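# pseudoreg

A pseudonymization registry for multi-site biomedical studies: it registers
study subjects and biosamples, mints collision-free pseudonyms with
transcription-safe check characters, prevents duplicate enrolment through
data-quality checks and fuzzy record linkage, manages visit schedules and
aliquots, renders machine-readable vial labels, and round-trips the whole
registry through plain CSV — all on local files, with single-writer locking
and consistent read-only snapshots, so a site can deploy it on a network
share in minutes with no server or database.

## Who it is for, and the privacy model

Study nurses and lab staff enrolling participants across many sites need to
(a) give every person and every vial a stable identifier that carries no
identity, and (b) be able to go *back* from an identifier to a person when a
follow-up requires it. The registry therefore stores exactly three kinds of
data and nothing else:

- **IDAT** — the identifying attributes captured at enrolment (names, date
  of birth, sex, per the configurable identity schema);
- **SDAT** — sample attributes (visit, type, aliquot number);
- the **pseudonyms** linking them: a subject ID (e.g. `SUB-BER-DEUZYV-F`)
  and one biosample ID per aliquot (e.g. `BIO-BER-FNCFVZ-S`).

Medical data never enter the registry — downstream systems hold them keyed
by pseudonym only — and every depseudonymization is written to an
append-only audit log.

## The core mechanisms

**Pseudonyms.** `prefix-site-body-check`, with a random body drawn from a
32-character alphabet that excludes the visually ambiguous I/O/0/1, and an
ISO 7064 MOD 37-2 check character computed over `prefix+site+body`. The
check character detects 100 % of single-character substitutions and, in
practice, all adjacent transpositions, so a mistyped ID surfaces as
*suspected transcription error* instead of a silent miss (or a wrong
record). Generation is rejection sampling with a bounded retry followed by
a deterministic scan, so it terminates near capacity and fails loudly at
capacity.

**Duplicate prevention.** Registration requires a prior search. Identities
are normalized (case folding, diacritic stripping, whitespace collapse,
ISO-8601 dates), then compared field by field: Jaro–Winkler similarity for
names, a rule-based comparison for dates (1.0 equal, 0.8 for a day/month
swap or a single differing component, else 0), equality for enums. The
weighted mean is classified against two thresholds — `block` ≥ 0.98 refuses
registration outright, `review` ≥ 0.85 requires an explicit, audited
override. Search supports `*`/`?` wildcards and runs over a date-of-birth
blocking index that is *provably* equivalent to a full scan under the
shipped weights (and falls back to a full scan whenever that guarantee
would not hold), so blocking is purely an optimization.

**Labels.** Each biosample label carries the biosample ID, subject ID,
visit and sample-type labels, and a DataMatrix, QR, or Code 128 symbol
whose content is exactly the biosample ID. Sheets are rendered as one
self-contained HTML file (inline SVG, no external references) for printing
from a browser on the device that holds the data.

## Worked example

```console
$ pseudoreg --registry demo init
initialized registry at demo (site BER)

$ pseudoreg --registry demo --actor nurse.lopez subject register \
    --field first_name=Maria --field last_name=García \
    --field date_of_birth=1985-06-11 --field sex=F
SUB-BER-DEUZYV-F
```

The printed value is the subject's pseudonym: the only token downstream
data ever carry. Re-entering the same person — even with different casing,
spacing, or missing diacritics — is refused:

```console
$ pseudoreg --registry demo subject register \
    --field "first_name=Maria " --field last_name=Garcia \
    --field date_of_birth=1985-06-11 --field sex=F
error: identity matches registered subject SUB-BER-DEUZYV-F (score 1.000); registration blocked
(exit code 1)
```

Biosamples are linked to the subject, one pseudonym per aliquot, checked
against the visit schedule:

```console
$ pseudoreg --registry demo --actor lab.chen sample register \
    --subject SUB-BER-DEUZYV-F --visit BL --type SER -n 2
BIO-BER-FNCFVZ-S  aliquot 1
BIO-BER-D3WVTY-P  aliquot 2

$ pseudoreg --registry demo search --field "last_name=GAR*"
SUB-BER-DEUZYV-F  score=1.000  exact_block

$ pseudoreg --registry demo --actor pi.wagner lookup BIO-BER-2SSLBD-2
[audit] depseudonymization of BIO-BER-2SSLBD-2 by pi.wagner was recorded
subject: SUB-BER-DEUZYV-F
visit: BL  type: SWB  aliquot: 1

$ pseudoreg --registry demo stats
subjects: 1
biosamples: 3
  visit BL: 3
  visit FU1: 0
  type SER: 2
  type PLA: 0
  type SWB: 1
  subjects through 2026-09: 1
```

Other commands: `pseudoreg export --backup` (deterministic CSV, resets the
backup reminder shown on every mutating command), `pseudoreg import --mode
register|restore` (bulk registration with row-level linkage, or verbatim
restore for migrations), `pseudoreg labels` (printable sheets), `pseudoreg
fixtures cohort` (synthetic identities with ground truth), and `pseudoreg
config init|validate`. A study is configured in one YAML file — pseudonym
formats, identity schema and linkage weights, visit schedule, sample
types, thresholds; see `examples/study.yaml`.

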