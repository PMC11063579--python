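# Quickstart

Every command supports `--help`; the global flags are `--registry DIR`
(default `registry`), `--actor NAME` (recorded in the audit log) and
`--read-only` (consistent snapshot, no write lock).

```console
# 1. create a study configuration and a registry
pseudoreg config init study.yaml          # edit to taste, then validate
pseudoreg config validate study.yaml
pseudoreg --registry reg init --config study.yaml

# 2. enrol a subject (the duplicate search runs automatically)
pseudoreg --registry reg --actor nurse.lopez subject register \
  --field first_name=Maria --field last_name=García \
  --field date_of_birth=1985-06-11 --field sex=F
# -> SUB-BER-......-X   (refused if the person is already registered;
#    add --override-review to accept a review-level match, audited)

# 3. search before/instead of registering (wildcards: * any run, ? one char)
pseudoreg --registry reg search --field "last_name=GAR*" --field date_of_birth=1985-06-11

# 4. register biosamples (one pseudonym per aliquot, schedule-checked)
pseudoreg --registry reg --actor lab.chen sample register \
  --subject SUB-BER-......-X --visit BL --type SER -n 2

# 5. print labels (self-contained HTML; datamatrix, qr or code128)
pseudoreg --registry reg labels --sample BIO-BER-......-X --copies 4 \
  --rows 4 --cols 3 -o sheet.html

# 6. look a pseudonym up again (always audited)
pseudoreg --registry reg --actor pi.wagner lookup BIO-BER-......-X

# 7. back up / migrate
pseudoreg --registry reg export backups/today --backup
pseudoreg --registry reg import --mode restore --what subjects backups/today/subjects.csv

# 8. statistics and parallel read access
pseudoreg --registry reg stats
pseudoreg --registry reg --read-only stats     # works while a writer is active
```

Exit codes: `0` success, `1` user or validation error (including refused
duplicates), `2` registry locked by another writer (the holder is named),
`3` corrupted registry state.

Mutating commands print a backup reminder until an export with `--backup`
is newer than the configured interval (default: daily).
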