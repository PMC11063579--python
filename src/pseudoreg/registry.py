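"""The registry: persistent subject/biosample store and workflow engine.

Separation of concerns is the privacy model: the registry stores
identifying attributes (IDAT), sample attributes (SDAT) and pseudonyms —
and structurally nothing else. Medical data never enter; downstream
systems hold them keyed by pseudonym only. Reidentification
(depseudonymization) is possible but always leaves an audit entry.

Workflow contracts enforced here:

* subject registration requires a *search proof* — evidence that the
  duplicate-preventing search ran against the current registry state for
  exactly this identity; blocked on certain matches, refusable on
  review-level matches unless explicitly overridden;
* biosample registration checks that the owning subject exists and that
  the (visit, sample type) combination is allowed by the study schedule;
* bulk import is all-or-nothing per *row*, never per file (except
  restore-mode pseudonym collisions, which abort the file with a diff);
* exports are deterministic (stable column and row order) and re-importable.

Storage is plain local files (line-delimited JSON records plus a YAML
config and a JSON meta file) guarded by a single-writer lock file; readers
take consistent snapshots without blocking the writer. No database server:
the tool must deploy onto a network share in minutes.
"""

from __future__ import annotations

import csv
import dataclasses
import datetime as _dt
import hashlib
import json
import os
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping

from . import config as _config
from . import linkage as _linkage
from . import pseudonyms as _pseudonyms
from .config import StudyConfig
from .errors import (
    CorruptRegistryError,
    DuplicateBlockedError,
    LockHeldError,
    MalformedFileError,
    MissingSearchError,
    NotFoundError,
    PseudonymCollisionError,
    QualityError,
    ScheduleViolationError,
    StaleLockError,
    StaleSearchError,
    TranscriptionSuspectedError,
    UnknownSubjectError,
)
from .linkage import MatchCandidate, NormalizedIdentity, RegistryIndex, SubjectIdentity

FORMAT_VERSION = 1


def utc_now_iso() -> str:
    return _dt.datetime.now(_dt.timezone.utc).isoformat(timespec="seconds")


# ---------------------------------------------------------------------------
# records


@dataclass(frozen=True)
class SubjectRecord:
    pseudonym: str
    identity: SubjectIdentity
    extra_properties: Mapping[str, str] = field(default_factory=dict)
    registered_at: str = ""
    registered_by: str = ""


@dataclass(frozen=True)
class BiosampleRecord:
    pseudonym: str
    subject_pseudonym: str
    visit_id: str
    sample_type: str
    aliquot_index: int
    attributes: Mapping[str, str] = field(default_factory=dict)
    registered_at: str = ""


@dataclass(frozen=True)
class AuditEntry:
    timestamp: str
    actor: str
    action: str
    target: str
    note: str = ""


@dataclass(frozen=True)
class SearchProof:
    """Evidence that the duplicate search ran for one identity at one state."""

    version: int
    fingerprint: str
    candidates: tuple[MatchCandidate, ...]
    mode: str


@dataclass(frozen=True)
class DepseudonymizationResult:
    kind: str  # "subject" | "biosample"
    record: SubjectRecord | BiosampleRecord
    owning_subject: SubjectRecord | None = None


@dataclass
class ImportReport:
    accepted: list[str] = field(default_factory=list)
    rejected: list[tuple[int, str]] = field(default_factory=list)
    duplicates_flagged: list[tuple[int, str, float]] = field(default_factory=list)

    @property
    def n_accepted(self) -> int:
        return len(self.accepted)


@dataclass(frozen=True)
class StatsReport:
    subjects_total: int
    biosamples_total: int
    per_visit: Mapping[str, int]
    per_sample_type: Mapping[str, int]
    monthly_cumulative_subjects: tuple[tuple[str, int], ...]
    monthly_cumulative_biosamples: tuple[tuple[str, int], ...]


class _IssuedView:
    """Constant-time membership over the subject and biosample pseudonym sets."""

    def __init__(self, *maps: Mapping[str, object]):
        self._maps = maps

    def __contains__(self, value: str) -> bool:
        return any(value in m for m in self._maps)


def identity_fingerprint(normalized: NormalizedIdentity) -> str:
    payload = json.dumps(sorted(normalized.values.items()), ensure_ascii=False)
    return hashlib.sha256(payload.encode("utf-8")).hexdigest()


# ---------------------------------------------------------------------------
# the registry


class Registry:
    """In-memory registry state (persistence lives in save/load/open functions)."""

    def __init__(
        self,
        config: StudyConfig,
        clock: Callable[[], str] | None = None,
        today: Callable[[], _dt.date] | None = None,
    ):
        self.config = config
        self.subjects: dict[str, SubjectRecord] = {}
        self.biosamples: dict[str, BiosampleRecord] = {}
        self.audit_log: list[AuditEntry] = []
        self.last_backup_at: str | None = None
        self.index = RegistryIndex(config.identity_schema)
        self._aliquot_counts: dict[tuple[str, str, str], int] = {}
        self._clock = clock or utc_now_iso
        self._today = today or _dt.date.today
        self._rng = random.Random(config.rng_seed)

    # -- helpers ------------------------------------------------------------

    def now(self) -> str:
        return self._clock()

    def _audit(self, actor: str, action: str, target: str, note: str = "") -> None:
        self.audit_log.append(
            AuditEntry(timestamp=self.now(), actor=actor, action=action, target=target, note=note)
        )

    def _fresh_pseudonym(self, scope: str) -> str:
        fmt = (
            self.config.subject_format if scope == "subject" else self.config.biosample_format
        )
        # membership view over both scopes without materializing a union set
        return _pseudonyms.generate_pseudonym(
            fmt, _IssuedView(self.subjects, self.biosamples), self._rng
        ).value

    # -- search -------------------------------------------------------------

    def search_subjects(
        self,
        query: SubjectIdentity | Mapping[str, str],
        mode: str = "combined",
    ) -> SearchProof:
        """Run the duplicate-preventing search; the proof is what registration wants."""
        candidates = _linkage.search(self.index, query, self.config, mode=mode)
        values = query.values if isinstance(query, SubjectIdentity) else query
        try:
            norm = _linkage.normalize_identity(
                SubjectIdentity(values=dict(values)), self.config.identity_schema
            )
            fp = identity_fingerprint(norm)
        except Exception:
            # partial / wildcarded query: fingerprint the raw query instead;
            # such a proof can never authorize a registration
            payload = json.dumps(sorted((k, str(v)) for k, v in dict(values).items()))
            fp = "query:" + hashlib.sha256(payload.encode()).hexdigest()
        return SearchProof(
            version=self.index.version,
            fingerprint=fp,
            candidates=tuple(candidates),
            mode=mode,
        )

    # -- registration -------------------------------------------------------

    def register_subject(
        self,
        identity: SubjectIdentity,
        search_proof: SearchProof | None,
        override_review: bool = False,
        actor: str = "unknown",
        extra_properties: Mapping[str, str] | None = None,
    ) -> SubjectRecord:
        """Register a subject and mint its pseudonym.

        Refused without a prior search for this exact identity against the
        current registry state; refused outright on an exact_block match;
        refused on review matches unless ``override_review`` (the override
        is audited).
        """
        issues = _linkage.quality_check(identity, self.config.identity_schema, self._today())
        errors = [i for i in issues if i.severity == "error"]
        if errors:
            raise QualityError(errors)
        norm = _linkage.normalize_identity(identity, self.config.identity_schema)
        if search_proof is None:
            raise MissingSearchError(
                "registration requires a prior search against the current registry"
            )
        if search_proof.fingerprint != identity_fingerprint(norm):
            raise MissingSearchError("the supplied search was not run for this identity")
        if search_proof.version != self.index.version:
            raise StaleSearchError(
                "the registry changed since the search; search again before registering"
            )
        blockers = [c for c in search_proof.candidates if c.classification == "exact_block"]
        if blockers:
            raise DuplicateBlockedError(
                f"identity matches registered subject {blockers[0].subject_pseudonym} "
                f"(score {blockers[0].score:.3f}); registration blocked",
                candidates=blockers,
            )
        reviews = [c for c in search_proof.candidates if c.classification == "review"]
        if reviews and not override_review:
            raise DuplicateBlockedError(
                "possible duplicate(s) need review: "
                + ", ".join(f"{c.subject_pseudonym} ({c.score:.3f})" for c in reviews[:5])
                + "; pass override_review=True to register anyway",
                candidates=reviews,
            )
        value = self._fresh_pseudonym("subject")
        record = SubjectRecord(
            pseudonym=value,
            identity=identity,
            extra_properties=dict(extra_properties or {}),
            registered_at=self.now(),
            registered_by=actor,
        )
        self.subjects[value] = record
        self.index.add(value, norm)
        note = ""
        if reviews and override_review:
            note = "review override: " + ", ".join(
                f"{c.subject_pseudonym}={c.score:.3f}" for c in reviews[:5]
            )
        self._audit(actor, "register_subject", value, note)
        return record

    def register_biosamples(
        self,
        subject_pseudonym: str,
        visit_id: str,
        sample_type: str,
        n_aliquots: int,
        attributes: Mapping[str, str] | None = None,
        actor: str = "unknown",
    ) -> list[BiosampleRecord]:
        """Mint one pseudonym per aliquot, linked to an existing subject."""
        if n_aliquots < 1:
            raise ValueError("n_aliquots must be >= 1")
        if subject_pseudonym not in self.subjects:
            raise UnknownSubjectError(
                f"no registered subject with pseudonym {subject_pseudonym!r}"
            )
        visit = self.config.visit_map().get(visit_id)
        if visit is None:
            raise ScheduleViolationError(
                f"unknown visit {visit_id!r}; schedule defines "
                f"{sorted(self.config.visit_map())}"
            )
        if sample_type not in visit.allowed_sample_types:
            raise ScheduleViolationError(
                f"sample type {sample_type!r} not allowed at visit {visit_id!r}; "
                f"allowed: {sorted(visit.allowed_sample_types)}"
            )
        key = (subject_pseudonym, visit_id, sample_type)
        offset = self._aliquot_counts.get(key, 0)
        self._aliquot_counts[key] = offset + n_aliquots
        out: list[BiosampleRecord] = []
        ts = self.now()
        for i in range(n_aliquots):
            value = self._fresh_pseudonym("biosample")
            rec = BiosampleRecord(
                pseudonym=value,
                subject_pseudonym=subject_pseudonym,
                visit_id=visit_id,
                sample_type=sample_type,
                aliquot_index=offset + i + 1,
                attributes=dict(attributes or {}),
                registered_at=ts,
            )
            self.biosamples[value] = rec
            self._audit(actor, "register_biosample", value, f"subject={subject_pseudonym}")
            out.append(rec)
        return out

    # -- lookup -------------------------------------------------------------

    def depseudonymize(self, pseudonym_value: str, actor: str) -> DepseudonymizationResult:
        """Authorized pseudonym-to-record lookup; every call is audited.

        A value that is not registered but fails its check character is
        reported as a suspected transcription error, not as plain not-found:
        the real record most likely exists under a near-identical ID.
        """
        value = pseudonym_value.strip()
        if value in self.subjects:
            self._audit(actor, "depseudonymize", value)
            return DepseudonymizationResult(kind="subject", record=self.subjects[value])
        if value in self.biosamples:
            rec = self.biosamples[value]
            self._audit(actor, "depseudonymize", value)
            return DepseudonymizationResult(
                kind="biosample", record=rec, owning_subject=self.subjects.get(rec.subject_pseudonym)
            )
        for fmt in (self.config.subject_format, self.config.biosample_format):
            result = _pseudonyms.validate_pseudonym(value, fmt)
            if not result.structural_defects and result.check_mismatch:
                raise TranscriptionSuspectedError(
                    f"{value!r} is structurally a {fmt.scope} pseudonym but its check "
                    "character does not verify — re-read the label, a character was "
                    "probably mistyped or mis-scanned"
                )
        raise NotFoundError(f"no record with pseudonym {value!r}")

    # -- reporting ----------------------------------------------------------

    def backup_due(self, now: str | None = None) -> tuple[bool, str]:
        now_dt = _dt.datetime.fromisoformat(now or self.now())
        if self.last_backup_at is None:
            return True, "no backup recorded yet — export a backup (pseudoreg export --backup)"
        last = _dt.datetime.fromisoformat(self.last_backup_at)
        age_days = (now_dt - last).total_seconds() / 86400.0
        if age_days >= self.config.backup_interval_days:
            return True, (
                f"last backup {self.last_backup_at} is {age_days:.1f} days old "
                f"(interval: {self.config.backup_interval_days} d) — export a backup"
            )
        return False, f"last backup {self.last_backup_at}"

    def statistics(self) -> StatsReport:
        """Counts recomputed by full scan — always consistent with the records."""
        per_visit: dict[str, int] = {v.visit_id: 0 for v in self.config.schedule}
        per_type: dict[str, int] = {s.code: 0 for s in self.config.sample_types}
        for b in self.biosamples.values():
            per_visit[b.visit_id] = per_visit.get(b.visit_id, 0) + 1
            per_type[b.sample_type] = per_type.get(b.sample_type, 0) + 1

        def monthly(records: Iterable[str]) -> tuple[tuple[str, int], ...]:
            counts: dict[str, int] = {}
            for ts in records:
                month = ts[:7]  # YYYY-MM of the ISO timestamp
                counts[month] = counts.get(month, 0) + 1
            out = []
            cum = 0
            for month in sorted(counts):
                cum += counts[month]
                out.append((month, cum))
            return tuple(out)

        return StatsReport(
            subjects_total=len(self.subjects),
            biosamples_total=len(self.biosamples),
            per_visit=per_visit,
            per_sample_type=per_type,
            monthly_cumulative_subjects=monthly(
                r.registered_at for r in self.subjects.values()
            ),
            monthly_cumulative_biosamples=monthly(
                r.registered_at for r in self.biosamples.values()
            ),
        )

    # -- canonical form -----------------------------------------------------

    def canonical_form(self) -> dict:
        """Order-independent plain-data snapshot used for equality round-trips.

        Excludes the audit log and backup timestamp: two registries are "the
        same study data" when config and records agree, regardless of who
        looked at what when.
        """
        return {
            "config": _config.to_dict(self.config),
            "subjects": [
                {
                    "pseudonym": r.pseudonym,
                    "identity": dict(r.identity.values),
                    "extra_properties": dict(r.extra_properties),
                    "registered_at": r.registered_at,
                    "registered_by": r.registered_by,
                }
                for r in sorted(self.subjects.values(), key=lambda r: r.pseudonym)
            ],
            "biosamples": [
                {
                    "pseudonym": r.pseudonym,
                    "subject_pseudonym": r.subject_pseudonym,
                    "visit_id": r.visit_id,
                    "sample_type": r.sample_type,
                    "aliquot_index": r.aliquot_index,
                    "attributes": dict(r.attributes),
                    "registered_at": r.registered_at,
                }
                for r in sorted(self.biosamples.values(), key=lambda r: r.pseudonym)
            ],
        }

    def check_integrity(self) -> None:
        """Referential integrity + scope disjointness; raises CorruptRegistryError."""
        overlap = set(self.subjects) & set(self.biosamples)
        if overlap:
            raise CorruptRegistryError(f"pseudonyms in both scopes: {sorted(overlap)[:5]}")
        for b in self.biosamples.values():
            if b.subject_pseudonym not in self.subjects:
                raise CorruptRegistryError(
                    f"biosample {b.pseudonym} references missing subject {b.subject_pseudonym}"
                )

    def _restore_subject(self, record: SubjectRecord) -> None:
        norm = _linkage.normalize_identity(record.identity, self.config.identity_schema)
        self.subjects[record.pseudonym] = record
        self.index.add(record.pseudonym, norm)

    def _restore_biosample(self, record: BiosampleRecord) -> None:
        self.biosamples[record.pseudonym] = record
        key = (record.subject_pseudonym, record.visit_id, record.sample_type)
        self._aliquot_counts[key] = max(
            self._aliquot_counts.get(key, 0), record.aliquot_index
        )


# ---------------------------------------------------------------------------
# bulk import / export (delimited files, RFC 4180, UTF-8, header row)


def _subject_columns(cfg: StudyConfig) -> list[str]:
    return (
        ["pseudonym"]
        + [f.name for f in cfg.identity_schema.fields]
        + ["extra_properties", "registered_at", "registered_by"]
    )


BIOSAMPLE_COLUMNS = [
    "pseudonym",
    "subject_pseudonym",
    "visit_id",
    "sample_type",
    "aliquot_index",
    "attributes",
    "registered_at",
]


def _read_rows(source: str | Path | Iterable[dict]) -> list[dict]:
    if isinstance(source, (str, Path)):
        p = Path(source)
        if not p.exists():
            raise MalformedFileError(f"no such file: {p}")
        try:
            with p.open("r", encoding="utf-8", newline="") as fh:
                reader = csv.DictReader(fh)
                if reader.fieldnames is None:
                    raise MalformedFileError(f"{p}: empty file, expected a header row")
                return [dict(row) for row in reader]
        except csv.Error as exc:
            raise MalformedFileError(f"{p}: CSV parse error: {exc}") from exc
    return [dict(r) for r in source]


def _parse_json_cell(raw: str | None, what: str, row_no: int) -> dict:
    if not raw:
        return {}
    try:
        d = json.loads(raw)
    except json.JSONDecodeError as exc:
        raise MalformedFileError(f"row {row_no}: bad JSON in {what}: {exc}") from exc
    if not isinstance(d, dict):
        raise MalformedFileError(f"row {row_no}: {what} must be a JSON object")
    return d


def bulk_import_subjects(
    registry: Registry,
    source: str | Path | Iterable[dict],
    mode: str = "register_new",
    actor: str = "import",
) -> ImportReport:
    """Bulk subject import for retrospective pseudonymization and migration.

    ``register_new``: each row runs the full quality + linkage pipeline
    against the registry *and* the rows already accepted from this file;
    duplicates are rejected row-by-row and listed in the report.

    ``restore_with_pseudonyms``: pseudonyms are preserved verbatim (update
    migration / backup restore); any pseudonym collision — within the file
    or with the registry — aborts the whole file with a diff report.
    """
    if mode not in ("register_new", "restore_with_pseudonyms"):
        raise ValueError(f"unknown import mode {mode!r}")
    rows = _read_rows(source)
    schema = registry.config.identity_schema
    field_names = [f.name for f in schema.fields]
    report = ImportReport()

    if mode == "restore_with_pseudonyms":
        fmt = registry.config.subject_format
        seen: dict[str, int] = {}
        collisions: list[tuple[int, str, str]] = []
        for i, row in enumerate(rows, start=2):  # header is line 1
            psn = (row.get("pseudonym") or "").strip()
            if psn in seen:
                collisions.append((i, psn, f"also in file at row {seen[psn]}"))
            elif psn in registry.subjects or psn in registry.biosamples:
                collisions.append((i, psn, "already registered"))
            else:
                seen[psn] = i
        if collisions:
            raise PseudonymCollisionError(
                "restore aborted, pseudonym collisions:\n"
                + "\n".join(f"  row {r}: {p} ({why})" for r, p, why in collisions),
                collisions=collisions,
            )
        for i, row in enumerate(rows, start=2):
            psn = (row.get("pseudonym") or "").strip()
            result = _pseudonyms.validate_pseudonym(psn, fmt)
            if not result.ok:
                report.rejected.append((i, f"invalid pseudonym {psn!r}: {'; '.join(result.defects)}"))
                continue
            identity = SubjectIdentity(
                values={n: (row.get(n) or "").strip() for n in field_names if (row.get(n) or "").strip()}
            )
            try:
                extra = _parse_json_cell(row.get("extra_properties"), "extra_properties", i)
                record = SubjectRecord(
                    pseudonym=psn,
                    identity=identity,
                    extra_properties=extra,
                    registered_at=(row.get("registered_at") or registry.now()),
                    registered_by=(row.get("registered_by") or actor),
                )
                registry._restore_subject(record)
            except Exception as exc:
                report.rejected.append((i, str(exc)))
                continue
            registry._audit(actor, "restore_subject", psn)
            report.accepted.append(psn)
        return report

    for i, row in enumerate(rows, start=2):
        identity = SubjectIdentity(
            values={n: (row.get(n) or "").strip() for n in field_names if (row.get(n) or "").strip()}
        )
        try:
            extra = _parse_json_cell(row.get("extra_properties"), "extra_properties", i)
            proof = registry.search_subjects(identity, mode="fuzzy")
            record = registry.register_subject(
                identity,
                proof,
                override_review=False,
                actor=actor,
                extra_properties=extra,
            )
        except DuplicateBlockedError as exc:
            best = exc.candidates[0] if exc.candidates else None
            report.rejected.append((i, f"duplicate: {exc}"))
            if best is not None:
                report.duplicates_flagged.append((i, best.subject_pseudonym, best.score))
            continue
        except Exception as exc:
            report.rejected.append((i, str(exc)))
            continue
        report.accepted.append(record.pseudonym)
    return report


def bulk_import_biosamples(
    registry: Registry,
    source: str | Path | Iterable[dict],
    mode: str = "register_new",
    actor: str = "import",
) -> ImportReport:
    """Bulk biosample import; register_new mints fresh pseudonyms per row,
    restore preserves them (collisions abort the file, mirroring subjects)."""
    if mode not in ("register_new", "restore_with_pseudonyms"):
        raise ValueError(f"unknown import mode {mode!r}")
    rows = _read_rows(source)
    report = ImportReport()

    if mode == "restore_with_pseudonyms":
        fmt = registry.config.biosample_format
        seen: dict[str, int] = {}
        collisions: list[tuple[int, str, str]] = []
        for i, row in enumerate(rows, start=2):
            psn = (row.get("pseudonym") or "").strip()
            if psn in seen:
                collisions.append((i, psn, f"also in file at row {seen[psn]}"))
            elif psn in registry.subjects or psn in registry.biosamples:
                collisions.append((i, psn, "already registered"))
            else:
                seen[psn] = i
        if collisions:
            raise PseudonymCollisionError(
                "restore aborted, pseudonym collisions:\n"
                + "\n".join(f"  row {r}: {p} ({why})" for r, p, why in collisions),
                collisions=collisions,
            )
        for i, row in enumerate(rows, start=2):
            psn = (row.get("pseudonym") or "").strip()
            result = _pseudonyms.validate_pseudonym(psn, fmt)
            if not result.ok:
                report.rejected.append((i, f"invalid pseudonym {psn!r}: {'; '.join(result.defects)}"))
                continue
            subject = (row.get("subject_pseudonym") or "").strip()
            if subject not in registry.subjects:
                report.rejected.append((i, f"unknown subject {subject!r}"))
                continue
            visit = (row.get("visit_id") or "").strip()
            stype = (row.get("sample_type") or "").strip()
            vdef = registry.config.visit_map().get(visit)
            if vdef is None or stype not in vdef.allowed_sample_types:
                report.rejected.append((i, f"(visit={visit!r}, sample_type={stype!r}) not in schedule"))
                continue
            try:
                attrs = _parse_json_cell(row.get("attributes"), "attributes", i)
                rec = BiosampleRecord(
                    pseudonym=psn,
                    subject_pseudonym=subject,
                    visit_id=visit,
                    sample_type=stype,
                    aliquot_index=int(row.get("aliquot_index") or 1),
                    attributes=attrs,
                    registered_at=(row.get("registered_at") or registry.now()),
                )
            except (ValueError, MalformedFileError) as exc:
                report.rejected.append((i, str(exc)))
                continue
            registry._restore_biosample(rec)
            registry._audit(actor, "restore_biosample", psn)
            report.accepted.append(psn)
        return report

    for i, row in enumerate(rows, start=2):
        try:
            attrs = _parse_json_cell(row.get("attributes"), "attributes", i)
            recs = registry.register_biosamples(
                subject_pseudonym=(row.get("subject_pseudonym") or "").strip(),
                visit_id=(row.get("visit_id") or "").strip(),
                sample_type=(row.get("sample_type") or "").strip(),
                n_aliquots=int(row.get("n_aliquots") or 1),
                attributes=attrs,
                actor=actor,
            )
        except Exception as exc:
            report.rejected.append((i, str(exc)))
            continue
        report.accepted.extend(r.pseudonym for r in recs)
    return report


def export_registry(
    registry: Registry,
    out_dir: str | Path,
    scope: str = "all",
    backup: bool = False,
    actor: str = "export",
) -> dict[str, Path]:
    """Write deterministic, re-importable CSV files (rows sorted by pseudonym).

    With ``backup=True`` the export counts as the registry's backup and
    resets the reminder clock.
    """
    if scope not in ("subjects", "biosamples", "all"):
        raise ValueError(f"unknown export scope {scope!r}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    if scope in ("subjects", "all"):
        p = out / "subjects.csv"
        cols = _subject_columns(registry.config)
        with p.open("w", encoding="utf-8", newline="") as fh:
            w = csv.DictWriter(fh, fieldnames=cols)
            w.writeheader()
            for r in sorted(registry.subjects.values(), key=lambda r: r.pseudonym):
                row = {"pseudonym": r.pseudonym}
                for f in registry.config.identity_schema.fields:
                    row[f.name] = r.identity.get(f.name, "")
                row["extra_properties"] = (
                    json.dumps(dict(r.extra_properties), sort_keys=True, ensure_ascii=False)
                    if r.extra_properties
                    else ""
                )
                row["registered_at"] = r.registered_at
                row["registered_by"] = r.registered_by
                w.writerow(row)
        paths["subjects"] = p
    if scope in ("biosamples", "all"):
        p = out / "biosamples.csv"
        with p.open("w", encoding="utf-8", newline="") as fh:
            w = csv.DictWriter(fh, fieldnames=BIOSAMPLE_COLUMNS)
            w.writeheader()
            for r in sorted(registry.biosamples.values(), key=lambda r: r.pseudonym):
                w.writerow(
                    {
                        "pseudonym": r.pseudonym,
                        "subject_pseudonym": r.subject_pseudonym,
                        "visit_id": r.visit_id,
                        "sample_type": r.sample_type,
                        "aliquot_index": r.aliquot_index,
                        "attributes": (
                            json.dumps(dict(r.attributes), sort_keys=True, ensure_ascii=False)
                            if r.attributes
                            else ""
                        ),
                        "registered_at": r.registered_at,
                    }
                )
        paths["biosamples"] = p
    if backup:
        registry.last_backup_at = registry.now()
        registry._audit(actor, "backup", str(out))
    else:
        registry._audit(actor, "export", str(out))
    return paths


# ---------------------------------------------------------------------------
# persistence + locking


def save_registry(registry: Registry, path: str | Path) -> None:
    """Compacted snapshot: line-delimited JSON records, meta written last."""
    registry.check_integrity()
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)

    def write_atomic(name: str, text: str) -> None:
        tmp = p / (name + ".tmp")
        tmp.write_text(text, encoding="utf-8")
        os.replace(tmp, p / name)

    write_atomic("config.yaml", _config.dumps_config(registry.config))
    write_atomic(
        "subjects.jsonl",
        "".join(
            json.dumps(
                {
                    "pseudonym": r.pseudonym,
                    "identity": dict(r.identity.values),
                    "extra_properties": dict(r.extra_properties),
                    "registered_at": r.registered_at,
                    "registered_by": r.registered_by,
                },
                ensure_ascii=False,
                sort_keys=True,
            )
            + "\n"
            for r in sorted(registry.subjects.values(), key=lambda r: r.pseudonym)
        ),
    )
    write_atomic(
        "biosamples.jsonl",
        "".join(
            json.dumps(
                {
                    "pseudonym": r.pseudonym,
                    "subject_pseudonym": r.subject_pseudonym,
                    "visit_id": r.visit_id,
                    "sample_type": r.sample_type,
                    "aliquot_index": r.aliquot_index,
                    "attributes": dict(r.attributes),
                    "registered_at": r.registered_at,
                },
                ensure_ascii=False,
                sort_keys=True,
            )
            + "\n"
            for r in sorted(registry.biosamples.values(), key=lambda r: r.pseudonym)
        ),
    )
    write_atomic(
        "audit.jsonl",
        "".join(json.dumps(dataclasses.asdict(e), ensure_ascii=False) + "\n" for e in registry.audit_log),
    )
    write_atomic(
        "meta.json",
        json.dumps(
            {
                "format_version": FORMAT_VERSION,
                "saved_at": registry.now(),
                "last_backup_at": registry.last_backup_at,
                "subject_count": len(registry.subjects),
                "biosample_count": len(registry.biosamples),
            },
            indent=2,
        ),
    )


def load_registry(
    path: str | Path,
    clock: Callable[[], str] | None = None,
    today: Callable[[], _dt.date] | None = None,
) -> Registry:
    p = Path(path)
    if not (p / "meta.json").exists():
        raise CorruptRegistryError(f"{p} is not a registry directory (no meta.json)")
    try:
        meta = json.loads((p / "meta.json").read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise CorruptRegistryError(f"meta.json unreadable: {exc}") from exc
    if meta.get("format_version") != FORMAT_VERSION:
        raise CorruptRegistryError(
            f"unsupported registry format version {meta.get('format_version')!r}"
        )
    cfg = _config.load_config(p / "config.yaml")
    reg = Registry(cfg, clock=clock, today=today)
    reg.last_backup_at = meta.get("last_backup_at")

    def read_jsonl(name: str) -> list[dict]:
        f = p / name
        if not f.exists():
            raise CorruptRegistryError(f"missing {name}")
        out = []
        for lineno, line in enumerate(f.read_text(encoding="utf-8").splitlines(), start=1):
            if not line.strip():
                continue
            try:
                out.append(json.loads(line))
            except json.JSONDecodeError as exc:
                raise CorruptRegistryError(f"{name}:{lineno}: bad record: {exc}") from exc
        return out

    subjects = read_jsonl("subjects.jsonl")
    biosamples = read_jsonl("biosamples.jsonl")
    if len(subjects) != meta.get("subject_count") or len(biosamples) != meta.get(
        "biosample_count"
    ):
        raise CorruptRegistryError(
            "record counts disagree with meta.json (torn or partial snapshot?)"
        )
    for d in subjects:
        reg._restore_subject(
            SubjectRecord(
                pseudonym=d["pseudonym"],
                identity=SubjectIdentity(values=d["identity"]),
                extra_properties=d.get("extra_properties", {}),
                registered_at=d.get("registered_at", ""),
                registered_by=d.get("registered_by", ""),
            )
        )
    for d in biosamples:
        reg._restore_biosample(BiosampleRecord(
            pseudonym=d["pseudonym"],
            subject_pseudonym=d["subject_pseudonym"],
            visit_id=d["visit_id"],
            sample_type=d["sample_type"],
            aliquot_index=int(d["aliquot_index"]),
            attributes=d.get("attributes", {}),
            registered_at=d.get("registered_at", ""),
        ))
    for e in read_jsonl("audit.jsonl"):
        reg.audit_log.append(AuditEntry(**e))
    reg.check_integrity()
    return reg


LOCK_FILE = "registry.lock"


def _read_lock(p: Path) -> dict:
    try:
        return json.loads(p.read_text(encoding="utf-8"))
    except (OSError, json.JSONDecodeError):
        return {"holder": "unknown", "acquired_at": "unknown"}


class RegistryHandle:
    """Write handle (exclusive lock, saves on close) or read-only snapshot."""

    def __init__(self, registry: Registry, path: Path, mode: str, lock_path: Path | None):
        self.registry = registry
        self.path = path
        self.mode = mode
        self._lock_path = lock_path
        self._closed = False

    def save(self) -> None:
        if self.mode != "write":
            raise PermissionError("read-only handle cannot save")
        save_registry(self.registry, self.path)

    def close(self) -> None:
        if self._closed:
            return
        if self.mode == "write":
            self.save()
            if self._lock_path is not None and self._lock_path.exists():
                self._lock_path.unlink()
        self._closed = True

    def __enter__(self) -> "RegistryHandle":
        return self

    def __exit__(self, exc_type, exc, tb) -> None:
        if exc_type is None:
            self.close()
        elif self.mode == "write" and self._lock_path is not None and self._lock_path.exists():
            # release the lock but do not persist a half-applied operation
            self._lock_path.unlink()
            self._closed = True


def open_registry(
    path: str | Path,
    mode: str = "write",
    config: StudyConfig | None = None,
    actor: str = "unknown",
    takeover: bool = False,
    clock: Callable[[], str] | None = None,
    today: Callable[[], _dt.date] | None = None,
) -> RegistryHandle:
    """Open (or initialize) a registry directory.

    ``write`` acquires the exclusive lock file (holder + timestamp); a
    second writer fails with the holder's name. A lock older than the
    configured stale timeout is *reported*, never silently broken —
    takeover requires the explicit flag. ``read_only`` loads a consistent
    snapshot of the durable state without touching the lock, so readers
    never block the writer.
    """
    if mode not in ("write", "read_only"):
        raise ValueError(f"unknown open mode {mode!r}")
    p = Path(path)
    initialized = (p / "meta.json").exists()

    if mode == "read_only":
        if not initialized:
            raise CorruptRegistryError(f"{p} is not an initialized registry")
        return RegistryHandle(load_registry(p, clock=clock, today=today), p, "read_only", None)

    if not initialized and config is None:
        raise CorruptRegistryError(
            f"{p} is not an initialized registry; pass a StudyConfig to create one"
        )
    p.mkdir(parents=True, exist_ok=True)
    lock_path = p / LOCK_FILE
    now = (clock or utc_now_iso)()
    stale_hours = (
        config.lock_stale_hours
        if config is not None
        else _config.load_config(p / "config.yaml").lock_stale_hours
        if (p / "config.yaml").exists()
        else 12.0
    )
    while True:
        try:
            fd = os.open(lock_path, os.O_CREAT | os.O_EXCL | os.O_WRONLY)
        except FileExistsError:
            info = _read_lock(lock_path)
            holder = info.get("holder", "unknown")
            acquired = info.get("acquired_at", "unknown")
            try:
                age_h = (
                    _dt.datetime.fromisoformat(now) - _dt.datetime.fromisoformat(acquired)
                ).total_seconds() / 3600.0
            except ValueError:
                age_h = float("inf")
            if age_h < stale_hours:
                raise LockHeldError(holder, acquired)
            if not takeover:
                raise StaleLockError(holder, acquired)
            lock_path.unlink(missing_ok=True)
            continue
        break
    with os.fdopen(fd, "w", encoding="utf-8") as fh:
        json.dump({"holder": actor, "acquired_at": now, "pid": os.getpid()}, fh)
    if initialized:
        reg = load_registry(p, clock=clock, today=today)
    else:
        reg = Registry(config, clock=clock, today=today)
        save_registry(reg, p)
    return RegistryHandle(reg, p, "write", lock_path)
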