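"""Registry workflows: registration contracts, lookup, bulk I/O, locking, stats."""

import dataclasses
import datetime as dt
import random

import pytest

from pseudoreg import Registry, SubjectIdentity, default_config
from pseudoreg.errors import (
    CorruptRegistryError,
    DuplicateBlockedError,
    LockHeldError,
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
from pseudoreg.registry import (
    bulk_import_biosamples,
    bulk_import_subjects,
    export_registry,
    load_registry,
    open_registry,
    save_registry,
)

IDENT2 = SubjectIdentity(
    values={
        "first_name": "Omar", "last_name": "Haddad",
        "date_of_birth": "1975-11-20", "sex": "M",
    }
)


# -- subject registration ---------------------------------------------------


def test_registration_requires_a_search(registry, identity):
    with pytest.raises(MissingSearchError):
        registry.register_subject(identity, None, actor="nurse")


def test_search_must_be_for_the_same_identity(registry, identity):
    proof = registry.search_subjects(IDENT2, mode="fuzzy")
    with pytest.raises(MissingSearchError):
        registry.register_subject(identity, proof, actor="nurse")


def test_stale_search_is_rejected(registry, identity):
    proof_early = registry.search_subjects(IDENT2, mode="fuzzy")
    registry.register_subject(IDENT2, proof_early, actor="nurse")
    proof = registry.search_subjects(identity, mode="fuzzy")
    # another registration changes the registry state
    other = SubjectIdentity(
        values={"first_name": "Eva", "last_name": "Novak",
                "date_of_birth": "1990-05-06", "sex": "F"}
    )
    registry.register_subject(
        other, registry.search_subjects(other, mode="fuzzy"), actor="nurse"
    )
    with pytest.raises(StaleSearchError):
        registry.register_subject(identity, proof, actor="nurse")


def test_identical_identity_is_always_blocked(registered, identity):
    registry, record = registered
    proof = registry.search_subjects(identity, mode="fuzzy")
    with pytest.raises(DuplicateBlockedError) as exc:
        registry.register_subject(identity, proof, actor="nurse")
    assert record.pseudonym in str(exc.value)


def test_review_match_needs_explicit_override_and_is_audited(registered):
    registry, record = registered
    near = SubjectIdentity(
        values={"first_name": "Maria", "last_name": "Rosso",  # 1 edit
                "date_of_birth": "1980-03-04", "sex": "F"}
    )
    proof = registry.search_subjects(near, mode="fuzzy")
    assert any(c.classification == "review" for c in proof.candidates)
    with pytest.raises(DuplicateBlockedError):
        registry.register_subject(near, proof, actor="nurse")
    rec = registry.register_subject(near, proof, override_review=True, actor="nurse")
    entry = registry.audit_log[-1]
    assert entry.action == "register_subject" and "override" in entry.note
    assert rec.pseudonym != record.pseudonym


def test_quality_errors_block_registration(registry):
    bad = SubjectIdentity(
        values={"first_name": "Ann", "last_name": "Lee",
                "date_of_birth": "2090-01-01", "sex": "F"}
    )
    with pytest.raises(QualityError):
        registry.register_subject(
            bad, registry.search_subjects(IDENT2, mode="fuzzy"), actor="nurse"
        )


# -- biosamples -------------------------------------------------------------


def test_aliquots_get_distinct_pseudonyms_and_running_indices(registered):
    registry, record = registered
    first = registry.register_biosamples(record.pseudonym, "BL", "SER", 3, actor="lab")
    assert [b.aliquot_index for b in first] == [1, 2, 3]
    assert len({b.pseudonym for b in first}) == 3
    assert all(b.subject_pseudonym == record.pseudonym for b in first)
    more = registry.register_biosamples(record.pseudonym, "BL", "SER", 2, actor="lab")
    assert [b.aliquot_index for b in more] == [4, 5]


def test_unknown_subject_and_schedule_violations(registered):
    registry, record = registered
    with pytest.raises(UnknownSubjectError):
        registry.register_biosamples("SUB-BER-QQQQQQ-0", "BL", "SER", 1, actor="lab")
    with pytest.raises(ScheduleViolationError):
        registry.register_biosamples(record.pseudonym, "V99", "SER", 1, actor="lab")
    with pytest.raises(ScheduleViolationError) as exc:
        registry.register_biosamples(record.pseudonym, "FU1", "PLA", 1, actor="lab")
    assert "SER" in str(exc.value)  # allowed types are listed


# -- depseudonymization -----------------------------------------------------


def test_depseudonymization_returns_record_and_is_always_audited(registered):
    registry, record = registered
    n0 = len(registry.audit_log)
    res = registry.depseudonymize(record.pseudonym, actor="pi")
    assert res.kind == "subject" and res.record is record
    sample = registry.register_biosamples(record.pseudonym, "BL", "SWB", 1, actor="lab")[0]
    res2 = registry.depseudonymize(sample.pseudonym, actor="pi")
    assert res2.kind == "biosample"
    assert res2.owning_subject.pseudonym == record.pseudonym
    lookups = [e for e in registry.audit_log[n0:] if e.action == "depseudonymize"]
    assert len(lookups) == 2 and all(e.actor == "pi" for e in lookups)


def test_transcription_error_is_distinguished_from_not_found(registered):
    registry, record = registered
    body = record.pseudonym.split("-")[2]
    altered = record.pseudonym.replace(body, ("3" if body[0] != "3" else "4") + body[1:], 1)
    with pytest.raises(TranscriptionSuspectedError):
        registry.depseudonymize(altered, actor="pi")
    with pytest.raises(NotFoundError):
        registry.depseudonymize("not-a-pseudonym", actor="pi")


# -- bulk import / export ---------------------------------------------------


def _rows(n, seed=0):
    rng = random.Random(seed)
    rows = []
    for i in range(n):
        rows.append(
            {
                "first_name": f"Name{i}",
                "last_name": f"Surname{rng.randrange(10**6)}",
                "date_of_birth": f"{rng.randint(1940, 2000)}-{rng.randint(1,12):02d}-{rng.randint(1,28):02d}",
                "sex": rng.choice(["F", "M"]),
            }
        )
    return rows


def test_duplicate_rows_within_one_file_are_rejected(registry):
    row = _rows(1)[0]
    report = bulk_import_subjects(registry, [row, dict(row)], mode="register_new")
    assert report.n_accepted == 1
    assert len(report.rejected) == 1
    assert report.rejected[0][0] == 3  # second data row (header is line 1)
    assert report.duplicates_flagged and report.duplicates_flagged[0][2] == 1.0


def test_export_restore_export_is_identity(registered, tmp_path):
    registry, record = registered
    registry.register_biosamples(record.pseudonym, "BL", "SER", 2, actor="lab")
    bulk_import_subjects(registry, _rows(20, seed=4), mode="register_new")
    paths = export_registry(registry, tmp_path / "exp1", scope="all")

    fresh = Registry(registry.config)
    rep_s = bulk_import_subjects(
        fresh, paths["subjects"], mode="restore_with_pseudonyms"
    )
    rep_b = bulk_import_biosamples(
        fresh, paths["biosamples"], mode="restore_with_pseudonyms"
    )
    assert not rep_s.rejected and not rep_b.rejected
    assert fresh.canonical_form() == registry.canonical_form()

    paths2 = export_registry(fresh, tmp_path / "exp2", scope="all")
    for key in paths:
        assert paths[key].read_text() == paths2[key].read_text()


def test_restore_collision_aborts_the_whole_file(registered):
    registry, record = registered
    row = {
        "pseudonym": record.pseudonym,
        "first_name": "Else", "last_name": "Other",
        "date_of_birth": "1960-01-01", "sex": "F",
    }
    with pytest.raises(PseudonymCollisionError):
        bulk_import_subjects(registry, [row], mode="restore_with_pseudonyms")
    assert len(registry.subjects) == 1  # nothing applied


def test_empty_registry_exports_header_only_files(registry, tmp_path):
    paths = export_registry(registry, tmp_path, scope="all")
    for p in paths.values():
        lines = p.read_text().strip().splitlines()
        assert len(lines) == 1 and "," in lines[0]


def test_exported_columns_are_documented_and_stable(registered, tmp_path):
    registry, _ = registered
    paths = export_registry(registry, tmp_path, scope="all")
    header = paths["subjects"].read_text().splitlines()[0]
    assert header == "pseudonym,first_name,last_name,date_of_birth,sex,extra_properties,registered_at,registered_by"
    header_b = paths["biosamples"].read_text().splitlines()[0]
    assert header_b == "pseudonym,subject_pseudonym,visit_id,sample_type,aliquot_index,attributes,registered_at"


# -- backup & statistics ----------------------------------------------------


def test_backup_due_rules(registry, tmp_path):
    due, _ = registry.backup_due()
    assert due  # never backed up
    export_registry(registry, tmp_path, backup=True)
    due, _ = registry.backup_due()
    assert not due  # 1 hour < 1 day handled by fresh timestamp
    registry.last_backup_at = (
        dt.datetime.now(dt.timezone.utc) - dt.timedelta(days=2)
    ).isoformat(timespec="seconds")
    due, msg = registry.backup_due()
    assert due and "2.0 days" in msg


def test_statistics_consistent_with_records(registered):
    registry, record = registered
    proof = registry.search_subjects(IDENT2, mode="fuzzy")
    registry.register_subject(IDENT2, proof, actor="nurse")
    registry.register_biosamples(record.pseudonym, "BL", "SER", 3, actor="lab")
    s = registry.statistics()
    assert s.subjects_total == 2
    assert s.biosamples_total == 3
    assert s.per_visit["BL"] == 3 and s.per_visit["FU1"] == 0
    assert s.per_sample_type["SER"] == 3
    cum = [c for _, c in s.monthly_cumulative_subjects]
    assert cum == sorted(cum) and cum[-1] == 2


def test_empty_registry_statistics_are_all_zero(registry):
    s = registry.statistics()
    assert s.subjects_total == 0 and s.biosamples_total == 0
    assert set(s.per_visit.values()) == {0}
    assert s.monthly_cumulative_subjects == ()


# -- persistence & locking --------------------------------------------------


def test_save_load_is_identity(registered, tmp_path):
    registry, record = registered
    registry.register_biosamples(record.pseudonym, "BL", "PLA", 2, actor="lab")
    save_registry(registry, tmp_path / "reg")
    loaded = load_registry(tmp_path / "reg")
    assert loaded.canonical_form() == registry.canonical_form()
    assert [e.action for e in loaded.audit_log] == [e.action for e in registry.audit_log]


def test_torn_snapshot_is_detected(registered, tmp_path):
    registry, _ = registered
    save_registry(registry, tmp_path / "reg")
    (tmp_path / "reg" / "subjects.jsonl").write_text("", encoding="utf-8")
    with pytest.raises(CorruptRegistryError):
        load_registry(tmp_path / "reg")


def test_single_writer_lock_and_read_snapshot(tmp_path, cfg, identity):
    h = open_registry(tmp_path / "reg", mode="write", config=cfg, actor="alice")
    reg = h.registry
    rec = reg.register_subject(
        identity, reg.search_subjects(identity, mode="fuzzy"), actor="alice"
    )
    h.save()
    with pytest.raises(LockHeldError) as exc:
        open_registry(tmp_path / "reg", mode="write", actor="bob")
    assert exc.value.holder == "alice"
    snap = open_registry(tmp_path / "reg", mode="read_only")
    assert snap.registry.canonical_form() == reg.canonical_form()
    with pytest.raises(PermissionError):
        snap.save()
    h.close()
    h2 = open_registry(tmp_path / "reg", mode="write", actor="bob")
    assert rec.pseudonym in h2.registry.subjects
    h2.close()


def test_stale_lock_requires_explicit_takeover(tmp_path, cfg):
    old = (dt.datetime.now(dt.timezone.utc) - dt.timedelta(hours=48)).isoformat(
        timespec="seconds"
    )
    h = open_registry(tmp_path / "reg", mode="write", config=cfg, actor="alice")
    h.save()
    lock = tmp_path / "reg" / "registry.lock"
    lock.write_text(f'{{"holder": "alice", "acquired_at": "{old}"}}', encoding="utf-8")
    with pytest.raises(StaleLockError):
        open_registry(tmp_path / "reg", mode="write", actor="bob")
    h2 = open_registry(tmp_path / "reg", mode="write", actor="bob", takeover=True)
    h2.close()


# -- invariants over random operation sequences -----------------------------


def test_referential_integrity_after_random_operation_sequences(cfg):
    rng = random.Random(21)
    registry = Registry(cfg)
    visits = [(v.visit_id, st) for v in cfg.schedule for st in v.allowed_sample_types]
    rows = _rows(30, seed=9)
    mutations = 0
    for step in range(120):
        op = rng.random()
        if op < 0.5 and rows:
            row = rows.pop()
            ident = SubjectIdentity(values=row)
            try:
                registry.register_subject(
                    ident, registry.search_subjects(ident, mode="fuzzy"), actor="t"
                )
                mutations += 1
            except Exception:
                pass
        elif op < 0.8 and registry.subjects:
            psn = rng.choice(sorted(registry.subjects))
            visit, stype = rng.choice(visits)
            registry.register_biosamples(psn, visit, stype, rng.randint(1, 3), actor="t")
            mutations += 1
        elif registry.biosamples:
            registry.depseudonymize(rng.choice(sorted(registry.biosamples)), actor="t")
            mutations += 1
        registry.check_integrity()
    # audit completeness: one entry per subject/lookup, one per aliquot
    assert len(registry.audit_log) >= mutations
    assert not (set(registry.subjects) & set(registry.biosamples))
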