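"""Synthetic cohort generator: determinism, typo model soundness, evaluation."""

import random

import pytest

from pseudoreg import fixtures as F
from pseudoreg.config import default_config
from pseudoreg.linkage import normalize_identity, parse_iso_date


def test_duplicate_free_cohort_is_all_singletons():
    cohort = F.generate_cohort(100, duplicate_rate=0.0, seed=1)
    assert cohort.truth == list(range(100))
    assert cohort.typo_log == []


def test_same_seed_gives_bit_identical_cohorts():
    a = F.generate_cohort(300, duplicate_rate=0.1, max_typos=2, seed=11)
    b = F.generate_cohort(300, duplicate_rate=0.1, max_typos=2, seed=11)
    assert [i.values for i in a.identities] == [i.values for i in b.identities]
    assert a.truth == b.truth and a.typo_log == b.typo_log
    c = F.generate_cohort(300, duplicate_rate=0.1, max_typos=2, seed=12)
    assert [i.values for i in a.identities] != [i.values for i in c.identities]


def test_duplicate_count_and_edit_budget():
    n, rate, max_typos = 1000, 0.05, 2
    cohort = F.generate_cohort(n, duplicate_rate=rate, max_typos=max_typos, seed=3)
    dups = [i for i, c in enumerate(cohort.truth) if c != i]
    assert len(dups) == int(n * rate)
    by_index = {}
    for e in cohort.typo_log:
        by_index.setdefault(e.index, []).append(e)
    for i in dups:
        edits = by_index[i]
        assert 1 <= len(edits) <= max_typos
        # at most one edit per field, at most one to the date of birth
        fields = [e.field for e in edits]
        assert len(set(fields)) == len(fields)
        assert fields.count("date_of_birth") <= 1
        # duplicates appear after their original
        assert cohort.truth[i] < i
        # unedited fields are identical to the original
        orig = cohort.identities[cohort.truth[i]]
        dup = cohort.identities[i]
        for name in orig.values:
            if name not in fields:
                assert dup.get(name) == orig.get(name)


def test_every_logged_edit_is_a_declared_operation():
    cohort = F.generate_cohort(600, duplicate_rate=0.08, max_typos=2, seed=5)
    for e in cohort.typo_log:
        assert e.op.split("@")[0].split(":")[0] in ("sub", "del", "swap", "dmswap", "comp")
        if e.field == "date_of_birth":
            # date edits keep the value a valid calendar date
            assert parse_iso_date(cohort.identities[e.index].get(e.field)) is not None


def test_originals_are_separable_below_review_threshold():
    cfg = default_config()
    cohort = F.generate_cohort(400, duplicate_rate=0.0, seed=9)
    from pseudoreg.linkage import RegistryIndex

    index = RegistryIndex(cfg.identity_schema)
    for i, ident in enumerate(cohort.identities):
        norm = normalize_identity(ident, cfg.identity_schema)
        assert index.fuzzy_search(norm, cfg) == [], f"record {i} not separable"
        index.add(str(i), norm)


def test_cohort_csv_round_trip(tmp_path):
    cohort = F.generate_cohort(50, duplicate_rate=0.1, seed=2)
    F.cohort_to_csv(cohort, tmp_path / "c.csv", tmp_path / "t.csv")
    import csv

    with (tmp_path / "c.csv").open(encoding="utf-8") as fh:
        rows = list(csv.DictReader(fh))
    assert len(rows) == 50
    assert rows[0].keys() == {"first_name", "last_name", "date_of_birth", "sex"}
    with (tmp_path / "t.csv").open(encoding="utf-8") as fh:
        truth = list(csv.DictReader(fh))
    assert [int(r["cluster_id"]) for r in truth] == cohort.truth


# -- evaluation conventions -------------------------------------------------


def test_duplicate_free_cohort_scores_perfectly_by_convention():
    cohort = F.generate_cohort(200, duplicate_rate=0.0, seed=4)
    flags = F.sequential_registration_flags(cohort)
    ev = F.evaluate_linkage(cohort, flags)
    assert ev.precision == 1.0 and ev.recall == 1.0
    assert ev.true_positives == 0 and ev.false_positives == 0


def test_flag_everything_gives_full_recall_and_base_rate_precision():
    cohort = F.generate_cohort(400, duplicate_rate=0.1, max_typos=1, seed=6)
    # a degenerate matcher that flags every record after the first, naming
    # the true original for duplicates and an arbitrary record otherwise
    flags = []
    for i in range(len(cohort.identities)):
        if i == 0:
            flags.append(F.SequentialFlag(index=0, flagged=False, top_match_index=None, top_score=0.0))
        else:
            top = cohort.truth[i] if cohort.truth[i] != i else 0
            flags.append(F.SequentialFlag(index=i, flagged=True, top_match_index=top, top_score=1.0))
    ev = F.evaluate_linkage(cohort, flags)
    assert ev.recall == 1.0
    n_dup = cohort.n_duplicates
    assert ev.precision == pytest.approx(n_dup / (len(cohort.identities) - 1))


def test_default_matcher_metrics_are_reproducible():
    cohort = F.generate_cohort(1500, duplicate_rate=0.05, max_typos=2, seed=7)
    ev1 = F.evaluate_linkage(cohort, F.sequential_registration_flags(cohort))
    ev2 = F.evaluate_linkage(cohort, F.sequential_registration_flags(cohort))
    assert ev1 == ev2
    assert ev1.recall >= 0.95 and ev1.precision >= 0.90
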