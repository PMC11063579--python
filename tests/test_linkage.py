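"""Normalization, quality checks, similarity, and search/oracle equivalence."""

import datetime as dt
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pseudoreg import fixtures as F
from pseudoreg.errors import EmptyQueryError, SchemaViolationError
from pseudoreg.linkage import (
    RegistryIndex,
    SubjectIdentity,
    aggregate_score,
    classify_match,
    date_similarity,
    field_similarity,
    has_wildcards,
    jaro_winkler,
    normalize_identity,
    normalize_text,
    quality_check,
    search,
    wildcard_regex,
)


def jw_oracle(s1: str, s2: str) -> float:
    """Independent Jaro-Winkler written straight from the definition."""
    if s1 == s2:
        return 1.0
    if not s1 or not s2:
        return 0.0
    match_dist = max(len(s1), len(s2)) // 2 - 1
    m1, m2 = [], []
    used = set()
    for i, c in enumerate(s1):
        for j in range(max(0, i - match_dist), min(len(s2), i + match_dist + 1)):
            if j not in used and s2[j] == c:
                m1.append(c)
                m2.append((j, s2[j]))
                used.add(j)
                break
    if not m1:
        return 0.0
    m2_sorted = [c for _, c in sorted(m2)]
    # half-transpositions floored, as in the original reference implementation
    t = sum(a != b for a, b in zip(m1, m2_sorted)) // 2
    m = len(m1)
    jaro = (m / len(s1) + m / len(s2) + (m - t) / m) / 3
    if jaro <= 0.7:
        return jaro
    ell = 0
    for a, b in zip(s1[:4], s2[:4]):
        if a != b:
            break
        ell += 1
    return jaro + ell * 0.1 * (1 - jaro)


# -- normalization ----------------------------------------------------------


def test_normalization_rules(cfg):
    raw = SubjectIdentity(
        values={
            "first_name": " Anna  Léa ",
            "last_name": "  Müller ",
            "date_of_birth": "1980-3-4",
            "sex": "f",
        }
    )
    norm = normalize_identity(raw, cfg.identity_schema)
    assert norm.get("last_name") == "MULLER"
    assert norm.get("first_name") == "ANNA LEA"
    assert norm.get("date_of_birth") == "1980-03-04"
    assert norm.get("sex") == "F"


def test_invalid_calendar_date_is_a_schema_violation(cfg):
    raw = SubjectIdentity(
        values={
            "first_name": "A", "last_name": "B",
            "date_of_birth": "1980-02-30", "sex": "F",
        }
    )
    with pytest.raises(SchemaViolationError) as exc:
        normalize_identity(raw, cfg.identity_schema)
    assert any("date_of_birth" in f for f in exc.value.fields)


def test_schema_violations_list_all_offending_fields(cfg):
    raw = SubjectIdentity(values={"first_name": "", "date_of_birth": "bad", "sex": "Q"})
    with pytest.raises(SchemaViolationError) as exc:
        normalize_identity(raw, cfg.identity_schema)
    joined = " ".join(exc.value.fields)
    for name in ("first_name", "last_name", "date_of_birth", "sex"):
        assert name in joined


@settings(derandomize=True, max_examples=300)
@given(st.text(max_size=40))
def test_text_normalization_is_idempotent(s):
    once = normalize_text(s)
    assert normalize_text(once) == once


# -- quality checks ---------------------------------------------------------


def test_quality_check_error_and_warning_rules(cfg, today):
    schema = cfg.identity_schema

    def issues_for(**over):
        base = {
            "first_name": "Maria", "last_name": "Rossi",
            "date_of_birth": "1980-03-04", "sex": "F",
        }
        base.update(over)
        return quality_check(SubjectIdentity(values=base), schema, today)

    assert issues_for() == []
    future = issues_for(date_of_birth="2030-01-01")
    assert any(i.severity == "error" and i.field == "date_of_birth" for i in future)
    old = issues_for(date_of_birth="1900-01-01")
    assert any(i.severity == "warning" and i.field == "date_of_birth" for i in old)
    short = issues_for(last_name="X")
    assert {i.severity for i in short if i.field == "last_name"} == {"warning"}
    placeholder = issues_for(first_name="XXX")
    assert any("placeholder" in i.message for i in placeholder)
    missing = issues_for(last_name="")
    assert any(i.severity == "error" and i.field == "last_name" for i in missing)


# -- similarity -------------------------------------------------------------


def test_jaro_winkler_reference_values():
    assert jaro_winkler("MARTHA", "MARHTA") == pytest.approx(0.961, abs=5e-4)
    assert jaro_winkler("DWAYNE", "DUANE") == pytest.approx(0.84, abs=5e-3)
    assert jaro_winkler("X", "X") == 1.0
    assert jaro_winkler("ABC", "XYZ") == 0.0


@settings(derandomize=True, max_examples=300)
@given(st.text(alphabet="ABCDEFG", max_size=10), st.text(alphabet="ABCDEFG", max_size=10))
def test_jaro_winkler_agrees_with_independent_implementation(a, b):
    assert jaro_winkler(a, b) == pytest.approx(jw_oracle(a, b), abs=1e-12)
    assert jaro_winkler(a, b) == jaro_winkler(b, a)


@pytest.mark.parametrize(
    "a,b,expected",
    [
        ("1980-03-04", "1980-03-04", 1.0),
        ("1980-03-04", "1980-04-03", 0.8),  # day/month transposed
        ("1980-03-04", "1981-03-04", 0.8),  # one component differs
        ("1980-03-04", "1980-03-11", 0.8),
        ("1980-03-04", "1981-04-04", 0.0),  # two components differ
        ("1980-03-04", "junk", 0.0),
    ],
)
def test_date_similarity_rules(a, b, expected):
    assert date_similarity(a, b) == expected


def test_field_similarity_dispatch():
    assert field_similarity("F", "F", "enum") == 1.0
    assert field_similarity("F", "M", "enum") == 0.0
    assert field_similarity("ANNA", "ANNA", "text") == 1.0


# -- aggregation ------------------------------------------------------------


def test_aggregate_score_arithmetic_and_redistribution():
    assert aggregate_score({"a": 1.0, "b": 0.5}, {"a": 1, "b": 1}) == 0.75
    # field b missing entirely: weight redistributed to a
    assert aggregate_score({"a": 0.6}, {"a": 1, "b": 1}) == 0.6
    assert aggregate_score({"a": 1.0, "b": 1.0}, {"a": 1, "b": 1}) == 1.0


@settings(derandomize=True, max_examples=200)
@given(
    st.dictionaries(
        st.sampled_from(["a", "b", "c"]),
        st.floats(min_value=0, max_value=1),
        min_size=1,
    ),
    st.sampled_from(["a", "b", "c"]),
    st.floats(min_value=0, max_value=0.5),
)
def test_aggregate_is_monotone_in_each_field(scores, bump_field, bump):
    weights = {"a": 1.0, "b": 0.7, "c": 0.3}
    if bump_field not in scores:
        return
    bumped = dict(scores)
    bumped[bump_field] = min(1.0, bumped[bump_field] + bump)
    assert aggregate_score(bumped, weights) >= aggregate_score(scores, weights) - 1e-12


@pytest.mark.parametrize(
    "score,expected",
    [(1.0, "exact_block"), (0.98, "exact_block"), (0.90, "review"), (0.85, "review"), (0.5, "no_match")],
)
def test_classification_thresholds(score, expected):
    assert classify_match(score, (0.98, 0.85)) == expected


# -- search -----------------------------------------------------------------


def _build_index(cfg, n=400, seed=5, duplicate_rate=0.05):
    cohort = F.generate_cohort(n, duplicate_rate=duplicate_rate, max_typos=2, seed=seed)
    index = RegistryIndex(cfg.identity_schema)
    store = []
    for i, ident in enumerate(cohort.identities):
        norm = normalize_identity(ident, cfg.identity_schema)
        index.add(f"P{i:05d}", norm)
        store.append((f"P{i:05d}", dict(norm.values)))
    return cohort, index, store


def _brute_force(index, store, norm_query, cfg, mode):
    """Full-scan oracle over the same similarity definitions (no blocking)."""
    hits = set()
    if mode in ("fuzzy", "combined"):
        qvals = {k: v for k, v in norm_query.items() if not has_wildcards(v)}
        if qvals:
            for psn, rec in store:
                s = index.score_record(qvals, rec)
                if s is not None and s[0] >= cfg.review_threshold:
                    hits.add(psn)
    if mode in ("wildcard", "combined"):
        pats = {k: wildcard_regex(v) for k, v in norm_query.items()}
        for psn, rec in store:
            if all(rec.get(k) is not None and p.match(rec[k]) for k, p in pats.items()):
                hits.add(psn)
    return hits


def _normalize_query(qd, cfg):
    from pseudoreg.linkage import parse_iso_date

    fmap = cfg.identity_schema.field_map()
    out = {}
    for k, v in qd.items():
        v = v.strip()
        if not v or k not in fmap:
            continue
        f = fmap[k]
        if f.kind == "text" or has_wildcards(v):
            out[k] = normalize_text(v)
        elif f.kind == "date":
            d = parse_iso_date(v)
            out[k] = d.isoformat() if d else normalize_text(v)
        else:
            out[k] = normalize_text(v)
    return out


def test_wildcard_semantics(cfg):
    index = RegistryIndex(cfg.identity_schema)
    for i, (last, dob) in enumerate(
        [("SMITH", "1980-01-01"), ("SMYTH", "1981-02-02"), ("ADAMS", "1982-03-03")]
    ):
        ident = SubjectIdentity(
            values={"first_name": "Ann", "last_name": last, "date_of_birth": dob, "sex": "F"}
        )
        index.add(f"P{i}", normalize_identity(ident, cfg.identity_schema))
    res = search(index, {"last_name": "SM*"}, cfg, mode="wildcard")
    assert [c.subject_pseudonym for c in res] == ["P0", "P1"]
    res = search(index, {"last_name": "SM?TH"}, cfg, mode="wildcard")
    assert [c.subject_pseudonym for c in res] == ["P0", "P1"]
    res = search(index, {"last_name": "*TH"}, cfg, mode="wildcard")
    assert [c.subject_pseudonym for c in res] == ["P0", "P1"]


def test_exact_identity_ranks_first_with_score_one(cfg):
    cohort, index, _ = _build_index(cfg, n=100, seed=2, duplicate_rate=0.0)
    target = cohort.identities[17]
    res = search(index, dict(target.values), cfg, mode="fuzzy")
    assert res and res[0].subject_pseudonym == "P00017"
    assert res[0].score == 1.0
    assert res[0].classification == "exact_block"


def test_empty_query_raises(cfg):
    index = RegistryIndex(cfg.identity_schema)
    with pytest.raises(EmptyQueryError):
        search(index, {}, cfg)
    with pytest.raises(EmptyQueryError):
        search(index, {"first_name": "  "}, cfg)


def test_blocked_search_equals_brute_force_oracle(cfg):
    """Result sets identical to a full scan for typo'd, partial and wildcard queries."""
    cohort, index, store = _build_index(cfg, n=400, seed=5)
    rng = random.Random(13)
    checked = 0
    for _ in range(150):
        base = cohort.identities[rng.randrange(len(cohort.identities))]
        if rng.random() < 0.7:
            q, _log = F._make_duplicate(base, 0, 2, rng)
        else:
            q = base
        qd = dict(q.values)
        mode = rng.choice(["fuzzy", "combined", "wildcard"])
        if mode == "wildcard" and rng.random() < 0.7:
            qd = {"last_name": qd["last_name"][:2] + "*"}
        elif rng.random() < 0.2:
            qd.pop("date_of_birth")  # forces the full-scan fallback
        res = search(index, qd, cfg, mode=mode)
        got = {c.subject_pseudonym for c in res}
        expected = _brute_force(index, store, _normalize_query(qd, cfg), cfg, mode)
        assert got == expected, (mode, qd)
        checked += 1
    assert checked == 150


def test_search_ordering_is_deterministic(cfg):
    cohort, index, _ = _build_index(cfg, n=200, seed=8)
    q = dict(cohort.identities[0].values)
    a = [(c.subject_pseudonym, c.score) for c in search(index, q, cfg)]
    b = [(c.subject_pseudonym, c.score) for c in search(index, q, cfg)]
    assert a == b
    scores = [s for _, s in a]
    assert scores == sorted(scores, reverse=True)
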