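"""Identity normalization, data-quality checks, and duplicate-preventing search.

Enrolment staff search *before* they register: the search combines

* **wildcard matching** (``*`` any run, ``?`` one character — study-nurse
  syntax, no regex exposure) on normalized values, and
* **fuzzy record linkage**: per-field similarities (Jaro–Winkler for text,
  a rule-based comparison for dates, equality for enums) aggregated into a
  weighted mean, classified against two thresholds — ``block`` (certain
  duplicate, registration refused) and ``review`` (needs a human decision).

Scalability comes from blocking on date-of-birth component pairs. The key
property, proved in docs/methods.md and enforced at runtime: with the
shipped field weights no pair of records can reach the review threshold
unless their dates of birth agree on at least two of (year, month, day)
or are a day/month transposition — and every such pair shares a block key.
Whenever the configured weights (or a query without a date of birth) void
that guarantee, search silently falls back to a full scan, so blocked
search is *always* result-identical to the brute-force oracle.
"""

from __future__ import annotations

import datetime as _dt
import re
import unicodedata
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping

from .config import IdentityFieldSchema, StudyConfig
from .errors import EmptyQueryError, NoComparableFieldsError, SchemaViolationError

# ---------------------------------------------------------------------------
# identity containers


@dataclass(frozen=True)
class SubjectIdentity:
    """Raw directly-identifying attributes (IDAT) captured at enrolment.

    Only attributes declared in the identity-field schema are ever stored;
    there is deliberately no slot for clinical payload — medical data live
    in downstream systems keyed by pseudonym only.
    """

    values: Mapping[str, str]

    def get(self, name: str, default: str = "") -> str:
        return self.values.get(name, default)


@dataclass(frozen=True)
class NormalizedIdentity:
    values: Mapping[str, str]

    def get(self, name: str, default: str = "") -> str:
        return self.values.get(name, default)


@dataclass(frozen=True)
class QualityIssue:
    field: str
    severity: str  # "error" | "warning"
    message: str


@dataclass(frozen=True)
class MatchCandidate:
    subject_pseudonym: str
    score: float
    per_field_scores: Mapping[str, float]
    classification: str  # "exact_block" | "review" | "no_match"


# ---------------------------------------------------------------------------
# normalization


_WS = re.compile(r"\s+")


def _norm_text_once(s: str) -> str:
    s = unicodedata.normalize("NFKD", s)
    s = "".join(c for c in s if not unicodedata.combining(c))
    s = s.casefold().upper()
    return _WS.sub(" ", s).strip()


def normalize_text(s: str) -> str:
    """Case-fold, strip diacritics, collapse whitespace; idempotent by fixpoint."""
    prev = s
    for _ in range(4):
        cur = _norm_text_once(prev)
        if cur == prev:
            return cur
        prev = cur
    return prev


def parse_iso_date(s: str) -> _dt.date | None:
    """Strict ISO 8601 calendar date (YYYY-MM-DD, unpadded accepted); None if invalid."""
    m = re.fullmatch(r"(\d{4})-(\d{1,2})-(\d{1,2})", s.strip())
    if not m:
        return None
    try:
        return _dt.date(int(m.group(1)), int(m.group(2)), int(m.group(3)))
    except ValueError:
        return None


def normalize_identity(raw: SubjectIdentity, schema: IdentityFieldSchema) -> NormalizedIdentity:
    """Deterministic, idempotent canonical form used for all matching.

    Raises :class:`SchemaViolationError` listing *all* offending fields:
    missing/blank required fields, invalid calendar dates, enum values
    outside the configured set, and values for undeclared fields.
    """
    fmap = schema.field_map()
    bad: list[str] = []
    out: dict[str, str] = {}
    for name in raw.values:
        if name not in fmap:
            bad.append(f"{name} (not in schema)")
    for f in schema.fields:
        v = raw.get(f.name, "")
        v = v.strip() if isinstance(v, str) else str(v)
        if not v:
            if f.required:
                bad.append(f"{f.name} (required, missing or blank)")
            continue
        if f.kind == "text":
            out[f.name] = normalize_text(v)
        elif f.kind == "date":
            d = parse_iso_date(v)
            if d is None:
                bad.append(f"{f.name} (not a valid ISO calendar date: {v!r})")
            else:
                out[f.name] = d.isoformat()
        elif f.kind == "enum":
            canon = normalize_text(v)
            matched = next(
                (ev for ev in f.enum_values if normalize_text(ev) == canon), None
            )
            if matched is None:
                bad.append(f"{f.name} (value {v!r} not one of {list(f.enum_values)})")
            else:
                out[f.name] = matched
    if bad:
        raise SchemaViolationError(bad)
    return NormalizedIdentity(values=out)


_PLACEHOLDERS = {"X", "XX", "XXX", "TEST", "UNKNOWN", "NA", "N/A", "NONE", "?", "-", "ANONYMOUS"}
_MAX_PLAUSIBLE_AGE_YEARS = 110


def quality_check(
    identity: SubjectIdentity,
    schema: IdentityFieldSchema,
    today: _dt.date | None = None,
) -> list[QualityIssue]:
    """Total data-quality screen: never raises, returns error and warning issues.

    Errors make an identity unregistrable (missing required fields, invalid
    or future dates, enum values outside the configured set); warnings flag
    suspicious but admissible values (implausible age, single-character
    names, placeholder strings).
    """
    today = today or _dt.date.today()
    issues: list[QualityIssue] = []
    fmap = schema.field_map()
    for name in identity.values:
        if name not in fmap:
            issues.append(QualityIssue(name, "error", "field is not part of the identity schema"))
    for f in schema.fields:
        v = identity.get(f.name, "")
        v = v.strip() if isinstance(v, str) else str(v)
        if not v:
            if f.required:
                issues.append(QualityIssue(f.name, "error", "required field is missing or blank"))
            continue
        if f.kind == "date":
            d = parse_iso_date(v)
            if d is None:
                issues.append(
                    QualityIssue(f.name, "error", f"{v!r} is not a valid ISO calendar date")
                )
                continue
            if d > today:
                issues.append(QualityIssue(f.name, "error", f"date {d.isoformat()} lies in the future"))
            elif (today - d).days > _MAX_PLAUSIBLE_AGE_YEARS * 365.25:
                issues.append(
                    QualityIssue(
                        f.name,
                        "warning",
                        f"date {d.isoformat()} implies an age above "
                        f"{_MAX_PLAUSIBLE_AGE_YEARS} years",
                    )
                )
        elif f.kind == "enum":
            canon = normalize_text(v)
            if not any(normalize_text(ev) == canon for ev in f.enum_values):
                issues.append(
                    QualityIssue(f.name, "error", f"{v!r} not one of {list(f.enum_values)}")
                )
        else:  # text
            norm = normalize_text(v)
            if len(norm) == 1:
                issues.append(QualityIssue(f.name, "warning", "single-character value"))
            if norm in _PLACEHOLDERS:
                issues.append(QualityIssue(f.name, "warning", f"placeholder-like value {v!r}"))
    return issues


# ---------------------------------------------------------------------------
# similarity


def _jaro(a: str, b: str) -> float:
    if a == b:
        return 1.0
    la, lb = len(a), len(b)
    if la == 0 or lb == 0:
        return 0.0
    window = max(la, lb) // 2 - 1
    if window < 0:
        window = 0
    match_a = [False] * la
    match_b = [False] * lb
    matches = 0
    for i in range(la):
        lo = max(0, i - window)
        hi = min(lb, i + window + 1)
        ca = a[i]
        for j in range(lo, hi):
            if not match_b[j] and b[j] == ca:
                match_a[i] = True
                match_b[j] = True
                matches += 1
                break
    if matches == 0:
        return 0.0
    transpositions = 0
    j = 0
    for i in range(la):
        if match_a[i]:
            while not match_b[j]:
                j += 1
            if a[i] != b[j]:
                transpositions += 1
            j += 1
    t = transpositions // 2
    m = matches
    return (m / la + m / lb + (m - t) / m) / 3.0


@lru_cache(maxsize=1 << 20)
def _jw_cached(a: str, b: str) -> float:
    sim = _jaro(a, b)
    if sim > 0.7:  # standard boost threshold
        prefix = 0
        for ca, cb in zip(a, b):
            if ca != cb or prefix == 4:
                break
            prefix += 1
        sim += 0.1 * prefix * (1.0 - sim)
    return sim


def jaro_winkler(a: str, b: str) -> float:
    """Jaro–Winkler similarity (prefix scale 0.1, max prefix 4, boost > 0.7).

    Memoized: identity fields draw from heavily repeated name pools, so the
    cache turns bulk linkage from quadratic string work into dictionary hits.
    """
    if a > b:
        a, b = b, a
    return _jw_cached(a, b)


def date_similarity(a: str, b: str) -> float:
    """Rule-based date comparison on canonical ISO strings.

    1.0 exact; 0.8 for a day/month transposition or exactly one differing
    component (typo in one of year, month, day); 0.0 otherwise or unparseable.
    """
    if a == b:
        return 1.0
    da, db = parse_iso_date(a), parse_iso_date(b)
    if da is None or db is None:
        return 0.0
    return _date_similarity_parts(
        (da.year, da.month, da.day), (db.year, db.month, db.day)
    )


def _date_similarity_parts(pa: tuple[int, int, int], pb: tuple[int, int, int]) -> float:
    if pa == pb:
        return 1.0
    if pa[0] == pb[0] and pa[1] == pb[2] and pa[2] == pb[1]:
        return 0.8  # day/month transposed
    if sum(x != y for x, y in zip(pa, pb)) == 1:
        return 0.8  # exactly one component differs
    return 0.0


def field_similarity(a: str, b: str, kind: str) -> float:
    """Similarity in [0, 1] for two *normalized* values of the same field kind."""
    if kind == "text":
        return jaro_winkler(a, b)
    if kind == "date":
        return date_similarity(a, b)
    if kind == "enum":
        return 1.0 if a == b else 0.0
    raise ValueError(f"unknown field kind {kind!r}")


def aggregate_score(
    per_field: Mapping[str, float], weights: Mapping[str, float]
) -> float:
    """Weighted arithmetic mean over the fields present in *per_field*.

    Fields missing from either record simply do not appear in *per_field*;
    their weight is thereby redistributed across the comparable fields.
    """
    total = 0.0
    acc = 0.0
    for name, s in per_field.items():
        w = weights.get(name, 0.0)
        total += w
        acc += w * s
    if total <= 0:
        raise NoComparableFieldsError("no comparable fields with positive weight")
    return acc / total


def classify_match(score: float, thresholds: tuple[float, float]) -> str:
    """Map an aggregate score to exact_block / review / no_match."""
    block, review = thresholds
    if score >= block:
        return "exact_block"
    if score >= review:
        return "review"
    return "no_match"


# ---------------------------------------------------------------------------
# wildcard patterns


_WILDCARD_CHARS = ("*", "?")


def has_wildcards(value: str) -> bool:
    return any(c in value for c in _WILDCARD_CHARS)


def wildcard_regex(pattern: str) -> re.Pattern:
    """Translate literal ``*``/``?`` syntax to an anchored regex (nothing else is special)."""
    out = []
    for ch in pattern:
        if ch == "*":
            out.append(".*")
        elif ch == "?":
            out.append(".")
        else:
            out.append(re.escape(ch))
    return re.compile("".join(out) + r"\Z")


# ---------------------------------------------------------------------------
# the searchable index


def _dob_block_keys(y: int, m: int, d: int) -> tuple:
    lo, hi = (m, d) if m <= d else (d, m)
    return (
        ("ym", y, m),
        ("yd", y, d),
        ("md", m, d),
        ("yswap", y, lo, hi),
    )


class RegistryIndex:
    """In-memory search index over registered subjects.

    Holds the normalized identity per pseudonym plus the date-of-birth
    block maps. ``comparisons`` counts candidate records visited by fuzzy
    scoring (the quantity that must grow at most linearly with registry
    size); it is a diagnostic, not part of any result.
    """

    def __init__(self, schema: IdentityFieldSchema):
        self.schema = schema
        self._fields = list(schema.fields)
        self._weights = schema.weights()
        self._total_weight = sum(self._weights.values())
        self._date_field = next((f.name for f in self._fields if f.kind == "date"), None)
        self._records: list[tuple[str, Mapping[str, str], tuple[int, int, int] | None]] = []
        self._by_pseudonym: dict[str, int] = {}
        self._blocks: dict[tuple, list[int]] = {}
        self._no_dob: list[int] = []
        self.comparisons = 0

    def __len__(self) -> int:
        return len(self._records)

    @property
    def version(self) -> int:
        """Monotone state counter; searches are only valid against the version they saw."""
        return len(self._records)

    def add(self, pseudonym: str, normalized: NormalizedIdentity) -> None:
        idx = len(self._records)
        dob = None
        if self._date_field is not None:
            ds = normalized.get(self._date_field, "")
            d = parse_iso_date(ds) if ds else None
            if d is not None:
                dob = (d.year, d.month, d.day)
        self._records.append((pseudonym, dict(normalized.values), dob))
        self._by_pseudonym[pseudonym] = idx
        if dob is None:
            self._no_dob.append(idx)
        else:
            for key in _dob_block_keys(*dob):
                self._blocks.setdefault(key, []).append(idx)

    # -- scoring ------------------------------------------------------------

    def score_record(
        self, query: Mapping[str, str], record: Mapping[str, str]
    ) -> tuple[float, dict[str, float]] | None:
        """Aggregate fuzzy score of a record against a literal normalized query.

        Returns None when no field is comparable. This exact routine is the
        definition of the score: the brute-force oracle and the blocked
        search both call it (cheap fields first, in schema order, so the
        floating-point accumulation order is identical everywhere), and
        blocking can only affect *which* records are visited, never how
        they are scored.
        """
        per_field: dict[str, float] = {}
        for f in self._scoring_order():
            q = query.get(f.name)
            r = record.get(f.name)
            if q is None or r is None or self._weights[f.name] <= 0:
                continue
            per_field[f.name] = field_similarity(q, r, f.kind)
        if not per_field:
            return None
        return aggregate_score(per_field, self._weights), per_field

    def _scoring_order(self):
        return [f for f in self._fields if f.kind != "text"] + [
            f for f in self._fields if f.kind == "text"
        ]

    def _blocking_sound(self, query: Mapping[str, str], review: float) -> bool:
        """True iff date-of-birth blocking provably finds every record >= review.

        Requires (a) the query to carry a parseable date of birth and (b)
        the configured weights to make the date field decisive: any subset
        of non-date fields alone must stay below the review threshold even
        at similarity 1.0. Otherwise the caller must do a full scan.
        """
        if self._date_field is None or self._date_field not in query:
            return False
        if parse_iso_date(query[self._date_field]) is None:
            return False
        w_d = self._weights[self._date_field]
        w_rest = self._total_weight - w_d
        if w_rest + w_d <= 0:
            return False
        return w_rest / (w_rest + w_d) < review

    def _fuzzy_candidates(self, query: Mapping[str, str]) -> Iterable[int]:
        d = parse_iso_date(query[self._date_field])
        seen: set[int] = set()
        for key in _dob_block_keys(d.year, d.month, d.day):
            for idx in self._blocks.get(key, ()):
                if idx not in seen:
                    seen.add(idx)
                    yield idx
        for idx in self._no_dob:
            if idx not in seen:
                seen.add(idx)
                yield idx

    def fuzzy_search(
        self, query: NormalizedIdentity, config: StudyConfig
    ) -> list[MatchCandidate]:
        """All records scoring >= review_threshold, blocked when provably safe.

        The inner loop scores cheap fields (date as precomputed component
        tuples, enums) before string similarities and drops a candidate as
        soon as even perfect similarity on its remaining fields cannot
        reach the threshold — an exact cutoff, so the result set equals the
        unpruned brute-force computation, in the same accumulation order.
        """
        qvals = {k: v for k, v in query.values.items() if not has_wildcards(v)}
        if not qvals:
            return []
        review = config.review_threshold
        thresholds = (config.block_threshold, config.review_threshold)
        # query plan: (name, kind, query value, weight), cheap fields first;
        # the query's date is pre-parsed so candidates compare int tuples
        plan: list[tuple[str, str, object, float]] = []
        for f in self._scoring_order():
            q = qvals.get(f.name)
            w = self._weights[f.name]
            if q is None or w <= 0:
                continue
            if f.kind == "date" and f.name == self._date_field:
                d = parse_iso_date(q)
                plan.append(
                    (f.name, "dob", ((d.year, d.month, d.day) if d else None, q), w)
                )
            else:
                plan.append((f.name, f.kind, q, w))
        if not plan:
            return []
        full_total = sum(p[3] for p in plan)
        out: list[MatchCandidate] = []
        if self._blocking_sound(qvals, review):
            candidates = self._fuzzy_candidates(qvals)
        else:
            candidates = range(len(self._records))
        records = self._records
        for idx in candidates:
            pseudonym, record, dob = records[idx]
            self.comparisons += 1
            if len(record) == len(self._fields):
                total = full_total
            else:
                total = sum(w for name, _k, _q, w in plan if name in record)
                if total <= 0:
                    continue
            acc = 0.0
            remaining = total
            cutoff = review * total
            per_field: dict[str, float] = {}
            dropped = False
            for name, kind, q, w in plan:
                if kind == "dob":
                    qtuple, qstring = q
                    if dob is not None and qtuple is not None:
                        s = _date_similarity_parts(qtuple, dob)
                    else:
                        r = record.get(name)
                        if r is None:
                            continue
                        s = date_similarity(qstring, r)
                else:
                    r = record.get(name)
                    if r is None:
                        continue
                    s = jaro_winkler(q, r) if kind == "text" else (1.0 if q == r else 0.0)
                per_field[name] = s
                acc += w * s
                remaining -= w
                if acc + remaining < cutoff:
                    dropped = True
                    break
            if dropped or not per_field:
                continue
            score = acc / total
            out.append(
                MatchCandidate(
                    subject_pseudonym=pseudonym,
                    score=score,
                    per_field_scores=per_field,
                    classification=classify_match(score, thresholds),
                )
            )
        out.sort(key=lambda c: (-c.score, c.subject_pseudonym))
        return out

    # -- wildcard -----------------------------------------------------------

    def wildcard_search(
        self, query: NormalizedIdentity, config: StudyConfig
    ) -> list[MatchCandidate]:
        """Full-scan pattern match; every provided field must match its pattern.

        Wildcarded fields score 1.0 (the pattern matched), literal fields
        score by similarity (necessarily 1.0, since they had to match
        exactly) — so pure pattern hits rank by pseudonym, deterministic.
        """
        patterns = {name: wildcard_regex(v) for name, v in query.values.items()}
        if not patterns:
            return []
        thresholds = (config.block_threshold, config.review_threshold)
        kinds = {f.name: f.kind for f in self._fields}
        out: list[MatchCandidate] = []
        for pseudonym, record, _dob in self._records:
            per_field: dict[str, float] = {}
            matched = True
            for name, pat in patterns.items():
                rv = record.get(name)
                if rv is None or not pat.match(rv):
                    matched = False
                    break
                per_field[name] = 1.0
            if not matched:
                continue
            score = aggregate_score(per_field, self._weights)
            out.append(
                MatchCandidate(
                    subject_pseudonym=pseudonym,
                    score=score,
                    per_field_scores=per_field,
                    classification=classify_match(score, thresholds),
                )
            )
        out.sort(key=lambda c: (-c.score, c.subject_pseudonym))
        return out


def search(
    index: RegistryIndex,
    query: SubjectIdentity | NormalizedIdentity | Mapping[str, str],
    config: StudyConfig,
    mode: str = "combined",
) -> list[MatchCandidate]:
    """Rank registry candidates for a (partial, possibly wildcarded) query.

    Modes: ``wildcard`` (pattern match), ``fuzzy`` (score >= review
    threshold), ``combined`` (union; a record found both ways keeps its
    fuzzy score). Ordering is score descending, pseudonym ascending.
    Results are guaranteed identical to a brute-force scan of the registry.
    """
    if mode not in ("wildcard", "fuzzy", "combined"):
        raise ValueError(f"unknown search mode {mode!r}")
    if isinstance(query, SubjectIdentity):
        values = dict(query.values)
    elif isinstance(query, NormalizedIdentity):
        values = dict(query.values)
    else:
        values = dict(query)
    # normalize query fields individually; wildcard characters pass through
    fmap = index.schema.field_map()
    norm: dict[str, str] = {}
    for name, v in values.items():
        v = (v or "").strip()
        if not v or name not in fmap:
            continue
        f = fmap[name]
        if f.kind == "text" or has_wildcards(v):
            norm[name] = normalize_text(v)
        elif f.kind == "date":
            d = parse_iso_date(v)
            norm[name] = d.isoformat() if d else normalize_text(v)
        else:
            canon = normalize_text(v)
            matched = next((ev for ev in f.enum_values if normalize_text(ev) == canon), None)
            norm[name] = matched if matched is not None else canon
    if not norm:
        raise EmptyQueryError("search query must contain at least one non-empty field")
    nq = NormalizedIdentity(values=norm)
    if mode == "wildcard":
        return index.wildcard_search(nq, config)
    if mode == "fuzzy":
        return index.fuzzy_search(nq, config)
    fuzzy = index.fuzzy_search(nq, config)
    by_psn = {c.subject_pseudonym: c for c in fuzzy}
    for c in index.wildcard_search(nq, config):
        by_psn.setdefault(c.subject_pseudonym, c)
    out = list(by_psn.values())
    out.sort(key=lambda c: (-c.score, c.subject_pseudonym))
    return out
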