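"""Deterministic synthetic identities with ground truth.

Multi-site studies cannot ship real enrolment data with their tooling, so
every stage — linkage quality, bulk import, scaling — is exercised against
cohorts built here. The generator emulates the features of identity data
that matter to record linkage:

* names drawn from bundled multi-locale pools (including diacritics, so
  normalization is exercised) with a Zipf-like skew — real name frequencies
  are heavy-tailed, which is exactly what creates chance near-matches;
* dates of birth over a realistic range, uniform by construction;
* controlled duplicates: a configurable fraction of records are copies of
  earlier records with 1..max_typos edits (character substitution, adjacent
  transposition, deletion, or a day/month swap), at most one edit per field
  and at most one to the date of birth, with every edit logged;
* separability: a candidate original is resampled if it scores at or above
  the default review threshold against any previously accepted original, so
  every flaggable pair in a generated cohort is a *true* duplicate — recall
  and precision shortfalls indict the matcher, never the data.

Everything is driven by one integer seed and is bit-reproducible.
"""

from __future__ import annotations

import csv
import random
from dataclasses import dataclass, field
from pathlib import Path

from .config import StudyConfig, default_config
from .linkage import RegistryIndex, SubjectIdentity, normalize_identity

# Bundled name pools. Multi-locale on purpose: the registries this package
# targets run across many countries, and diacritics/compound names are the
# normal case, not the edge case.
FEMALE_FIRST = [
    "Maria", "Anna", "Sofia", "Elena", "Laura", "Martina", "Giulia", "Francesca",
    "Chiara", "Alessia", "Lucia", "Carmen", "Isabel", "Pilar", "Dolores", "Ana",
    "Marta", "Teresa", "Beatriz", "Catarina", "Inês", "Amélie", "Camille", "Chloé",
    "Léa", "Manon", "Margaux", "Julia", "Hannah", "Lena", "Charlotte", "Emilia",
    "Frieda", "Katharina", "Sabine", "Ursula", "Helga", "Ingrid", "Astrid", "Sigrid",
    "Agnieszka", "Katarzyna", "Magdalena", "Zofia", "Ewa", "Petra", "Jana", "Zuzana",
    "Katarína", "Mária", "Eva", "Olga", "Irina", "Natalia", "Svetlana", "Amina",
    "Fatima", "Leila", "Yasmin", "Aisha", "Grace", "Ruth", "Esther", "Naomi",
    "Emily", "Olivia", "Sophie", "Alice", "Rose", "Margaret",
]
MALE_FIRST = [
    "Giovanni", "Marco", "Luca", "Andrea", "Francesco", "Alessandro", "Matteo",
    "Lorenzo", "Antonio", "Giuseppe", "Carlos", "José", "Manuel", "Javier", "Miguel",
    "Pedro", "Luis", "Diego", "João", "Tiago", "Nuno", "Pierre", "Jean", "Louis",
    "Antoine", "Hugo", "Théo", "Lucas", "Jonas", "Felix", "Maximilian", "Johann",
    "Karl", "Heinrich", "Wolfgang", "Dieter", "Jürgen", "Stefan", "Andreas", "Tobias",
    "Piotr", "Krzysztof", "Andrzej", "Tomasz", "Marek", "Pavol", "Ján", "Peter",
    "Milan", "Ivan", "Dmitri", "Sergei", "Nikolai", "Omar", "Karim", "Youssef",
    "Ali", "Hassan", "Samuel", "David", "Daniel", "Joseph", "Thomas", "James",
    "William", "Henry", "George", "Arthur", "Oliver", "Jack",
]
SURNAMES = [
    "Rossi", "Russo", "Ferrari", "Esposito", "Bianchi", "Romano", "Colombo", "Ricci",
    "Marino", "Greco", "Bruno", "Gallo", "Conti", "DeLuca", "Mancini", "Costa",
    "Giordano", "Rizzo", "Lombardi", "Moretti", "García", "Fernández", "González",
    "Rodríguez", "López", "Martínez", "Sánchez", "Pérez", "Gómez", "Martín", "Jiménez",
    "Ruiz", "Hernández", "Díaz", "Moreno", "Álvarez", "Romero", "Navarro", "Torres",
    "Domínguez", "Silva", "Santos", "Ferreira", "Pereira", "Oliveira", "Almeida",
    "Sousa", "Ribeiro", "Carvalho", "Gomes", "Martin", "Bernard", "Dubois", "Thomas",
    "Robert", "Richard", "Petit", "Durand", "Leroy", "Moreau", "Lefèvre", "Fournier",
    "Girard", "Bonnet", "Müller", "Schmidt", "Schneider", "Fischer", "Weber", "Meyer",
    "Wagner", "Becker", "Schulz", "Hoffmann", "Schäfer", "Koch", "Bauer", "Richter",
    "Klein", "Wolf", "Schröder", "Neumann", "Zimmermann", "Braun", "Krüger", "Hofmann",
    "Nowak", "Kowalski", "Wiśniewski", "Wójcik", "Kowalczyk", "Kamiński", "Lewandowski",
    "Zieliński", "Szymański", "Horváth", "Kováč", "Tóth", "Nagy", "Balog", "Molnár",
    "Novák", "Svoboda", "Dvořák", "Černý", "Procházka", "Ivanov", "Petrov", "Smirnov",
    "Volkov", "Popov", "Haddad", "Khalil", "Saleh", "Mansour", "Nasser", "Amari",
    "Diallo", "Traoré", "Keita", "Touré", "Okafor", "Adeyemi", "Mensah", "Osei",
    "Smith", "Jones", "Taylor", "Brown", "Williams", "Wilson", "Johnson", "Davies",
    "Robinson", "Wright", "Thompson", "Evans", "Walker", "White", "Roberts", "Green",
    "Hall", "Wood", "Jackson", "Clarke", "Jansen", "DeVries", "VanDijk", "Bakker",
    "Visser", "Smit", "Meijer", "Mulder", "Bos", "Vos", "Peters", "Hendriks",
    "Yılmaz", "Kaya", "Demir", "Çelik", "Şahin", "Öztürk", "Aydın", "Arslan",
]

_DOB_YEARS = (1920, 2007)


def _cum_weights(n: int) -> list[float]:
    # Zipf-like rank weights (1/rank^0.8): heavy head, long tail
    acc, out = 0.0, []
    for r in range(1, n + 1):
        acc += r ** -0.8
        out.append(acc)
    return out

_CW_F = _cum_weights(len(FEMALE_FIRST))
_CW_M = _cum_weights(len(MALE_FIRST))
_CW_S = _cum_weights(len(SURNAMES))


@dataclass(frozen=True)
class TypoEdit:
    index: int
    field: str
    op: str  # e.g. "sub@2:l->k", "swap@0", "del@4", "dmswap", "comp:month:5->7"


@dataclass
class SyntheticCohort:
    identities: list[SubjectIdentity]
    truth: list[int]  # cluster id per record = index of the cluster's original
    typo_log: list[TypoEdit]
    seed: int

    @property
    def n_duplicates(self) -> int:
        return sum(1 for i, c in enumerate(self.truth) if c != i)


def _sample_dob(rng: random.Random) -> str:
    y = rng.randint(*_DOB_YEARS)
    m = rng.randint(1, 12)
    d = rng.randint(1, 28)  # every generated date is valid in every month
    return f"{y:04d}-{m:02d}-{d:02d}"


def _sample_identity(rng: random.Random) -> SubjectIdentity:
    if rng.random() < 0.5:
        sex, pool, cw = "F", FEMALE_FIRST, _CW_F
    else:
        sex, pool, cw = "M", MALE_FIRST, _CW_M
    first = rng.choices(pool, cum_weights=cw, k=1)[0]
    last = rng.choices(SURNAMES, cum_weights=_CW_S, k=1)[0]
    return SubjectIdentity(
        values={
            "first_name": first,
            "last_name": last,
            "date_of_birth": _sample_dob(rng),
            "sex": sex,
        }
    )


_LETTERS = "abcdefghijklmnopqrstuvwxyz"


def _edit_name(value: str, rng: random.Random) -> tuple[str, str]:
    """One character edit that provably changes the string; returns (new, op)."""
    ops = ["sub", "del", "swap"]
    rng.shuffle(ops)
    for op in ops:
        if op == "sub":
            pos = rng.randrange(len(value))
            old = value[pos]
            new_c = rng.choice([c for c in _LETTERS if c != old.lower()])
            new_c = new_c.upper() if old.isupper() else new_c
            return value[:pos] + new_c + value[pos + 1 :], f"sub@{pos}:{old}->{new_c}"
        if op == "del" and len(value) > 3:
            pos = rng.randrange(len(value))
            return value[:pos] + value[pos + 1 :], f"del@{pos}"
        if op == "swap":
            pairs = [i for i in range(len(value) - 1) if value[i] != value[i + 1]]
            if pairs:
                pos = rng.choice(pairs)
                return (
                    value[:pos] + value[pos + 1] + value[pos] + value[pos + 2 :],
                    f"swap@{pos}",
                )
    raise AssertionError("unreachable: substitution always applies")


def _edit_dob(value: str, rng: random.Random) -> tuple[str, str]:
    """One date edit: day/month swap when meaningful, else one-component change."""
    y, m, d = (int(x) for x in value.split("-"))
    if d <= 12 and d != m and rng.random() < 0.5:
        return f"{y:04d}-{d:02d}-{m:02d}", "dmswap"
    comp = rng.choice(["year", "month", "day"])
    if comp == "year":
        ny = rng.choice([x for x in range(_DOB_YEARS[0], _DOB_YEARS[1] + 1) if x != y])
        return f"{ny:04d}-{m:02d}-{d:02d}", f"comp:year:{y}->{ny}"
    if comp == "month":
        nm = rng.choice([x for x in range(1, 13) if x != m])
        return f"{y:04d}-{nm:02d}-{d:02d}", f"comp:month:{m}->{nm}"
    nd = rng.choice([x for x in range(1, 29) if x != d])
    return f"{y:04d}-{m:02d}-{nd:02d}", f"comp:day:{d}->{nd}"


_EDITABLE_FIELDS = ("first_name", "last_name", "date_of_birth")


def _make_duplicate(
    original: SubjectIdentity, index: int, max_typos: int, rng: random.Random
) -> tuple[SubjectIdentity, list[TypoEdit]]:
    k = rng.randint(1, max(1, max_typos))
    fields = rng.sample(_EDITABLE_FIELDS, k=min(k, len(_EDITABLE_FIELDS)))
    values = dict(original.values)
    log: list[TypoEdit] = []
    for f in fields:
        if f == "date_of_birth":
            values[f], op = _edit_dob(values[f], rng)
        else:
            values[f], op = _edit_name(values[f], rng)
        log.append(TypoEdit(index=index, field=f, op=op))
    return SubjectIdentity(values=values), log


def generate_cohort(
    n: int,
    duplicate_rate: float = 0.0,
    max_typos: int = 2,
    seed: int = 0,
    config: StudyConfig | None = None,
) -> SyntheticCohort:
    """Generate *n* identities, ``floor(n * duplicate_rate)`` of them duplicates.

    Duplicates always appear after their original (sequential registration
    must be able to catch them). Each original is guaranteed to score below
    the configured review threshold against every other original.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0.0 <= duplicate_rate < 1.0):
        raise ValueError("duplicate_rate must lie in [0, 1)")
    cfg = config or default_config()
    rng = random.Random(seed)
    n_dup = int(n * duplicate_rate)
    dup_slots = set(rng.sample(range(1, n), k=n_dup)) if n_dup else set()

    index = RegistryIndex(cfg.identity_schema)
    identities: list[SubjectIdentity] = []
    truth: list[int] = []
    typo_log: list[TypoEdit] = []
    original_indices: list[int] = []

    for i in range(n):
        if i in dup_slots and original_indices:
            src = rng.choice(original_indices)
            dup, log = _make_duplicate(identities[src], i, max_typos, rng)
            identities.append(dup)
            truth.append(truth[src])
            typo_log.extend(log)
            continue
        for attempt in range(1000):
            cand = _sample_identity(rng)
            norm = normalize_identity(cand, cfg.identity_schema)
            hits = index.fuzzy_search(norm, cfg)
            if not hits:
                break
        else:
            raise RuntimeError(
                "could not sample a separable identity after 1000 attempts; "
                "the name/date space is saturated for this cohort size"
            )
        identities.append(cand)
        truth.append(i)
        original_indices.append(i)
        index.add(str(i), norm)

    return SyntheticCohort(identities=identities, truth=truth, typo_log=typo_log, seed=seed)


def cohort_to_csv(
    cohort: SyntheticCohort, path: str | Path, truth_path: str | Path | None = None
) -> None:
    """Write the cohort as a bulk-import CSV (and optionally the truth labels)."""
    fields = ["first_name", "last_name", "date_of_birth", "sex"]
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=fields)
        w.writeheader()
        for ident in cohort.identities:
            w.writerow({f: ident.get(f, "") for f in fields})
    if truth_path is not None:
        with Path(truth_path).open("w", encoding="utf-8", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["record_index", "cluster_id"])
            for i, c in enumerate(cohort.truth):
                w.writerow([i, c])


# ---------------------------------------------------------------------------
# linkage evaluation against ground truth


@dataclass(frozen=True)
class SequentialFlag:
    """Outcome of the duplicate search for one record during sequential registration."""

    index: int
    flagged: bool
    top_match_index: int | None  # registry record (by cohort index) ranked first
    top_score: float


@dataclass(frozen=True)
class LinkageEvaluation:
    precision: float
    recall: float
    true_positives: int
    false_positives: int
    false_negatives: int
    true_negatives: int


def sequential_registration_flags(
    cohort: SyntheticCohort, config: StudyConfig | None = None
) -> list[SequentialFlag]:
    """Register the cohort in order with linkage active; flagged records are skipped.

    Mirrors the production flow: each identity is searched against everything
    accepted so far; any candidate at or above the review threshold flags the
    record as a suspected duplicate and it is not registered.
    """
    cfg = config or default_config()
    index = RegistryIndex(cfg.identity_schema)
    flags: list[SequentialFlag] = []
    for i, ident in enumerate(cohort.identities):
        norm = normalize_identity(ident, cfg.identity_schema)
        hits = index.fuzzy_search(norm, cfg)
        if hits:
            flags.append(
                SequentialFlag(
                    index=i,
                    flagged=True,
                    top_match_index=int(hits[0].subject_pseudonym),
                    top_score=hits[0].score,
                )
            )
        else:
            flags.append(SequentialFlag(index=i, flagged=False, top_match_index=None, top_score=0.0))
            index.add(str(i), norm)
    return flags


def evaluate_linkage(
    cohort: SyntheticCohort, flags: list[SequentialFlag]
) -> LinkageEvaluation:
    """Precision/recall of duplicate flagging against the cohort's ground truth.

    A flagged record counts as a true positive only when it is a true
    duplicate *and* the top-ranked match belongs to its own cluster.
    Degenerate convention: with no positives (and no false positives),
    precision and recall are both defined as 1.0.
    """
    tp = fp = fn = tn = 0
    for flag in flags:
        is_dup = cohort.truth[flag.index] != flag.index
        if flag.flagged:
            correct = (
                is_dup
                and flag.top_match_index is not None
                and cohort.truth[flag.top_match_index] == cohort.truth[flag.index]
            )
            if correct:
                tp += 1
            else:
                fp += 1
        elif is_dup:
            fn += 1
        else:
            tn += 1
    precision = tp / (tp + fp) if (tp + fp) else 1.0
    recall = tp / (tp + fn) if (tp + fn) else 1.0
    return LinkageEvaluation(
        precision=precision,
        recall=recall,
        true_positives=tp,
        false_positives=fp,
        false_negatives=fn,
        true_negatives=tn,
    )
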