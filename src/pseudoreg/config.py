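"""Study configuration: the single artifact that drives every other module.

A study is described by one human-editable YAML file holding

* the pseudonym formats for subjects and biosamples (prefix, site code,
  body length, alphabet, check-character scheme),
* the identity-field schema (which attributes are captured at enrolment
  and their record-linkage weights),
* the visit schedule and the biosample types collected at each visit,
* linkage thresholds, and the backup-reminder interval.

Validation is total and cumulative: an invalid configuration raises
:class:`~pseudoreg.errors.ConfigValidationError` listing *every* violated
invariant, never a silent default. Dates are ISO 8601 everywhere; the
registry is deployed across countries with conflicting local conventions,
so no locale-dependent format is ever parsed or emitted.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigParseError, ConfigValidationError

#: Characters over which ISO 7064 MOD 37-2 is defined (check char may also be ``*``).
ISO7064_CHARSET = "0123456789ABCDEFGHIJKLMNOPQRSTUVWXYZ"

#: Default pseudonym body alphabet: uppercase alphanumerics minus the
#: visually ambiguous I, O, 0, 1 — labels are read by humans and scanners.
DEFAULT_ALPHABET = "23456789ABCDEFGHJKLMNPQRSTUVWXYZ"

FIELD_KINDS = ("text", "date", "enum")
CHECK_SCHEMES = ("iso7064_mod37_2", "none")
SCOPES = ("subject", "biosample")
GENERATION_MODES = ("random", "sequential")


@dataclass(frozen=True)
class PseudonymFormat:
    """Rendering and generation rules for one pseudonym scope.

    A rendered pseudonym is ``prefix SEP site_code SEP body [SEP check]``,
    e.g. ``SUB-BER-K7M2QX-4``. The check character (when the scheme is
    active) is ISO 7064 MOD 37-2 computed over ``prefix + site_code + body``.
    """

    prefix: str
    site_code: str
    body_length: int
    scope: str
    alphabet: str = DEFAULT_ALPHABET
    separator: str = "-"
    check_scheme: str = "iso7064_mod37_2"
    generation_mode: str = "random"

    @property
    def capacity(self) -> int:
        return len(self.alphabet) ** self.body_length

    def validate(self) -> list[str]:
        issues: list[str] = []
        tag = f"{self.scope or '?'} format"
        if self.scope not in SCOPES:
            issues.append(f"{tag}: scope {self.scope!r} not one of {SCOPES}")
        if self.check_scheme not in CHECK_SCHEMES:
            issues.append(f"{tag}: check_scheme {self.check_scheme!r} not one of {CHECK_SCHEMES}")
        if self.generation_mode not in GENERATION_MODES:
            issues.append(
                f"{tag}: generation_mode {self.generation_mode!r} not one of {GENERATION_MODES}"
            )
        if len(set(self.alphabet)) < 2:
            issues.append(f"{tag}: alphabet needs >=2 distinct characters")
        if len(set(self.alphabet)) != len(self.alphabet):
            issues.append(f"{tag}: alphabet has repeated characters")
        if len(self.separator) != 1:
            issues.append(f"{tag}: separator must be exactly one character")
        elif self.separator in self.alphabet:
            issues.append(f"{tag}: separator {self.separator!r} must not occur in the alphabet")
        if not isinstance(self.body_length, int) or self.body_length < 1:
            issues.append(f"{tag}: body_length must be a positive integer")
        for name, part in (("prefix", self.prefix), ("site_code", self.site_code)):
            if not part:
                issues.append(f"{tag}: {name} must be non-empty")
            elif any(c not in ISO7064_CHARSET for c in part):
                issues.append(
                    f"{tag}: {name} {part!r} must use uppercase A-Z / digits only"
                )
        if self.check_scheme == "iso7064_mod37_2":
            bad = sorted(set(c for c in self.alphabet if c not in ISO7064_CHARSET))
            if bad:
                issues.append(
                    f"{tag}: alphabet characters {bad} not representable in ISO 7064 MOD 37-2"
                )
        return issues


@dataclass(frozen=True)
class IdentityField:
    """One captured identity attribute (IDAT) and its linkage weight."""

    name: str
    kind: str
    required: bool = True
    enum_values: tuple[str, ...] = ()
    match_weight: float = 1.0


@dataclass(frozen=True)
class IdentityFieldSchema:
    fields: tuple[IdentityField, ...]

    def field_map(self) -> dict[str, IdentityField]:
        return {f.name: f for f in self.fields}

    def weights(self) -> dict[str, float]:
        return {f.name: f.match_weight for f in self.fields}

    def validate(self) -> list[str]:
        issues: list[str] = []
        names = [f.name for f in self.fields]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            issues.append(f"identity schema: duplicate field names {dupes}")
        if not any(f.required for f in self.fields):
            issues.append("identity schema: at least one field must be required")
        for f in self.fields:
            if f.kind not in FIELD_KINDS:
                issues.append(f"identity field {f.name!r}: kind {f.kind!r} not one of {FIELD_KINDS}")
            if f.match_weight < 0:
                issues.append(f"identity field {f.name!r}: match_weight must be non-negative")
            if f.kind == "enum" and len(f.enum_values) < 2:
                issues.append(f"identity field {f.name!r}: enum needs >=2 values")
            if f.kind != "enum" and f.enum_values:
                issues.append(f"identity field {f.name!r}: enum_values given for non-enum kind")
        if sum(f.match_weight for f in self.fields) <= 0:
            issues.append("identity schema: match weights must sum to > 0")
        return issues


@dataclass(frozen=True)
class VisitDefinition:
    visit_id: str
    label: str
    order_index: int
    allowed_sample_types: tuple[str, ...] = ()


@dataclass(frozen=True)
class SampleType:
    code: str
    label: str


@dataclass(frozen=True)
class StudyConfig:
    subject_format: PseudonymFormat
    biosample_format: PseudonymFormat
    identity_schema: IdentityFieldSchema
    schedule: tuple[VisitDefinition, ...]
    sample_types: tuple[SampleType, ...]
    block_threshold: float = 0.98
    review_threshold: float = 0.85
    backup_interval_days: int = 1
    expected_capacity: int = 100_000
    lock_stale_hours: float = 12.0
    rng_seed: int | None = None

    def visit_map(self) -> dict[str, VisitDefinition]:
        return {v.visit_id: v for v in self.schedule}

    def sample_type_map(self) -> dict[str, SampleType]:
        return {s.code: s for s in self.sample_types}

    def validate(self) -> list[str]:
        issues: list[str] = []
        issues += self.subject_format.validate()
        issues += self.biosample_format.validate()
        issues += self.identity_schema.validate()
        if self.subject_format.scope != "subject":
            issues.append("subject_format must have scope 'subject'")
        if self.biosample_format.scope != "biosample":
            issues.append("biosample_format must have scope 'biosample'")
        if (
            self.subject_format.prefix == self.biosample_format.prefix
            and self.subject_format.site_code == self.biosample_format.site_code
        ):
            issues.append(
                "subject and biosample formats must be distinguishable "
                "(different prefix or site_code)"
            )
        vids = [v.visit_id for v in self.schedule]
        if len(set(vids)) != len(vids):
            issues.append("schedule: visit_id values must be unique")
        orders = [v.order_index for v in self.schedule]
        if any(b <= a for a, b in zip(orders, orders[1:])):
            issues.append("schedule: order_index must be strictly increasing")
        codes = {s.code for s in self.sample_types}
        if len(codes) != len(self.sample_types):
            issues.append("sample_types: codes must be unique")
        for v in self.schedule:
            for st in v.allowed_sample_types:
                if st not in codes:
                    issues.append(
                        f"visit {v.visit_id!r}: allowed sample type {st!r} "
                        "is not declared in sample_types"
                    )
        if not (0.0 <= self.review_threshold <= 1.0 and 0.0 <= self.block_threshold <= 1.0):
            issues.append("linkage thresholds must lie in [0, 1]")
        if self.block_threshold < self.review_threshold:
            issues.append(
                f"block_threshold ({self.block_threshold}) must be >= "
                f"review_threshold ({self.review_threshold})"
            )
        if not isinstance(self.backup_interval_days, int) or self.backup_interval_days < 1:
            issues.append("backup_interval_days must be a positive integer")
        return issues

    def check(self) -> "StudyConfig":
        """Raise with every violation, warn on soft limits, return self."""
        issues = self.validate()
        if issues:
            raise ConfigValidationError(issues)
        for fmt in (self.subject_format, self.biosample_format):
            if fmt.capacity < self.expected_capacity:
                warnings.warn(
                    f"{fmt.scope} pseudonym space ({fmt.capacity}) is below the "
                    f"expected registry capacity ({self.expected_capacity})",
                    stacklevel=2,
                )
        return self


# ---------------------------------------------------------------------------
# serialization


def to_dict(cfg: StudyConfig) -> dict:
    """Canonical plain-data form (YAML/JSON-able, stable key order)."""
    d = dataclasses.asdict(cfg)

    def listify(x):
        if isinstance(x, tuple):
            return [listify(i) for i in x]
        if isinstance(x, dict):
            return {k: listify(v) for k, v in x.items()}
        return x

    return listify(d)


def dumps_config(cfg: StudyConfig) -> str:
    return yaml.safe_dump(to_dict(cfg), sort_keys=False, allow_unicode=True)


def save_config(cfg: StudyConfig, path: str | Path) -> None:
    Path(path).write_text(dumps_config(cfg), encoding="utf-8")


def _from_dict(d: dict) -> StudyConfig:
    try:
        schema = IdentityFieldSchema(
            fields=tuple(
                IdentityField(
                    name=f["name"],
                    kind=f["kind"],
                    required=bool(f.get("required", True)),
                    enum_values=tuple(f.get("enum_values") or ()),
                    match_weight=float(f.get("match_weight", 1.0)),
                )
                for f in d["identity_schema"]["fields"]
            )
        )
        cfg = StudyConfig(
            subject_format=PseudonymFormat(**d["subject_format"]),
            biosample_format=PseudonymFormat(**d["biosample_format"]),
            identity_schema=schema,
            schedule=tuple(
                VisitDefinition(
                    visit_id=v["visit_id"],
                    label=v["label"],
                    order_index=int(v["order_index"]),
                    allowed_sample_types=tuple(v.get("allowed_sample_types") or ()),
                )
                for v in d["schedule"]
            ),
            sample_types=tuple(
                SampleType(code=s["code"], label=s["label"]) for s in d["sample_types"]
            ),
            block_threshold=float(d.get("block_threshold", 0.98)),
            review_threshold=float(d.get("review_threshold", 0.85)),
            backup_interval_days=int(d.get("backup_interval_days", 1)),
            expected_capacity=int(d.get("expected_capacity", 100_000)),
            lock_stale_hours=float(d.get("lock_stale_hours", 12.0)),
            rng_seed=d.get("rng_seed"),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigParseError(f"configuration structure invalid: {exc!r}") from exc
    return cfg.check()


def loads_config(text: str) -> StudyConfig:
    try:
        d = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigParseError(f"not valid YAML: {exc}") from exc
    if not isinstance(d, dict):
        raise ConfigParseError("configuration file must contain a YAML mapping")
    return _from_dict(d)


def load_config(path: str | Path) -> StudyConfig:
    """Load and fully validate a study configuration file."""
    p = Path(path)
    if not p.exists():
        raise ConfigParseError(f"no such config file: {p}")
    return loads_config(p.read_text(encoding="utf-8"))


def default_config() -> StudyConfig:
    """A documented, valid demo configuration (quickstart, tests, fixtures).

    Two visits (baseline + one follow-up), three biosample types, and the
    canonical four identity attributes. The sex field carries a reduced
    linkage weight: with only a handful of possible values it contributes
    little evidence of identity, and keeping non-date weights low preserves
    the guarantee that no record pair can reach the review threshold on
    names alone (which is what makes date-of-birth blocking exact).
    """
    return StudyConfig(
        subject_format=PseudonymFormat(
            prefix="SUB", site_code="BER", body_length=6, scope="subject"
        ),
        biosample_format=PseudonymFormat(
            prefix="BIO", site_code="BER", body_length=6, scope="biosample"
        ),
        identity_schema=IdentityFieldSchema(
            fields=(
                IdentityField(name="first_name", kind="text", required=True, match_weight=1.0),
                IdentityField(name="last_name", kind="text", required=True, match_weight=1.0),
                IdentityField(name="date_of_birth", kind="date", required=True, match_weight=1.0),
                IdentityField(
                    name="sex",
                    kind="enum",
                    required=True,
                    enum_values=("F", "M", "X"),
                    match_weight=0.25,
                ),
            )
        ),
        schedule=(
            VisitDefinition(
                visit_id="BL",
                label="Baseline",
                order_index=0,
                allowed_sample_types=("SER", "PLA", "SWB"),
            ),
            VisitDefinition(
                visit_id="FU1",
                label="Follow-up 1",
                order_index=1,
                allowed_sample_types=("SER", "SWB"),
            ),
        ),
        sample_types=(
            SampleType(code="SER", label="Serum"),
            SampleType(code="PLA", label="Plasma"),
            SampleType(code="SWB", label="Swab"),
        ),
    ).check()
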