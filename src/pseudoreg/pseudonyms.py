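"""Pseudonym generation and validation.

A pseudonym is the only token that ever travels with downstream data or
printed biosample labels, so two properties matter above all:

* **collision freedom** — generation against the set of already-issued
  values never returns a member of that set, and detects a full format
  space instead of looping;
* **transcription safety** — a trailing ISO 7064 MOD 37-2 check character
  over ``prefix + site_code + body`` detects 100% of single-character
  substitutions and virtually all adjacent transpositions, so a mistyped
  ID is reported as a *likely transcription error* rather than resolving
  to nothing (or worse, to someone else).

Bodies are drawn at random by default: sequential counters would leak
enrolment order through any exported artifact. A ``sequential`` mode
remains available for migrating registries that were numbered that way.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .config import ISO7064_CHARSET, PseudonymFormat
from .errors import CapacityExhaustedError, CharacterOutOfAlphabetError

# Check characters come from the charset extended with '*', per ISO 7064
# MOD 37-2 (37 possible remainders need 37 symbols).
CHECK_CHARSET = ISO7064_CHARSET + "*"

_ISO_VALUE = {c: i for i, c in enumerate(CHECK_CHARSET)}


def _iso_checksum(text: str) -> int:
    """Running MOD 37-2 checksum; a full value with check char yields 1."""
    check = 0
    for ch in text:
        try:
            v = _ISO_VALUE[ch]
        except KeyError:
            raise CharacterOutOfAlphabetError(
                f"character {ch!r} not representable in ISO 7064 MOD 37-2"
            ) from None
        check = (2 * check + v) % 37
    return check


def compute_check_character(body: str) -> str:
    """ISO 7064 MOD 37-2 check character for *body* (uppercase A-Z / digits).

    The returned character (``0-9A-Z*``) makes ``_iso_checksum(body + c) == 1``.
    """
    if not body:
        raise CharacterOutOfAlphabetError("check character of an empty string is undefined")
    if "*" in body:
        raise CharacterOutOfAlphabetError("'*' may only appear as a check character")
    return CHECK_CHARSET[(1 - 2 * _iso_checksum(body)) % 37]


def verify_check_character(text: str) -> bool:
    """True iff the final character of *text* is the valid check character."""
    if len(text) < 2:
        return False
    try:
        return _iso_checksum(text) == 1
    except CharacterOutOfAlphabetError:
        return False


@dataclass(frozen=True)
class Pseudonym:
    value: str
    scope: str


@dataclass(frozen=True)
class ValidationResult:
    """Outcome of structural + check-character validation.

    ``structural_defects`` and ``check_mismatch`` are reported separately:
    a structurally sound value with a bad check character is almost
    certainly a transcription error of a real pseudonym, which callers
    (e.g. depseudonymization) treat differently from garbage input.
    """

    ok: bool
    structural_defects: tuple[str, ...] = ()
    check_mismatch: bool = False

    @property
    def defects(self) -> tuple[str, ...]:
        out = list(self.structural_defects)
        if self.check_mismatch:
            out.append("check character does not verify (suspected transcription error)")
        return tuple(out)


def render(fmt: PseudonymFormat, body: str) -> str:
    parts = [fmt.prefix, fmt.site_code, body]
    if fmt.check_scheme == "iso7064_mod37_2":
        parts.append(compute_check_character(fmt.prefix + fmt.site_code + body))
    return fmt.separator.join(parts)


def validate_pseudonym(value: str, fmt: PseudonymFormat) -> ValidationResult:
    """Total structural + check validation; never raises."""
    defects: list[str] = []
    n_parts = 4 if fmt.check_scheme == "iso7064_mod37_2" else 3
    parts = value.split(fmt.separator)
    if len(parts) != n_parts:
        return ValidationResult(
            ok=False,
            structural_defects=(
                f"expected {n_parts} '{fmt.separator}'-separated parts, got {len(parts)}",
            ),
        )
    prefix, site, body = parts[0], parts[1], parts[2]
    if prefix != fmt.prefix:
        defects.append(f"prefix {prefix!r} != expected {fmt.prefix!r}")
    if site != fmt.site_code:
        defects.append(f"site code {site!r} != expected {fmt.site_code!r}")
    if len(body) != fmt.body_length:
        defects.append(f"body length {len(body)} != expected {fmt.body_length}")
    bad = sorted(set(c for c in body if c not in fmt.alphabet))
    if bad:
        defects.append(f"body characters {bad} outside the configured alphabet")
    check_mismatch = False
    if fmt.check_scheme == "iso7064_mod37_2":
        check = parts[3]
        if len(check) != 1 or check not in CHECK_CHARSET:
            defects.append(f"check character {check!r} is not a single ISO 7064 symbol")
        elif not defects:
            check_mismatch = not verify_check_character(prefix + site + body + check)
    return ValidationResult(
        ok=not defects and not check_mismatch,
        structural_defects=tuple(defects),
        check_mismatch=check_mismatch,
    )


def _body_from_index(fmt: PseudonymFormat, index: int) -> str:
    chars = []
    for _ in range(fmt.body_length):
        index, rem = divmod(index, len(fmt.alphabet))
        chars.append(fmt.alphabet[rem])
    return "".join(reversed(chars))


_MAX_RANDOM_RETRIES = 64


def generate_pseudonym(
    fmt: PseudonymFormat,
    existing: set[str],
    rng: random.Random,
) -> Pseudonym:
    """Generate a fresh pseudonym not present in *existing* (full rendered values).

    Bounded rejection sampling (64 draws) followed by a deterministic
    lexicographic scan of the body space guarantees termination: near
    capacity the scan finds the free slot, at capacity it raises
    :class:`CapacityExhaustedError` instead of looping forever.

    Deterministic: the same rng state and existing set always produce the
    same value, so seeded runs are reproducible.
    """
    if fmt.generation_mode == "sequential":
        for idx in range(fmt.capacity):
            value = render(fmt, _body_from_index(fmt, idx))
            if value not in existing:
                return Pseudonym(value=value, scope=fmt.scope)
        raise CapacityExhaustedError(
            f"{fmt.scope} pseudonym space exhausted ({fmt.capacity} values)"
        )
    for _ in range(_MAX_RANDOM_RETRIES):
        body = "".join(rng.choice(fmt.alphabet) for _ in range(fmt.body_length))
        value = render(fmt, body)
        if value not in existing:
            return Pseudonym(value=value, scope=fmt.scope)
    # dense space: fall back to an exhaustive ordered scan
    for idx in range(fmt.capacity):
        value = render(fmt, _body_from_index(fmt, idx))
        if value not in existing:
            return Pseudonym(value=value, scope=fmt.scope)
    raise CapacityExhaustedError(
        f"{fmt.scope} pseudonym space exhausted ({fmt.capacity} values)"
    )
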