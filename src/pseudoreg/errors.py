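"""Exception hierarchy.

Every error a caller is expected to handle programmatically has its own
class; the CLI maps them onto stable exit codes (1 user/validation,
2 lock conflict, 3 data corruption).
"""

from __future__ import annotations


class PseudoregError(Exception):
    """Base class for all package errors."""


class ConfigValidationError(PseudoregError):
    """A study configuration violates one or more invariants.

    Carries *all* violations found, not just the first.
    """

    def __init__(self, issues: list[str]):
        self.issues = list(issues)
        super().__init__(
            "invalid study configuration:\n" + "\n".join(f"  - {i}" for i in self.issues)
        )


class ConfigParseError(PseudoregError):
    """The configuration file could not be parsed at all."""


class CapacityExhaustedError(PseudoregError):
    """The pseudonym format space has no free values left."""


class CharacterOutOfAlphabetError(PseudoregError):
    """A character fed to the check-character computation is not representable."""


class SchemaViolationError(PseudoregError):
    """An identity record violates the configured identity-field schema."""

    def __init__(self, fields: list[str], message: str | None = None):
        self.fields = list(fields)
        super().__init__(message or f"schema violation in fields: {', '.join(self.fields)}")


class NoComparableFieldsError(PseudoregError):
    """Two identities share no scorable field."""


class EmptyQueryError(PseudoregError):
    """A search query contained no usable field."""


class MissingSearchError(PseudoregError):
    """Registration attempted without a prior search against the current state."""


class StaleSearchError(PseudoregError):
    """The registry changed between the search and the registration attempt."""


class DuplicateBlockedError(PseudoregError):
    """Registration refused because linkage found an (unoverridden) match."""

    def __init__(self, message: str, candidates=None):
        self.candidates = candidates or []
        super().__init__(message)


class QualityError(PseudoregError):
    """Identity failed data-quality checks with error-level issues."""

    def __init__(self, issues):
        self.issues = list(issues)
        super().__init__(
            "identity failed quality checks:\n"
            + "\n".join(f"  - [{i.field}] {i.message}" for i in self.issues)
        )


class UnknownSubjectError(PseudoregError):
    """Biosample registration referenced a subject pseudonym not in the registry."""


class ScheduleViolationError(PseudoregError):
    """A (visit, sample type) combination is not allowed by the study schedule."""


class NotFoundError(PseudoregError):
    """Pseudonym not present in the registry."""


class TranscriptionSuspectedError(PseudoregError):
    """Pseudonym not found AND its check character does not verify.

    Distinct from :class:`NotFoundError`: the value was almost certainly
    mistyped or mis-scanned, so the caller should re-read the label rather
    than conclude the record does not exist.
    """


class MalformedFileError(PseudoregError):
    """A bulk-import file could not be parsed."""


class PseudonymCollisionError(PseudoregError):
    """Restore-mode import found colliding pseudonyms; the file is rejected whole."""

    def __init__(self, message: str, collisions=None):
        self.collisions = collisions or []
        super().__init__(message)


class LockHeldError(PseudoregError):
    """Another writer holds the registry lock."""

    def __init__(self, holder: str, acquired_at: str):
        self.holder = holder
        self.acquired_at = acquired_at
        super().__init__(
            f"registry is locked for writing by {holder!r} since {acquired_at}"
        )


class StaleLockError(PseudoregError):
    """The lock file is older than the stale timeout; takeover requires an explicit flag."""

    def __init__(self, holder: str, acquired_at: str):
        self.holder = holder
        self.acquired_at = acquired_at
        super().__init__(
            f"registry lock held by {holder!r} since {acquired_at} looks stale; "
            "pass takeover=True (CLI: --take-over) to break it explicitly"
        )


class CorruptRegistryError(PseudoregError):
    """Persistent registry state failed an integrity check on load."""
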