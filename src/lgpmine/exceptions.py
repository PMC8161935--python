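"""Exception hierarchy shared across the package."""


class LgpmineError(Exception):
    """Base class for all package errors."""


class InvalidInputError(LgpmineError, ValueError):
    """A value passed to an operation violates its preconditions."""


class ConfigurationError(LgpmineError, ValueError):
    """An evolution or split configuration is unusable."""


class FormatError(LgpmineError, ValueError):
    """A file does not follow the expected on-disk format."""


class SchemaVersionError(FormatError):
    """A model archive was written by an incompatible schema version."""


class FeatureNotFoundError(LgpmineError, KeyError):
    """A feature name is absent from the collection's universe."""

    def __init__(self, name: str, candidates: list[str]):
        self.name = name
        self.candidates = candidates
        hint = f"; did you mean one of {candidates}?" if candidates else ""
        super().__init__(f"unknown feature {name!r}{hint}")


class GenerationError(LgpmineError, RuntimeError):
    """The synthetic-data generator could not satisfy its constraints."""
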