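"""Exception hierarchy for gochem."""


class GochemError(Exception):
    """Base class for all gochem errors."""


class ResolutionError(GochemError):
    """An identifier does not resolve to a term or registered relation."""


class ConfigurationError(GochemError):
    """A rule or relation configuration is invalid."""


class OboParseError(GochemError):
    """Malformed OBO input.

    Carries the 1-based line number of the offending line when known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class OboWriteError(GochemError):
    """The in-memory ontology cannot be serialized to OBO 1.2."""


class MissingChemicalError(GochemError):
    """A requested chemical class is absent from the chemical ontology.

    Mirrors the curation protocol: missing entities must be requested from
    the chemical ontology before a term can be generated.
    """


class DuplicateTermError(GochemError):
    """A generated label already exists in the target ontology."""


class StaleInputError(GochemError):
    """A classification result does not cover the ontology being synced."""


class SyncConflictError(GochemError):
    """A sync report no longer matches the ontology it is applied to."""
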