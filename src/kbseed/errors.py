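"""Exception hierarchy for seed building and serving."""


class KbseedError(Exception):
    """Base class for all package errors."""


class SetupError(KbseedError):
    """A setup document could not be parsed or refers to unknown classes."""


class ConfigurationError(KbseedError):
    """A resource/selector configuration is unusable (bad XPath, unknown
    column, missing query text...)."""


class ValidationError(KbseedError):
    """A model violates a structural invariant in a way that prevents use."""


class FetchError(KbseedError):
    """A source could not be fetched; carries the offending URI."""

    def __init__(self, uri: str, message: str, status: int | None = None):
        super().__init__(f"{message} [{uri}]")
        self.uri = uri
        self.status = status


class BuildError(KbseedError):
    """Triplification failed (URI collision, unresolvable predicate...)."""


class CycleError(ValidationError):
    """Resource dependency graph contains a cycle."""

    def __init__(self, members: list[str]):
        super().__init__("dependency cycle among resources: " + " -> ".join(members))
        self.members = members


class ClientError(KbseedError):
    """A bad API request (unknown prefix, bad format token, bad route).

    ``status`` mirrors the HTTP status the server layer should emit.
    """

    def __init__(self, message: str, status: int = 400):
        super().__init__(message)
        self.status = status


class FederationError(KbseedError):
    """A SERVICE endpoint could not be reached or answered with an error."""
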