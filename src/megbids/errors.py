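"""Exception hierarchy for the megbids package."""


class MegBidsError(Exception):
    """Base class for all megbids errors."""


class FilenameError(MegBidsError):
    """A filename does not match the entity grammar.

    Carries a single machine-readable ``reason`` code, one of
    ``bad-order``, ``bad-key``, ``bad-label``, ``bad-suffix``, ``no-match``.
    """

    def __init__(self, reason: str, message: str):
        super().__init__(message)
        self.reason = reason


class ContractError(MegBidsError):
    """A precondition of an operation was violated (e.g. a missing required entity)."""


class AmbiguityError(MegBidsError):
    """Two applicable sidecars cannot be ordered (same depth, same specificity)."""


class ResolutionError(MegBidsError):
    """Metadata inheritance could not be resolved (e.g. unreadable sidecar)."""


class GeometryError(MegBidsError):
    """Degenerate fiducial geometry (collinear landmarks)."""


class CurationError(MegBidsError):
    """A curation manifest is invalid or curation failed."""


class FixtureError(MegBidsError):
    """Fixture generation or mutation could not proceed."""
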