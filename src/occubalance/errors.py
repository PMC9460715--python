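"""Exception hierarchy for the pipeline."""


class OccubalanceError(Exception):
    """Base class for all package errors."""


class FormatError(OccubalanceError):
    """A file does not conform to its declared annotation format."""


class ValidationError(OccubalanceError):
    """An in-memory object violates a structural invariant."""


class PlanningError(OccubalanceError):
    """A balance plan cannot be constructed from the given counts."""


class PoolError(OccubalanceError):
    """Component-pool loading or sampling failed (e.g. empty category)."""


class SynthesisError(OccubalanceError):
    """Geometric placement or crop synthesis failed after retries."""


class PackingError(OccubalanceError):
    """A synthetic crop cannot be placed on any base image."""


class FixtureError(OccubalanceError):
    """A fixture specification cannot be realized."""
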