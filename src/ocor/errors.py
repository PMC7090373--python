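"""Exception hierarchy for the oCOR pipeline.

Every error raised by the library derives from :class:`OcorError` so callers
can catch one type at the pipeline boundary; specific subclasses distinguish
missing data (recoverable per-timepoint) from physically infeasible sessions.
"""


class OcorError(Exception):
    """Base class for all oCOR errors."""


class MissingDataError(OcorError):
    """Required data (e.g. a baseline sample) is absent from the session."""


class MissingTimepointError(MissingDataError):
    """No COHb sample exists within tolerance of the requested time."""


class InvalidRiseError(OcorError):
    """ΔCOHb% at the requested time is zero or negative; tHb-mass undefined."""


class InfeasibleSessionError(OcorError):
    """Modelled CO losses meet or exceed the administered dose."""


class ConfigurationError(OcorError):
    """Inconsistent configuration (e.g. STPD requested without ambient data)."""


class SchemaError(OcorError):
    """Input file violates the session-table schema; message names row/column."""
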