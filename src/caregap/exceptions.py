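"""Exception hierarchy.

Validation failures (bad user input, incoherent probabilities, infeasible
transfer plans) raise :class:`ValidationError`; missing or malformed
configuration (absent rate cells, unknown stratifiers, bad pipeline configs)
raises :class:`ConfigurationError`.  The CLI maps the two onto distinct exit
codes.
"""


class CareGapError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(CareGapError, ValueError):
    """Input data or parameters violate a documented invariant."""


class ConfigurationError(CareGapError):
    """A required configuration element (e.g. a rate cell) is missing."""


class PipelineError(CareGapError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
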