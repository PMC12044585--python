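"""Exception hierarchy shared across the package."""


class CausalAttribError(Exception):
    """Base class for all package errors."""


class SchemaError(CausalAttribError):
    """An input table is missing a required column."""


class ParseError(CausalAttribError):
    """A cell in an input table could not be interpreted."""


class ConfigError(CausalAttribError):
    """An invalid configuration (duplicate names, bad ranges, ...)."""


class UndefinedProbabilityError(CausalAttribError):
    """A probability of causation is not identified from the data.

    Raised when a conditioning set has zero weight, when PN is requested
    with p1 = 0, when PS is requested with p0 = 1, or when a Bayesian
    network query reaches a conditional-probability cell with no support.
    """


class ThresholdNotFoundError(CausalAttribError):
    """No candidate cutpoint satisfies the exception allowance."""


class PipelineError(CausalAttribError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
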