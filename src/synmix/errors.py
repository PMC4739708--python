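"""Exception hierarchy shared by all pipeline stages."""


class SynmixError(Exception):
    """Base class for all package errors."""


class ParameterError(SynmixError, ValueError):
    """A parameter violates its documented invariant."""


class InsufficientDataError(SynmixError, ValueError):
    """Too few observations for the requested computation."""


class MissingDataError(SynmixError, ValueError):
    """A required field (Ra, Vm, ...) is absent; QC must not silently pass."""


class DegenerateInputError(SynmixError, ValueError):
    """Zero-variance or otherwise degenerate input to a statistical test."""


class ClassExhaustedError(SynmixError, RuntimeError):
    """Without-replacement sampling ran out of connections in an outcome class."""

    def __init__(self, outcome: str):
        self.outcome = outcome
        super().__init__(
            f"outcome class {outcome!r} exhausted before the stop threshold was reached"
        )


class SchemaError(SynmixError, ValueError):
    """An input table does not conform to the expected CSV schema."""
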