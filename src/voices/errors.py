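"""Exception types shared across the pipeline."""


class VoicesError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(VoicesError):
    """A spec/config object violates its invariants (names the offending field)."""


class SchemaError(VoicesError):
    """An input table does not match the declared schema."""


class UnknownCountryError(VoicesError):
    """A country is not present in the shipped UN-region mapping table."""


class DegenerateDataError(VoicesError):
    """A statistic cannot be computed on the given data (e.g. empty cohort)."""


class StageError(VoicesError):
    """A pipeline stage failed; carries the stage name for context."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
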