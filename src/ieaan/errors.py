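"""Exception hierarchy shared across the package."""


class IeaanError(Exception):
    """Base class for all package-specific errors."""


class FormatError(IeaanError):
    """A file or table violates the expected on-disk dialect."""


class DomainError(IeaanError):
    """A value lies outside its mathematical domain (e.g. negative expression)."""


class ConsistencyError(IeaanError):
    """Two inputs that must agree (matrix vs metadata) do not."""


class DegenerateInputError(IeaanError):
    """An input is structurally valid but too small/degenerate for the operation."""


class ContractError(IeaanError):
    """A caller violated an interface precondition (e.g. dimension mismatch)."""


class DivergenceError(IeaanError):
    """Training produced a non-finite loss."""


class ConfigurationError(IeaanError):
    """A configuration object violates its invariants."""


class PipelineError(IeaanError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
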