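"""Exception hierarchy shared across the package."""


class GpcrEvalError(Exception):
    """Base class for all package-specific errors."""


class PdbParseError(GpcrEvalError):
    """A coordinate file could not be parsed; the message names the line."""


class EmptySelectionError(GpcrEvalError):
    """A distance query matched no atoms (e.g. Gly under a side-chain filter)."""


class ValidationError(GpcrEvalError):
    """An input object or configuration violates a documented invariant."""


class GenerationError(GpcrEvalError):
    """A synthetic-data request is geometrically or combinatorially infeasible."""
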