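"""Exception hierarchy for the CSSI pipeline.

The CLI maps these onto exit codes: schema problems exit 2, fitting
degeneracies exit 3, everything else exits 1.
"""


class CSSIError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CSSIError):
    """Invalid cutoff table, reference table, or generator parameters."""


class SchemaError(CSSIError):
    """Malformed input file: wrong header, unparseable cell, unknown token."""


class CodingError(CSSIError):
    """A worker record cannot be coded (e.g. unknown sex value)."""


class FittingError(CSSIError):
    """Penalized fit cannot proceed (single-class outcome, non-convergence)."""


class StabilityError(CSSIError):
    """Bootstrap resampling could not produce usable resamples."""
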