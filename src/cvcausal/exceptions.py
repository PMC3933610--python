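"""Exception hierarchy.

All package errors derive from :class:`CvCausalError` so callers can catch
one base class; the subclasses distinguish bad user input from degenerate
data from mis-specified analyses.
"""


class CvCausalError(Exception):
    """Base class for all errors raised by cvcausal."""


class InputError(CvCausalError):
    """Malformed or unusable input data (files, series, tables)."""


class ConfigurationError(CvCausalError):
    """Invalid run configuration (missing columns, bad method set)."""


class SpecificationError(CvCausalError):
    """Invalid embedding or simulation specification."""


class DegenerateInputError(CvCausalError):
    """Input that makes the requested quantity undefined (e.g. constant
    series for normalization, zero denominator for a causality ratio)."""


class InsufficientDataError(CvCausalError):
    """Not enough samples for the requested operation (embedding rows,
    admissible neighbors, window length)."""


class FitError(CvCausalError):
    """Numerical failure of a model fit (rank deficiency etc.)."""
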