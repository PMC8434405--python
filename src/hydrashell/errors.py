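"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: ConfigError -> 2, InputError (and its
format/topology subclasses) -> 3, AnalysisError -> 4.
"""


class HydrashellError(Exception):
    """Base class for all package errors."""


class ParameterError(HydrashellError, ValueError):
    """A function argument violates its contract (negative rate, empty selection, ...)."""


class ConfigError(HydrashellError, ValueError):
    """An analysis configuration file failed validation."""


class InputError(HydrashellError):
    """Input data could not be read or is internally inconsistent."""


class FormatError(InputError):
    """A structure/trajectory file is malformed or inconsistent (e.g. atom-count mismatch)."""


class TopologyError(InputError):
    """The topology lacks information an operation needs (bonds, water geometry, flags)."""


class UnsupportedBoxError(ParameterError):
    """Only orthorhombic periodic boxes are supported."""


class AnalysisError(HydrashellError, RuntimeError):
    """An estimator could not produce a result from otherwise valid input."""
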