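"""Exception hierarchy shared across the pipeline.

``InputError`` maps to CLI exit code 2, ``NumericalError`` to exit code 3.
"""


class AmoplsError(Exception):
    """Base class for all package errors."""


class InputError(AmoplsError, ValueError):
    """Invalid or inconsistent user input (files, tables, factor labels)."""


class ConfigError(AmoplsError, ValueError):
    """Invalid configuration (thresholds, simulation settings)."""


class LipidParseError(InputError):
    """A lipid shorthand name has no parsable carbons:double-bond field."""


class NumericalError(AmoplsError, RuntimeError):
    """Numerical failure (non-convergence, degenerate model)."""
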