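"""Exception hierarchy shared across the toolkit.

Error classes are grouped so the command-line layer can map them to stable
exit codes: design/configuration problems, file-format problems, statistical
degeneracies, and I/O failures.
"""


class CnScreenError(Exception):
    """Base class for all errors raised by this package."""


class DesignError(CnScreenError, ValueError):
    """Invalid screen-design arithmetic input (counts, MOI, coverage)."""


class ConfigError(CnScreenError, ValueError):
    """Invalid simulation or pipeline configuration."""


class FormatError(CnScreenError, ValueError):
    """Structurally invalid input table (duplicate ids, missing columns)."""


class ParseError(FormatError):
    """Unparseable cell in an input file; message carries row/column context."""


class NormalizationError(CnScreenError, ValueError):
    """Size-factor estimation failed (e.g. empty reference sgRNA set)."""


class NullConstructionError(CnScreenError, ValueError):
    """Non-targeting resampling null could not be built."""


class CallingError(CnScreenError, ValueError):
    """Essentiality calling is missing a required ingredient."""


class DegenerateInputError(CnScreenError, ValueError):
    """Statistical test input is degenerate (e.g. zero variance off-target)."""


class UndefinedCorrelationError(DegenerateInputError):
    """Pearson correlation undefined because one vector has zero variance."""
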