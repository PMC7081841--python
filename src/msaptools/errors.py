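"""Exception hierarchy shared across the package.

Exit-code mapping used by the command-line interface:
0 success, 2 usage/configuration, 3 file format, 4 data content.
"""


class MsapError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigurationError(MsapError):
    """Invalid parameter or configuration value (usage error)."""

    exit_code = 2


class UsageError(ConfigurationError):
    """Operation called with arguments that can never be valid."""


class InfeasiblePanelError(ConfigurationError):
    """Requested locus panel cannot fit in the size range at the given spacing."""


class FormatError(MsapError):
    """Malformed input file: missing columns, bad enum labels, unparsable rows."""

    exit_code = 3


class DataError(MsapError):
    """Well-formed input whose content violates a domain invariant."""

    exit_code = 4


class DegenerateDataError(DataError):
    """Data with no variance where a test statistic is undefined."""
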