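"""Exception hierarchy.

Two broad families map onto the CLI exit codes: configuration problems
(bad parameters, missing models; exit code 2) and data problems
(malformed files, grid mismatches, degenerate designs; exit code 3).
"""


class SynchroFluorError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SynchroFluorError):
    """Invalid configuration: missing fluorophore model, bad parameter, …"""

    exit_code = 2


class InvalidParameterError(ConfigurationError):
    """A numeric parameter violates its constraint (e.g. fwhm <= 0)."""


class DataError(SynchroFluorError):
    """Invalid or inconsistent data."""

    exit_code = 3


class GridMismatchError(DataError):
    """A wavelength offset is not representable on the scan grids, or the
    requested diagonal does not intersect the measured EEM."""


class DegenerateDesignError(DataError):
    """A regression/summary was requested on a design with no information
    (identical concentrations, fewer than two replicates, …)."""


class ParseError(DataError):
    """A spectrum/EEM file violates the documented CSV dialect."""
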