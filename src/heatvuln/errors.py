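"""Exception hierarchy.

Every error carries an ``exit_code`` used by the CLI: 1 for configuration /
validation problems, 2 for data problems discovered while processing.
"""


class HeatvulnError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class SchemaError(HeatvulnError):
    """An input file lacks a mandatory attribute or column."""

    exit_code = 2


class EmptyInputError(HeatvulnError):
    """An input collection (layer, raster list, table) is empty."""

    exit_code = 2


class GeoreferenceError(HeatvulnError):
    """A raster or vector layer is missing usable georeferencing."""

    exit_code = 2


class UnsupportedFormatError(HeatvulnError):
    """The file format or band layout is not supported."""

    exit_code = 2


class AlignmentError(HeatvulnError):
    """Two layers do not share a grid geometry or reference system."""

    exit_code = 2


class ResolutionError(HeatvulnError):
    """Raster resolution is too coarse for the polygon layer."""

    exit_code = 1


class DegenerateVarianceError(HeatvulnError):
    """A column is constant where non-zero dispersion is required."""

    exit_code = 2


class InstabilityError(HeatvulnError):
    """The leading principal component is not unique."""

    exit_code = 2


class UnknownClassError(HeatvulnError):
    """A land-cover code is outside the configured classification."""

    exit_code = 2


class OrientationError(HeatvulnError):
    """Indicator orientation metadata is absent or inconsistent."""

    exit_code = 1


class ConfigError(HeatvulnError):
    """A run configuration is invalid or references missing inputs."""

    exit_code = 1


class ParseError(HeatvulnError):
    """A record could not be parsed; the message names the row."""

    exit_code = 2
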