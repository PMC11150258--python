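"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: usage errors exit 2 (argparse),
:class:`DataError` exits 3, :class:`NumericalError` exits 4.
"""


class SoftSensorError(Exception):
    """Base class for package errors."""


class DataError(SoftSensorError):
    """Malformed, incompatible or missing input data."""


class SimulationError(SoftSensorError):
    """The process simulator produced an invalid state."""


class NumericalError(SoftSensorError):
    """A linear solve or other numerical routine failed."""


class WindowExhaustedError(SoftSensorError):
    """A moving window was requested past the end of the database."""
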