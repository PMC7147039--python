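"""Exception hierarchy shared across the pipeline.

The CLI maps these onto exit codes: ConfigError -> 2, DataError -> 3,
ConvergenceError -> 4.
"""


class CommuteExposureError(Exception):
    """Base class for all package errors."""


class ConfigError(CommuteExposureError):
    """Invalid configuration or specification."""


class DataError(CommuteExposureError):
    """Invalid, missing or degenerate input data."""


class RoutingError(DataError):
    """No route exists between the requested termini."""


class SnapError(DataError):
    """A point could not be snapped to the network within the allowed radius."""


class ConvergenceError(CommuteExposureError):
    """An iterative fit failed to converge."""


class SeparationError(ConvergenceError):
    """Complete separation in the conditional logistic likelihood."""
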