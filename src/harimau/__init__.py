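"""Two-layer population history toolkit.

Craniometric affinity via Q-mode correlation and NeighborNet split networks,
an ancient mitochondrial DNA read-to-haplogroup pipeline with deamination
modelling and contamination estimation, and radiocarbon calibration with
highest-density calendar ranges.
"""

from importlib import resources

__version__ = "0.1.0"


def data_path(name: str):
    """Return a path-like handle to a bundled data file."""
    return resources.files("harimau.data").joinpath(name)


class HarimauError(Exception):
    """Base class for all package errors."""


class ValidationError(HarimauError):
    """Malformed or inconsistent input (CLI exit code 2)."""


class InsufficientDataError(HarimauError):
    """Structurally valid input with too little data to proceed (CLI exit code 3)."""
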