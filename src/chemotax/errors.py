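"""Exception hierarchy for the chemotax pipeline."""


class ChemotaxError(Exception):
    """Base class for all chemotax errors."""


class ImageIOError(ChemotaxError):
    """An image file could not be read or written."""


class ValidationError(ChemotaxError):
    """An input violated a documented precondition or invariant."""


class PlateDetectionError(ChemotaxError):
    """No plate circle could be found with sufficient confidence.

    Callers can fall back to a manual geometry override
    (``--center/--radius`` on the CLI).
    """


class CapacityError(ChemotaxError):
    """The synthetic generator could not place all requested objects
    without overlap within the bounded number of retries."""


class DegenerateFitError(ChemotaxError):
    """A statistical fit is undefined for the given data
    (e.g. zero predictor variance, a single strain, rank deficiency)."""
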