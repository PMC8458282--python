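"""Exception hierarchy shared across the pipeline."""


class RdmorphError(Exception):
    """Base class for all rdmorph errors."""


class InvalidSpecError(RdmorphError, ValueError):
    """Phantom specification violates its invariants."""


class InvalidDesignError(RdmorphError, ValueError):
    """Cohort design violates its invariants (e.g. negative SD, n < 2)."""


class EmptyMaskError(RdmorphError, ValueError):
    """A layer mask contains no foreground pixels."""


class TopologyError(RdmorphError, ValueError):
    """Mask is not band-like: no two long boundaries could be recovered."""


class NoIntersectionError(RdmorphError, ValueError):
    """A calliper ray failed to intersect the opposite boundary curve."""


class NoDetachmentError(RdmorphError, ValueError):
    """No station exceeds the detachment height threshold."""


class ROIPlacementError(RdmorphError, ValueError):
    """An ROI does not fit inside its arc; the message names the offender."""


class CropError(RdmorphError, ValueError):
    """ROI polygon lies (partially) outside the image bounds."""


class ZeroReferenceError(RdmorphError, ZeroDivisionError):
    """Relative-thickness reference resolved to zero."""


class InsufficientDesignError(RdmorphError, ValueError):
    """Rate regression needs observations on at least three distinct days."""


class IncompleteDesignError(RdmorphError, ValueError):
    """Cohort is missing (region, day) cells; the message lists the gaps."""


class DegenerateVarianceError(RdmorphError, ValueError):
    """All groups have zero within-group variance; tests are undefined."""
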