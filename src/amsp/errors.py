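"""Exception and warning types shared across the package."""


class AmspError(Exception):
    """Base class for all package-specific errors."""


class InfeasibleGeometry(AmspError):
    """Side lengths or angles cannot form a real quadrilateral.

    Raised for non-positive lengths or when the radicand of the area
    formula is negative beyond rounding error, which signals mutually
    inconsistent measurements rather than an extreme but valid geometry.
    """


class DegenerateQuadrilateral(AmspError):
    """A diagonal has zero length, so the diagonal/angle system is undefined."""


class DegenerateQuadrilateralWarning(UserWarning):
    """The reconstructed quadrilateral self-intersects (crossed polygon).

    The closed-form area is still algebraically defined and is returned,
    but it no longer equals the area of a simple polygon.
    """


class MissingDenominator(AmspError):
    """A change rate was requested without a preoperative hexagon area."""


class InvalidLandmarks(AmspError):
    """Landmark set violates its invariants (coincident points or a
    self-intersecting hexagon)."""


class ZeroLengthRay(AmspError):
    """An angle was requested at a vertex with a coincident ray endpoint."""


class RejectionLimitExceeded(AmspError):
    """The cohort sampler failed to produce a valid patient within the
    configured number of redraws."""


class MissingField(AmspError):
    """A validation record lacks a required column."""
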