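"""Derive measured quantities from six midsagittal landmark coordinates.

The abdominal midsagittal outline is the hexagon T-X-P-S-Ai-As: anterosuperior
edge of T12 (T), xiphoid process (X), superior edge of the pubis (P),
anterosuperior corner of the sacrum (S), and the inferior and superior
osteotomy apexes (Ai, As).  All distances, the hinge angles beta and gamma,
and the hexagon/quadrilateral areas are computed from the coordinates alone,
so every output is invariant under rigid motions and reflections of the
landmark frame.  Coordinates are in cm, in an arbitrary rigid frame.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from shapely.geometry import Polygon

from .errors import InvalidLandmarks, ZeroLengthRay
from .geometry import QuadGeometry, chord_d, shoelace_area

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MidsagittalLandmarks:
    """Planar coordinates (cm) of the six midsagittal landmarks.

    Invariants: the six points are pairwise distinct and the hexagon in
    cyclic order T, X, P, S, Ai, As is a simple polygon.
    """

    x_pt: np.ndarray
    p_pt: np.ndarray
    s_pt: np.ndarray
    ai_pt: np.ndarray
    as_pt: np.ndarray
    t_pt: np.ndarray

    def __post_init__(self) -> None:
        for name in ("x_pt", "p_pt", "s_pt", "ai_pt", "as_pt", "t_pt"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
            if getattr(self, name).shape != (2,):
                raise InvalidLandmarks(f"{name} must be a planar point, got shape "
                                       f"{getattr(self, name).shape}")
        pts = self.hexagon()
        labels = ("T", "X", "P", "S", "Ai", "As")
        for i in range(6):
            for j in range(i + 1, 6):
                if np.allclose(pts[i], pts[j], atol=1e-12):
                    raise InvalidLandmarks(
                        f"landmarks {labels[i]} and {labels[j]} coincide at {pts[i]}"
                    )
        if not Polygon(pts).is_valid:
            raise InvalidLandmarks("hexagon T-X-P-S-Ai-As self-intersects")

    def hexagon(self) -> np.ndarray:
        """Vertices in the cyclic outline order T, X, P, S, Ai, As, shape (6, 2)."""
        return np.vstack([self.t_pt, self.x_pt, self.p_pt,
                          self.s_pt, self.ai_pt, self.as_pt])


@dataclass(frozen=True)
class MeasurementSet:
    """Every scalar measured from one landmark set.

    Lengths in cm, angles in degrees, areas (unsigned) in cm².  ``pa_s``
    and ``xa_i`` are reported as descriptive distances; they do not enter
    the area model.
    """

    d: float        # X-P
    ps: float       # P-S
    s_ai: float     # S-Ai
    b: float        # Ai-As
    as_t: float     # As-T
    xt: float       # X-T
    a: float        # P-Ai
    c: float        # X-As
    pa_s: float     # P-As (descriptive)
    xa_i: float     # X-Ai (descriptive)
    beta: float
    gamma: float
    s_hex: float        # hexagon T-X-P-S-Ai-As
    s_quad: float       # quadrilateral X-P-Ai-As
    s_tri_xast: float   # triangle X-As-T
    s_tri_psai: float   # triangle P-S-Ai


def angle_at(vertex, ray1_end, ray2_end, *, directed: bool = False) -> float:
    """Angle at ``vertex`` between the rays to the two endpoints, degrees.

    Undirected (default): the unsigned angle in [0, 180].  Directed: the
    counter-clockwise angle from ray 1 to ray 2 in [0, 360), which is what
    reflex hinge configurations require.
    """
    v = np.asarray(vertex, dtype=float)
    r1 = np.asarray(ray1_end, dtype=float) - v
    r2 = np.asarray(ray2_end, dtype=float) - v
    if np.linalg.norm(r1) == 0.0 or np.linalg.norm(r2) == 0.0:
        raise ZeroLengthRay(f"ray endpoint coincides with vertex {v}")
    ang = math.degrees(math.atan2(r1[0] * r2[1] - r1[1] * r2[0], float(r1 @ r2)))
    if directed:
        return ang % 360.0
    return abs(ang)


def _hinge_angles(landmarks: MidsagittalLandmarks) -> tuple[float, float]:
    """Hinge angles on the ventral (abdomen-interior) side, range (0, 360).

    The sign of the *hexagon's* shoelace area fixes which side is the
    interior.  The hexagon is always a simple polygon (validated), so its
    orientation is well defined even when the inner quadrilateral is
    crossed, and reflex hinges (> 180 deg) are represented correctly in
    either handedness of the landmark frame.
    """
    p, ai, as_, x = (landmarks.p_pt, landmarks.ai_pt, landmarks.as_pt, landmarks.x_pt)
    orient = shoelace_area(landmarks.hexagon())
    if orient == 0.0:
        raise InvalidLandmarks("hexagon T-X-P-S-Ai-As is degenerate (zero area)")
    if orient > 0:
        beta = angle_at(ai, as_, p, directed=True)
        gamma = angle_at(as_, x, ai, directed=True)
    else:
        beta = angle_at(ai, p, as_, directed=True)
        gamma = angle_at(as_, ai, x, directed=True)
    return beta, gamma


def measure(landmarks: MidsagittalLandmarks) -> MeasurementSet:
    """Compute all distances, hinge angles and areas from the landmarks."""
    x, p, s, ai, as_, t = (landmarks.x_pt, landmarks.p_pt, landmarks.s_pt,
                           landmarks.ai_pt, landmarks.as_pt, landmarks.t_pt)
    dist = lambda u, v: float(np.linalg.norm(u - v))
    beta, gamma = _hinge_angles(landmarks)
    return MeasurementSet(
        d=dist(x, p),
        ps=dist(p, s),
        s_ai=dist(s, ai),
        b=dist(ai, as_),
        as_t=dist(as_, t),
        xt=dist(x, t),
        a=dist(p, ai),
        c=dist(x, as_),
        pa_s=dist(p, as_),
        xa_i=dist(x, ai),
        beta=beta,
        gamma=gamma,
        s_hex=abs(shoelace_area(landmarks.hexagon())),
        s_quad=abs(shoelace_area([x, p, ai, as_])),
        s_tri_xast=abs(shoelace_area([x, as_, t])),
        s_tri_psai=abs(shoelace_area([p, s, ai])),
    )


def quad_measurement_to_geometry(
    meas: MeasurementSet, d_tolerance: float = 0.05
) -> QuadGeometry:
    """Bridge a measurement set to the model inputs (a, b, c, beta, gamma).

    As a consistency diagnostic, the chord implied by the five scalars is
    compared with the measured X-P distance; a relative discrepancy above
    ``d_tolerance`` is logged as a warning (the geometry is still returned).
    """
    geom = QuadGeometry(a=meas.a, b=meas.b, c=meas.c, beta=meas.beta, gamma=meas.gamma)
    if meas.d > 0:
        implied = chord_d(geom.a, geom.b, geom.c, geom.beta, geom.gamma)
        if abs(implied - meas.d) > d_tolerance * meas.d:
            logger.warning(
                "measured chord d=%.4g cm disagrees with the value %.4g cm "
                "implied by (a, b, c, beta, gamma) beyond %.0f%%",
                meas.d, implied, 100 * d_tolerance,
            )
    return geom
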