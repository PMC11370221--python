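"""Closed-form osteotomy area model and its coordinate-geometry oracle.

The midsagittal abdominal quadrilateral is described by three side lengths
``a`` (pubis to inferior osteotomy apex), ``b`` (between the two osteotomy
apexes), ``c`` (superior apex to xiphoid) and the two hinge angles ``beta``
(at the inferior apex) and ``gamma`` (at the superior apex).  A closing-wedge
pedicle subtraction osteotomy of wedge angles ``alpha1``/``alpha2`` opens the
hinges to ``beta + alpha1`` and ``gamma + alpha2`` while the sides stay rigid,
so the postoperative area follows from the same formula evaluated at the
opened angles:

    S = sqrt( [a^2+b^2-2ab cos(beta)] * [b^2+c^2-2bc cos(gamma)]
              - [b^2 + ac cos(beta+gamma) - ab cos(beta) - bc cos(gamma)]^2 ) / 2

The predicted area change (ac-AMSP) is the post-minus-pre difference, and the
change rate (CR) divides it by the preoperative hexagonal abdominal area.

Every quantity has a second, independent route through explicit planar
coordinates (`reconstruct_vertices` + `shoelace_area`), which the tests use
as an oracle; the two routes agree to 1e-9 relative for all feasible inputs.

All interface angles are degrees; radians appear only inside computations.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import (
    DegenerateQuadrilateral,
    DegenerateQuadrilateralWarning,
    InfeasibleGeometry,
    MissingDenominator,
)

logger = logging.getLogger(__name__)

#: Relative tolerance for internal geometric identities (documented constant).
GEOMETRY_RTOL = 1e-9


@dataclass(frozen=True)
class QuadGeometry:
    """Preoperative quadrilateral scalars driving the prediction.

    Parameters
    ----------
    a, b, c : float
        Side lengths in cm: pubis→inferior apex, inferior→superior apex,
        superior apex→xiphoid.
    beta, gamma : float
        Hinge angles in degrees at the inferior and superior osteotomy
        apexes, measured on the ventral (quadrilateral-interior) side.
        Values above 180° (reflex hinges) are admitted.
    """

    a: float
    b: float
    c: float
    beta: float
    gamma: float

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0 and self.c > 0):
            raise InfeasibleGeometry(
                f"side lengths must be positive, got a={self.a}, b={self.b}, c={self.c}"
            )
        for name in ("beta", "gamma"):
            v = getattr(self, name)
            if not 0.0 < v < 360.0:
                raise InfeasibleGeometry(f"{name} must lie in (0, 360) degrees, got {v}")


@dataclass(frozen=True)
class OsteotomyPlan:
    """Wedge angles of the two osteotomies, in degrees.

    ``is_actual`` distinguishes postoperatively measured wedge angles
    from the preoperative plan; it does not change any computation.
    """

    alpha1: float
    alpha2: float
    is_actual: bool = False

    def __post_init__(self) -> None:
        if self.alpha1 < 0 or self.alpha2 < 0:
            raise InfeasibleGeometry(
                f"wedge angles must be non-negative, got "
                f"alpha1={self.alpha1}, alpha2={self.alpha2}"
            )


@dataclass(frozen=True)
class PredictionResult:
    """Pre/post quadrilateral state and the predicted area change.

    Areas in cm², lengths in cm, angles in degrees.  ``cr`` is a percent
    and is ``None`` when no preoperative hexagon area was supplied.
    ``s_quad_pre`` is the value actually used in the subtraction (the
    measured override when one was given); ``s_quad_pre_computed`` always
    carries the closed-form value for consistency diagnostics.
    """

    s_quad_pre: float
    s_quad_post: float
    ac_amsp: float
    cr: Optional[float]
    d_pre: float
    d_post: float
    m_pre: float
    m_post: float
    n_pre: float
    n_post: float
    theta_pre: float
    theta_post: float
    s_quad_pre_computed: float


def _check_sides(a: float, b: float, c: float) -> None:
    if not (a > 0 and b > 0 and c > 0):
        raise InfeasibleGeometry(
            f"side lengths must be positive, got a={a}, b={b}, c={c}"
        )


def reconstruct_vertices(a: float, b: float, c: float, beta: float, gamma: float) -> np.ndarray:
    """Realize the quadrilateral as planar points A, B, C, D.

    Canonical frame: B (inferior apex) at the origin, C (superior apex) on
    the positive x axis, the interior above the x axis for hinge angles
    below 180°.  The interior-side angle at B equals ``beta`` and at C
    equals ``gamma``.

    Returns
    -------
    ndarray of shape (4, 2)
        Rows are A, B, C, D in cyclic order.
    """
    _check_sides(a, b, c)
    br, gr = math.radians(beta), math.radians(gamma)
    bpt = np.array([0.0, 0.0])
    cpt = np.array([b, 0.0])
    apt = np.array([a * math.cos(br), a * math.sin(br)])
    dpt = cpt + np.array([c * math.cos(math.pi - gr), c * math.sin(math.pi - gr)])
    return np.vstack([apt, bpt, cpt, dpt])


def shoelace_area(points) -> float:
    """Signed polygon area: half the cyclic sum of cross products.

    Positive for counter-clockwise vertex order; 0 for degenerate input.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3 or pts.shape[1] != 2:
        return 0.0
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def _segments_properly_cross(p1, p2, q1, q2, rtol: float = 1e-12) -> bool:
    """Strict interior crossing of two segments; touching within a relative
    tolerance of the segment scale does not count."""
    def orient(u, v, w):
        return (v[0] - u[0]) * (w[1] - u[1]) - (v[1] - u[1]) * (w[0] - u[0])

    scale = max(np.linalg.norm(p2 - p1), np.linalg.norm(q2 - q1)) ** 2
    eps = rtol * max(scale, 1.0)
    o1, o2 = orient(p1, p2, q1), orient(p1, p2, q2)
    o3, o4 = orient(q1, q2, p1), orient(q1, q2, p2)
    if min(abs(o1), abs(o2), abs(o3), abs(o4)) <= eps:
        return False
    return (o1 > 0) != (o2 > 0) and (o3 > 0) != (o4 > 0)


def _is_crossed(vertices: np.ndarray) -> bool:
    """True when the A-B-C-D ring self-intersects (a crossed quadrilateral).

    Only proper crossings of the two non-adjacent edge pairs count;
    collapse to a triangle (coincident vertices) is not a crossing.
    """
    a, b, c, d = vertices
    return (_segments_properly_cross(d, a, b, c)
            or _segments_properly_cross(a, b, c, d))


def quad_area(a: float, b: float, c: float, beta: float, gamma: float) -> float:
    """Quadrilateral area from sides and hinge angles (closed form), cm².

    Pass ``beta + alpha1`` and ``gamma + alpha2`` for the postoperative
    state.  Emits :class:`DegenerateQuadrilateralWarning` when the
    corresponding polygon self-intersects (the value is still returned);
    raises :class:`InfeasibleGeometry` for non-positive sides or a
    radicand negative beyond rounding.
    """
    _check_sides(a, b, c)
    br, gr = math.radians(beta), math.radians(gamma)
    t1 = a * a + b * b - 2.0 * a * b * math.cos(br)
    t2 = b * b + c * c - 2.0 * b * c * math.cos(gr)
    # grouped so the a<->c, beta<->gamma relabeling is bitwise invariant
    t3 = b * b + a * c * math.cos(br + gr) - (a * b * math.cos(br) + b * c * math.cos(gr))
    radicand = t1 * t2 - t3 * t3
    scale = max(t1 * t2, t3 * t3, 1.0)
    if radicand < 0.0:
        if radicand < -1e-12 * scale:
            raise InfeasibleGeometry(
                f"negative radicand ({radicand:g}) for "
                f"(a={a}, b={b}, c={c}, beta={beta}, gamma={gamma})"
            )
        radicand = 0.0
    if _is_crossed(reconstruct_vertices(a, b, c, beta, gamma)):
        warnings.warn(
            f"quadrilateral (a={a}, b={b}, c={c}, beta={beta}, gamma={gamma}) "
            "self-intersects; closed-form area no longer equals the simple-polygon area",
            DegenerateQuadrilateralWarning,
            stacklevel=2,
        )
    return math.sqrt(radicand) / 2.0


def diagonals_and_theta(
    a: float, b: float, c: float, beta: float, gamma: float
) -> tuple[float, float, float]:
    """Diagonals m = |AC|, n = |BD| (cm) and the angle theta between them (deg).

    By the cross-diagonal identity, ``0.5 * m * n * sin(theta)`` equals
    :func:`quad_area` on the same inputs.
    """
    _check_sides(a, b, c)
    br, gr = math.radians(beta), math.radians(gamma)
    m = math.sqrt(max(0.0, a * a + b * b - 2.0 * a * b * math.cos(br)))
    n = math.sqrt(max(0.0, b * b + c * c - 2.0 * b * c * math.cos(gr)))
    if m * n == 0.0:
        raise DegenerateQuadrilateral(
            f"zero-length diagonal (m={m}, n={n}); theta undefined"
        )
    num = b * b + a * c * math.cos(br + gr) - (a * b * math.cos(br) + b * c * math.cos(gr))
    cos_theta = min(1.0, max(-1.0, num / (m * n)))
    return m, n, math.degrees(math.acos(cos_theta))


def chord_d(a: float, b: float, c: float, beta: float, gamma: float) -> float:
    """Length of the ventral chord |DA| (xiphoid to pubis), cm."""
    v = reconstruct_vertices(a, b, c, beta, gamma)
    return float(np.linalg.norm(v[3] - v[0]))


def predict(
    geom: QuadGeometry,
    plan: OsteotomyPlan,
    s_quad_pre_measured: Optional[float] = None,
    s_hex_pre: Optional[float] = None,
    *,
    require_cr: bool = False,
) -> PredictionResult:
    """Predict the postoperative quadrilateral state and the area change.

    Parameters
    ----------
    geom : QuadGeometry
        Preoperative sides and hinge angles.
    plan : OsteotomyPlan
        Wedge angles added to ``beta`` and ``gamma``.
    s_quad_pre_measured : float, optional
        Directly measured preoperative quadrilateral area (cm²).  When
        given it replaces the computed value in the subtraction; a
        discrepancy above 5% relative is logged as a diagnostic.
    s_hex_pre : float, optional
        Preoperative hexagonal abdominal area (cm²), the denominator of
        the change rate.  Without it ``cr`` is ``None``.
    require_cr : bool
        Raise :class:`MissingDenominator` instead of returning ``cr=None``.
    """
    if s_hex_pre is not None and not s_hex_pre > 0:
        raise MissingDenominator(f"s_hex_pre must be positive, got {s_hex_pre}")
    if require_cr and s_hex_pre is None:
        raise MissingDenominator("change rate requested but s_hex_pre not supplied")

    beta_post = geom.beta + plan.alpha1
    gamma_post = geom.gamma + plan.alpha2

    s_pre_computed = quad_area(geom.a, geom.b, geom.c, geom.beta, geom.gamma)
    s_post = quad_area(geom.a, geom.b, geom.c, beta_post, gamma_post)

    s_pre = s_pre_computed
    if s_quad_pre_measured is not None:
        s_pre = float(s_quad_pre_measured)
        if s_pre_computed > 0 and abs(s_pre - s_pre_computed) > 0.05 * s_pre_computed:
            logger.warning(
                "measured preoperative quadrilateral area %.4g cm^2 deviates "
                "from the closed-form value %.4g cm^2 by more than 5%%",
                s_pre, s_pre_computed,
            )

    ac_amsp = s_post - s_pre
    cr = None if s_hex_pre is None else ac_amsp / s_hex_pre * 100.0

    m_pre, n_pre, th_pre = diagonals_and_theta(geom.a, geom.b, geom.c, geom.beta, geom.gamma)
    m_post, n_post, th_post = diagonals_and_theta(geom.a, geom.b, geom.c, beta_post, gamma_post)

    return PredictionResult(
        s_quad_pre=s_pre,
        s_quad_post=s_post,
        ac_amsp=ac_amsp,
        cr=cr,
        d_pre=chord_d(geom.a, geom.b, geom.c, geom.beta, geom.gamma),
        d_post=chord_d(geom.a, geom.b, geom.c, beta_post, gamma_post),
        m_pre=m_pre,
        m_post=m_post,
        n_pre=n_pre,
        n_post=n_post,
        theta_pre=th_pre,
        theta_post=th_post,
        s_quad_pre_computed=s_pre_computed,
    )
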