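"""Closed-form area model vs the coordinate-geometry oracle."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from amsp import (
    DegenerateQuadrilateral,
    DegenerateQuadrilateralWarning,
    InfeasibleGeometry,
    MissingDenominator,
    OsteotomyPlan,
    QuadGeometry,
    chord_d,
    diagonals_and_theta,
    predict,
    quad_area,
    reconstruct_vertices,
    shoelace_area,
)
from conftest import MEAN_HEX_AREA, ORACLE

lengths = st.floats(min_value=0.1, max_value=50.0, allow_nan=False)
hinge_angles = st.floats(min_value=1.0, max_value=179.0, allow_nan=False)
wedges = st.floats(min_value=0.0, max_value=80.0, allow_nan=False)


def sine_identity_area(a, b, c, beta, gamma):
    """Second closed form: half the absolute signed sum of triangle terms."""
    br, gr = math.radians(beta), math.radians(gamma)
    return 0.5 * abs(a * b * math.sin(br) + b * c * math.sin(gr)
                     - a * c * math.sin(br + gr))


@pytest.mark.parametrize(
    "a,b,c,beta,gamma,expected",
    [
        (1, 1, 1, 90, 90, 1.0),                       # unit square missing side d
        (1, 1, 1, 60, 60, math.sqrt(3) / 4),          # collapse to equilateral triangle
        (17.5, 6.1, 13.5, 128.4, 63.1, ORACLE["s_quad_pre"]),
        (17.5, 6.1, 13.5, 128.4 + 38.4, 63.1 + 38.4, ORACLE["s_quad_post"]),
    ],
)
def test_quad_area_analytic_and_oracle_cases(a, b, c, beta, gamma, expected):
    assert quad_area(a, b, c, beta, gamma) == pytest.approx(expected, rel=1e-9)


def test_reconstruct_vertices_canonical_frame():
    v = reconstruct_vertices(1, 1, 1, 90, 90)
    np.testing.assert_allclose(v, [(0, 1), (0, 0), (1, 0), (1, 1)], atol=1e-12)
    v = reconstruct_vertices(1, 1, 1, 60, 60)
    np.testing.assert_allclose(v[0], v[3], atol=1e-12)  # A coincides with D
    v = reconstruct_vertices(17.5, 6.1, 13.5, 128.4, 63.1)
    np.testing.assert_allclose(v[0], ORACLE["A_pre"], atol=1e-6)
    np.testing.assert_allclose(v[3], ORACLE["D_pre"], atol=1e-6)


@given(a=lengths, b=lengths, c=lengths, beta=hinge_angles, gamma=hinge_angles)
@settings(derandomize=True, max_examples=300, deadline=None)
def test_reconstruction_satisfies_side_and_angle_contract(a, b, c, beta, gamma):
    apt, bpt, cpt, dpt = reconstruct_vertices(a, b, c, beta, gamma)
    assert np.linalg.norm(apt - bpt) == pytest.approx(a, rel=1e-9)
    assert np.linalg.norm(cpt - bpt) == pytest.approx(b, rel=1e-9)
    assert np.linalg.norm(dpt - cpt) == pytest.approx(c, rel=1e-9)
    cos_b = (apt - bpt) @ (cpt - bpt) / (a * b)
    assert math.degrees(math.acos(np.clip(cos_b, -1, 1))) == pytest.approx(beta, abs=1e-7)
    cos_c = (bpt - cpt) @ (dpt - cpt) / (b * c)
    assert math.degrees(math.acos(np.clip(cos_c, -1, 1))) == pytest.approx(gamma, abs=1e-7)


def test_shoelace_sign_convention():
    square = [(0, 0), (1, 0), (1, 1), (0, 1)]
    assert shoelace_area(square) == pytest.approx(1.0)
    assert shoelace_area(square[::-1]) == pytest.approx(-1.0)
    assert shoelace_area([(0, 0), (1, 1)]) == 0.0
    v = reconstruct_vertices(17.5, 6.1, 13.5, 128.4, 63.1)
    assert shoelace_area(v) == pytest.approx(ORACLE["s_quad_pre"], rel=1e-9)


@given(a=lengths, b=lengths, c=lengths, beta=hinge_angles, gamma=hinge_angles,
       alpha1=wedges, alpha2=wedges)
@settings(derandomize=True, max_examples=300, deadline=None)
def test_triple_oracle_equivalence(a, b, c, beta, gamma, alpha1, alpha2):
    """Radical formula == |shoelace of reconstruction| == sine identity,
    both preoperatively and at the opened (post-wedge) hinge angles."""
    for be, ga in ((beta, gamma), (beta + alpha1, gamma + alpha2)):
        if be >= 355 or ga >= 355:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", DegenerateQuadrilateralWarning)
            s = quad_area(a, b, c, be, ga)
        tol = 1e-9 * max(1.0, a * a + b * b + c * c)
        assert abs(s - abs(shoelace_area(reconstruct_vertices(a, b, c, be, ga)))) <= tol
        assert abs(s - sine_identity_area(a, b, c, be, ga)) <= tol


@given(a=lengths, b=lengths, c=lengths, beta=hinge_angles, gamma=hinge_angles)
@settings(derandomize=True, max_examples=200, deadline=None)
def test_reversal_symmetry_is_exact(a, b, c, beta, gamma):
    """Relabeling the quadrilateral end for end (A<->D, B<->C) leaves the
    closed form bitwise invariant."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", DegenerateQuadrilateralWarning)
        assert quad_area(a, b, c, beta, gamma) == quad_area(c, b, a, gamma, beta)


def test_diagonals_square_and_mean_case():
    m, n, theta = diagonals_and_theta(1, 1, 1, 90, 90)
    assert (m, n) == pytest.approx((math.sqrt(2), math.sqrt(2)), rel=1e-12)
    assert theta == pytest.approx(90.0, abs=1e-9)
    m, n, theta = diagonals_and_theta(17.5, 6.1, 13.5, 128.4, 63.1)
    assert m == pytest.approx(ORACLE["m_pre"], rel=1e-9)
    assert n == pytest.approx(ORACLE["n_pre"], rel=1e-9)
    assert theta == pytest.approx(ORACLE["theta_pre"], abs=1e-7)


@given(a=lengths, b=lengths, c=lengths, beta=hinge_angles, gamma=hinge_angles)
@settings(derandomize=True, max_examples=200, deadline=None)
def test_cross_diagonal_area_identity(a, b, c, beta, gamma):
    """0.5 * m * n * sin(theta) reproduces the quadrilateral area."""
    m, n, theta = diagonals_and_theta(a, b, c, beta, gamma)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", DegenerateQuadrilateralWarning)
        s = quad_area(a, b, c, beta, gamma)
    assert abs(0.5 * m * n * math.sin(math.radians(theta)) - s) \
        <= 1e-9 * max(1.0, m * n)


def test_diagonals_zero_length_raises():
    with pytest.raises(DegenerateQuadrilateral):
        diagonals_and_theta(1, 1, 1, 360, 90)  # cos(360) = 1 makes m = 0


@pytest.mark.parametrize(
    "args,expected",
    [((1, 1, 1, 90, 90), 1.0),
     ((1, 1, 1, 60, 60), 0.0),
     ((17.5, 6.1, 13.5, 128.4, 63.1), ORACLE["d_pre"])],
)
def test_chord_d(args, expected):
    assert chord_d(*args) == pytest.approx(expected, abs=1e-9)


def test_invalid_inputs_raise():
    with pytest.raises(InfeasibleGeometry):
        quad_area(-1, 1, 1, 90, 90)
    with pytest.raises(InfeasibleGeometry):
        reconstruct_vertices(1, 0, 1, 90, 90)
    with pytest.raises(InfeasibleGeometry):
        QuadGeometry(a=1, b=1, c=1, beta=0, gamma=90)
    with pytest.raises(InfeasibleGeometry):
        OsteotomyPlan(alpha1=-5, alpha2=0)


def test_crossed_quadrilateral_warns_but_returns():
    with pytest.warns(DegenerateQuadrilateralWarning):
        s = quad_area(10, 1, 10, 45, 45)
    assert s == pytest.approx(
        abs(shoelace_area(reconstruct_vertices(10, 1, 10, 45, 45))), rel=1e-9)


def test_collapsed_triangle_does_not_warn():
    with warnings.catch_warnings():
        warnings.simplefilter("error", DegenerateQuadrilateralWarning)
        quad_area(1, 1, 1, 60, 60)


class TestPredict:
    def test_zero_wedge_is_identity(self, mean_geometry):
        res = predict(mean_geometry, OsteotomyPlan(0, 0), s_hex_pre=MEAN_HEX_AREA)
        assert res.ac_amsp == pytest.approx(0.0, abs=1e-12 * res.s_quad_pre)
        assert res.cr == pytest.approx(0.0, abs=1e-12)

    def test_mean_case_prediction(self, mean_geometry, mean_plan):
        res = predict(mean_geometry, mean_plan, s_hex_pre=MEAN_HEX_AREA)
        assert res.s_quad_pre == pytest.approx(ORACLE["s_quad_pre"], rel=1e-9)
        assert res.s_quad_post == pytest.approx(ORACLE["s_quad_post"], rel=1e-9)
        assert res.ac_amsp == pytest.approx(ORACLE["ac_amsp"], rel=1e-9)
        assert res.cr == pytest.approx(ORACLE["cr_pct"], rel=1e-9)
        assert res.d_pre == pytest.approx(ORACLE["d_pre"], rel=1e-9)
        assert res.d_post == pytest.approx(ORACLE["d_post"], rel=1e-9)
        assert res.ac_amsp == pytest.approx(res.s_quad_post - res.s_quad_pre)

    def test_measured_override_drives_subtraction(self, mean_geometry, mean_plan):
        res = predict(mean_geometry, mean_plan, s_quad_pre_measured=100.0)
        assert res.s_quad_pre == 100.0
        assert res.s_quad_pre_computed == pytest.approx(ORACLE["s_quad_pre"], rel=1e-9)
        assert res.ac_amsp == pytest.approx(ORACLE["s_quad_post"] - 100.0, rel=1e-9)

    def test_cr_absent_without_hexagon(self, mean_geometry, mean_plan):
        assert predict(mean_geometry, mean_plan).cr is None
        with pytest.raises(MissingDenominator):
            predict(mean_geometry, mean_plan, require_cr=True)
        with pytest.raises(MissingDenominator):
            predict(mean_geometry, mean_plan, s_hex_pre=-3.0)

    @given(alpha1=wedges, alpha2=wedges)
    @settings(derandomize=True, max_examples=100, deadline=None)
    def test_path_independence_of_the_two_wedges(self, alpha1, alpha2):
        """Applying both wedges at once equals applying them sequentially:
        the model depends only on the summed hinge angles."""
        geom = QuadGeometry(17.5, 6.1, 13.5, 128.4, 63.1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", DegenerateQuadrilateralWarning)
            joint = predict(geom, OsteotomyPlan(alpha1, alpha2))
            step1 = predict(geom, OsteotomyPlan(alpha1, 0))
            interim = QuadGeometry(geom.a, geom.b, geom.c,
                                   geom.beta + alpha1, geom.gamma)
            step2 = predict(interim, OsteotomyPlan(0, alpha2))
        assert step2.s_quad_post == pytest.approx(joint.s_quad_post, rel=1e-12)
        assert step1.ac_amsp + step2.ac_amsp == pytest.approx(joint.ac_amsp, rel=1e-9)

    def test_local_monotonicity_at_cohort_means(self):
        """Both wedge angles increase the area at the cohort-mean state
        (central finite differences)."""
        h = 1e-4
        for da1, da2 in ((h, 0.0), (0.0, h)):
            up = quad_area(17.5, 6.1, 13.5, 128.4 + da1, 63.1 + da2)
            dn = quad_area(17.5, 6.1, 13.5, 128.4 - da1, 63.1 - da2)
            assert (up - dn) / (2 * h) > 0
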