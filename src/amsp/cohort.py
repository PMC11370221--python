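"""Synthetic cohort of ankylosing-spondylitis osteotomy patients.

Generates virtual patients whose preoperative midsagittal geometry follows
the reported cohort distributions (means ± SDs of the sides, hinge angles,
peripheral segments and spinopelvic covariates), with planned wedge angles
(POVA) per osteotomy and actual wedge angles (AOVA) modelled as the plan
minus a small execution bias.  Postoperative landmarks are produced by
literally applying the rigidity assumption: the caudal block (P, S) rotates
about the inferior apex by alpha1 and the cranial block (X, T) rotates about
the superior apex by alpha2, so the seven peripheral segment lengths are
preserved exactly and the closed-form prediction is exact in this simulated
world.  "Measured" postoperative areas add Gaussian planimetry noise on top.

All draws are truncated normals; each patient gets an independent,
counter-indexed substream of the root seed, so cohorts are reproducible
and order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Optional

import numpy as np
from scipy.special import ndtr, ndtri

from .errors import RejectionLimitExceeded, InvalidLandmarks
from .geometry import OsteotomyPlan, reconstruct_vertices, shoelace_area
from .landmarks import MidsagittalLandmarks, measure

MeanSd = tuple[float, float]


@dataclass(frozen=True)
class CohortParams:
    """Distribution parameters of the simulated cohort.

    Each geometric or angular parameter is a (mean, sd) pair; defaults are
    the reported preoperative cohort statistics.  Lengths in cm, angles in
    degrees, areas in cm².  ``aova_bias`` is the per-osteotomy difference
    POVA − AOVA; ``area_noise_sd`` is planimetry noise added to the
    "measured" postoperative hexagon area.  Covariates (GK, LL, TK, SVA)
    are descriptive only and are drawn for both the pre- and postoperative
    columns of the report.
    """

    n_patients: int = 11
    a: MeanSd = (17.5, 2.60)
    b: MeanSd = (6.1, 1.16)
    c: MeanSd = (13.5, 3.03)
    beta: MeanSd = (128.4, 24.09)
    gamma: MeanSd = (63.1, 17.42)
    xt: MeanSd = (14.0, 2.94)
    as_t: MeanSd = (3.8, 1.31)
    s_ai: MeanSd = (8.2, 1.66)
    ps: MeanSd = (11.4, 0.87)
    pova: MeanSd = (38.4, 9.43)
    aova_bias: MeanSd = (0.8, 2.0)
    area_noise_sd: float = 5.0
    gk_pre: MeanSd = (102.9, 19.17)
    gk_post: MeanSd = (34.2, 19.35)
    ll_pre: MeanSd = (-29.2, 26.50)
    ll_post: MeanSd = (39.9, 20.78)
    tk_pre: MeanSd = (51.7, 21.85)
    tk_post: MeanSd = (49.1, 23.28)
    sva_pre: MeanSd = (350.0, 123.72)
    sva_post: MeanSd = (123.2, 57.57)
    seed: int = 0
    max_rejections: int = 1000

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be at least 2")
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, tuple) and v[1] < 0:
                raise ValueError(f"{f.name} sd must be non-negative, got {v[1]}")
        if self.area_noise_sd < 0:
            raise ValueError("area_noise_sd must be non-negative")


@dataclass(frozen=True)
class SyntheticPatient:
    """One simulated case with ground truth on both sides of surgery."""

    id: int
    landmarks_pre: MidsagittalLandmarks
    plan: OsteotomyPlan                  # POVA draws
    actual: OsteotomyPlan                # AOVA draws
    landmarks_post: MidsagittalLandmarks
    s_hex_pre: float
    s_hex_post_true: float
    s_hex_post_measured: float
    covariates: dict = field(default_factory=dict)


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float,
                  lo: float = -np.inf, hi: float = np.inf) -> float:
    if sd == 0.0:
        return float(min(max(mean, lo), hi))
    # inverse-CDF sampling of the truncated normal
    u = rng.uniform(ndtr((lo - mean) / sd), ndtr((hi - mean) / sd))
    return float(mean + sd * ndtri(u))


def _third_vertex(u: np.ndarray, v: np.ndarray, ru: float, rv: float,
                  away_from: np.ndarray) -> Optional[np.ndarray]:
    """Point at distance ru from u and rv from v, on the side of line u-v
    opposite ``away_from``; None when the circles do not intersect."""
    base = v - u
    L = float(np.linalg.norm(base))
    if not (abs(ru - rv) < L < ru + rv):
        return None
    ex = base / L
    ey = np.array([-ex[1], ex[0]])
    x = (L * L + ru * ru - rv * rv) / (2.0 * L)
    h2 = ru * ru - x * x
    if h2 <= 0.0:
        return None
    h = np.sqrt(h2)
    side = np.sign(float((away_from - u) @ ey))
    if side == 0.0:
        return None
    return u + x * ex - side * h * ey


def apply_osteotomy(
    landmarks_pre: MidsagittalLandmarks, alpha1: float, alpha2: float
) -> MidsagittalLandmarks:
    """Rigidly rotate the caudal block (P, S) about Ai by ``alpha1`` and the
    cranial block (X, T) about As by ``alpha2``, opening the hinge angles to
    beta + alpha1 and gamma + alpha2 while preserving the seven peripheral
    segment lengths exactly."""
    if alpha1 < 0 or alpha2 < 0:
        raise ValueError("wedge angles must be non-negative")
    p, s, ai = landmarks_pre.p_pt, landmarks_pre.s_pt, landmarks_pre.ai_pt
    x, t, as_ = landmarks_pre.x_pt, landmarks_pre.t_pt, landmarks_pre.as_pt
    # hexagon orientation fixes which rotation sense opens the hinges,
    # matching the interior-side convention of landmark measurement
    orient = 1.0 if shoelace_area(landmarks_pre.hexagon()) > 0 else -1.0

    def rot(theta_deg: float, center: np.ndarray):
        th = np.radians(theta_deg)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        return lambda q: center + R @ (q - center)

    r_caudal = rot(orient * alpha1, ai)
    r_cranial = rot(-orient * alpha2, as_)
    return MidsagittalLandmarks(
        x_pt=r_cranial(x), p_pt=r_caudal(p), s_pt=r_caudal(s),
        ai_pt=ai.copy(), as_pt=as_.copy(), t_pt=r_cranial(t),
    )


def sample_patient(params: CohortParams, draw_index: int) -> SyntheticPatient:
    """Draw one patient from ``params`` on substream ``draw_index``.

    Rejection-samples until the peripheral triangles close (triangle
    inequalities for T against X-As and S against P-Ai), the hexagon is a
    simple polygon, and the hexagon area decomposes into quadrilateral plus
    the two peripheral triangles (T and S outside the quadrilateral — the
    anatomical configuration).
    """
    rng = np.random.default_rng(np.random.SeedSequence(params.seed, spawn_key=(draw_index,)))

    def _peripheral(u, v, pair1: MeanSd, pair2: MeanSd, away):
        # redraw the offset pair until its triangle closes; conditional on the
        # quad, so the quad scalars' marginals stay (almost) as configured.
        # None after the budget: the quad itself is too extreme — redraw it.
        for _ in range(min(params.max_rejections, 100)):
            r1 = _trunc_normal(rng, *pair1, lo=1e-6)
            r2 = _trunc_normal(rng, *pair2, lo=1e-6)
            pt = _third_vertex(u, v, r1, r2, away_from=away)
            if pt is not None:
                return pt
        return None

    for _ in range(params.max_rejections):
        a = _trunc_normal(rng, *params.a, lo=1e-6)
        b = _trunc_normal(rng, *params.b, lo=1e-6)
        c = _trunc_normal(rng, *params.c, lo=1e-6)
        beta = _trunc_normal(rng, *params.beta, lo=5.0, hi=355.0)
        gamma = _trunc_normal(rng, *params.gamma, lo=5.0, hi=355.0)

        p_pt, ai_pt, as_pt, x_pt = reconstruct_vertices(a, b, c, beta, gamma)
        centroid = (p_pt + ai_pt + as_pt + x_pt) / 4.0
        # T closes the triangle on edge X-As, dorsal-cranial of it; S on edge P-Ai
        t_pt = _peripheral(x_pt, as_pt, params.xt, params.as_t, centroid)
        s_pt = _peripheral(p_pt, ai_pt, params.ps, params.s_ai, centroid)
        if t_pt is None or s_pt is None:
            continue

        alpha1 = _trunc_normal(rng, *params.pova, lo=0.0)
        alpha2 = _trunc_normal(rng, *params.pova, lo=0.0)
        bias1 = rng.normal(*params.aova_bias) if params.aova_bias[1] > 0 else params.aova_bias[0]
        bias2 = rng.normal(*params.aova_bias) if params.aova_bias[1] > 0 else params.aova_bias[0]
        try:
            lm = MidsagittalLandmarks(x_pt=x_pt, p_pt=p_pt, s_pt=s_pt,
                                      ai_pt=ai_pt, as_pt=as_pt, t_pt=t_pt)
            m = measure(lm)
            if abs(m.s_hex - (m.s_quad + m.s_tri_xast + m.s_tri_psai)) > 1e-9 * max(m.s_hex, 1.0):
                continue
            # ground truth must round-trip through measurement: rejects the
            # rare clockwise-winding hexagons the placement heuristic can
            # produce on anatomically implausible sliver quadrilaterals
            if abs(m.beta - beta) > 1e-6 or abs(m.gamma - gamma) > 1e-6:
                continue
            plan = OsteotomyPlan(alpha1=alpha1, alpha2=alpha2, is_actual=False)
            actual = OsteotomyPlan(alpha1=max(alpha1 - bias1, 0.0),
                                   alpha2=max(alpha2 - bias2, 0.0), is_actual=True)
            lm_post = apply_osteotomy(lm, actual.alpha1, actual.alpha2)
        except InvalidLandmarks:
            continue
        break
    else:
        raise RejectionLimitExceeded(
            f"no valid patient within {params.max_rejections} redraws "
            f"(draw_index={draw_index})"
        )
    s_hex_pre = m.s_hex
    s_hex_post_true = measure(lm_post).s_hex
    noise = rng.normal(0.0, params.area_noise_sd) if params.area_noise_sd > 0 else 0.0

    cov = {}
    for name in ("gk", "ll", "tk", "sva"):
        for when in ("pre", "post"):
            mean, sd = getattr(params, f"{name}_{when}")
            cov[f"{name}_{when}"] = float(rng.normal(mean, sd)) if sd > 0 else mean

    return SyntheticPatient(
        id=draw_index,
        landmarks_pre=lm,
        plan=plan,
        actual=actual,
        landmarks_post=lm_post,
        s_hex_pre=s_hex_pre,
        s_hex_post_true=s_hex_post_true,
        s_hex_post_measured=s_hex_post_true + noise,
        covariates=cov,
    )


def generate_cohort(params: CohortParams) -> list[SyntheticPatient]:
    """Generate ``params.n_patients`` patients, deterministic under the seed."""
    return [sample_patient(params, i) for i in range(params.n_patients)]
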