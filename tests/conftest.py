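"""Shared fixtures: the cohort-mean worked case and zero-variance generators.

ORACLE holds expected values computed by an independent brute-force
coordinate script (trigonometric vertex placement + shoelace sums) and
frozen here; the tests compare the package's closed-form route against them.
"""

import dataclasses

import pytest

from amsp import CohortParams, OsteotomyPlan, QuadGeometry

# Brute-force coordinate oracle values for the cohort-mean quadrilateral
# (a, b, c, beta, gamma) = (17.5, 6.1, 13.5, 128.4 deg, 63.1 deg) and the
# mean two-level wedge plan alpha1 = alpha2 = 38.4 deg.
ORACLE = {
    "s_quad_pre": 102.09973881929278,
    "m_pre": 21.81914414200106,
    "n_pre": 12.039269221026224,
    "theta_pre": 128.98138943934003,
    "d_pre": 10.990661105339688,
    "A_pre": (-10.87008615, 13.7146355),
    "D_pre": (-0.0078686, 12.0392666),
    "s_quad_post": 170.60963588152117,
    "ac_amsp": 68.50989706222839,
    "d_post": 27.429686367724244,
    "cr_pct": 44.80699611656533,       # against hexagon area 152.9 cm^2
    "paired_t_example_t": -3.464101615137754,
    "paired_t_example_p": 0.07417990022744857,
}

MEAN_HEX_AREA = 152.9  # reported mean preoperative hexagon area, cm^2


@pytest.fixture
def mean_geometry() -> QuadGeometry:
    return QuadGeometry(a=17.5, b=6.1, c=13.5, beta=128.4, gamma=63.1)


@pytest.fixture
def mean_plan() -> OsteotomyPlan:
    return OsteotomyPlan(alpha1=38.4, alpha2=38.4)


def make_zero_sd_params(**overrides) -> CohortParams:
    """Cohort parameters with every SD forced to zero (degenerate draws at
    the cohort means), optionally overridden field by field."""
    base = CohortParams()
    kwargs = {}
    for f in dataclasses.fields(CohortParams):
        v = getattr(base, f.name)
        kwargs[f.name] = (v[0], 0.0) if isinstance(v, tuple) else v
    kwargs["area_noise_sd"] = 0.0
    kwargs.update(overrides)
    return CohortParams(**kwargs)


@pytest.fixture
def zero_sd_params() -> CohortParams:
    return make_zero_sd_params(n_patients=3, seed=42)
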