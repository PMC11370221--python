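"""Paired-comparison validation report shaped like the clinical tables.

Two tables are produced.  The parameter table compares every preoperative
scalar with its postoperative counterpart (covariates GK/LL/TK/SVA, the
sides a/b/c, the ventral chord d, the peripheral segments XT/TAs/SAi/PS,
and the hexagonal abdominal area).  The prediction table compares planned
vs actual wedge angles (pooled over both osteotomies), predicted vs actual
area change, and predicted vs actual change rate.

All comparisons are two-sided paired t tests; the reported difference is
(first series − second series), i.e. pre − post or planned/predicted −
actual.  No multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import MissingField
from .geometry import predict
from .landmarks import measure, quad_measurement_to_geometry

#: significance level of the report
ALPHA = 0.05

#: (label, pre column, post column) rows of the parameter table
TABLE1_ROWS = [
    ("GK (deg)", "gk_pre", "gk_post"),
    ("LL (deg)", "ll_pre", "ll_post"),
    ("TK (deg)", "tk_pre", "tk_post"),
    ("SVA", "sva_pre", "sva_post"),
    ("a (cm)", "a_pre", "a_post"),
    ("b (cm)", "b_pre", "b_post"),
    ("c (cm)", "c_pre", "c_post"),
    ("d (cm)", "d_pre", "d_post"),
    ("XT (cm)", "xt_pre", "xt_post"),
    ("TAs (cm)", "tas_pre", "tas_post"),
    ("SAi (cm)", "sai_pre", "sai_post"),
    ("PS (cm)", "ps_pre", "ps_post"),
    ("a-AMSP (cm2)", "amsp_pre", "amsp_post"),
]

TABLE2_ROWS = [
    ("OVA (deg)", "ova_planned", "ova_actual"),
    ("ac-AMSP (cm2)", "ac_predicted", "ac_actual"),
    ("CR (%)", "cr_predicted", "cr_actual"),
]


@dataclass(frozen=True)
class PairedComparison:
    """One row of a paired table: summary statistics and the paired t test."""

    label: str
    mean_x: float
    sd_x: float
    mean_y: float
    sd_y: float
    n: int
    df: int
    mean_diff: float
    ci95_low: float
    ci95_high: float
    t_stat: float
    p_value: float
    significant: bool
    zero_variance: bool = False


@dataclass(frozen=True)
class ValidationReport:
    """The two paired tables plus the significance level used to flag rows."""

    table1: list[PairedComparison]
    table2: list[PairedComparison]
    alpha: float = ALPHA

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Machine-readable form: one DataFrame per table."""
        return (pd.DataFrame([asdict(r) for r in self.table1]),
                pd.DataFrame([asdict(r) for r in self.table2]))

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "table1": [asdict(r) for r in self.table1],
            "table2": [asdict(r) for r in self.table2],
        }

    def to_text(self) -> str:
        """Human-readable rendering of both tables."""
        out = []
        for title, frame in zip(
            ("Pre- vs postoperative parameters",
             "Planned/predicted vs actual"),
            self.to_frames(),
        ):
            frame = frame.drop(columns=["zero_variance"])
            frame["p_value"] = frame["p_value"].map(lambda p: f"{p:.4g}")
            for col in ("mean_x", "sd_x", "mean_y", "sd_y", "mean_diff",
                        "ci95_low", "ci95_high", "t_stat"):
                frame[col] = frame[col].map(lambda v: f"{v:.2f}")
            out.append(title)
            out.append(frame.to_string(index=False))
            out.append("")
        out.append(f"significance flagged at alpha = {self.alpha}")
        return "\n".join(out)


def paired_t(x: Sequence[float], y: Sequence[float], label: str = "") -> PairedComparison:
    """Two-sided paired t test of ``x`` against ``y``.

    The difference direction is x − y.  When the paired differences have
    zero variance the test degenerates: p = 1 for identically zero
    differences, p = 0 (flagged ``zero_variance``) for a non-zero constant
    difference.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be one-dimensional vectors of equal length")
    n = x.size
    if n < 2:
        raise ValueError("paired t test needs at least two pairs")
    d = x - y
    mean_diff = float(d.mean())
    s_d = float(d.std(ddof=1))
    df = n - 1
    zero_variance = s_d == 0.0
    if zero_variance:
        t_stat = 0.0 if mean_diff == 0.0 else float(np.sign(mean_diff)) * np.inf
        p_value = 1.0 if mean_diff == 0.0 else 0.0
        ci_low = ci_high = mean_diff
    else:
        se = s_d / np.sqrt(n)
        t_stat = mean_diff / se
        p_value = float(2.0 * stats.t.sf(abs(t_stat), df))
        t_crit = float(stats.t.ppf(0.975, df))
        ci_low, ci_high = mean_diff - t_crit * se, mean_diff + t_crit * se
    return PairedComparison(
        label=label,
        mean_x=float(x.mean()), sd_x=float(x.std(ddof=1)),
        mean_y=float(y.mean()), sd_y=float(y.std(ddof=1)),
        n=n, df=df,
        mean_diff=mean_diff,
        ci95_low=float(ci_low), ci95_high=float(ci_high),
        t_stat=float(t_stat), p_value=p_value,
        significant=p_value < ALPHA,
        zero_variance=zero_variance,
    )


def cohort_records(cohort) -> pd.DataFrame:
    """Flatten synthetic patients (or pass through dict records) into the
    per-patient columns the report consumes.

    Predicted quantities are recomputed from the measured preoperative
    geometry and the *planned* wedge angles; actual quantities come from the
    (noisy) measured postoperative hexagon area.
    """
    rows = []
    for pat in cohort:
        if isinstance(pat, dict):
            rows.append(pat)
            continue
        pre = measure(pat.landmarks_pre)
        post = measure(pat.landmarks_post)
        geom = quad_measurement_to_geometry(pre)
        pred = predict(geom, pat.plan, s_hex_pre=pat.s_hex_pre)
        ac_actual = pat.s_hex_post_measured - pat.s_hex_pre
        rows.append({
            "patient_id": pat.id,
            **{k: pat.covariates[k] for k in sorted(pat.covariates)},
            "a_pre": pre.a, "a_post": post.a,
            "b_pre": pre.b, "b_post": post.b,
            "c_pre": pre.c, "c_post": post.c,
            "d_pre": pre.d, "d_post": post.d,
            "xt_pre": pre.xt, "xt_post": post.xt,
            "tas_pre": pre.as_t, "tas_post": post.as_t,
            "sai_pre": pre.s_ai, "sai_post": post.s_ai,
            "ps_pre": pre.ps, "ps_post": post.ps,
            "beta_pre": pre.beta, "beta_post": post.beta,
            "gamma_pre": pre.gamma, "gamma_post": post.gamma,
            "amsp_pre": pat.s_hex_pre,
            "amsp_post": pat.s_hex_post_measured,
            "alpha1_planned": pat.plan.alpha1, "alpha2_planned": pat.plan.alpha2,
            "alpha1_actual": pat.actual.alpha1, "alpha2_actual": pat.actual.alpha2,
            "ac_predicted": pred.ac_amsp,
            "ac_actual": ac_actual,
            "cr_predicted": pred.cr,
            "cr_actual": ac_actual / pat.s_hex_pre * 100.0,
        })
    return pd.DataFrame(rows)


def build_report(cohort) -> ValidationReport:
    """Build the two-table report from synthetic patients or dict records."""
    frame = cohort_records(cohort)
    if frame.empty:
        raise ValueError("cohort is empty")

    def col(name: str) -> np.ndarray:
        if name not in frame.columns:
            raise MissingField(f"cohort records lack required column '{name}'")
        return frame[name].to_numpy(dtype=float)

    table1 = [paired_t(col(cx), col(cy), label) for label, cx, cy in TABLE1_ROWS]

    # wedge angles pooled over both osteotomies (two per patient)
    ova_planned = np.concatenate([col("alpha1_planned"), col("alpha2_planned")])
    ova_actual = np.concatenate([col("alpha1_actual"), col("alpha2_actual")])
    table2 = [paired_t(ova_planned, ova_actual, TABLE2_ROWS[0][0])]
    for label, cx, cy in TABLE2_ROWS[1:]:
        table2.append(paired_t(col(cx), col(cy), label))
    return ValidationReport(table1=table1, table2=table2)
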