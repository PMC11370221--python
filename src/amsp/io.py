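"""CSV schemas, config loading and serialization.

Conventions: comma-separated, mandatory header row, UTF-8, '.' decimal.
Units are fixed (cm, cm², degrees) and encoded in the column names so they
cannot drift.  Floats are written with 12 significant digits, which makes
write-then-read round-trips exact at double precision for these magnitudes.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .cohort import CohortParams, SyntheticPatient
from .errors import AmspError
from .geometry import OsteotomyPlan, PredictionResult, QuadGeometry
from .landmarks import MidsagittalLandmarks

FLOAT_FMT = "%.12g"

#: landmark CSV long-format columns
LANDMARK_COLUMNS = ["patient_id", "landmark", "x_cm", "y_cm"]
LANDMARK_NAMES = ["X", "P", "S", "Ai", "As", "T"]

#: measurement CSV columns (optional ones may be empty)
MEASUREMENT_COLUMNS = [
    "patient_id", "a_cm", "b_cm", "c_cm", "beta_deg", "gamma_deg",
    "s_quad_pre_cm2", "s_hex_pre_cm2", "alpha1_deg", "alpha2_deg",
]


class SchemaError(AmspError):
    """A CSV file does not match its schema; the message names the line."""


@dataclasses.dataclass(frozen=True)
class MeasurementRecord:
    """One row of the measurement CSV, validated into model inputs."""

    patient_id: str
    geometry: QuadGeometry
    plan: OsteotomyPlan
    s_quad_pre: Optional[float] = None
    s_hex_pre: Optional[float] = None


def _require_columns(frame: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")


def read_measurements(path) -> list[MeasurementRecord]:
    """Read and validate a measurement CSV.

    Raises :class:`SchemaError` with the 1-based file line number for any
    malformed row (the header is line 1).
    """
    frame = pd.read_csv(path)
    _require_columns(frame, ["patient_id", "a_cm", "b_cm", "c_cm",
                             "beta_deg", "gamma_deg", "alpha1_deg", "alpha2_deg"], path)
    records = []
    for idx, row in frame.iterrows():
        line = idx + 2
        try:
            geom = QuadGeometry(a=float(row["a_cm"]), b=float(row["b_cm"]),
                                c=float(row["c_cm"]), beta=float(row["beta_deg"]),
                                gamma=float(row["gamma_deg"]))
            plan = OsteotomyPlan(alpha1=float(row["alpha1_deg"]),
                                 alpha2=float(row["alpha2_deg"]))
            opt = {}
            for key, col in (("s_quad_pre", "s_quad_pre_cm2"),
                             ("s_hex_pre", "s_hex_pre_cm2")):
                if col in frame.columns and pd.notna(row[col]):
                    opt[key] = float(row[col])
            records.append(MeasurementRecord(patient_id=str(row["patient_id"]),
                                             geometry=geom, plan=plan, **opt))
        except (ValueError, TypeError, AmspError) as exc:
            raise SchemaError(f"{path}: line {line}: {exc}") from exc
    return records


def write_predictions(results: list[tuple[str, PredictionResult]], path,
                      fmt: str = "csv") -> None:
    rows = []
    for pid, res in results:
        row = {"patient_id": pid, **dataclasses.asdict(res)}
        rows.append(row)
    frame = pd.DataFrame(rows)
    if fmt == "json":
        Path(path).write_text(json.dumps(rows, indent=2, default=float) + "\n")
    else:
        frame.to_csv(path, index=False, float_format=FLOAT_FMT)


def landmarks_to_frame(patients: dict[str, MidsagittalLandmarks]) -> pd.DataFrame:
    rows = []
    for pid, lm in patients.items():
        for name, pt in zip(LANDMARK_NAMES,
                            (lm.x_pt, lm.p_pt, lm.s_pt, lm.ai_pt, lm.as_pt, lm.t_pt)):
            rows.append({"patient_id": pid, "landmark": name,
                         "x_cm": pt[0], "y_cm": pt[1]})
    return pd.DataFrame(rows, columns=LANDMARK_COLUMNS)


def write_landmarks(patients: dict[str, MidsagittalLandmarks], path) -> None:
    landmarks_to_frame(patients).to_csv(path, index=False, float_format=FLOAT_FMT)


def read_landmarks(path) -> dict[str, MidsagittalLandmarks]:
    """Read a long-format landmark CSV into per-patient landmark sets.

    Each patient must contribute exactly the six named landmarks.
    """
    frame = pd.read_csv(path)
    _require_columns(frame, LANDMARK_COLUMNS, path)
    out: dict[str, MidsagittalLandmarks] = {}
    for pid, grp in frame.groupby("patient_id", sort=False):
        names = list(grp["landmark"])
        if sorted(names) != sorted(LANDMARK_NAMES):
            raise SchemaError(
                f"{path}: patient {pid}: expected landmarks "
                f"{LANDMARK_NAMES}, got {names}"
            )
        pts = {r["landmark"]: np.array([float(r["x_cm"]), float(r["y_cm"])])
               for _, r in grp.iterrows()}
        try:
            out[str(pid)] = MidsagittalLandmarks(
                x_pt=pts["X"], p_pt=pts["P"], s_pt=pts["S"],
                ai_pt=pts["Ai"], as_pt=pts["As"], t_pt=pts["T"])
        except AmspError as exc:
            raise SchemaError(f"{path}: patient {pid}: {exc}") from exc
    return out


def write_cohort(frame: pd.DataFrame, path) -> None:
    """Write the flattened per-patient cohort table (see
    :func:`amsp.validation.cohort_records`)."""
    frame.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_cohort(path) -> list[dict]:
    frame = pd.read_csv(path)
    if frame.empty:
        raise SchemaError(f"{path}: cohort file has no rows")
    return frame.to_dict(orient="records")


def load_cohort_params(config_path=None, seed: Optional[int] = None,
                       n_patients: Optional[int] = None) -> CohortParams:
    """Build :class:`CohortParams` from a flat key/value YAML config.

    Mean/sd pairs appear as two-element lists under the field name; scalar
    fields as scalars.  Keys absent from the file keep their defaults;
    ``seed``/``n_patients`` arguments override the file.
    """
    kwargs: dict = {}
    if config_path is not None:
        raw = yaml.safe_load(Path(config_path).read_text()) or {}
        valid = {f.name for f in dataclasses.fields(CohortParams)}
        unknown = set(raw) - valid
        if unknown:
            raise SchemaError(f"{config_path}: unknown config key(s) {sorted(unknown)}")
        for key, value in raw.items():
            kwargs[key] = tuple(value) if isinstance(value, (list, tuple)) else value
    if seed is not None:
        kwargs["seed"] = seed
    if n_patients is not None:
        kwargs["n_patients"] = n_patients
    return CohortParams(**kwargs)


def cohort_landmark_map(patients: list[SyntheticPatient], which: str = "pre"
                        ) -> dict[str, MidsagittalLandmarks]:
    attr = "landmarks_pre" if which == "pre" else "landmarks_post"
    return {str(p.id): getattr(p, attr) for p in patients}
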