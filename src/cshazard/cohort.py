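"""Cohort tables, phenotype definitions and covariate harmonization.

A *current-status* cohort holds one row per subject: the observation age, the
case/control status at that age, the blood-pressure measurements that defined
it, and any covariates.  Two source dialects are supported:

* ``hufs`` — community-study style: three seated readings per subject, the
  reported pressure is the mean of the second and third readings; a subject
  is a case when SBP or DBP reaches the active thresholds or they are on
  anti-hypertensive treatment.
* ``nhanes`` — national-survey style: one to four readings averaged over the
  non-missing values; the case definition additionally counts a physician
  diagnosis, and records may carry survey weights and stratum labels.

Two threshold sets are available: the classical 140/90 mm Hg definition
(``jnc_140_90``) and the 2017 revision 130/80 mm Hg (``acc2017_130_80``).
Every 140/90 case is by construction also a 130/80 case.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import DialectError, MissingDataError, ValidationError

THRESHOLDS = {
    "jnc_140_90": (140.0, 90.0),
    "acc2017_130_80": (130.0, 80.0),
}

DIALECTS = ("hufs", "nhanes", "generic")

#: reserved (non-covariate) column names in cohort files
RESERVED_COLUMNS = (
    "observation_age", "event", "sbp", "dbp", "on_treatment",
    "ever_diagnosed", "survey_weight", "stratum",
)


@dataclass(frozen=True)
class BPReadings:
    """Repeated blood-pressure readings for one subject (mm Hg).

    Missing readings are ``None`` (or NaN).  The ``hufs`` dialect requires at
    least three readings; ``nhanes`` accepts one to four.
    """

    systolic: Sequence[Optional[float]]
    diastolic: Sequence[Optional[float]]
    dialect: str = "hufs"

    def __post_init__(self):
        if self.dialect not in ("hufs", "nhanes"):
            raise DialectError(f"unknown dialect {self.dialect!r}")
        for name, vals in (("systolic", self.systolic), ("diastolic", self.diastolic)):
            if len(vals) == 0:
                raise ValidationError(f"{name} readings must be non-empty")
            if len(vals) > 4:
                raise ValidationError(f"at most 4 {name} readings supported")
            for v in vals:
                if v is not None and not (isinstance(v, float) and math.isnan(v)):
                    if not math.isfinite(float(v)) or float(v) <= 0:
                        raise ValidationError(f"{name} readings must be positive")
        if len(self.systolic) != len(self.diastolic):
            raise ValidationError("systolic and diastolic lists must match in length")


def _present(values):
    return [float(v) for v in values
            if v is not None and not (isinstance(v, float) and math.isnan(v))]


def average_bp(readings: BPReadings) -> tuple:
    """Reported (SBP, DBP) from repeated readings, per dialect.

    ``hufs``: the mean of the second and third readings (three readings are
    taken; the first is discarded).  ``nhanes``: the mean of all non-missing
    readings.
    """
    if readings.dialect == "hufs":
        if len(readings.systolic) < 3:
            raise DialectError("hufs dialect requires at least 3 readings")
        s23 = _present(readings.systolic[1:3])
        d23 = _present(readings.diastolic[1:3])
        if len(s23) < 2 or len(d23) < 2:
            raise MissingDataError("hufs dialect: readings 2 and 3 must be present")
        return (float(np.mean(s23)), float(np.mean(d23)))
    sbp_vals = _present(readings.systolic)
    dbp_vals = _present(readings.diastolic)
    if not sbp_vals or not dbp_vals:
        raise MissingDataError("all readings missing")
    return (float(np.mean(sbp_vals)), float(np.mean(dbp_vals)))


def classify_hypertension(sbp, dbp, on_treatment, ever_diagnosed=None,
                          threshold_set: str = "jnc_140_90",
                          dialect: str = "hufs") -> bool:
    """Case/control status at the observation age.

    A subject is a case when SBP or DBP reaches the active thresholds, when
    they are on anti-hypertensive treatment, or — in the ``nhanes`` dialect
    only — when a physician has ever diagnosed hypertension.  A missing
    ``ever_diagnosed`` is treated as false, so the classification stays well
    defined for sources without that field.
    """
    if threshold_set not in THRESHOLDS:
        raise ValidationError(f"unknown threshold_set {threshold_set!r}")
    sbp, dbp = float(sbp), float(dbp)
    if sbp < 0 or dbp < 0 or not (math.isfinite(sbp) and math.isfinite(dbp)):
        raise ValidationError("blood pressures must be finite and non-negative")
    s_star, d_star = THRESHOLDS[threshold_set]
    if ever_diagnosed is None or (isinstance(ever_diagnosed, float)
                                  and math.isnan(ever_diagnosed)):
        diagnosed = False
    else:
        diagnosed = bool(ever_diagnosed)
    return bool(
        sbp >= s_star
        or dbp >= d_star
        or bool(on_treatment)
        or (dialect == "nhanes" and diagnosed)
    )


def derive_covariates(height_cm, weight_kg, waist_cm, hip_cm, fat_mass_kg):
    """Anthropometric derivations: (BMI kg/m², waist-hip ratio, percent fat).

    BMI is weight over height squared; WHR is waist over hip circumference
    (both in cm, dimensionless ratio); percent fat is fat mass over weight
    times 100.
    """
    for name, v in (("height_cm", height_cm), ("weight_kg", weight_kg),
                    ("waist_cm", waist_cm), ("hip_cm", hip_cm),
                    ("fat_mass_kg", fat_mass_kg)):
        if not (float(v) > 0):
            raise ValidationError(f"{name} must be positive, got {v}")
    bmi = weight_kg / (height_cm / 100.0) ** 2
    whr = waist_cm / hip_cm
    percent_fat = 100.0 * fat_mass_kg / weight_kg
    return float(bmi), float(whr), float(percent_fat)


def recalibrate_insulin(value: float) -> float:
    """Harmonize a 2013–2014-protocol insulin value (mIU/L) to the older
    assay scale: ``10 ** (0.9765 * log10(x + 0.07832))``.

    Strictly increasing in its argument; defined at zero.
    """
    x = float(value)
    if x < 0:
        raise ValidationError("insulin must be non-negative")
    return float(10.0 ** (0.9765 * math.log10(x + 0.07832)))


def harmonize_weights(weights, n_cycles: int, group_labels=None) -> np.ndarray:
    """Rescale survey weights pooled over ``n_cycles`` survey cycles.

    Each weight is multiplied by ``1 / n_cycles`` and the result divided by
    its group's mean, so each group's harmonized weights average to one.  The
    output is invariant to pre-scaling any group's weights by a constant.
    """
    w = np.asarray(weights, dtype=float)
    if w.ndim != 1 or w.size == 0:
        raise ValidationError("weights must be a non-empty 1-d array")
    if not np.all(np.isfinite(w)) or np.any(w <= 0):
        raise ValidationError("weights must be positive and finite")
    if int(n_cycles) < 1:
        raise ValidationError("n_cycles must be >= 1")
    w = w / float(n_cycles)
    if group_labels is None:
        groups = np.zeros(w.size, dtype=int)
    else:
        groups = np.asarray(group_labels)
        if groups.shape != w.shape:
            raise ValidationError("group_labels must align with weights")
    out = np.empty_like(w)
    for g in np.unique(groups):
        mask = groups == g
        mean = w[mask].mean()
        if mean <= 0:
            raise ValidationError(f"group {g!r} has non-positive total weight")
        out[mask] = w[mask] / mean
    return out


@dataclass
class CurrentStatusRecord:
    """One subject: a single observation age with the event status by then."""

    observation_age: float
    event: bool
    sbp: float = math.nan
    dbp: float = math.nan
    on_treatment: bool = False
    ever_diagnosed: Optional[bool] = None
    covariates: Mapping[str, float] = field(default_factory=dict)
    survey_weight: Optional[float] = None
    stratum: Optional[str] = None

    def __post_init__(self):
        if not math.isfinite(float(self.observation_age)):
            raise ValidationError("observation_age must be finite")
        if self.survey_weight is not None and not (self.survey_weight > 0):
            raise ValidationError("survey_weight must be positive when present")


class Cohort:
    """An ordered collection of current-status records.

    Internally a :class:`pandas.DataFrame` with the reserved columns of
    :data:`RESERVED_COLUMNS` plus one column per covariate.  All records share
    the same covariate names.
    """

    def __init__(self, df: pd.DataFrame, covariate_names: Sequence[str],
                 threshold_set: str = "jnc_140_90", group_label: str = ""):
        if len(df) == 0:
            raise ValidationError("cohort must contain at least one record")
        if threshold_set not in THRESHOLDS:
            raise ValidationError(f"unknown threshold_set {threshold_set!r}")
        for name in ("observation_age", "event"):
            if name not in df.columns:
                raise ValidationError(f"cohort frame lacks column {name!r}")
        for name in covariate_names:
            if name in RESERVED_COLUMNS:
                raise ValidationError(f"{name!r} is a reserved column name")
            if name not in df.columns:
                raise ValidationError(f"covariate column {name!r} missing")
        self.df = df.reset_index(drop=True)
        self.covariate_names = list(covariate_names)
        self.threshold_set = threshold_set
        self.group_label = group_label

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_records(cls, records: Sequence[CurrentStatusRecord],
                     threshold_set: str = "jnc_140_90", group_label: str = ""):
        if not records:
            raise ValidationError("cohort must contain at least one record")
        cov_names = list(records[0].covariates)
        rows = []
        for r in records:
            if list(r.covariates) != cov_names:
                raise ValidationError("all records must share covariate names")
            row = {
                "observation_age": r.observation_age,
                "event": bool(r.event),
                "sbp": r.sbp,
                "dbp": r.dbp,
                "on_treatment": bool(r.on_treatment),
                "ever_diagnosed": r.ever_diagnosed,
                "survey_weight": r.survey_weight,
                "stratum": r.stratum,
            }
            row.update(r.covariates)
            rows.append(row)
        return cls(pd.DataFrame(rows), cov_names, threshold_set, group_label)

    # -- array views -------------------------------------------------------
    def __len__(self):
        return len(self.df)

    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def observation_ages(self) -> np.ndarray:
        return self.df["observation_age"].to_numpy(dtype=float)

    @property
    def events(self) -> np.ndarray:
        return self.df["event"].to_numpy(dtype=bool)

    @property
    def weights(self):
        if "survey_weight" not in self.df.columns:
            return None
        w = self.df["survey_weight"].to_numpy(dtype=float)
        if np.all(np.isnan(w)):
            return None
        return w

    def covariate_array(self, name: str) -> np.ndarray:
        if name not in self.covariate_names:
            raise ValidationError(f"unknown covariate {name!r}")
        return self.df[name].to_numpy(dtype=float)

    def covariate_matrix(self, names: Sequence[str]) -> np.ndarray:
        return np.column_stack([self.covariate_array(n) for n in names])

    def subset(self, mask) -> "Cohort":
        return Cohort(self.df.loc[np.asarray(mask)], self.covariate_names,
                      self.threshold_set, self.group_label)

    def records(self):
        for _, row in self.df.iterrows():
            yield CurrentStatusRecord(
                observation_age=row["observation_age"],
                event=bool(row["event"]),
                sbp=row.get("sbp", math.nan),
                dbp=row.get("dbp", math.nan),
                on_treatment=bool(row.get("on_treatment", False)),
                ever_diagnosed=row.get("ever_diagnosed"),
                covariates={k: row[k] for k in self.covariate_names},
                survey_weight=None if pd.isna(row.get("survey_weight")) else row.get("survey_weight"),
                stratum=None if pd.isna(row.get("stratum")) else row.get("stratum"),
            )


DEFAULT_COLUMN_MAP = {
    "observation_age": "observation_age",
    "sbp": "sbp",
    "dbp": "dbp",
    "on_treatment": "on_treatment",
    "ever_diagnosed": "ever_diagnosed",
    "survey_weight": "survey_weight",
    "stratum": "stratum",
    "event": "event",
}


def load_column_map(path) -> dict:
    """Read a YAML ``field: column`` mapping (survey variable names like
    ``BPXSY1`` can be bound here instead of being hard-coded)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ValidationError("column map must be a mapping")
    return doc


def read_cohort(path, dialect: str = "generic",
                threshold_set: str = "jnc_140_90",
                column_map: Optional[Mapping[str, object]] = None,
                group_label: str = "") -> Cohort:
    """Read a delimited cohort table (CSV/TSV by extension).

    When systolic/diastolic pressure columns are present (possibly several
    reading columns, listed under ``sbp``/``dbp`` in ``column_map``), the
    event status is (re)computed with :func:`average_bp` and
    :func:`classify_hypertension` under the active dialect and thresholds;
    otherwise an explicit ``event`` column is required.  Remaining numeric
    columns become covariates.  Errors name the offending column or row.
    """
    if dialect not in DIALECTS:
        raise DialectError(f"unknown dialect {dialect!r}")
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)

    age_col = cmap["observation_age"]
    if age_col not in df.columns:
        raise ValidationError(f"missing required column {age_col!r}")

    def numeric(col, required_name):
        try:
            return pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = int(np.argmax(coerced.isna() & df[col].notna()))
            raise ValidationError(
                f"column {col!r} ({required_name}) has an unparseable value "
                f"at row {bad}: {df[col].iloc[bad]!r}"
            ) from None

    out = pd.DataFrame({"observation_age": numeric(age_col, "observation_age")})
    used = {age_col}

    def cols_of(key):
        spec = cmap.get(key)
        if spec is None:
            return []
        names = spec if isinstance(spec, (list, tuple)) else [spec]
        return [c for c in names if c in df.columns]

    sbp_cols, dbp_cols = cols_of("sbp"), cols_of("dbp")
    if sbp_cols and dbp_cols:
        s = np.column_stack([numeric(c, "sbp") for c in sbp_cols])
        d = np.column_stack([numeric(c, "dbp") for c in dbp_cols])
        used.update(sbp_cols + dbp_cols)
        if s.shape[1] == 1:
            sbp, dbp = s[:, 0], d[:, 0]
        else:
            sbp = np.empty(len(df))
            dbp = np.empty(len(df))
            for i in range(len(df)):
                readings = BPReadings(list(s[i]), list(d[i]),
                                      dialect if dialect != "generic" else "nhanes")
                sbp[i], dbp[i] = average_bp(readings)
        out["sbp"], out["dbp"] = sbp, dbp
    else:
        out["sbp"] = math.nan
        out["dbp"] = math.nan

    for key, default in (("on_treatment", False), ("ever_diagnosed", None)):
        cols = cols_of(key)
        if cols:
            out[key] = df[cols[0]].astype("boolean").to_numpy(na_value=False if key == "on_treatment" else None)
            used.add(cols[0])
        else:
            out[key] = default

    for key in ("survey_weight", "stratum"):
        cols = cols_of(key)
        if cols:
            out[key] = numeric(cols[0], key) if key == "survey_weight" else df[cols[0]]
            used.add(cols[0])
        else:
            out[key] = math.nan if key == "survey_weight" else None

    have_bp = not out["sbp"].isna().all()
    event_cols = cols_of("event")
    if have_bp:
        events = []
        for i in range(len(out)):
            events.append(classify_hypertension(
                out["sbp"].iloc[i], out["dbp"].iloc[i],
                out["on_treatment"].iloc[i], out["ever_diagnosed"].iloc[i],
                threshold_set, dialect if dialect != "generic" else "hufs"))
        out["event"] = events
    elif event_cols:
        out["event"] = df[event_cols[0]].astype(bool)
        used.add(event_cols[0])
    else:
        raise ValidationError(
            "file has neither blood-pressure columns nor an 'event' column"
        )

    covariates = [c for c in df.columns if c not in used and c not in RESERVED_COLUMNS]
    for c in covariates:
        out[c] = numeric(c, f"covariate {c}")
    return Cohort(out, covariates, threshold_set, group_label)


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort as delimited text (TSV for .tsv/.txt, else CSV);
    round-trips losslessly through :func:`read_cohort`."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    cols = list(RESERVED_COLUMNS) + cohort.covariate_names
    present = [c for c in cols if c in cohort.df.columns]
    cohort.df[present].to_csv(path, sep=sep, index=False)
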