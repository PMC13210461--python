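"""TDM event-record datasets: domain types, covariate derivations, CSV I/O.

A dataset is a flat, NONMEM-style event table — one row per dose or
observation per subject — which is the interchange shape the population-PK
field uses.  Internally each subject carries its dose events, trough/random
concentration records, and a piecewise-constant renal-function series.

Units are fixed throughout the package: hours for time, mg for dose amounts,
mg/L for concentrations, mL/min for eGFR, years for age.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "LLOQ",
    "EGFR_CAP",
    "DoseEvent",
    "ConcentrationRecord",
    "CovariateSeries",
    "Subject",
    "StudyDataset",
    "ColumnMap",
    "DatasetError",
    "read_dataset",
    "write_dataset",
    "cap_egfr",
    "body_size_descriptors",
    "renal_function_estimates",
]

logger = logging.getLogger(__name__)

#: Assay lower limit of quantification, mg/L.  Records below it are flagged
#: BLQ and excluded from the analysis set (M1 handling: discard).
LLOQ = 0.8

#: Upper cap applied to eGFR (mL/min) to avoid implausible renal-function
#: estimates in elderly patients with low muscle mass.
EGFR_CAP = 130.0


class DatasetError(ValueError):
    """Raised for malformed event tables or invariant violations."""


@dataclass(frozen=True)
class DoseEvent:
    """A single IV infusion: start time (h since first dose), amount (mg),
    and infusion duration (h, 1 h by default)."""

    time: float
    amount: float
    infusion_duration: float = 1.0

    def __post_init__(self) -> None:
        if self.time < 0:
            raise DatasetError(f"dose time must be >= 0, got {self.time}")
        if not (self.amount > 0):
            raise DatasetError(f"dose amount must be > 0, got {self.amount}")
        if not (self.infusion_duration > 0):
            raise DatasetError(
                f"infusion duration must be > 0, got {self.infusion_duration}"
            )

    @property
    def rate(self) -> float:
        """Infusion rate in mg/h."""
        return self.amount / self.infusion_duration


@dataclass(frozen=True)
class ConcentrationRecord:
    """An observed serum concentration.

    ``time_since_last_dose`` is the *recorded* interval between the last
    administration and sampling, not the nominal dosing interval.
    ``blq`` is true iff ``value`` is below the assay LLOQ (0.8 mg/L);
    BLQ records are excluded from the analysis set.
    """

    time: float
    value: float
    blq: bool = False
    time_since_last_dose: float | None = None

    def __post_init__(self) -> None:
        if self.time < 0:
            raise DatasetError(f"observation time must be >= 0, got {self.time}")
        if self.value < 0:
            raise DatasetError(f"concentration must be >= 0, got {self.value}")
        if self.blq != (self.value < LLOQ):
            raise DatasetError(
                f"blq flag inconsistent with value {self.value} (LLOQ {LLOQ})"
            )
        if (
            self.time_since_last_dose is not None
            and self.time_since_last_dose > self.time + 1e-9
        ):
            raise DatasetError("time_since_last_dose exceeds time since first dose")


@dataclass(frozen=True)
class CovariateSeries:
    """Per-subject covariates: constant age plus a piecewise-constant eGFR
    series of (time, value) knots; raw columns (weight, height, ...) ride
    along in ``extras`` and never enter the structural model directly."""

    age: float
    egfr: tuple[tuple[float, float], ...]
    extras: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 < self.age < 150):
            raise DatasetError(f"implausible age {self.age}")
        if not self.egfr:
            raise DatasetError("eGFR series must contain at least one value")
        times = [t for t, _ in self.egfr]
        if any(t1 < t0 for t0, t1 in zip(times, times[1:])):
            raise DatasetError("eGFR series times must be non-decreasing")
        for _, v in self.egfr:
            if not (0 < v <= EGFR_CAP):
                raise DatasetError(
                    f"eGFR value {v} outside (0, {EGFR_CAP}]; cap before constructing"
                )

    def egfr_at(self, t: float) -> float:
        """eGFR in force at time t: the last knot at or before t (first knot
        for earlier times)."""
        current = self.egfr[0][1]
        for knot_t, v in self.egfr:
            if knot_t <= t:
                current = v
            else:
                break
        return current


@dataclass(frozen=True)
class Subject:
    """One patient: dose events, concentration records, covariates."""

    id: str
    doses: tuple[DoseEvent, ...]
    observations: tuple[ConcentrationRecord, ...]
    covariates: CovariateSeries

    def __post_init__(self) -> None:
        if not self.doses:
            raise DatasetError(f"subject {self.id} has no dose events")
        dtimes = [d.time for d in self.doses]
        if any(t1 < t0 for t0, t1 in zip(dtimes, dtimes[1:])):
            raise DatasetError(f"subject {self.id}: dose times not sorted")
        first = dtimes[0]
        for obs in self.observations:
            if obs.time < first - 1e-9:
                raise DatasetError(
                    f"subject {self.id}: observation at {obs.time} h precedes "
                    f"first dose at {first} h"
                )

    @property
    def analysis_observations(self) -> tuple[ConcentrationRecord, ...]:
        """Quantifiable (non-BLQ) records — the formal analysis set."""
        return tuple(o for o in self.observations if not o.blq)

    def last_dose_time_before(self, t: float) -> float | None:
        prior = [d.time for d in self.doses if d.time <= t + 1e-9]
        return max(prior) if prior else None


@dataclass(frozen=True)
class StudyDataset:
    """A cohort of subjects plus free-text provenance metadata."""

    subjects: tuple[Subject, ...]
    provenance: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [s.id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise DatasetError("subject ids must be unique")

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self):
        return iter(self.subjects)

    def subject(self, sid: str) -> Subject:
        for s in self.subjects:
            if s.id == sid:
                return s
        raise KeyError(sid)

    @property
    def n_observations(self) -> int:
        return sum(len(s.analysis_observations) for s in self.subjects)

    @property
    def n_blq(self) -> int:
        return sum(sum(o.blq for o in s.observations) for s in self.subjects)


# ---------------------------------------------------------------------------
# Derived covariates
# ---------------------------------------------------------------------------


def cap_egfr(raw_egfr: float) -> float:
    """Cap an eGFR value at 130 mL/min.

    Idempotent and order-preserving below the cap; raises on non-positive
    input (an eGFR of zero or less is not a valid renal-function estimate).
    """
    if not (raw_egfr > 0):
        raise DatasetError(f"eGFR must be positive, got {raw_egfr}")
    return min(float(raw_egfr), EGFR_CAP)


def body_size_descriptors(weight: float, height: float, sex: str) -> dict[str, float]:
    """BMI, Mosteller BSA, Devine ideal body weight, and adjusted body weight.

    Parameters
    ----------
    weight : kg
    height : cm
    sex : "male" or "female" (case-insensitive; "m"/"f" accepted)

    Returns a dict with keys ``bmi`` (kg/m^2), ``bsa`` (m^2), ``ibw`` (kg),
    ``abw`` (kg).  ABW applies a 0.4 correction factor to weight in excess of
    ideal (ABW = IBW + 0.4*(WT - IBW)); when actual weight is below ideal the
    excess term is negative and ABW < IBW, which callers may clamp if desired.
    """
    if not (weight > 0 and height > 0):
        raise DatasetError("weight and height must be positive")
    sex_norm = sex.strip().lower()
    if sex_norm in ("m", "male"):
        female = False
    elif sex_norm in ("f", "female"):
        female = True
    else:
        raise DatasetError(f"unrecognised sex {sex!r}")

    h_m = height / 100.0
    bmi = weight / (h_m * h_m)
    bsa = math.sqrt(height * weight / 3600.0)
    height_in = height / 2.54
    ibw = (45.5 if female else 50.0) + 2.3 * (height_in - 60.0)
    ibw = max(ibw, 1.0)  # guard for very short stature
    abw = ibw + 0.4 * (weight - ibw)
    return {"bmi": bmi, "bsa": bsa, "ibw": ibw, "abw": abw}


def renal_function_estimates(
    age: float,
    sex: str,
    weight: float,
    serum_creatinine: float,
    bsa: float | None = None,
    height: float | None = None,
) -> dict[str, float]:
    """Cockcroft–Gault and CKD-EPI (2021 race-free creatinine) estimates.

    Returns ``cg_mLmin`` (Cockcroft–Gault, mL/min), ``ckdepi_normalized``
    (mL/min/1.73 m^2), and ``ckdepi_absolute_mLmin`` (de-indexed by BSA/1.73).
    ``bsa`` may be supplied directly or computed from ``height`` (cm) via
    Mosteller.  Results are *not* capped; callers apply :func:`cap_egfr`.
    """
    if not (age > 0 and weight > 0 and serum_creatinine > 0):
        raise DatasetError("age, weight and serum creatinine must be positive")
    sex_norm = sex.strip().lower()
    female = sex_norm in ("f", "female")
    if not female and sex_norm not in ("m", "male"):
        raise DatasetError(f"unrecognised sex {sex!r}")

    cg = (140.0 - age) * weight / (72.0 * serum_creatinine)
    if female:
        cg *= 0.85

    kappa = 0.7 if female else 0.9
    alpha = -0.241 if female else -0.302
    scr_k = serum_creatinine / kappa
    egfr_norm = (
        142.0
        * min(scr_k, 1.0) ** alpha
        * max(scr_k, 1.0) ** -1.200
        * 0.9938**age
    )
    if female:
        egfr_norm *= 1.012

    if bsa is None:
        if height is None:
            raise DatasetError("provide bsa or height to de-index CKD-EPI")
        bsa = math.sqrt(height * weight / 3600.0)
    egfr_abs = egfr_norm * bsa / 1.73
    return {
        "cg_mLmin": cg,
        "ckdepi_normalized": egfr_norm,
        "ckdepi_absolute_mLmin": egfr_abs,
    }


# ---------------------------------------------------------------------------
# Event-record I/O
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ColumnMap:
    """Column-name mapping for the delimited event table (NONMEM dialect)."""

    id: str = "ID"
    time: str = "TIME"
    amt: str = "AMT"
    dur: str = "DUR"
    dv: str = "DV"
    blq: str = "BLQ"
    egfr: str = "EGFR"
    age: str = "AGE"
    #: optional raw covariate columns carried into ``CovariateSeries.extras``
    extras: tuple[str, ...] = ("WT", "HT", "SEX", "SCR", "CG")


def _is_missing(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x)) or x == "."


def read_dataset(
    path: str | Path,
    dialect: ColumnMap | None = None,
    sep: str = ",",
) -> StudyDataset:
    """Read a delimited NONMEM-style event table into a :class:`StudyDataset`.

    A row with positive AMT is a dose event; a row with a non-missing DV is a
    concentration record.  Records whose value falls below the LLOQ are
    flagged BLQ regardless of the file's flag column, so the analysis set is
    always LLOQ-consistent.  Rows missing mandatory fields raise
    :class:`DatasetError` naming the offending row.
    """
    cm = dialect or ColumnMap()
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=sep)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise DatasetError(f"cannot parse {path}: {exc}") from exc

    for col in (cm.id, cm.time):
        if col not in df.columns:
            raise DatasetError(f"{path}: missing mandatory column {col!r}")

    subjects: list[Subject] = []
    n_flagged = 0
    for sid, grp in df.groupby(cm.id, sort=False):
        times = grp[cm.time].to_numpy(dtype=float)
        if any(t1 < t0 for t0, t1 in zip(times, times[1:])):
            raise DatasetError(f"subject {sid}: event times are not non-decreasing")

        doses: list[DoseEvent] = []
        observations: list[ConcentrationRecord] = []
        egfr_knots: list[tuple[float, float]] = []
        age_val: float | None = None
        extras: dict[str, float] = {}

        for row_idx, row in grp.iterrows():
            t = float(row[cm.time])
            if cm.age in grp.columns and not _is_missing(row[cm.age]):
                age_val = float(row[cm.age])
            if cm.egfr in grp.columns and not _is_missing(row[cm.egfr]):
                egfr_knots.append((t, cap_egfr(float(row[cm.egfr]))))
            for col in cm.extras:
                if col in grp.columns and not _is_missing(row[col]):
                    try:
                        extras[col.lower()] = float(row[col])
                    except (TypeError, ValueError):
                        pass  # non-numeric extras (e.g. sex strings) skipped

            amt = row[cm.amt] if cm.amt in grp.columns else None
            dv = row[cm.dv] if cm.dv in grp.columns else None
            is_dose = not _is_missing(amt) and float(amt) > 0
            is_obs = not _is_missing(dv)
            if is_dose:
                dur = 1.0
                if cm.dur in grp.columns and not _is_missing(row[cm.dur]):
                    dur = float(row[cm.dur])
                try:
                    doses.append(DoseEvent(time=t, amount=float(amt), infusion_duration=dur))
                except DatasetError as exc:
                    raise DatasetError(f"row {row_idx} (subject {sid}): {exc}") from exc
            elif is_obs:
                value = float(dv)
                blq = value < LLOQ
                if blq:
                    n_flagged += 1
                last = max((dt for dt in (d.time for d in doses) if dt <= t), default=None)
                tsld = t - last if last is not None else None
                observations.append(
                    ConcentrationRecord(
                        time=t, value=value, blq=blq, time_since_last_dose=tsld
                    )
                )
            else:
                raise DatasetError(
                    f"row {row_idx} (subject {sid}): neither a dose (AMT) nor an "
                    f"observation (DV)"
                )

        if age_val is None:
            raise DatasetError(f"subject {sid}: no AGE value found")
        if not egfr_knots:
            raise DatasetError(f"subject {sid}: no EGFR value found")
        # collapse consecutive duplicate knots
        knots: list[tuple[float, float]] = []
        for kt, kv in egfr_knots:
            if not knots or knots[-1][1] != kv:
                knots.append((kt, kv))
        subjects.append(
            Subject(
                id=str(sid),
                doses=tuple(doses),
                observations=tuple(observations),
                covariates=CovariateSeries(
                    age=age_val, egfr=tuple(knots), extras=extras
                ),
            )
        )
        logger.debug(
            "subject %s: %d doses, %d observations (%d BLQ)",
            sid,
            len(doses),
            len(observations),
            sum(o.blq for o in observations),
        )

    ds = StudyDataset(
        subjects=tuple(subjects),
        provenance={"source": str(path), "blq_flagged": str(n_flagged)},
    )
    logger.info(
        "read %d subjects, %d quantifiable observations, %d BLQ from %s",
        len(ds),
        ds.n_observations,
        ds.n_blq,
        path,
    )
    return ds


def write_dataset(dataset: StudyDataset, path: str | Path, sep: str = ",") -> None:
    """Write a dataset back to the delimited event-record format.

    ``write_dataset`` followed by :func:`read_dataset` round-trips to an
    equal dataset (non-numeric extras excepted).
    """
    rows: list[dict] = []
    for s in dataset.subjects:
        events: list[tuple[float, int, dict]] = []
        for d in s.doses:
            events.append(
                (d.time, 0, {"AMT": d.amount, "DUR": d.infusion_duration, "DV": None, "BLQ": None})
            )
        for o in s.observations:
            events.append((o.time, 1, {"AMT": None, "DUR": None, "DV": o.value, "BLQ": int(o.blq)}))
        events.sort(key=lambda e: (e[0], e[1]))
        for t, _, payload in events:
            row = {
                "ID": s.id,
                "TIME": t,
                "AGE": s.covariates.age,
                "EGFR": s.covariates.egfr_at(t),
                **payload,
            }
            for k, v in s.covariates.extras.items():
                row[k.upper()] = v
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


def analysis_subset(dataset: StudyDataset) -> StudyDataset:
    """Drop subjects with no quantifiable (non-BLQ) observations — the same
    rule the study applies to patients without available concentrations."""
    kept = tuple(s for s in dataset.subjects if s.analysis_observations)
    prov = dict(dataset.provenance)
    prov["subjects_dropped_all_blq"] = str(len(dataset.subjects) - len(kept))
    return StudyDataset(subjects=kept, provenance=prov)


def datasets_equal(a: StudyDataset, b: StudyDataset, tol: float = 1e-9) -> bool:
    """Structural equality up to floating-point tolerance (round-trip check)."""
    if len(a) != len(b):
        return False
    for sa, sb in zip(a.subjects, b.subjects):
        if sa.id != sb.id or len(sa.doses) != len(sb.doses):
            return False
        if len(sa.observations) != len(sb.observations):
            return False
        for da, db in zip(sa.doses, sb.doses):
            if (
                abs(da.time - db.time) > tol
                or abs(da.amount - db.amount) > tol
                or abs(da.infusion_duration - db.infusion_duration) > tol
            ):
                return False
        for oa, ob in zip(sa.observations, sb.observations):
            if abs(oa.time - ob.time) > tol or abs(oa.value - ob.value) > tol:
                return False
            if oa.blq != ob.blq:
                return False
        if abs(sa.covariates.age - sb.covariates.age) > tol:
            return False
        if sa.covariates.egfr_at(0.0) != sb.covariates.egfr_at(0.0):
            return False
    return True
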