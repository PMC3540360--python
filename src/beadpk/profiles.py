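"""Data model and CSV I/O for concentration-time profiles and dosing records.

A *profile* is one (subject, phase, analyte) concentration-time series.
The study design has four phases — two embolization (bead) cycles and two
IV cycles — and two analytes: the parent drug (irinotecan, CPT-11) and its
metabolite (SN-38), whose plasma exposure is roughly a thousand-fold lower.

Time convention
---------------
``time_h`` is elapsed time since the *completion of administration* for the
phase: end of embolization for the bead route, end of the IV infusion for
the IV route.  This is the clock on which the sampling schedule is anchored
(the first sample is drawn "immediately on completion", time 0), and the
only clock on which sub-minute IV Tmax values are coherent.  Times are
stored in hours; minute-based input is converted by dividing by 60.

Measurements below the assay's lower limit of quantification carry
``bloq=True`` and no concentration.

CSV dialect
-----------
Comma-separated, UTF-8, header row::

    subject,phase,route,analyte,dose_mg,infusion_duration_h,time_h,conc_ng_ml,bloq

The empty string encodes an absent value.  ``bloq`` is ``true``/``false``.
A schema config may rename columns and declare the time unit (``h``/``min``).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
from pydantic import BaseModel

from .exceptions import DomainError, RowValidationError, SchemaError

__all__ = [
    "Phase",
    "Route",
    "Analyte",
    "SamplePoint",
    "ConcentrationProfile",
    "DoseRecord",
    "SummaryStat",
    "SchemaConfig",
    "read_profiles",
    "write_profiles",
    "read_dose_records",
    "write_dose_records",
]


class Phase(str, Enum):
    PRIMARY_EMBOLIZATION = "primary_embolization"
    SECONDARY_EMBOLIZATION = "secondary_embolization"
    PRIMARY_IV = "primary_iv"
    SECONDARY_IV = "secondary_iv"

    @property
    def cycle(self) -> str:
        return "primary" if self.value.startswith("primary") else "secondary"

    @property
    def route(self) -> "Route":
        return Route.BEAD if self.value.endswith("embolization") else Route.IV


class Route(str, Enum):
    BEAD = "bead_intraarterial"
    IV = "iv_infusion"


class Analyte(str, Enum):
    PARENT = "parent"
    METABOLITE = "metabolite"


@dataclass(frozen=True)
class SamplePoint:
    """One plasma sample: time since the phase origin, concentration, LOQ flag."""

    time_h: float
    conc_ng_ml: float | None
    bloq: bool = False

    def __post_init__(self):
        if not self.time_h >= 0:
            raise DomainError(f"time_h must be >= 0, got {self.time_h!r}")
        if self.bloq and self.conc_ng_ml is not None:
            raise DomainError("a BLOQ point must not carry a concentration")
        if self.conc_ng_ml is not None and not self.conc_ng_ml >= 0:
            raise DomainError(f"conc_ng_ml must be >= 0, got {self.conc_ng_ml!r}")

    @property
    def quantifiable(self) -> bool:
        return not self.bloq and self.conc_ng_ml is not None


@dataclass(frozen=True)
class ConcentrationProfile:
    """One subject/phase/analyte concentration-time series."""

    subject_id: str
    phase: Phase
    route: Route
    analyte: Analyte
    dose_mg: float
    infusion_duration_h: float | None
    points: tuple[SamplePoint, ...]

    def __post_init__(self):
        if not self.dose_mg > 0:
            raise DomainError(f"dose_mg must be > 0, got {self.dose_mg!r}")
        if self.phase.route is not self.route:
            raise DomainError(
                f"phase {self.phase.value} is inconsistent with route {self.route.value}"
            )
        if self.route is Route.IV:
            if self.infusion_duration_h is None or not self.infusion_duration_h > 0:
                raise DomainError("iv_infusion profiles require infusion_duration_h > 0")
        elif self.infusion_duration_h is not None:
            raise DomainError("bead profiles must not carry an infusion duration")
        times = [p.time_h for p in self.points]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise DomainError("points must be strictly increasing in time_h")

    def quantifiable_points(self) -> tuple[SamplePoint, ...]:
        return tuple(p for p in self.points if p.quantifiable)

    @property
    def n_quantifiable(self) -> int:
        return sum(p.quantifiable for p in self.points)

    @property
    def nca_eligible(self) -> bool:
        """At least 3 quantifiable points are required for NCA."""
        return self.n_quantifiable >= 3

    def times(self) -> np.ndarray:
        return np.array([p.time_h for p in self.points])


@dataclass(frozen=True)
class DoseRecord:
    """Body weight and administered dose for one subject/phase."""

    subject_id: str
    phase: Phase
    weight_kg: float
    dose_per_m2_mg: float | None
    dose_mg: float

    def __post_init__(self):
        if not self.weight_kg > 0:
            raise DomainError(f"weight_kg must be > 0, got {self.weight_kg!r}")
        if not self.dose_mg > 0:
            raise DomainError(f"dose_mg must be > 0, got {self.dose_mg!r}")
        if self.dose_per_m2_mg is not None:
            from .dosing import compute_dose

            expected = compute_dose(self.weight_kg, self.dose_per_m2_mg)
            if abs(expected - self.dose_mg) > 0.05:
                raise DomainError(
                    f"dose_mg {self.dose_mg} inconsistent with BSA dosing "
                    f"({expected:.3f} mg from {self.weight_kg} kg x "
                    f"{self.dose_per_m2_mg} mg/m^2)"
                )


@dataclass(frozen=True)
class SummaryStat:
    """Mean, sample SD, CV% and n for one parameter across subjects."""

    mean: float
    sd: float
    cv_percent: float
    n: int

    def __post_init__(self):
        if not self.n >= 1:
            raise DomainError("n must be >= 1")


class SchemaConfig(BaseModel):
    """Column-mapping config for reading foreign CSV dialects.

    ``columns`` maps canonical names to the names used in the file;
    ``time_unit`` declares the unit of the time column.
    """

    columns: dict[str, str] = {}
    time_unit: Literal["h", "min"] = "h"

    def file_column(self, canonical: str) -> str:
        return self.columns.get(canonical, canonical)


CSV_COLUMNS = (
    "subject",
    "phase",
    "route",
    "analyte",
    "dose_mg",
    "infusion_duration_h",
    "time_h",
    "conc_ng_ml",
    "bloq",
)


def _parse_float(text: str, column: str, line: int) -> float | None:
    if text == "":
        return None
    try:
        value = float(text)
    except ValueError:
        raise RowValidationError(f"column {column!r}: not a number: {text!r}", line)
    if not math.isfinite(value):
        raise RowValidationError(f"column {column!r}: non-finite value", line)
    return value


def read_profiles(path, schema: SchemaConfig | None = None) -> list[ConcentrationProfile]:
    """Read concentration-time profiles from a CSV file.

    Returns one profile per (subject, phase, analyte), points sorted by
    time.  Duplicate (subject, phase, analyte, time) rows, negative times
    or concentrations, and BLOQ rows carrying a concentration are rejected
    with the offending line number.
    """
    schema = schema or SchemaConfig()
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for canonical in CSV_COLUMNS:
            if schema.file_column(canonical) not in header:
                raise SchemaError(
                    f"missing column {schema.file_column(canonical)!r} in {path}"
                )
        groups: dict[tuple, dict] = {}
        for line, row in enumerate(reader, start=2):
            get = lambda c: (row.get(schema.file_column(c)) or "").strip()
            subject = get("subject")
            try:
                phase = Phase(get("phase"))
                route = Route(get("route"))
                analyte = Analyte(get("analyte"))
            except ValueError as exc:
                raise RowValidationError(str(exc), line) from None
            dose = _parse_float(get("dose_mg"), "dose_mg", line)
            duration = _parse_float(get("infusion_duration_h"), "infusion_duration_h", line)
            time = _parse_float(get("time_h"), "time_h", line)
            conc = _parse_float(get("conc_ng_ml"), "conc_ng_ml", line)
            bloq_text = get("bloq").lower()
            if bloq_text not in ("true", "false"):
                raise RowValidationError(f"column 'bloq': expected true/false, got {bloq_text!r}", line)
            bloq = bloq_text == "true"
            if time is None:
                raise RowValidationError("column 'time_h': value required", line)
            if schema.time_unit == "min":
                time = time / 60.0
            if time < 0:
                raise RowValidationError(f"negative time {time}", line)
            if conc is not None and conc < 0:
                raise RowValidationError(f"negative concentration {conc}", line)
            if bloq and conc is not None:
                raise RowValidationError("BLOQ row must not carry a concentration", line)
            key = (subject, phase, analyte)
            group = groups.setdefault(
                key,
                {"route": route, "dose_mg": dose, "duration": duration, "points": {}},
            )
            if group["dose_mg"] != dose or group["duration"] != duration or group["route"] != route:
                raise RowValidationError(
                    f"inconsistent route/dose/duration within profile {key}", line
                )
            if time in group["points"]:
                raise RowValidationError(
                    f"duplicate sample time {time} h for {key}", line
                )
            try:
                group["points"][time] = SamplePoint(time, conc, bloq)
            except DomainError as exc:
                raise RowValidationError(str(exc), line) from None

    profiles = []
    for (subject, phase, analyte), group in groups.items():
        if group["dose_mg"] is None:
            raise SchemaError(f"profile ({subject}, {phase.value}, {analyte.value}) lacks dose_mg")
        points = tuple(group["points"][t] for t in sorted(group["points"]))
        profiles.append(
            ConcentrationProfile(
                subject_id=subject,
                phase=phase,
                route=group["route"],
                analyte=analyte,
                dose_mg=group["dose_mg"],
                infusion_duration_h=group["duration"],
                points=points,
            )
        )
    return profiles


def _format_float(value: float | None) -> str:
    # repr round-trips float64 exactly through CSV
    return "" if value is None else repr(float(value))


def write_profiles(profiles: Iterable[ConcentrationProfile], path) -> None:
    """Write profiles in the canonical CSV dialect (lossless round trip)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for profile in profiles:
            for p in profile.points:
                writer.writerow(
                    [
                        profile.subject_id,
                        profile.phase.value,
                        profile.route.value,
                        profile.analyte.value,
                        _format_float(profile.dose_mg),
                        _format_float(profile.infusion_duration_h),
                        _format_float(p.time_h),
                        _format_float(p.conc_ng_ml),
                        "true" if p.bloq else "false",
                    ]
                )


DOSE_CSV_COLUMNS = ("subject", "phase", "weight_kg", "dose_per_m2_mg", "dose_mg")


def write_dose_records(records: Iterable[DoseRecord], path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(DOSE_CSV_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.subject_id,
                    r.phase.value,
                    _format_float(r.weight_kg),
                    _format_float(r.dose_per_m2_mg),
                    _format_float(r.dose_mg),
                ]
            )


def read_dose_records(path) -> list[DoseRecord]:
    path = Path(path)
    records = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        for canonical in DOSE_CSV_COLUMNS:
            if canonical not in (reader.fieldnames or []):
                raise SchemaError(f"missing column {canonical!r} in {path}")
        for line, row in enumerate(reader, start=2):
            records.append(
                DoseRecord(
                    subject_id=row["subject"],
                    phase=Phase(row["phase"]),
                    weight_kg=_parse_float(row["weight_kg"], "weight_kg", line),
                    dose_per_m2_mg=_parse_float(row["dose_per_m2_mg"], "dose_per_m2_mg", line),
                    dose_mg=_parse_float(row["dose_mg"], "dose_mg", line),
                )
            )
    return records
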