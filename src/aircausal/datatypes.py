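"""Core data containers shared across the ingest, regression and CCM layers.

The analysis operates on three kinds of series: hourly station-level ozone,
quality-controlled daily mean exposure, and daily stratified admission
counts.  All three are thin dataclasses around numpy/pandas objects so they
can be passed between modules without ambiguity about units or validity
flags.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DiseaseCategory",
    "AgeGroup",
    "StationHourlySeries",
    "DailyExposureSeries",
    "AdmissionRecord",
    "StratumCountSeries",
    "ICD10_PATTERN",
]

#: ICD-10 shape: one letter, two digits, optional dotted subcode ("J06.9").
ICD10_PATTERN = re.compile(r"^[A-Z][0-9]{2}(\.[0-9A-Za-z]{1,4})?$")


class DiseaseCategory(str, Enum):
    """Admission categories by ICD-10 chapter-J ranges.

    AURD: acute upper respiratory disease (J00-J06).
    ALRD: acute lower respiratory disease (J20-J22).
    OTHER_RESP: any other J00-J99 code.
    NON_RESP: outside chapter J.
    TOTAL_RESP: aggregate of all chapter-J admissions (aggregation-level
    label only; the record classifier never returns it).
    """

    AURD = "AURD"
    ALRD = "ALRD"
    OTHER_RESP = "OTHER_RESP"
    NON_RESP = "NON_RESP"
    TOTAL_RESP = "TOTAL_RESP"


class AgeGroup(str, Enum):
    CHILD = "0-14"
    ADULT = "15-64"
    ELDERLY = "65+"
    ALL = "all"

    @classmethod
    def of_age(cls, age: int) -> "AgeGroup":
        if age < 0:
            raise ValueError(f"negative age {age}")
        if age <= 14:
            return cls.CHILD
        if age <= 64:
            return cls.ADULT
        return cls.ELDERLY


GENDERS = ("male", "female")


@dataclass
class StationHourlySeries:
    """Hourly ozone (µg/m³) at one monitoring station; NaN marks missing."""

    station_id: str
    lon: float
    lat: float
    timestamps: pd.DatetimeIndex
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.timestamps) != len(self.values):
            raise ValueError("timestamps and values length mismatch")
        if len(self.timestamps) > 1:
            steps = np.diff(self.timestamps.asi8)
            if not np.all(steps == 3_600_000_000_000):
                raise ValueError(
                    f"station {self.station_id}: timestamps must be strictly "
                    "increasing with a 1-hour step"
                )
        finite = self.values[np.isfinite(self.values)]
        if finite.size and finite.min() < 0:
            raise ValueError(f"station {self.station_id}: negative concentration")


@dataclass
class DailyExposureSeries:
    """Daily mean ozone (µg/m³) with a per-day validity flag."""

    dates: pd.DatetimeIndex
    values: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not (len(self.dates) == len(self.values) == len(self.valid)):
            raise ValueError("dates/values/valid length mismatch")
        ok = self.values[self.valid]
        if ok.size and (np.any(~np.isfinite(ok)) or ok.min() < 0):
            raise ValueError("valid days must carry finite non-negative values")

    def __len__(self) -> int:
        return len(self.dates)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"date": self.dates, "value": self.values, "valid": self.valid}
        )

    def to_csv(self, path) -> None:
        df = self.to_frame()
        df["date"] = df["date"].dt.strftime("%Y-%m-%d")
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "DailyExposureSeries":
        """Read a daily series CSV: either `date,value,valid` or the
        simulator's `date,ozone_ugm3` dialect (all days valid)."""
        df = pd.read_csv(path)
        if "value" in df.columns:
            valid = (
                df["valid"].astype(bool).to_numpy()
                if "valid" in df.columns
                else np.ones(len(df), dtype=bool)
            )
            values = df["value"].to_numpy(dtype=float)
        elif "ozone_ugm3" in df.columns:
            values = df["ozone_ugm3"].to_numpy(dtype=float)
            valid = np.isfinite(values)
        else:
            raise ValueError(
                f"{path}: expected columns (date, value[, valid]) or "
                "(date, ozone_ugm3)"
            )
        return cls(pd.DatetimeIndex(pd.to_datetime(df["date"])), values, valid)


@dataclass(frozen=True)
class AdmissionRecord:
    """One emergency admission: date, hospital, gender, age and diagnosis."""

    date: pd.Timestamp
    hospital_id: str
    gender: str
    age: int
    icd10: str

    def __post_init__(self) -> None:
        if self.gender not in GENDERS:
            raise ValueError(f"gender must be one of {GENDERS}, got {self.gender!r}")
        if self.age < 0:
            raise ValueError("age must be >= 0")
        if not ICD10_PATTERN.match(self.icd10):
            raise ValueError(f"malformed ICD-10 code {self.icd10!r}")


@dataclass
class StratumCountSeries:
    """Daily admission counts for one (category, gender, age-group) stratum."""

    category: DiseaseCategory
    gender: str  # "male", "female" or "all"
    age_group: AgeGroup
    dates: pd.DatetimeIndex
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if len(self.dates) != len(self.counts):
            raise ValueError("dates and counts length mismatch")
        if self.counts.size:
            if not np.issubdtype(self.counts.dtype, np.integer):
                as_int = self.counts.astype(int)
                if not np.array_equal(as_int, self.counts):
                    raise ValueError("counts must be integers")
                self.counts = as_int
            if self.counts.min() < 0:
                raise ValueError("counts must be non-negative")
        if self.gender not in GENDERS + ("all",):
            raise ValueError(f"bad gender label {self.gender!r}")

    def __len__(self) -> int:
        return len(self.dates)

    @property
    def label(self) -> str:
        return f"{self.category.value}/{self.gender}/{self.age_group.value}"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "date": self.dates,
                "category": self.category.value,
                "gender": self.gender,
                "age_group": self.age_group.value,
                "count": self.counts,
            }
        )
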