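"""Reading, quality control and aggregation of monitoring and admission data.

Raw inputs are an hourly station-level ozone CSV and a record-level
admission CSV.  This module turns them into the two daily series the
analysis layers consume: a QC'd citywide daily-mean exposure series and
zero-filled stratified admission count series (disease category × gender ×
age group).
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    AdmissionRecord,
    AgeGroup,
    DailyExposureSeries,
    DiseaseCategory,
    GENDERS,
    ICD10_PATTERN,
    StationHourlySeries,
    StratumCountSeries,
)

__all__ = [
    "read_station_hourly",
    "read_admissions",
    "daily_mean_qc",
    "pool_citywide",
    "assign_nearest_station",
    "classify_icd10",
    "aggregate_daily_counts",
    "haversine_km",
]

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0


def read_station_hourly(path, dialect: str = "iso") -> list[StationHourlySeries]:
    """Read an hourly ozone CSV (`station,lon,lat,timestamp,ozone_ugm3`).

    Returns one series per station, reindexed to a full hourly grid between
    each station's first and last timestamp; unparsable value cells become
    missing with a logged warning.
    """
    df = pd.read_csv(path, dtype={"station": str})
    required = {"station", "lon", "lat", "timestamp", "ozone_ugm3"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required column(s) {sorted(missing)}")
    if df.empty:
        return []
    raw = df["ozone_ugm3"]
    values = pd.to_numeric(raw, errors="coerce")
    bad = values.isna() & raw.notna()
    if bad.any():
        logger.warning("%s: %d non-numeric ozone values treated as missing",
                       path, int(bad.sum()))
    df = df.assign(
        ozone_ugm3=values,
        timestamp=pd.to_datetime(df["timestamp"], dayfirst=(dialect == "dmy")),
    )
    out = []
    for sid, grp in df.groupby("station", sort=True):
        grp = grp.sort_values("timestamp")
        idx = pd.date_range(grp["timestamp"].iloc[0], grp["timestamp"].iloc[-1],
                            freq="h")
        series = grp.set_index("timestamp")["ozone_ugm3"].reindex(idx)
        out.append(
            StationHourlySeries(
                station_id=str(sid),
                lon=float(grp["lon"].iloc[0]),
                lat=float(grp["lat"].iloc[0]),
                timestamps=idx,
                values=series.to_numpy(dtype=float),
            )
        )
    return out


def read_admissions(path, dialect: str = "iso") -> list[AdmissionRecord]:
    """Read an admission CSV (`date,hospital,gender,age,icd10`).

    ``dialect='dmy'`` parses dates as dd/mm/yyyy; it is never auto-guessed.
    """
    df = pd.read_csv(path, dtype={"hospital": str, "icd10": str})
    required = {"date", "hospital", "gender", "age", "icd10"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required column(s) {sorted(missing)}")
    dates = pd.to_datetime(df["date"], dayfirst=(dialect == "dmy"))
    return [
        AdmissionRecord(
            date=d,
            hospital_id=str(h),
            gender=str(g).lower(),
            age=int(a),
            icd10=str(c),
        )
        for d, h, g, a, c in zip(dates, df["hospital"], df["gender"],
                                 df["age"], df["icd10"])
    ]


def daily_mean_qc(
    series: StationHourlySeries, min_completeness: float = 0.75
) -> DailyExposureSeries:
    """Daily mean with a completeness rule: a day is valid iff at least
    ``min_completeness`` of its 24 hours are non-missing; instrument-failure
    days are thereby excluded rather than imputed."""
    if not (0 < min_completeness <= 1):
        raise ValueError("min_completeness must be in (0, 1]")
    s = pd.Series(series.values, index=series.timestamps)
    by_day = s.groupby(s.index.floor("D"))
    n_obs = by_day.count()
    means = by_day.mean()
    dates = pd.DatetimeIndex(means.index)
    valid = (n_obs / 24.0 >= min_completeness).to_numpy()
    values = means.to_numpy(dtype=float)
    values[~valid & ~np.isfinite(values)] = np.nan
    return DailyExposureSeries(dates, values, valid)


def pool_citywide(
    per_station: Sequence[DailyExposureSeries], min_completeness: float = 0.75
) -> DailyExposureSeries:
    """Unweighted mean over stations with a valid value on each day.

    A pooled day is valid iff the fraction of stations reporting a valid
    value reaches ``min_completeness``.
    """
    if not per_station:
        raise ValueError("need at least one station series")
    frames = [
        s.to_frame().set_index("date")[["value", "valid"]] for s in per_station
    ]
    dates = frames[0].index
    for f in frames[1:]:
        dates = dates.union(f.index)
    if len(dates) == 0:
        raise ValueError("no overlapping dates between station series")
    vals = np.full((len(dates), len(frames)), np.nan)
    ok = np.zeros((len(dates), len(frames)), dtype=bool)
    for j, f in enumerate(frames):
        f = f.reindex(dates)
        fv = f["valid"].fillna(False).to_numpy(dtype=bool)
        ok[:, j] = fv
        vals[fv, j] = f["value"].to_numpy(dtype=float)[fv]
    n_ok = ok.sum(axis=1)
    valid = n_ok / len(frames) >= min_completeness
    with np.errstate(invalid="ignore"):
        values = np.where(n_ok > 0, np.nansum(vals, axis=1) / np.maximum(n_ok, 1),
                          np.nan)
    return DailyExposureSeries(pd.DatetimeIndex(dates), values, valid)


def haversine_km(lon1, lat1, lon2, lat2) -> float:
    """Great-circle distance in km on a 6371-km sphere."""
    lam1, phi1, lam2, phi2 = map(math.radians, (lon1, lat1, lon2, lat2))
    a = (
        math.sin((phi2 - phi1) / 2) ** 2
        + math.cos(phi1) * math.cos(phi2) * math.sin((lam2 - lam1) / 2) ** 2
    )
    return 2 * EARTH_RADIUS_KM * math.asin(math.sqrt(a))


def _check_coords(coords: Mapping[str, tuple], what: str) -> None:
    if not coords:
        raise ValueError(f"{what} coordinates must be non-empty")
    for cid, (lon, lat) in coords.items():
        if abs(lat) > 90 or abs(lon) > 180:
            raise ValueError(f"invalid coordinates for {what} {cid}: ({lon}, {lat})")


def assign_nearest_station(
    hospital_coords: Mapping[str, tuple],
    station_coords: Mapping[str, tuple],
) -> dict[str, str]:
    """Map each hospital to its great-circle-nearest station (ties broken by
    lexicographic station id).  Coordinates are `(lon, lat)` decimal degrees."""
    _check_coords(hospital_coords, "hospital")
    _check_coords(station_coords, "station")
    mapping = {}
    stations = sorted(station_coords.items())
    for hid, (hlon, hlat) in hospital_coords.items():
        best = min(stations, key=lambda s: (haversine_km(hlon, hlat, *s[1]), s[0]))
        mapping[hid] = best[0]
    return mapping


def classify_icd10(code: str) -> DiseaseCategory:
    """Classify an ICD-10 code by its 3-character root.

    J00-J06 → AURD, J20-J22 → ALRD, other J00-J99 → OTHER_RESP, anything
    outside chapter J → NON_RESP.  Subcodes ("J06.9") inherit the root's
    category.
    """
    if not isinstance(code, str) or not ICD10_PATTERN.match(code):
        raise ValueError(f"malformed ICD-10 code {code!r}")
    root = code[:3]
    if root[0] != "J":
        return DiseaseCategory.NON_RESP
    num = int(root[1:])
    if 0 <= num <= 6:
        return DiseaseCategory.AURD
    if 20 <= num <= 22:
        return DiseaseCategory.ALRD
    return DiseaseCategory.OTHER_RESP


_CATEGORIES = (DiseaseCategory.TOTAL_RESP, DiseaseCategory.AURD, DiseaseCategory.ALRD)
_GENDER_LEVELS = ("male", "female", "all")
_AGE_LEVELS = (AgeGroup.CHILD, AgeGroup.ADULT, AgeGroup.ELDERLY, AgeGroup.ALL)


def aggregate_daily_counts(
    records: Iterable[AdmissionRecord],
    date_range: pd.DatetimeIndex,
) -> list[StratumCountSeries]:
    """Aggregate records into zero-filled daily counts for every stratum
    combination (TOTAL_RESP/AURD/ALRD × gender incl. 'all' × age group incl.
    'all').  TOTAL_RESP counts every chapter-J (J00-J99) record; non-J
    records are ignored.  A record dated outside ``date_range`` is an error.
    """
    date_range = pd.DatetimeIndex(date_range)
    pos = {d: i for i, d in enumerate(date_range)}
    n = len(date_range)
    counts = {
        (c, g, a): np.zeros(n, dtype=int)
        for c in _CATEGORIES
        for g in _GENDER_LEVELS
        for a in _AGE_LEVELS
    }
    for r in records:
        if r.date not in pos:
            raise ValueError(f"record dated {r.date.date()} outside date_range")
        cat = classify_icd10(r.icd10)
        if cat is DiseaseCategory.NON_RESP:
            continue
        i = pos[r.date]
        age = AgeGroup.of_age(r.age)
        cats = [DiseaseCategory.TOTAL_RESP]
        if cat in (DiseaseCategory.AURD, DiseaseCategory.ALRD):
            cats.append(cat)
        for c in cats:
            for g in (r.gender, "all"):
                for a in (age, AgeGroup.ALL):
                    counts[(c, g, a)][i] += 1
    return [
        StratumCountSeries(category=c, gender=g, age_group=a,
                           dates=date_range, counts=arr)
        for (c, g, a), arr in counts.items()
    ]
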