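"""Domain types, climate preprocessing and outcome/climate bookkeeping.

The study design is longitudinal mark-resight monitoring of female mountain
goats: each row of the records table is one female-year, with a binary
parturition outcome (kid at heel during the May birth season), the previous
year's parturition status, the kid's summer fate, and the female's annual
survival.  Climate covariates are annual series: mean daily snow depth (m)
over late winter (March-April) and mean daily temperature (degC) over
mid-summer (July-August), both keyed by calendar year.

Timing conventions
------------------
Parturition (and kid summer fate) in birth year ``y`` responds to conditions
of the biological year leading into gestation and birth: late-winter snow of
year ``y`` itself (March-April precedes the May births) and the previous
growing season's temperature, ``y - 1``.  Adult annual survival runs over the
biological year June ``y`` to May ``y + 1``, so it is paired with summer
temperature of year ``y`` and late-winter snow of year ``y + 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LAPSE_RATE_C_PER_M",
    "IndividualYearRecord",
    "ClimateRecord",
    "AgeClassSpec",
    "DEFAULT_AGE_CLASSES",
    "SURVIVAL_AGE_CLASSES",
    "OFFSPRING_AGE_CLASSES",
    "adjust_temperature",
    "attach_climate",
    "assign_age_class",
    "read_records_csv",
    "read_climate_csv",
    "write_records_csv",
    "write_climate_csv",
]

#: Environmental lapse rate, degC per metre of elevation gain (negative:
#: temperature falls with elevation).
LAPSE_RATE_C_PER_M = -6.58 / 1000.0

RECORD_COLUMNS = [
    "individual_id",
    "site",
    "year",
    "age",
    "parturition",
    "prev_reproduction",
    "offspring_summer_survival",
    "adult_annual_survival",
]

OUTCOMES = ("parturition", "adult_survival", "offspring_survival")


@dataclass(frozen=True)
class IndividualYearRecord:
    """One female-year observation.

    Binary fields use 1/0; ``None`` marks a field that could not be
    determined that year (e.g. previous-year parturition in the capture
    year).  ``offspring_summer_survival`` is only defined when
    ``parturition == 1``.
    """

    individual_id: str
    site: str
    year: int
    age: int
    parturition: Optional[int] = None
    prev_reproduction: Optional[int] = None
    offspring_summer_survival: Optional[int] = None
    adult_annual_survival: Optional[int] = None
    twins: Optional[int] = None

    def __post_init__(self) -> None:
        if self.age < 1:
            raise ValueError(f"age must be >= 1, got {self.age}")
        if self.offspring_summer_survival is not None and self.parturition != 1:
            raise ValueError(
                "offspring_summer_survival set on a record without parturition"
            )


@dataclass(frozen=True)
class ClimateRecord:
    """Annual climate covariates: snow depth (m) and summer temperature (degC)."""

    year: int
    snow: float
    temp: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.snow) or not np.isfinite(self.temp):
            raise ValueError("climate values must be finite")
        if self.snow < 0:
            raise ValueError("snow depth cannot be negative")


@dataclass(frozen=True)
class AgeClassSpec:
    """Ordered, disjoint integer age bins with labels.

    The first bin is the reference class in model design matrices (it
    carries no dummy).  Ages outside every bin are excluded from analysis
    (for parturition: ages 1-2, at which no births are observed).
    """

    bins: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        covered: set[int] = set()
        prev_hi = -1
        for label, lo, hi in self.bins:
            if lo > hi:
                raise ValueError(f"bin {label!r} has lo > hi")
            if lo <= prev_hi:
                raise ValueError("bins must be ordered and disjoint")
            prev_hi = hi
            covered.update(range(lo, hi + 1))
        if not self.bins:
            raise ValueError("at least one bin required")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(label for label, _, _ in self.bins)

    @property
    def reference(self) -> str:
        return self.bins[0][0]

    @property
    def min_age(self) -> int:
        return self.bins[0][1]

    @property
    def max_age(self) -> int:
        return self.bins[-1][2]

    def assign(self, age: int) -> Optional[str]:
        for label, lo, hi in self.bins:
            if lo <= age <= hi:
                return label
        return None


#: Six-bin scheme used for parturition: primiparous ages singled out,
#: prime-aged pooled, two senescent bins.
DEFAULT_AGE_CLASSES = AgeClassSpec(
    bins=(
        ("3", 3, 3),
        ("4", 4, 4),
        ("5", 5, 5),
        ("6-10", 6, 10),
        ("11-13", 11, 13),
        ("14-16", 14, 16),
    )
)

#: Collapsed three-bin scheme used for adult female annual survival.
SURVIVAL_AGE_CLASSES = AgeClassSpec(
    bins=(("3-5", 3, 5), ("6-10", 6, 10), ("11-16", 11, 16))
)

#: Two-bin maternal-age scheme used for offspring summer survival.
OFFSPRING_AGE_CLASSES = AgeClassSpec(bins=(("3-10", 3, 10), ("11-16", 11, 16)))


def adjust_temperature(
    t_station: float, elev_station: float, elev_target: float
) -> float:
    """Project a station temperature to a target elevation via the lapse rate.

    Uses the environmental lapse rate of -6.58 degC per 1000 m: moving the
    measurement uphill by ``d`` metres lowers it by ``6.58 * d / 1000`` degC.
    """
    if not (np.isfinite(elev_station) and np.isfinite(elev_target)):
        raise ValueError("elevations must be finite")
    return t_station + (elev_target - elev_station) * LAPSE_RATE_C_PER_M


def assign_age_class(age: int, spec: AgeClassSpec = DEFAULT_AGE_CLASSES) -> Optional[str]:
    """Map an integer age to its bin label, or ``None`` if excluded."""
    return spec.assign(age)


def records_to_frame(records: Iterable[IndividualYearRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "individual_id": r.individual_id,
                "site": r.site,
                "year": r.year,
                "age": r.age,
                "parturition": r.parturition,
                "prev_reproduction": r.prev_reproduction,
                "offspring_summer_survival": r.offspring_summer_survival,
                "adult_annual_survival": r.adult_annual_survival,
                "twins": r.twins,
            }
        )
    df = pd.DataFrame(rows, columns=RECORD_COLUMNS + ["twins"])
    return df


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = records_to_frame(records)
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"records table missing columns: {missing}")
    dup = df.duplicated(subset=["individual_id", "year"])
    if dup.any():
        raise ValueError(
            f"duplicate (individual_id, year) pairs: {int(dup.sum())} rows"
        )
    return df


def _climate_frame(climate) -> pd.DataFrame:
    if isinstance(climate, pd.DataFrame):
        df = climate.rename(columns={"snow_m": "snow", "temp_c": "temp"}).copy()
    else:
        df = pd.DataFrame(
            [{"year": c.year, "snow": c.snow, "temp": c.temp} for c in climate]
        )
    for col in ("year", "snow", "temp"):
        if col not in df.columns:
            raise ValueError(f"climate table missing column {col!r}")
    return df.set_index("year")


@dataclass
class AttachResult:
    """Analysis table plus bookkeeping of rows dropped for missing fields."""

    table: pd.DataFrame
    n_input: int
    n_dropped: int

    def __post_init__(self) -> None:
        assert self.n_input == len(self.table) + self.n_dropped


def attach_climate(records, climate, outcome: str) -> AttachResult:
    """Join climate covariates onto records for one outcome's analysis.

    Parameters
    ----------
    records : DataFrame or iterable of IndividualYearRecord
    climate : DataFrame (year, snow_m, temp_c) or iterable of ClimateRecord
    outcome : one of ``parturition``, ``adult_survival``, ``offspring_survival``

    Returns
    -------
    AttachResult with a table holding ``y`` (the outcome), covariates
    ``snow``/``temp``, and the identifying columns; rows with any required
    field missing are dropped and counted, so
    ``n_input == len(table) + n_dropped``.
    """
    if outcome not in OUTCOMES:
        raise ValueError(f"unknown outcome {outcome!r}; expected one of {OUTCOMES}")
    df = _as_frame(records)
    clim = _climate_frame(climate)
    n_input = len(df)
    if n_input == 0:
        empty = df.assign(y=pd.Series(dtype=float), snow=np.nan, temp=np.nan)
        return AttachResult(table=empty, n_input=0, n_dropped=0)

    year = df["year"].to_numpy()
    if outcome == "adult_survival":
        snow_year, temp_year = year + 1, year
    else:  # parturition / offspring: gestation-year conditions
        snow_year, temp_year = year, year - 1

    needed = np.union1d(snow_year, temp_year)
    missing_years = sorted(set(needed) - set(clim.index))
    if missing_years:
        raise ValueError(f"climate series missing years: {missing_years}")

    out = df.copy()
    out["snow"] = clim["snow"].reindex(snow_year).to_numpy()
    out["temp"] = clim["temp"].reindex(temp_year).to_numpy()

    if outcome == "parturition":
        required = ["parturition", "prev_reproduction"]
        out["y"] = out["parturition"]
    elif outcome == "adult_survival":
        required = ["adult_annual_survival", "parturition"]
        out["y"] = out["adult_annual_survival"]
    else:
        required = ["offspring_summer_survival", "prev_reproduction"]
        out["y"] = out["offspring_summer_survival"]

    keep = out[required].notna().all(axis=1)
    dropped = int((~keep).sum())
    table = out.loc[keep].reset_index(drop=True)
    table["y"] = table["y"].astype(int)
    return AttachResult(table=table, n_input=n_input, n_dropped=dropped)


def build_analysis_table(
    records, climate, outcome: str, age_spec: AgeClassSpec
) -> AttachResult:
    """attach_climate plus age-class labelling and out-of-range exclusion."""
    res = attach_climate(records, climate, outcome)
    table = res.table
    if len(table) == 0:
        table = table.assign(age_class=pd.Series(dtype=object))
        return AttachResult(table, res.n_input, res.n_dropped)
    labels = table["age"].map(age_spec.assign)
    keep = labels.notna()
    dropped = res.n_dropped + int((~keep).sum())
    table = table.loc[keep].copy()
    table["age_class"] = labels[keep]
    return AttachResult(table.reset_index(drop=True), res.n_input, dropped)


# ---------------------------------------------------------------------------
# CSV round-tripping.  Files may carry '#'-prefixed provenance headers.

def read_records_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#", dtype={"individual_id": str, "site": str})
    return _as_frame(df)


def read_climate_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    for col in ("year", "snow_m", "temp_c"):
        if col not in df.columns:
            raise ValueError(f"climate CSV missing column {col!r}")
    return df


def _write_with_header(df: pd.DataFrame, path, header_lines: Sequence[str]) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)


def write_records_csv(df: pd.DataFrame, path, header_lines: Sequence[str] = ()) -> None:
    _write_with_header(df, path, header_lines)


def write_climate_csv(df: pd.DataFrame, path, header_lines: Sequence[str] = ()) -> None:
    out = df.rename(columns={"snow": "snow_m", "temp": "temp_c"})
    _write_with_header(out, path, header_lines)
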