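"""Station-climate processing: gap-filling, aridity indexes and trends.

The workflow mirrors standard practice for sparse lowland station
networks: one station with a complete record serves as predictor for
neighbouring stations whose monthly temperature/precipitation series
have gaps; gaps are filled by ordinary least squares, annual totals and
means are formed, and two aridity indexes are computed per station-year:

* De Martonne index  ``I_DM = P / (T + 10)``  (mm/°C), annual
  precipitation over mean annual temperature offset by 10 — lower is
  more arid, with values under ~15 indicating steppe conditions.
* UNEP index  ``I_UNEP = P / PET``  (dimensionless), with potential
  evapotranspiration estimated from monthly temperature by the
  Thornthwaite method; 0.2–0.5 marks semi-arid climate.
"""

from __future__ import annotations

import calendar
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StationRegression",
    "TrendFit",
    "fit_station_regression",
    "fill_gaps",
    "annual_summary",
    "de_martonne",
    "thornthwaite_pet",
    "day_length_correction",
    "unep_index",
    "classify_aridity",
    "linear_trend",
    "aridity_table",
    "read_climate_table",
    "write_climate_table",
    "DM_CLASSES",
    "UNEP_CLASSES",
]

CLIMATE_COLUMNS = ["station", "year", "month", "T", "P"]


def _validate_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CLIMATE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"climate table lacks columns: {missing}")
    if table.duplicated(["station", "year", "month"]).any():
        raise ValueError("duplicate (station, year, month) records")
    if ((table["month"] < 1) | (table["month"] > 12)).any():
        raise ValueError("month must be in 1..12")
    if (table["P"].dropna() < 0).any():
        raise ValueError("negative precipitation")
    return table


def read_climate_table(path) -> pd.DataFrame:
    """Read a delimited monthly climate table (empty cell = missing)."""
    table = pd.read_csv(path, dtype={"station": str})
    return _validate_table(table)


def write_climate_table(table: pd.DataFrame, path) -> None:
    _validate_table(table).to_csv(path, index=False)


@dataclass(frozen=True)
class StationRegression:
    """An OLS link of one station's variable to a predictor station."""

    target_station: str
    predictor_station: str
    variable: str
    slope: float
    intercept: float
    r: float
    n_overlap: int


@dataclass(frozen=True)
class TrendFit:
    """Linear trend of an annual series (slope in units per year)."""

    slope: float
    intercept: float
    r: float
    p_note: str = ""


def fit_station_regression(
    table: pd.DataFrame, target: str, predictor: str, variable: str
) -> StationRegression:
    """OLS of a target station's monthly variable on a predictor station's.

    Pairs months where both stations report the variable; a single
    slope/intercept is fitted over all pooled months. A constant target
    yields slope 0, intercept = target mean, r = 0 (the fill then
    reproduces the constant). Zero predictor variance is an error since
    the regression would be unidentifiable.
    """
    _validate_table(table)
    if variable not in ("T", "P"):
        raise ValueError("variable must be 'T' or 'P'")
    wide = table.pivot_table(
        index=["year", "month"], columns="station", values=variable, aggfunc="first"
    )
    for st in (target, predictor):
        if st not in wide.columns:
            raise ValueError(f"station {st!r} not in table")
    paired = wide[[target, predictor]].dropna()
    n = len(paired)
    if n < 2:
        raise ValueError(
            f"insufficient overlap between {target!r} and {predictor!r}: {n} paired months"
        )
    y = paired[target].to_numpy()
    x = paired[predictor].to_numpy()
    if np.var(x) == 0:
        raise ValueError(f"predictor station {predictor!r} has zero variance")
    if np.var(y) == 0:
        slope, intercept, r = 0.0, float(y.mean()), 0.0
    else:
        res = stats.linregress(x, y)
        slope, intercept, r = float(res.slope), float(res.intercept), float(res.rvalue)
    return StationRegression(target, predictor, variable, slope, intercept, r, n)


def fill_gaps(
    table: pd.DataFrame, regressions: list[StationRegression]
) -> pd.DataFrame:
    """Fill missing monthly values from fitted station regressions.

    Returns a copy with boolean columns ``T_filled`` / ``P_filled``
    marking imputed cells. Observed values are never altered. A gap
    whose predictor month is itself missing stays missing (and stays
    flagged False).
    """
    _validate_table(table)
    out = table.copy().reset_index(drop=True)
    for var in ("T", "P"):
        out[f"{var}_filled"] = False
    by_key = {(r.target_station, r.variable): r for r in regressions}
    for (station, var), reg in by_key.items():
        pred = out[out["station"] == reg.predictor_station].set_index(["year", "month"])[var]
        rows = out.index[(out["station"] == station) & out[var].isna()]
        for i in rows:
            key = (out.at[i, "year"], out.at[i, "month"])
            if key in pred.index and not pd.isna(pred.loc[key]):
                value = reg.slope * float(pred.loc[key]) + reg.intercept
                if var == "P":
                    value = max(value, 0.0)
                out.at[i, var] = value
                out.at[i, f"{var}_filled"] = True
    # report any gap left unfilled
    still = out[out[["T", "P"]].isna().any(axis=1)]
    if len(still):
        warnings.warn(
            f"{len(still)} station-months remain missing after gap-filling", stacklevel=2
        )
    return out


def annual_summary(table: pd.DataFrame, station: str, year: int) -> tuple[float, float]:
    """(annual precipitation sum mm, annual mean temperature °C).

    Requires all 12 months present for the station-year; the error names
    the missing months so the gap-filling step can be revisited.
    """
    sub = table[(table["station"] == station) & (table["year"] == year)]
    months_p = set(sub.loc[sub["P"].notna(), "month"])
    months_t = set(sub.loc[sub["T"].notna(), "month"])
    absent = sorted(set(range(1, 13)) - (months_p & months_t))
    if absent:
        raise ValueError(
            f"station {station!r} year {year}: months {absent} missing or incomplete"
        )
    return float(sub["P"].sum()), float(sub["T"].mean())


def de_martonne(p_annual: float, t_mean: float) -> float:
    """De Martonne aridity index P/(T+10) in mm/°C."""
    if t_mean <= -10:
        raise ValueError("De Martonne index undefined for T ≤ −10 °C")
    if p_annual < 0:
        raise ValueError("negative annual precipitation")
    return p_annual / (t_mean + 10.0)


def day_length_correction(latitude: float, month: int) -> float:
    """Thornthwaite monthly correction (mean day length/12)·(days/30).

    Day length from the standard solar-declination formula evaluated at
    the mid-month day of year; a non-leap calendar is used throughout.
    """
    days_in_month = calendar.monthrange(2001, month)[1]
    doy = sum(calendar.monthrange(2001, m)[1] for m in range(1, month)) + days_in_month / 2
    decl = 0.409 * math.sin(2 * math.pi * doy / 365 - 1.39)
    phi = math.radians(latitude)
    cos_omega = -math.tan(phi) * math.tan(decl)
    omega = math.acos(min(1.0, max(-1.0, cos_omega)))
    day_length_h = 24.0 / math.pi * omega
    return (day_length_h / 12.0) * (days_in_month / 30.0)


def thornthwaite_pet(
    monthly_t: np.ndarray, latitude: float, apply_day_length: bool = True
) -> np.ndarray:
    """Monthly potential evapotranspiration (mm) by Thornthwaite.

    Heat index I = Σ_{T>0} (T/5)^1.514 over the 12 months; exponent
    a = 6.75e−7·I³ − 7.71e−5·I² + 1.792e−2·I + 0.49239. Unadjusted
    PET = 16·(10T/I)^a for 0 < T ≤ 26.5 °C, the high-temperature
    polynomial −415.85 + 32.24·T − 0.43·T² above 26.5 °C, and 0 for
    freezing months; each month is then scaled by the day-length
    correction unless ``apply_day_length`` is False.
    """
    t = np.asarray(monthly_t, dtype=float)
    if t.shape != (12,):
        raise ValueError("monthly_t must hold exactly 12 values")
    if not -66.5 <= latitude <= 66.5:
        raise ValueError("latitude outside [-66.5, 66.5] (polar day/night)")
    heat_index = float(np.sum(np.where(t > 0, (np.maximum(t, 0) / 5.0) ** 1.514, 0.0)))
    if heat_index == 0:
        warnings.warn("all months at or below 0 °C: PET identically zero", stacklevel=2)
        return np.zeros(12)
    a = (
        6.75e-7 * heat_index**3
        - 7.71e-5 * heat_index**2
        + 1.792e-2 * heat_index
        + 0.49239
    )
    pet = np.zeros(12)
    moderate = (t > 0) & (t <= 26.5)
    hot = t > 26.5
    pet[moderate] = 16.0 * (10.0 * t[moderate] / heat_index) ** a
    pet[hot] = -415.85 + 32.24 * t[hot] - 0.43 * t[hot] ** 2
    if apply_day_length:
        corr = np.array([day_length_correction(latitude, m) for m in range(1, 13)])
        pet = pet * corr
    return pet


def unep_index(p_annual: float, pet_annual: float) -> float:
    """UNEP aridity index P/PET (dimensionless)."""
    if pet_annual <= 0:
        raise ValueError("annual PET must be positive")
    return p_annual / pet_annual


# Half-open [low, high) class schemes. The De Martonne bands follow the
# classical scheme (semi-arid/steppe for 15–20); the UNEP bands follow
# the 1992 UNEP drylands scheme (semi-arid for 0.2–0.5).
DM_CLASSES = [
    (10.0, "arid (<10)"),
    (15.0, "semi-arid (10–15)"),
    (20.0, "semi-arid/steppe (15–20)"),
    (24.0, "moderately dry (20–24)"),
    (28.0, "moderately humid (24–28)"),
    (math.inf, "humid (≥28)"),
]
UNEP_CLASSES = [
    (0.05, "hyper-arid (<0.05)"),
    (0.2, "arid (0.05–0.2)"),
    (0.5, "semi-arid (0.2–0.5)"),
    (0.65, "dry sub-humid (0.5–0.65)"),
    (math.inf, "humid (≥0.65)"),
]


def classify_aridity(value: float, scheme: str) -> str:
    """Label an index value under the 'DM' or 'UNEP' boundary scheme."""
    if not math.isfinite(value):
        raise ValueError("aridity index must be finite")
    bands = {"DM": DM_CLASSES, "UNEP": UNEP_CLASSES}.get(scheme.upper())
    if bands is None:
        raise ValueError("scheme must be 'DM' or 'UNEP'")
    for high, label in bands:
        if value < high:
            return label
    raise AssertionError("unreachable")


def linear_trend(years, values) -> TrendFit:
    """OLS trend of an annual index series; slope per year."""
    years = np.asarray(years, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(years) < 3:
        raise ValueError("trend needs at least 3 years")
    if np.var(values) == 0:
        return TrendFit(0.0, float(values.mean()), 0.0, "constant series")
    res = stats.linregress(years, values)
    return TrendFit(float(res.slope), float(res.intercept), float(res.rvalue))


def aridity_table(table: pd.DataFrame, latitude: float) -> pd.DataFrame:
    """Per station-year aridity results on a (gap-filled) monthly table.

    Years with any missing month are skipped. Output columns: station,
    year, P_annual, T_mean, I_DM, PET_annual, I_UNEP, class_DM,
    class_UNEP, n_filled.
    """
    _validate_table(table)
    has_flags = "P_filled" in table.columns and "T_filled" in table.columns
    records = []
    for (station, year), sub in table.groupby(["station", "year"], sort=True):
        complete = sub[["T", "P"]].notna().all(axis=None) and len(sub) == 12
        if not complete:
            continue
        p_annual, t_mean = annual_summary(table, station, year)
        monthly_t = sub.sort_values("month")["T"].to_numpy()
        pet_annual = float(thornthwaite_pet(monthly_t, latitude).sum())
        i_dm = de_martonne(p_annual, t_mean)
        i_unep = unep_index(p_annual, pet_annual) if pet_annual > 0 else math.nan
        n_filled = int(sub[["T_filled", "P_filled"]].sum().sum()) if has_flags else 0
        records.append(
            {
                "station": station,
                "year": year,
                "P_annual": p_annual,
                "T_mean": t_mean,
                "I_DM": i_dm,
                "PET_annual": pet_annual,
                "I_UNEP": i_unep,
                "class_DM": classify_aridity(i_dm, "DM"),
                "class_UNEP": classify_aridity(i_unep, "UNEP") if math.isfinite(i_unep) else "",
                "n_filled": n_filled,
            }
        )
    return pd.DataFrame.from_records(records)
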