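"""Vegetation-index rasters, threshold classification and area accounting.

Implements the degradation-assessment track: radiometric calibration of
digital-number imagery to top-of-atmosphere reflectance with dark-object
atmospheric correction, the NDVI and MSAVI2 indexes, threshold binning
(bare surfaces below 0.1, dense vegetation above 0.3, very dense canopy
above 0.55/0.57), per-class and per-zone area accounting in hectares,
two-date change rates, and the cross-index regression used to compare
exposed-area estimates between NDVI and MSAVI2.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy import stats

from .grid import Grid

__all__ = [
    "CalibrationMeta",
    "BinSpec",
    "PAPER_BINS",
    "calibrate",
    "ndvi",
    "msavi2",
    "classify",
    "area_by_class",
    "area_change",
    "zonal_area",
    "cross_index_regression",
    "index_histogram",
    "mosaic_first_valid",
]


@dataclass(frozen=True)
class CalibrationMeta:
    """Landsat-style band calibration and solar geometry.

    gain/offset convert digital numbers to at-sensor radiance
    (W·m⁻²·sr⁻¹·µm⁻¹ per DN); esun is the band's exo-atmospheric solar
    irradiance; the dark-object DN implements DOS1 atmospheric
    correction (the darkest scene object is assumed to have zero
    surface reflectance, so its radiance is subtracted as haze).
    """

    gain: float
    offset: float
    esun: float
    sun_elevation: float
    earth_sun_distance: float = 1.0
    dark_object_dn: float = 0.0

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ValueError("gain must be positive")
        if not 0 < self.sun_elevation <= 90:
            raise ValueError("sun_elevation must be in (0, 90]")
        if self.esun <= 0:
            raise ValueError("esun must be positive")


def calibrate(dn: Grid, meta: CalibrationMeta) -> Grid:
    """DN → top-of-atmosphere reflectance with dark-object subtraction.

    radiance = gain·DN + offset, minus the dark-object radiance, floored
    at zero; reflectance = π·L·d² / (esun·sin(sun_elevation)).
    """
    radiance = meta.gain * dn.values + meta.offset
    haze = meta.gain * meta.dark_object_dn + meta.offset
    radiance = np.maximum(radiance - haze, 0.0)
    rho = (
        math.pi
        * radiance
        * meta.earth_sun_distance**2
        / (meta.esun * math.sin(math.radians(meta.sun_elevation)))
    )
    return dn.with_values(rho)


def _index_pair(nir: Grid, red: Grid) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    nir.require_same_geometry(red, "NIR and RED bands")
    valid = nir.mask & red.mask
    return nir.values, red.values, valid


def ndvi(nir: Grid, red: Grid) -> Grid:
    """(NIR − RED)/(NIR + RED); zero-sum pixels become nodata."""
    n, r, valid = _index_pair(nir, red)
    denom = n + r
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(valid & (denom != 0), (n - r) / denom, np.nan)
    return nir.with_values(out)


def msavi2(nir: Grid, red: Grid) -> Grid:
    """Modified soil-adjusted vegetation index (self-adjusting L factor).

    (2·NIR + 1 − sqrt((2·NIR + 1)² − 8·(NIR − RED))) / 2. A negative
    discriminant (possible only for band values outside the physical
    range) is clamped to zero and the affected pixels are reported.
    """
    n, r, valid = _index_pair(nir, red)
    d = 2 * n + 1
    disc = d * d - 8 * (n - r)
    negative = valid & (disc < 0)
    if negative.any():
        warnings.warn(
            f"MSAVI2 discriminant negative on {int(negative.sum())} pixels; clamped to 0",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore"):
        out = (d - np.sqrt(np.maximum(disc, 0.0))) / 2.0
    return nir.with_values(np.where(valid, out, np.nan))


@dataclass(frozen=True)
class BinSpec:
    """Ordered half-open [low, high) value bins with labels.

    ``breaks`` are the interior breakpoints; ``labels`` has one more
    entry than ``breaks`` and names the bins from lowest to highest.
    """

    breaks: tuple[float, ...]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if list(self.breaks) != sorted(set(self.breaks)):
            raise ValueError("breakpoints must be strictly increasing")
        if len(self.labels) != len(self.breaks) + 1:
            raise ValueError("need exactly one more label than breakpoints")

    def bin_index(self, values: np.ndarray) -> np.ndarray:
        # right=False → value == break falls in the upper bin
        return np.digitize(values, self.breaks, right=False)


#: The threshold scheme used for the two-date comparison: bare/exposed
#: below 0.1, dense vegetation above 0.3, very dense canopy above 0.55.
PAPER_BINS = BinSpec(
    breaks=(0.1, 0.2, 0.3, 0.55),
    labels=(
        "exposed (<0.1)",
        "sparse (0.1–0.2)",
        "moderate (0.2–0.3)",
        "dense (0.3–0.55)",
        "very dense (≥0.55)",
    ),
)


def classify(index: Grid, bins: BinSpec) -> Grid:
    """Per-pixel bin index (0-based, nodata propagated as NaN)."""
    idx = bins.bin_index(index.values).astype(float)
    return index.with_values(np.where(index.mask, idx, np.nan))


def area_by_class(classified: Grid, labels: dict[int, str] | None = None) -> pd.DataFrame:
    """Area (ha) and share (%) per class of a categorical raster.

    Shares are relative to the non-nodata area. Requires a metric
    (projected) grid; geographic grids have no constant pixel area.
    """
    if classified.crs_units != "m":
        raise ValueError("area accounting requires a projected grid in metres")
    codes = classified.values[classified.mask].astype(int)
    px_ha = classified.pixel_size**2 / 1e4
    counts = pd.Series(codes).value_counts().sort_index()
    total = counts.sum()
    out = pd.DataFrame(
        {
            "class": counts.index,
            "pixels": counts.to_numpy(),
            "area_ha": counts.to_numpy() * px_ha,
            "share_pct": counts.to_numpy() / total * 100.0 if total else 0.0,
        }
    ).reset_index(drop=True)
    if labels:
        out.insert(1, "label", out["class"].map(labels))
    return out


def area_change(
    t1: pd.DataFrame, t2: pd.DataFrame, convention: str = "relative-to-first"
) -> pd.DataFrame:
    """Two-date per-class area change.

    ``convention`` names the denominator of the relative change:
    ``"relative-to-first"`` → 100·(A₂−A₁)/A₁ (the usual percent change),
    ``"relative-to-second"`` → 100·(A₂−A₁)/A₂ (the share of the later
    area that is new). Zero-denominator rows get NaN and a flag.
    """
    if convention not in ("relative-to-first", "relative-to-second"):
        raise ValueError(f"unknown change convention {convention!r}")
    merged = t1.merge(t2, on="class", how="outer", suffixes=("_t1", "_t2"))
    for col in ("area_ha_t1", "area_ha_t2"):
        merged[col] = merged[col].fillna(0.0)
    a1 = merged["area_ha_t1"].to_numpy()
    a2 = merged["area_ha_t2"].to_numpy()
    denom = a1 if convention == "relative-to-first" else a2
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.where(denom != 0, 100.0 * (a2 - a1) / denom, np.nan)
    out = merged[["class"]].copy()
    if "label_t1" in merged.columns:
        out["label"] = merged["label_t1"].fillna(merged.get("label_t2"))
    out["area_ha_t1"] = a1
    out["area_ha_t2"] = a2
    out["change_ha"] = a2 - a1
    out["change_pct"] = rel
    out["undefined"] = denom == 0
    out.attrs["convention"] = convention
    return out


def zonal_area(classified: Grid, zones: list, zone_ids: list | None = None,
               labels: dict[int, str] | None = None) -> pd.DataFrame:
    """Per-zone class areas using pixel-center containment.

    ``zones`` are shapely polygons in the grid's coordinate system.
    Pixel centers falling in no zone are ignored; centers in overlapping
    zones are counted in every zone containing them (zones meant as a
    partition should not overlap). Empty zones yield no rows and a
    warning.
    """
    if zone_ids is None:
        zone_ids = list(range(len(zones)))
    xs, ys = classified.cell_centers()
    frames = []
    for zid, geom in zip(zone_ids, zones):
        inside = shapely.contains_xy(geom, xs, ys) & classified.mask
        if not inside.any():
            warnings.warn(f"zone {zid!r} contains no valid pixels", stacklevel=2)
            continue
        sub = area_by_class(classified.with_values(
            np.where(inside, classified.values, np.nan)), labels)
        sub.insert(0, "zone", zid)
        frames.append(sub)
    if not frames:
        return pd.DataFrame(columns=["zone", "class", "pixels", "area_ha", "share_pct"])
    return pd.concat(frames, ignore_index=True)


def cross_index_regression(x, y) -> dict[str, float]:
    """OLS of one index's zonal exposed areas on the other's.

    Returns slope, intercept, r and R² (= r² identically); used to
    quantify how strongly the two indexes agree on where bare ground is.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 zones")
    if np.var(x) == 0:
        raise ValueError("zero variance in x")
    res = stats.linregress(x, y)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r": float(res.rvalue),
        "r_squared": float(res.rvalue) ** 2,
    }


def index_histogram(index: Grid, bin_width: float = 0.05) -> pd.DataFrame:
    """Pixel histogram of an index raster over [−1, 1], nodata excluded."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    edges = np.arange(-1.0, 1.0 + bin_width / 2, bin_width)
    if edges[-1] < 1.0:
        edges = np.append(edges, 1.0)
    counts, edges = np.histogram(index.values[index.mask], bins=edges)
    return pd.DataFrame({"low": edges[:-1], "high": edges[1:], "count": counts})


def mosaic_first_valid(a: Grid, b: Grid) -> Grid:
    """Combine two co-registered scenes, first valid pixel wins."""
    a.require_same_geometry(b, "mosaic inputs")
    return a.with_values(np.where(a.mask, a.values, b.values))
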