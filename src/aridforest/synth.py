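"""Synthetic inputs with the statistical structure the analysis assumes.

Three generators cover the three data tracks:

* :func:`simulate_climate` — a multi-station monthly temperature /
  precipitation network in which one reference station has a complete
  record and each satellite station is a linear transform of it plus
  noise (this is exactly the structure the gap-filling regression
  presumes, so the generating slope/intercept are recoverable). Gaps
  are punched uniformly at random into the satellite series only.
* :func:`simulate_scene` — two-date RED/NIR reflectance scenes over a
  categorical landscape (water / bare sand / sparse vegetation / dense
  forest) whose second date is drawn per-pixel from a known transition
  probability table; the realized pixel-count transition table is
  returned as ground truth.
* :func:`simulate_communes` — commune indicator tables (total forest
  area, absolute forest change) with planted cluster structure and true
  labels.

All generators are pure functions of (spec, seed): a fixed seed gives
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import Grid

__all__ = [
    "ClimateSimSpec",
    "SceneSimSpec",
    "CommuneSimSpec",
    "ClimateSim",
    "SceneSim",
    "simulate_climate",
    "simulate_scene",
    "simulate_communes",
    "DEFAULT_LEGEND",
    "DEFAULT_SIGNATURES",
    "DEGRADED_SIGNATURES",
    "DEFAULT_TRANSITIONS",
]

# ---------------------------------------------------------------- climate

# Monthly normals loosely typical of the lower Danube plain: annual mean
# temperature ~10.6 °C and annual precipitation ~565 mm, wetter in early
# summer, driest in late winter.
_MONTHLY_T = (-2.5, -0.5, 4.5, 11.0, 16.5, 20.5, 22.5, 22.0, 17.5, 11.5, 5.0, 0.0)
_MONTHLY_P = (35.0, 33.0, 38.0, 50.0, 62.0, 70.0, 60.0, 48.0, 42.0, 38.0, 45.0, 44.0)


@dataclass(frozen=True)
class ClimateSimSpec:
    """Parameters of the synthetic station network.

    Station 0 is the gap-free reference; stations 1..n−1 are generated
    as slope·reference + intercept + noise per variable, then
    ``gap_fraction`` of their months is removed. Interannual anomaly
    standard deviations control the year-to-year variability shared by
    all stations (through the reference), and hence — together with the
    noise — the inter-station correlation.
    """

    n_stations: int = 3
    years: tuple[int, int] = (1961, 2009)
    monthly_t_mean: tuple[float, ...] = _MONTHLY_T
    monthly_p_mean: tuple[float, ...] = _MONTHLY_P
    slopes_t: tuple[float, ...] = (1.05, 0.95)
    intercepts_t: tuple[float, ...] = (0.4, -0.3)
    slopes_p: tuple[float, ...] = (1.1, 0.9)
    intercepts_p: tuple[float, ...] = (-3.0, 4.0)
    noise_sd_t: float = 0.4
    noise_sd_p: float = 6.0
    t_anomaly_sd: float = 1.2
    p_anomaly_sd: float = 18.0
    gap_fraction: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_stations < 1:
            raise ValueError("need at least one station")
        if self.years[1] < self.years[0]:
            raise ValueError("invalid year range")
        if not 0 <= self.gap_fraction < 1:
            raise ValueError("gap_fraction must be in [0, 1)")
        if min(self.noise_sd_t, self.noise_sd_p, self.t_anomaly_sd, self.p_anomaly_sd) < 0:
            raise ValueError("standard deviations must be non-negative")
        n_sat = self.n_stations - 1
        for name in ("slopes_t", "intercepts_t", "slopes_p", "intercepts_p"):
            if len(getattr(self, name)) < n_sat:
                raise ValueError(f"{name} must supply one value per satellite station")
        if len(self.monthly_t_mean) != 12 or len(self.monthly_p_mean) != 12:
            raise ValueError("monthly normals must have 12 values")


@dataclass
class ClimateSim:
    """Generated table plus the truth needed for recovery tests."""

    table: pd.DataFrame           # station, year, month, T, P (NaN = gap)
    removed: pd.DataFrame         # the withheld true values of gapped months
    truth: dict                   # generating slopes/intercepts per station


def simulate_climate(spec: ClimateSimSpec) -> ClimateSim:
    rng = np.random.default_rng(spec.seed)
    y0, y1 = spec.years
    years = np.arange(y0, y1 + 1)
    n_months = len(years) * 12
    month = np.tile(np.arange(1, 13), len(years))
    year = np.repeat(years, 12)

    t_ref = np.asarray(spec.monthly_t_mean)[month - 1] + rng.normal(
        0.0, spec.t_anomaly_sd, n_months
    )
    p_ref = np.maximum(
        np.asarray(spec.monthly_p_mean)[month - 1]
        + rng.normal(0.0, spec.p_anomaly_sd, n_months),
        0.0,
    )

    frames = [
        pd.DataFrame(
            {"station": "st0", "year": year, "month": month, "T": t_ref, "P": p_ref}
        )
    ]
    truth = {"reference": "st0", "stations": {}}
    for i in range(1, spec.n_stations):
        t = (
            spec.slopes_t[i - 1] * t_ref
            + spec.intercepts_t[i - 1]
            + rng.normal(0.0, spec.noise_sd_t, n_months)
        )
        p = np.maximum(
            spec.slopes_p[i - 1] * p_ref
            + spec.intercepts_p[i - 1]
            + rng.normal(0.0, spec.noise_sd_p, n_months),
            0.0,
        )
        frames.append(
            pd.DataFrame({"station": f"st{i}", "year": year, "month": month, "T": t, "P": p})
        )
        truth["stations"][f"st{i}"] = {
            "slope_T": spec.slopes_t[i - 1],
            "intercept_T": spec.intercepts_t[i - 1],
            "slope_P": spec.slopes_p[i - 1],
            "intercept_P": spec.intercepts_p[i - 1],
        }
    table = pd.concat(frames, ignore_index=True)

    removed_rows = []
    for i in range(1, spec.n_stations):
        if spec.gap_fraction == 0:
            continue
        idx = table.index[table["station"] == f"st{i}"]
        n_gap = int(round(spec.gap_fraction * len(idx)))
        chosen = rng.choice(idx, size=n_gap, replace=False)
        removed_rows.append(table.loc[chosen].copy())
        table.loc[chosen, ["T", "P"]] = np.nan
    removed = (
        pd.concat(removed_rows, ignore_index=True)
        if removed_rows
        else table.iloc[0:0].copy()
    )
    return ClimateSim(table=table, removed=removed, truth=truth)


# ------------------------------------------------------------------ scene

DEFAULT_LEGEND = {1: "water", 2: "bare sand", 3: "sparse vegetation", 4: "dense forest"}

#: Per-class (RED, NIR) reflectance means and a common sd, chosen so the
#: class NDVI centres fall in the intended threshold bins: water ≈ −0.4,
#: bare sand ≈ 0.08 (<0.1, exposed), sparse ≈ 0.19 (0.1–0.2), dense
#: forest ≈ 0.84 (≥0.55, very dense canopy).
DEFAULT_SIGNATURES = {
    1: {"red": 0.05, "nir": 0.02, "sd": 0.01},
    2: {"red": 0.30, "nir": 0.35, "sd": 0.015},
    3: {"red": 0.15, "nir": 0.22, "sd": 0.015},
    4: {"red": 0.04, "nir": 0.45, "sd": 0.02},
}

#: A drought-stressed second date: forest canopy loses near-infrared
#: brightness (NDVI centre drops from ≈0.84 to ≈0.45), emulating spectral
#: degradation without land-use change.
DEGRADED_SIGNATURES = {
    1: {"red": 0.05, "nir": 0.02, "sd": 0.01},
    2: {"red": 0.30, "nir": 0.35, "sd": 0.015},
    3: {"red": 0.17, "nir": 0.22, "sd": 0.015},
    4: {"red": 0.10, "nir": 0.27, "sd": 0.02},
}

#: Default two-date dynamics: forest thinning to sparse vegetation and
#: bare sand, sparse vegetation destabilising to sand — the degradation
#: regime of a sandy aridizing landscape. Water is stable.
DEFAULT_TRANSITIONS = {
    1: {1: 1.0},
    2: {2: 0.95, 3: 0.05},
    3: {3: 0.80, 2: 0.15, 4: 0.05},
    4: {4: 0.85, 3: 0.10, 2: 0.05},
}


@dataclass(frozen=True)
class SceneSimSpec:
    """Parameters of the two-date synthetic scene.

    ``class_map_t1`` (optional) fixes the first-date landscape; when
    None a blocky random landscape is generated from ``class_weights``
    on ``block`` × ``block`` pixel patches. ``signatures_t2`` lets the
    second date use different (e.g. drought-degraded) spectra.
    """

    shape: tuple[int, int] = (128, 128)
    pixel_size: float = 30.0
    class_map_t1: np.ndarray | None = None
    class_weights: tuple[float, ...] = (0.08, 0.12, 0.30, 0.50)
    block: int = 8
    transitions: dict = field(default_factory=lambda: DEFAULT_TRANSITIONS)
    signatures: dict = field(default_factory=lambda: DEFAULT_SIGNATURES)
    signatures_t2: dict | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for cls, dest in self.transitions.items():
            total = sum(dest.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"transition probabilities for class {cls} sum to {total}")
        for sigs in (self.signatures, self.signatures_t2 or {}):
            for cls, sig in sigs.items():
                if not (0 <= sig["red"] <= 1 and 0 <= sig["nir"] <= 1):
                    raise ValueError(f"class {cls} reflectance mean outside [0, 1]")


@dataclass
class SceneSim:
    red_t1: Grid
    nir_t1: Grid
    red_t2: Grid
    nir_t2: Grid
    landuse_t1: Grid
    landuse_t2: Grid
    true_counts: pd.DataFrame     # pixel counts, rows = t2 class, cols = t1 class
    legend: dict[int, str]


def _random_landscape(spec: SceneSimSpec, rng: np.random.Generator) -> np.ndarray:
    classes = sorted(spec.signatures)
    nrows, ncols = spec.shape
    br = -(-nrows // spec.block)
    bc = -(-ncols // spec.block)
    weights = np.asarray(spec.class_weights, dtype=float)
    weights = weights / weights.sum()
    coarse = rng.choice(classes, size=(br, bc), p=weights)
    return np.kron(coarse, np.ones((spec.block, spec.block), dtype=int))[:nrows, :ncols]


def _draw_bands(
    class_map: np.ndarray, signatures: dict, rng: np.random.Generator,
    pixel_size: float,
) -> tuple[Grid, Grid]:
    red = np.zeros(class_map.shape)
    nir = np.zeros(class_map.shape)
    for cls, sig in signatures.items():
        sel = class_map == cls
        n = int(sel.sum())
        if n == 0:
            continue
        red[sel] = rng.normal(sig["red"], sig["sd"], n)
        nir[sel] = rng.normal(sig["nir"], sig["sd"], n)
    red = np.clip(red, 0.0, 1.0)
    nir = np.clip(nir, 0.0, 1.0)
    return (
        Grid(red, pixel_size=pixel_size),
        Grid(nir, pixel_size=pixel_size),
    )


def simulate_scene(spec: SceneSimSpec) -> SceneSim:
    rng = np.random.default_rng(spec.seed)
    classes = sorted(spec.signatures)
    if spec.class_map_t1 is not None:
        map_t1 = np.asarray(spec.class_map_t1, dtype=int)
        if map_t1.shape != spec.shape:
            raise ValueError("class_map_t1 shape disagrees with spec.shape")
    else:
        map_t1 = _random_landscape(spec, rng)

    map_t2 = map_t1.copy()
    for cls in classes:
        sel = map_t1 == cls
        n = int(sel.sum())
        if n == 0:
            continue
        dest = spec.transitions.get(cls, {cls: 1.0})
        targets = sorted(dest)
        probs = np.array([dest[t] for t in targets])
        map_t2[sel] = rng.choice(targets, size=n, p=probs)

    k = len(classes)
    pos = {c: i for i, c in enumerate(classes)}
    flat = np.array([pos[c] for c in map_t2.ravel()]) * k + np.array(
        [pos[c] for c in map_t1.ravel()]
    )
    counts = np.bincount(flat, minlength=k * k).reshape(k, k)
    names = [DEFAULT_LEGEND.get(c, str(c)) for c in classes]
    true_counts = pd.DataFrame(counts, index=names, columns=names)

    red_t1, nir_t1 = _draw_bands(map_t1, spec.signatures, rng, spec.pixel_size)
    sigs2 = spec.signatures_t2 or spec.signatures
    red_t2, nir_t2 = _draw_bands(map_t2, sigs2, rng, spec.pixel_size)

    return SceneSim(
        red_t1=red_t1,
        nir_t1=nir_t1,
        red_t2=red_t2,
        nir_t2=nir_t2,
        landuse_t1=Grid(map_t1.astype(float), pixel_size=spec.pixel_size),
        landuse_t2=Grid(map_t2.astype(float), pixel_size=spec.pixel_size),
        true_counts=true_counts,
        legend={c: DEFAULT_LEGEND.get(c, str(c)) for c in classes},
    )


# --------------------------------------------------------------- communes

#: Five planted commune types: (total forest ha, absolute change ha)
#: centroids for — in order — small stable, afforesting, small declining,
#: large heavily-declining and mid-sized near-stable communes, with the
#: afforesting group deliberately small (7 communes of 113).
_DEFAULT_CENTROIDS = (
    (300.0, -20.0),
    (5000.0, 400.0),
    (700.0, -350.0),
    (6000.0, -1400.0),
    (2500.0, -60.0),
)
_DEFAULT_N = (40, 7, 25, 16, 25)


@dataclass(frozen=True)
class CommuneSimSpec:
    n_clusters: int = 5
    centroids: tuple[tuple[float, float], ...] = _DEFAULT_CENTROIDS
    spreads: tuple[tuple[float, float], ...] = tuple((120.0, 35.0) for _ in range(5))
    n_per_cluster: tuple[int, ...] = _DEFAULT_N
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be ≥ 1")
        for name in ("centroids", "spreads", "n_per_cluster"):
            if len(getattr(self, name)) < self.n_clusters:
                raise ValueError(f"{name} must supply one entry per cluster")
        if any(c[0] < 0 for c in self.centroids[: self.n_clusters]):
            raise ValueError("forest-area centroids must be non-negative")


def simulate_communes(spec: CommuneSimSpec) -> tuple[pd.DataFrame, np.ndarray]:
    """Commune indicator table plus the true cluster labels (1-based)."""
    rng = np.random.default_rng(spec.seed)
    rows = []
    labels = []
    idx = 0
    for c in range(spec.n_clusters):
        (mu_total, mu_change) = spec.centroids[c]
        (sd_total, sd_change) = spec.spreads[c]
        for _ in range(spec.n_per_cluster[c]):
            total = max(rng.normal(mu_total, sd_total), 0.0) if sd_total else mu_total
            change = rng.normal(mu_change, sd_change) if sd_change else mu_change
            rows.append(
                {"commune": f"c{idx:03d}", "forest_total": total, "forest_change": change}
            )
            labels.append(c + 1)
            idx += 1
    return pd.DataFrame(rows), np.asarray(labels)
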