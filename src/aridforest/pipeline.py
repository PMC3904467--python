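"""End-to-end orchestration of the two analysis tracks.

Track 1 (climate aridization): gap-fill the station network, compute the
De Martonne and UNEP aridity indexes per station-year, fit linear trends.
Track 2 (degradation / clear-cutting): NDVI and MSAVI2 for both dates,
threshold classification and area accounting, zonal exposed-area
cross-index regression, the land-use transition matrix with balances,
and Ward clustering of the commune indicators.

Stages communicate through files so each is independently runnable and
auditable; `run_all` aborts with a stage-named error but keeps the
outputs of the stages that already completed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
import yaml

from . import __version__, climate, clusters, synth, transitions, vegindex
from .grid import read_ascii_grid, read_legend, write_ascii_grid, write_legend
from .vegindex import PAPER_BINS

__all__ = ["RunConfig", "StageError", "run_all", "make_demo", "load_config"]


@dataclass
class RunConfig:
    """All inputs and choices of one pipeline run (serialized as YAML)."""

    climate_table: str
    red_t1: str
    nir_t1: str
    red_t2: str
    nir_t2: str
    landuse_t1: str
    landuse_t2: str
    legend: str
    zones: str
    communes: str
    out_dir: str
    latitude: float = 44.0
    reference_station: str = "st0"
    change_convention: str = "relative-to-first"
    exposed_convention: str = "relative-to-second"
    k: int = 5
    standardize: bool = True
    seed: int = 0
    transfers: list = field(default_factory=list)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return RunConfig(**data)


class StageError(RuntimeError):
    """A pipeline stage failed; earlier stages' outputs are retained."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_climate(cfg: RunConfig, out: Path) -> dict:
    table = climate.read_climate_table(cfg.climate_table)
    stations = sorted(table["station"].unique())
    regs = []
    for st in stations:
        if st == cfg.reference_station:
            continue
        for var in ("T", "P"):
            if table.loc[table["station"] == st, var].isna().any():
                regs.append(
                    climate.fit_station_regression(table, st, cfg.reference_station, var)
                )
    filled = climate.fill_gaps(table, regs)
    aridity = climate.aridity_table(filled, cfg.latitude)
    aridity.round(3).to_csv(out / "aridity.csv", index=False)
    trend_rows = []
    for st, sub in aridity.groupby("station"):
        for col in ("I_DM", "I_UNEP"):
            fit = climate.linear_trend(sub["year"], sub[col])
            trend_rows.append(
                {"station": st, "index": col, "slope_per_year": fit.slope,
                 "intercept": fit.intercept, "r": fit.r}
            )
    trends = pd.DataFrame(trend_rows)
    trends.round(5).to_csv(out / "trends.csv", index=False)
    reg_table = pd.DataFrame([asdict(r) for r in regs])
    reg_table.round(5).to_csv(out / "station_regressions.csv", index=False)
    return {
        "aridity": aridity,
        "trends": trends,
        "min_inter_station_r": float(reg_table["r"].min()) if len(reg_table) else None,
    }


def _load_zones(path) -> tuple[list, list]:
    with open(path) as fh:
        gj = json.load(fh)
    geoms, ids = [], []
    for i, feat in enumerate(gj["features"]):
        geoms.append(shapely.geometry.shape(feat["geometry"]))
        ids.append(feat.get("properties", {}).get("zone", i))
    return geoms, ids


def _stage_vegindex(cfg: RunConfig, out: Path) -> dict:
    bands = {
        name: read_ascii_grid(getattr(cfg, name))
        for name in ("red_t1", "nir_t1", "red_t2", "nir_t2")
    }
    zones, zone_ids = _load_zones(cfg.zones)
    labels = dict(enumerate(PAPER_BINS.labels))
    results: dict = {"areas": {}, "zonal_exposed": {}}
    classified = {}
    for date in ("t1", "t2"):
        for name, fn in (("ndvi", vegindex.ndvi), ("msavi2", vegindex.msavi2)):
            index = fn(bands[f"nir_{date}"], bands[f"red_{date}"])
            cls = vegindex.classify(index, PAPER_BINS)
            classified[(name, date)] = cls
            areas = vegindex.area_by_class(cls, labels)
            areas.round(3).to_csv(out / f"area_{name}_{date}.csv", index=False)
            results["areas"][(name, date)] = areas
            hist = vegindex.index_histogram(index)
            hist.to_csv(out / f"hist_{name}_{date}.csv", index=False)
            zonal = vegindex.zonal_area(cls, zones, zone_ids, labels)
            exposed = (
                zonal[zonal["class"] == 0]
                .set_index("zone")["area_ha"]
                .reindex(zone_ids)
                .fillna(0.0)
            )
            results["zonal_exposed"][(name, date)] = exposed
    for name in ("ndvi", "msavi2"):
        chg = vegindex.area_change(
            results["areas"][(name, "t1")],
            results["areas"][(name, "t2")],
            cfg.change_convention,
        )
        chg.round(3).to_csv(out / f"change_{name}.csv", index=False)
        results[f"change_{name}"] = chg
    # exposed-area change under the share-of-later-area convention
    exp = vegindex.area_change(
        results["areas"][("ndvi", "t1")].query("`class` == 0"),
        results["areas"][("ndvi", "t2")].query("`class` == 0"),
        cfg.exposed_convention,
    )
    exp.round(3).to_csv(out / "change_ndvi_exposed.csv", index=False)
    reg = vegindex.cross_index_regression(
        results["zonal_exposed"][("ndvi", "t2")].to_numpy(),
        results["zonal_exposed"][("msavi2", "t2")].to_numpy(),
    )
    pd.DataFrame([reg]).round(5).to_csv(out / "cross_index_regression.csv", index=False)
    results["cross_index_regression"] = reg
    return results


def _stage_transitions(cfg: RunConfig, out: Path) -> dict:
    legend = read_legend(cfg.legend)
    m1 = read_ascii_grid(cfg.landuse_t1)
    m2 = read_ascii_grid(cfg.landuse_t2)
    matrix = transitions.cross_tabulate(m1, m2, legend)
    matrix.write_csv(out / "transition_matrix.csv")
    bal = transitions.balance(matrix)
    bal.round(3).to_csv(out / "balance.csv", index_label="category")
    transfer_rows = [
        {"from": a, "to": b, "net_ha": transitions.net_transfer(matrix, a, b)}
        for a, b in (tuple(t) for t in cfg.transfers)
    ]
    if transfer_rows:
        pd.DataFrame(transfer_rows).round(3).to_csv(out / "net_transfers.csv", index=False)
    return {"matrix": matrix, "balance": bal, "transfers": transfer_rows}


def _stage_clusters(cfg: RunConfig, out: Path) -> dict:
    table = pd.read_csv(cfg.communes, dtype={"commune": str})
    assignment = clusters.ward_cluster(table, k=cfg.k, standardize=cfg.standardize)
    assignment.labels.to_csv(out / "cluster_assignment.csv")
    profile = clusters.cluster_profile(assignment, table)
    profile.round(3).to_csv(out / "cluster_profile.csv", index=False)
    return {"assignment": assignment, "profile": profile}


_STAGES = [
    ("climate", _stage_climate),
    ("vegindex", _stage_vegindex),
    ("transitions", _stage_transitions),
    ("clusters", _stage_clusters),
]

_INPUT_FIELDS = [
    "climate_table", "red_t1", "nir_t1", "red_t2", "nir_t2",
    "landuse_t1", "landuse_t2", "legend", "zones", "communes",
]


def run_all(cfg: RunConfig) -> dict:
    """Execute all stages, write a consolidated plain-text report.

    Returns the in-memory stage results keyed by stage name; everything
    in the report is also written as a delimited table under
    ``cfg.out_dir``.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.save(out / "config_used.yaml")
    checksums = {f: _sha256(getattr(cfg, f)) for f in _INPUT_FIELDS
                 if Path(getattr(cfg, f)).exists()}
    results: dict = {}
    for name, fn in _STAGES:
        try:
            results[name] = fn(cfg, out)
        except Exception as exc:  # noqa: BLE001 - stage-named abort contract
            raise StageError(name, exc) from exc
    _write_report(cfg, results, checksums, out / "report.txt")
    return results


def _write_report(cfg: RunConfig, results: dict, checksums: dict, path) -> None:
    cfg_hash = hashlib.sha256(
        yaml.safe_dump(asdict(cfg), sort_keys=True).encode()
    ).hexdigest()[:16]
    lines = [
        "aridforest consolidated report",
        "=" * 34,
        "",
        "[provenance]",
        f"package_version: {__version__}",
        f"config_hash: {cfg_hash}",
        f"seed: {cfg.seed}",
        "input_checksums:",
    ]
    lines += [f"  {k}: {v}" for k, v in sorted(checksums.items())]
    cl = results["climate"]
    lines += ["", "[climate]"]
    if cl["min_inter_station_r"] is not None:
        lines.append(f"min inter-station r of gap-fill regressions: "
                     f"{cl['min_inter_station_r']:.3f}")
    for _, row in cl["trends"].iterrows():
        lines.append(
            f"trend {row['station']} {row['index']}: "
            f"{row['slope_per_year']:+.4f} per year (r={row['r']:.2f})"
        )
    vg = results["vegindex"]
    lines += ["", "[vegindex]"]
    for name in ("ndvi", "msavi2"):
        chg = vg[f"change_{name}"]
        for _, row in chg.iterrows():
            lines.append(
                f"{name} {row['label']}: {row['area_ha_t1']:.1f} → "
                f"{row['area_ha_t2']:.1f} ha ({row['change_pct']:+.1f}% "
                f"{cfg.change_convention})"
            )
    reg = vg["cross_index_regression"]
    lines.append(
        f"zonal exposed-area NDVI~MSAVI2 (t2): R²={reg['r_squared']:.3f} r={reg['r']:.3f}"
    )
    tr = results["transitions"]
    lines += ["", "[transitions]"]
    for cat, row in tr["balance"].iterrows():
        lines.append(
            f"{cat}: {row['total_t1']:.1f} → {row['total_t2']:.1f} ha "
            f"(net {row['net']:+.1f} ha)"
        )
    for t in tr["transfers"]:
        lines.append(f"net transfer {t['from']} → {t['to']}: {t['net_ha']:.1f} ha")
    cs = results["clusters"]
    lines += ["", "[clusters]"]
    for _, row in cs["profile"].iterrows():
        lines.append(
            f"cluster {int(row['cluster'])}: n={int(row['n'])}, "
            f"mean forest {row['forest_total_mean']:.0f} ha, "
            f"mean change {row['forest_change_mean']:+.0f} ha, "
            f"{row['forest_share_pct']:.1f}% of forest area"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def make_demo(out_dir, seed: int = 0, scene_shape: tuple[int, int] = (128, 128),
              n_zones: tuple[int, int] = (2, 2)) -> RunConfig:
    """Generate the full synthetic input set and a ready-to-run config.

    The demo emulates the study conditions: three correlated stations
    over 1961–2009 with gaps in the two satellite stations, a two-date
    scene degrading between dates, and 113 communes in five planted
    groups. Zones are a rectangular partition of the scene.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng_seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, size=3)

    sim = synth.simulate_climate(synth.ClimateSimSpec(seed=int(rng_seeds[0])))
    climate.write_climate_table(sim.table, out / "climate.csv")

    scene = synth.simulate_scene(
        synth.SceneSimSpec(
            shape=scene_shape,
            seed=int(rng_seeds[1]),
            signatures_t2=synth.DEGRADED_SIGNATURES,
        )
    )
    for name in ("red_t1", "nir_t1", "red_t2", "nir_t2", "landuse_t1", "landuse_t2"):
        write_ascii_grid(getattr(scene, name), out / f"{name}.asc")
    write_legend(scene.legend, out / "legend.csv")
    scene.true_counts.to_csv(out / "true_transition_counts.csv", index_label="category")

    nrows, ncols = scene_shape
    px = scene.red_t1.pixel_size
    width, height = ncols * px, nrows * px
    features = []
    zr, zc = n_zones
    for i in range(zr):
        for j in range(zc):
            x0, x1 = j * width / zc, (j + 1) * width / zc
            y0, y1 = i * height / zr, (i + 1) * height / zr
            features.append(
                {
                    "type": "Feature",
                    "properties": {"zone": f"z{i}{j}"},
                    "geometry": {
                        "type": "Polygon",
                        "coordinates": [[[x0, y0], [x1, y0], [x1, y1], [x0, y1], [x0, y0]]],
                    },
                }
            )
    with open(out / "zones.geojson", "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)

    communes, true_labels = synth.simulate_communes(
        synth.CommuneSimSpec(seed=int(rng_seeds[2]))
    )
    communes.to_csv(out / "communes.csv", index=False)
    np.savetxt(out / "true_commune_labels.txt", true_labels, fmt="%d")

    cfg = RunConfig(
        climate_table=str(out / "climate.csv"),
        red_t1=str(out / "red_t1.asc"),
        nir_t1=str(out / "nir_t1.asc"),
        red_t2=str(out / "red_t2.asc"),
        nir_t2=str(out / "nir_t2.asc"),
        landuse_t1=str(out / "landuse_t1.asc"),
        landuse_t2=str(out / "landuse_t2.asc"),
        legend=str(out / "legend.csv"),
        zones=str(out / "zones.geojson"),
        communes=str(out / "communes.csv"),
        out_dir=str(out / "results"),
        seed=seed,
        transfers=[["dense forest", "bare sand"]],
    )
    cfg.save(out / "config.yaml")
    return cfg
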