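"""End-to-end orchestration: synthesis/ingest -> accessibility -> typology ->
Gini -> coupling -> geographical detector, with CSV/JSON report tables.

Every stage writes a plain-text table into the output directory; a JSON run
manifest records the seed, the config hash, and package versions so a rerun
with the same config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import eldermatch
from eldermatch import aging_typology, coupling, equity_gini, geodetector, terrain_access
from eldermatch.gridio import read_ascii_grid
from eldermatch.synthetic_province import (
    FACTOR_IDS,
    Province,
    ProvinceConfig,
    generate_province,
    write_province,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Settings for one pipeline run (synthetic by default)."""

    seed: int = 0
    outdir: str = "eldermatch_out"
    province: ProvinceConfig | None = None  # synthesized when input_dir is None
    input_dir: str | None = None            # pre-written province artefacts
    access_mode: str = "gravity"
    access_budget: float = 1.0               # hours (service_area) / decay (gravity)
    gini_method: str = "lorenz_trapezoid"
    normalization: str = "per_group"
    detector_k: int = 5
    n_perm: int = 999
    write_lorenz_plot: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        prov = raw.pop("province", None)
        cfg = cls(**raw)
        if prov is not None:
            if "years" in prov:
                prov["years"] = tuple(prov["years"])
            if "raster_shape" in prov:
                prov["raster_shape"] = tuple(prov["raster_shape"])
            cfg.province = ProvinceConfig(**prov)
        return cfg


def load_province(input_dir: str | Path, config: ProvinceConfig | None = None) -> Province:
    """Rebuild a Province from artefacts written by ``write_province``."""
    d = Path(input_dir)
    from eldermatch.gridio import read_geojson

    polygons, props = read_geojson(d / "units.geojson")
    units = pd.DataFrame(props)
    units["x"] = [p.centroid.x for p in polygons]
    units["y"] = [p.centroid.y for p in polygons]
    panel = pd.read_csv(d / "panel.csv")
    facilities = pd.read_csv(d / "facilities.csv")
    dem = read_ascii_grid(d / "dem.asc")
    nodes_df = pd.read_csv(d / "road_nodes.csv")
    nodes = {r.node_id: (r.x, r.y) for r in nodes_df.itertuples()}
    edges_df = pd.read_csv(d / "road_edges.csv")
    edges = [
        (r.from_node, r.to_node, float(r.length_m), r.road_class)
        for r in edges_df.itertuples()
    ]
    return Province(config or ProvinceConfig(), units, polygons, panel, facilities, dem, nodes, edges)


def _accessibility_by_year(province: Province, mode: str, budget: float) -> pd.DataFrame:
    """Per-unit-year accessibility; each census year only counts facilities
    already established by that year."""
    graph = terrain_access.build_cost_graph(
        province.road_nodes, province.road_edges, province.dem
    )
    units_xy = province.units.set_index("unit_id")
    rows = []
    for year in sorted(province.panel["year"].unique()):
        cross = province.panel[province.panel["year"] == year]
        units = [
            {
                "unit_id": r.unit_id,
                "x": units_xy.loc[r.unit_id, "x"],
                "y": units_xy.loc[r.unit_id, "y"],
                "pop_65plus": r.pop_65plus,
            }
            for r in cross.itertuples()
        ]
        fac = province.facilities[province.facilities["established"] <= year]
        scores = terrain_access.accessibility(
            units, fac.to_dict("records"), graph, mode=mode, budget=budget
        )
        rows += [(s.unit_id, year, s.S, s.mode, s.budget) for s in scores]
    return pd.DataFrame(rows, columns=["unit_id", "year", "S_raw", "mode", "budget"])


def _facility_counts(province: Province) -> pd.DataFrame:
    rows = []
    for year in sorted(province.panel["year"].unique()):
        counts = (
            province.facilities[province.facilities["established"] <= year]
            .groupby("unit_id")
            .size()
        )
        for uid in province.units["unit_id"]:
            rows.append((uid, year, int(counts.get(uid, 0))))
    return pd.DataFrame(rows, columns=["unit_id", "year", "n_facilities"])


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run all stages and write the report bundle; returns paths by table name."""
    t0 = time.perf_counter()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if config.input_dir is not None:
        province = load_province(config.input_dir, config.province)
    else:
        prov_cfg = config.province or ProvinceConfig(seed=config.seed)
        province = generate_province(prov_cfg)
        write_province(province, outdir / "province")
    years = sorted(province.panel["year"].unique())
    paths: dict[str, Path] = {}

    def emit(name: str, df: pd.DataFrame) -> None:
        paths[name] = outdir / f"{name}.csv"
        df.to_csv(paths[name], index=False, float_format="%.6f")
        logger.info("stage %-22s -> %s (%.2fs)", name, paths[name], time.perf_counter() - t0)

    # accessibility
    access = _accessibility_by_year(province, config.access_mode, config.access_budget)
    emit("accessibility", access)

    # aging typology + growth mismatch per consecutive census period
    fac_counts = _facility_counts(province)
    typ_frames, gap_frames = [], []
    for y0, y1 in zip(years, years[1:]):
        typ_frames.append(aging_typology.typology_map(province.panel, (y0, y1)))
        gap_frames.append(
            aging_typology.growth_gap_table(province.panel, fac_counts, (y0, y1))
        )
    emit("typology", pd.concat(typ_frames, ignore_index=True))
    emit("growth_gap", pd.concat(gap_frames, ignore_index=True))

    # Lorenz / Gini per year
    gini_rows, lorenz_rows, curves = [], [], {}
    for year in years:
        merged = province.panel[province.panel["year"] == year].merge(
            access[access["year"] == year], on=["unit_id", "year"]
        )
        res = equity_gini.gini(
            merged["pop_65plus"].to_numpy(),
            merged["S_raw"].to_numpy(),
            method=config.gini_method,
        )
        gini_rows.append((year, res.G, res.method, res.undp_class))
        curves[str(year)] = res.lorenz_points
        for px, py in res.lorenz_points:
            lorenz_rows.append((year, px, py))
    emit("gini", pd.DataFrame(gini_rows, columns=["year", "G", "method", "undp_class"]))
    emit("lorenz_points", pd.DataFrame(lorenz_rows, columns=["year", "cum_pop_share", "cum_access_share"]))
    if config.write_lorenz_plot:
        equity_gini.plot_lorenz(curves, str(outdir / "lorenz.png"))

    # coupling coordination
    coup = coupling.coupling_table(
        province.panel, access[["unit_id", "year", "S_raw"]], normalization=config.normalization
    )
    emit("coupling", coup)
    emit("level_distribution", coupling.level_distribution(coup))

    # geographical detector on the final year's coordination degree
    final = coup[coup["year"] == years[-1]].merge(
        province.panel[province.panel["year"] == years[-1]][["unit_id", *FACTOR_IDS]],
        on="unit_id",
    )
    outcome = final["D"].to_numpy()
    k = min(config.detector_k, max(2, len(final) // 3))
    strata = {}
    q_rows = []
    rng_seed = config.seed
    for f in FACTOR_IDS:
        sf = geodetector.jenks_labels(
            coupling.range_normalize(final[f].to_numpy()), k
        )
        sf.factor_id = f
        strata[f] = sf
        qres = geodetector.factor_q(sf, outcome, factor_id=f)
        p = geodetector.q_significance(sf, outcome, "permutation", config.n_perm, seed=rng_seed)
        q_rows.append((f, qres.q, p))
    q_table = pd.DataFrame(q_rows, columns=["factor", "q", "p_value"])
    q_table["rank"] = q_table["q"].rank(ascending=False, method="min").astype(int)
    emit("q_table", q_table)

    inter_rows = []
    for fa, fb in combinations(FACTOR_IDS, 2):
        res = geodetector.interaction_q(strata[fa], strata[fb], outcome)
        inter_rows.append((fa, fb, res.q_a, res.q_b, res.q_ab, res.interaction_class))
    emit(
        "interactions",
        pd.DataFrame(
            inter_rows, columns=["factor_a", "factor_b", "q_a", "q_b", "q_ab", "interaction_class"]
        ),
    )

    # VIF/correlation screen over all unit-years: 3x the cross-section rows,
    # much stabler regressions than the 14-row final year alone
    vifs, corr = geodetector.vif_screen(province.panel[list(FACTOR_IDS)])
    emit(
        "vif",
        pd.DataFrame(
            [(v.factor_id, v.r_squared, v.vif, v.flagged) for v in vifs],
            columns=["factor", "r_squared", "vif", "flagged"],
        ),
    )
    corr.round(6).to_csv(outdir / "pearson_corr.csv")
    paths["pearson_corr"] = outdir / "pearson_corr.csv"

    cfg_dict = _config_dict(config)
    cfg_dict.pop("outdir", None)  # manifest must not depend on where it lands
    manifest = {
        "package": "eldermatch",
        "version": eldermatch.__version__,
        "seed": config.seed,
        "config_hash": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "config": cfg_dict,
        "n_units": int(len(province.units)),
        "years": [int(y) for y in years],
        "tables": {k: v.name for k, v in paths.items()},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    paths["manifest"] = outdir / "manifest.json"
    return paths


def _config_dict(config: RunConfig) -> dict:
    d = asdict(config)
    if d.get("province") and isinstance(d["province"].get("covariate_corr"), np.ndarray):
        d["province"]["covariate_corr"] = d["province"]["covariate_corr"].tolist()
    return d


# ---------------------------------------------------------------------------
# input validation
# ---------------------------------------------------------------------------

REQUIRED = {
    "panel.csv": ["unit_id", "year", "pop_total", "pop_65plus", "pop_55_64", "pop_working", *FACTOR_IDS],
    "facilities.csv": ["facility_id", "unit_id", "x", "y", "beds", "ownership", "established"],
    "road_edges.csv": ["from_node", "to_node", "length_m", "road_class"],
    "road_nodes.csv": ["node_id", "x", "y"],
}

ROAD_CLASSES = set(terrain_access.DEFAULT_ROAD_CLASSES)


def validate_inputs(input_dir: str | Path) -> list[str]:
    """Schema diagnostics for a province artefact directory; empty list = OK."""
    d = Path(input_dir)
    problems: list[str] = []
    for fname, cols in REQUIRED.items():
        path = d / fname
        if not path.exists():
            problems.append(f"{fname}: missing file")
            continue
        try:
            df = pd.read_csv(path)
        except Exception as exc:  # unreadable files are reported, not raised
            problems.append(f"{fname}: unreadable ({exc})")
            continue
        missing = [c for c in cols if c not in df.columns]
        extra_factors = []
        if fname == "panel.csv":
            extra_factors = [
                c
                for c in df.columns
                if c not in cols and c.upper() == c and len(c) == 2 and c[0].isalpha()
            ]
        if missing:
            problems.append(f"{fname}: missing columns {missing}")
        if extra_factors:
            problems.append(f"{fname}: unexpected factor columns {extra_factors}")
        if missing:
            continue
        if fname == "panel.csv":
            pops = df[["pop_total", "pop_65plus", "pop_55_64", "pop_working"]]
            for idx in df.index[(pops < 0).any(axis=1)]:
                problems.append(f"panel.csv: negative population at row {idx + 2}")
            over = df["pop_65plus"] + df["pop_55_64"] + df["pop_working"] > df["pop_total"]
            for idx in df.index[over]:
                problems.append(f"panel.csv: sub-populations exceed total at row {idx + 2}")
        if fname == "facilities.csv":
            for idx in df.index[df["beds"] <= 0]:
                problems.append(f"facilities.csv: non-positive beds at row {idx + 2}")
        if fname == "road_edges.csv":
            bad = ~df["road_class"].isin(ROAD_CLASSES)
            for idx in df.index[bad]:
                problems.append(
                    f"road_edges.csv: unknown road_class {df.loc[idx, 'road_class']!r} at row {idx + 2}"
                )
    for fname in ("dem.asc", "units.geojson"):
        if not (d / fname).exists():
            problems.append(f"{fname}: missing file")
    return problems
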