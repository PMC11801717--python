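"""End-to-end orchestration: simulate -> indices -> trend -> effectiveness ->
factors -> detect, with validation, deterministic manifests and CSV/JSON
outputs.

The pipeline runs a synthetic scenario end to end. Factor layers are generated
against the computed county effectiveness (so their explanatory power is
designed and known), and the engineering factors take the long way round on
purpose: designed intensities are realized as two land-use epochs and an
afforestation table, re-derived by the factor-preparation stage, and only then
discretized and fed to the Geodetector — exercising the same bookkeeping a
real land-use product would.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import effectiveness as eff
from . import factors as fp
from . import geodetector as gd
from . import indices, io, synth, trend
from .types import FactorPartition, UnitMap, VegeffError

__all__ = ["PipelineConfig", "PipelineResult", "validate_inputs", "run_pipeline"]

#: Engineering factors realized through land-use epochs: name -> (from, to).
LANDUSE_FACTORS = {
    "returning_farmland_to_grassland": (synth.CROPLAND, synth.GRASSLAND),
    "returning_unused_land_to_grassland": (synth.UNUSED, synth.GRASSLAND),
    "maintaining_original_forest": (synth.FOREST, synth.FOREST),
    "maintaining_original_grassland": (synth.GRASSLAND, synth.GRASSLAND),
}
AFFORESTATION_FACTOR = "accumulated_afforestation_intensity"


@dataclass
class PipelineConfig:
    scenario: synth.ScenarioConfig
    out_dir: str | None = None
    periods: list[tuple[int, int]] = field(
        default_factory=lambda: [(2000, 2010), (2000, 2015), (2000, 2020)]
    )
    baseline_period: tuple[int, int] = (2000, 2010)
    analysis_period: tuple[int, int] = (2000, 2020)
    thresholds: tuple[float, float] = (0.01, 0.05)
    soil_pct: float = 5.0
    veg_pct: float = 95.0
    per_year_norm: bool = False
    alpha: float = 0.05
    top_fraction: float = 0.5
    by_subregion: bool = False
    write_rasters: bool = False
    #: Tolerance for the designed factor q; coarse unit counts need a wider
    #: band because single swaps move the variance ratio in discrete lumps.
    factor_tol: float = 0.02


@dataclass
class PipelineResult:
    units: UnitMap
    vqqi: "indices.AnnualRasterStack"
    series: "indices.AnnualSeries"
    grades: dict
    table: pd.DataFrame
    summary: pd.DataFrame
    partitions: list[FactorPartition]
    detections: list[gd.FactorDetection]
    main_factors: list[gd.FactorDetection]
    interactions: list[gd.InteractionDetection]
    risk: gd.RiskDetection | None
    subregion_detections: pd.DataFrame | None
    manifest: dict


def validate_inputs(config: PipelineConfig) -> list[str]:
    """Configuration consistency report; never mutates anything."""
    issues: list[str] = []
    sc = config.scenario
    years = set(int(y) for y in sc.years)
    for period in list(config.periods) + [config.baseline_period, config.analysis_period]:
        if period[0] >= period[1]:
            issues.append(f"period {period} is not increasing")
        missing = [y for y in period if y not in years]
        if missing:
            issues.append(f"period {period} outside scenario years {min(years)}-{max(years)}")
    if config.baseline_period not in config.periods:
        issues.append(f"baseline period {config.baseline_period} not among periods")
    if config.analysis_period not in config.periods:
        issues.append(f"analysis period {config.analysis_period} not among periods")
    t1, t2 = config.thresholds
    if not 0 < t1 < t2 < 1:
        issues.append(f"significance thresholds {config.thresholds} must be ordered in (0,1)")
    if not 0 <= config.soil_pct < config.veg_pct <= 100:
        issues.append("dimidiate percentiles must satisfy 0 <= soil < veg <= 100")
    for spec in sc.factor_specs:
        if spec.n_groups > sc.n_units:
            issues.append(f"factor {spec.name}: {spec.n_groups} groups for {sc.n_units} units")
    if sc.transition_spec:
        for (frm, to), frac in sc.transition_spec.items():
            arr = np.atleast_1d(np.asarray(frac, dtype=float))
            if (arr < 0).any() or arr.sum() != arr.sum():  # negative or NaN
                issues.append(f"transition {frm}->{to}: invalid fractions")
    return issues


def _config_hash(config: PipelineConfig) -> str:
    def clean(obj):
        if isinstance(obj, dict):
            return {str(k): clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [clean(v) for v in obj]
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        return obj

    d = asdict(config)
    d.pop("out_dir", None)  # hash the scientific configuration, not paths
    payload = json.dumps(clean(d), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()


def _engineering_partitions(
    config: PipelineConfig, units: UnitMap, e_t: pd.Series
) -> tuple[list[FactorPartition], pd.DataFrame | None]:
    """Designed engineering factors realized through land-use epochs and the
    afforestation table, then recovered by the factor-preparation stage."""
    sc = config.scenario
    designed = {}
    for spec in sc.factor_specs:
        if spec.name in LANDUSE_FACTORS or spec.name == AFFORESTATION_FACTOR:
            designed[spec.name] = (spec, synth.simulate_factor(sc, e_t, spec, tol=config.factor_tol))
    parts: list[FactorPartition] = []
    bookkeeping = None
    lu_specs = {k: v for k, v in designed.items() if k in LANDUSE_FACTORS}
    if lu_specs:
        transition_spec = {
            LANDUSE_FACTORS[name]: (part.values / 100.0).to_numpy()
            for name, (_, part) in lu_specs.items()
        }
        sc_lu = replace(sc, transition_spec=transition_spec)
        lu0, lu1, bookkeeping = synth.simulate_landuse(sc_lu, units)
        for name, (spec, _) in lu_specs.items():
            frm, to = LANDUSE_FACTORS[name]
            if frm == to:
                values = fp.maintenance_intensity(lu0, lu1, frm, units)
            else:
                values = fp.transition_intensity(lu0, lu1, frm, to, units)
            parts.append(fp.jenks_breaks(values, spec.n_groups, name, spec.category))
    if AFFORESTATION_FACTOR in designed:
        spec, part = designed[AFFORESTATION_FACTOR]
        table = synth.simulate_afforestation(sc, units, part.values)
        values = fp.afforestation_intensity(table, units)
        parts.append(fp.jenks_breaks(values, spec.n_groups, spec.name, spec.category))
    return parts, bookkeeping


def _zonal_partitions(
    config: PipelineConfig, units: UnitMap, e_t: pd.Series
) -> list[FactorPartition]:
    """Non-engineering factors rasterized per unit and recovered zonally."""
    sc = config.scenario
    parts = []
    for spec in sc.factor_specs:
        if spec.name in LANDUSE_FACTORS or spec.name == AFFORESTATION_FACTOR:
            continue
        part = synth.simulate_factor(sc, e_t, spec, tol=config.factor_tol)
        raster = np.full(units.labels.shape, np.nan)
        for uid in units.unit_ids:
            raster[units.labels == uid] = part.values[uid]
        values = fp.zonal_aggregate(raster, units, "mean")
        parts.append(fp.jenks_breaks(values, spec.n_groups, spec.name, spec.category))
    return parts


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the whole chain on a synthetic scenario and write its outputs."""
    issues = validate_inputs(config)
    if issues:
        raise VegeffError("invalid pipeline configuration: " + "; ".join(issues))
    sc = config.scenario
    units = synth.make_units(sc)
    ndvi, npp = synth.simulate_stacks(sc, units)

    fvc = indices.fvc_from_ndvi(ndvi, config.soil_pct, config.veg_pct)
    nfvc = indices.normalize_stack(fvc, per_year=config.per_year_norm)
    nnpp = indices.normalize_stack(npp, per_year=config.per_year_norm)
    vq = indices.vqqi(nfvc, nnpp)
    series = indices.change_year(indices.regional_series(vq))

    grades = {p: trend.trend_grades(vq, p, config.thresholds) for p in config.periods}
    table = eff.effectiveness_table(grades, units, config.baseline_period)
    summary = eff.area_summary(table, units)

    period_label = f"{config.analysis_period[0]}-{config.analysis_period[1]}"
    e_t = table.loc[table["period"] == period_label].set_index("unit_id")["E_t"]

    eng_parts, lu_book = _engineering_partitions(config, units, e_t)
    zon_parts = _zonal_partitions(config, units, e_t)
    order = [s.name for s in sc.factor_specs]
    partitions = sorted(eng_parts + zon_parts, key=lambda p: order.index(p.factor_name))

    detections = [gd.factor_q(e_t, p) for p in partitions]
    main = gd.select_main_factors(detections, config.top_fraction, config.alpha)
    by_name = {p.factor_name: p for p in partitions}
    interactions = []
    for i in range(len(main)):
        for j in range(i + 1, len(main)):
            interactions.append(
                gd.interaction_q(e_t, by_name[main[i].factor_name], by_name[main[j].factor_name])
            )
    risk = gd.risk_detect(e_t, by_name[main[0].factor_name], config.alpha) if main else None

    sub_det = None
    if config.by_subregion and units.subregion:
        rows = []
        sub = pd.Series(dict(units.subregion))
        for region in sorted(set(sub)):
            uids = sub.index[sub == region]
            y_r = e_t.loc[e_t.index.intersection(uids)]
            if y_r.to_numpy().var() == 0 or len(y_r) < 3:
                continue
            for p in partitions:
                strata_r = p.strata.loc[y_r.index]
                if strata_r.nunique() < 2 or len(y_r) <= strata_r.nunique():
                    continue
                sub_part = FactorPartition(
                    p.factor_name, p.category, p.values.loc[y_r.index], strata_r, p.breaks
                )
                det = gd.factor_q(y_r, sub_part)
                rows.append(
                    {"subregion": region, "factor": p.factor_name, "q": det.q, "p": det.p}
                )
        sub_det = pd.DataFrame(rows)

    manifest = {
        "config_hash": _config_hash(config),
        "seed": int(sc.seed),
        "n_units": int(sc.n_units),
        "grid": [int(sc.grid_rows), int(sc.grid_cols)],
        "years": [int(sc.years[0]), int(sc.years[-1])],
        "periods": [list(p) for p in config.periods],
        "stages": [
            "simulate", "indices", "trend", "effectiveness", "factors", "detect",
        ],
    }

    result = PipelineResult(
        units, vq, series, grades, table, summary, partitions, detections, main,
        interactions, risk, sub_det, manifest,
    )
    if config.out_dir is not None:
        _write_outputs(config, result, lu_book)
    return result


def _write_outputs(config: PipelineConfig, res: PipelineResult, lu_book) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    res.series.to_frame().to_csv(out / "vqqi_series.csv", index=False)
    res.table.to_csv(out / "effectiveness.csv", index=False)
    res.summary.to_csv(out / "area_summary.csv", index=False)
    fdir = out / "factors"
    fdir.mkdir(exist_ok=True)
    for p in res.partitions:
        p.to_frame().to_csv(fdir / f"{p.factor_name}.csv", index=False)
    pd.DataFrame(
        [{"factor": d.factor_name, "q": d.q, "p": d.p} for d in res.detections]
    ).to_csv(out / "detections.csv", index=False)
    pd.DataFrame(
        [
            {"factor_a": i.pair[0], "factor_b": i.pair[1], "q_a": i.q_a,
             "q_b": i.q_b, "q_ab": i.q_ab, "type": i.type}
            for i in res.interactions
        ]
    ).to_csv(out / "interactions.csv", index=False)
    if res.subregion_detections is not None:
        res.subregion_detections.to_csv(out / "subregion_detections.csv", index=False)
    if lu_book is not None:
        lu_book.to_csv(out / "landuse_bookkeeping.csv", index=False)
    if res.risk is not None:
        io.write_report(
            out / "risk.json",
            {
                "factor": res.risk.factor_name,
                "argmax_stratum": res.risk.argmax_stratum,
                "optimal_strata": res.risk.optimal_strata,
                "optimal_range": list(res.risk.optimal_range),
                "strata": res.risk.strata.to_dict("records"),
            },
        )
    series_info = {
        "trend_slope_pct_per_yr": res.series.trend_slope,
        "trend_p": res.series.trend_p,
        "change_year": res.series.change_year,
        "change_p": res.series.change_p,
        "mean_vqqi_pct": float(np.mean(res.series.values)),
    }
    io.write_report(out / "series_summary.json", series_info)
    io.write_report(out / "manifest.json", res.manifest)
    io.write_units(out, res.units)
    if config.write_rasters:
        io.write_stack(out / "rasters", res.vqqi)
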