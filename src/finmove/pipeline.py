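"""End-to-end orchestration: simulate → ingest → fit → classify → spatial stages.

A single nested config (YAML/JSON-able dict) drives the run. Each stage
writes its outputs under the run directory and the manifest records the
config hash, seed and SHA-256 digests of every primary output, so a re-run
with identical config and seed is byte-checkable. Stage failures abort with
the failing stage named; outputs of completed stages are retained.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import argos, classify, grids, habitat, homerange, simulate, ssm, traffic
from .sampler import MCMCConfig, fit_hssm

log = logging.getLogger("finmove")

STAGE_ORDER = ["simulate", "ingest", "fit", "classify", "homerange", "habitat", "overlap", "report"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "outdir": "runs/demo",
    "stages": list(STAGE_ORDER),
    "simulate": {
        "n_platforms": 3,
        "n_steps": 150,
        "step_hours": 12.0,
        "obs_rate_per_day": 3.0,
        "origin": [8.0, 42.5],
        "scene": {
            "grid": {"lon0": 4.0, "lat0": 40.0, "dlon": 0.05, "dlat": 0.05, "nx": 160, "ny": 120},
            "front_lon": 7.0,
            "front_width_deg": 0.3,
            "n_days": 40,
            "lane": [[4.5, 40.5], [11.0, 44.0]],
            "lane_width_deg": 0.15,
            "lane_value": 300,
        },
    },
    "ingest": {
        "argos_csv": None,  # defaults to the simulate stage's output
        "gap_threshold_days": 4.0,
        "min_duration_days": 3.0,
        "min_fixes": 10,
    },
    "fit": {
        "step_hours": 12.0,
        "mcmc": {"chains": 2, "iters": 3000, "burn": 1500, "thin": 5},
    },
    "classify": {"cutoffs": [1.25, 1.75]},
    "homerange": {"core_level": 0.5, "total_level": 0.9},
    "habitat": {"threshold_km": 7.0},
    "overlap": {"percentile": 90.0},
}


def merge_config(overrides: dict | None) -> dict:
    cfg = copy.deepcopy(DEFAULT_CONFIG)

    def merge(dst, src):
        for k, v in src.items():
            if isinstance(v, dict) and isinstance(dst.get(k), dict):
                merge(dst[k], v)
            else:
                dst[k] = v

    if overrides:
        merge(cfg, overrides)
    return cfg


def load_config(path: str | Path | None) -> dict:
    overrides = yaml.safe_load(Path(path).read_text()) if path else None
    return merge_config(overrides)


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def validate_config(cfg: dict) -> None:
    unknown = [s for s in cfg["stages"] if s not in STAGE_ORDER]
    if unknown:
        raise ValueError(f"unknown stage(s): {unknown}")
    if "ingest" in cfg["stages"] and "simulate" not in cfg["stages"]:
        src = cfg["ingest"].get("argos_csv")
        if not src:
            raise ValueError("config key ingest.argos_csv is required when the simulate stage is off")
        if not Path(src).exists():
            raise ValueError(f"config key ingest.argos_csv points to a missing file: {src}")


def run(config: dict | None = None, outdir: str | Path | None = None) -> Path:
    """Execute the configured stages in order; returns the run directory."""
    cfg = merge_config(config or {})
    validate_config(cfg)
    out = Path(outdir or cfg["outdir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    stages = [s for s in STAGE_ORDER if s in cfg["stages"]]
    state: dict = {}
    manifest = {
        "config": cfg,
        "config_hash": config_hash(cfg),
        "seed": seed,
        "stages": stages,
        "outputs": {},
    }
    for stage in stages:
        log.info("stage %s", stage)
        try:
            _STAGE_FUNCS[stage](cfg, seed, out, state)
        except Exception as exc:
            (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
            raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc
    for p in sorted(out.glob("*")):
        if p.is_file() and p.name != "manifest.json":
            manifest["outputs"][p.name] = _digest(p)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return out


# ---------------------------------------------------------------------------
# stages


def _stage_simulate(cfg, seed, out, state):
    sc = cfg["simulate"]
    params = simulate.default_params()
    all_fixes = []
    truths = []
    for i in range(int(sc["n_platforms"])):
        truth = simulate.simulate_dcrws(
            params=params,
            n_steps=int(sc["n_steps"]),
            step_hours=float(sc["step_hours"]),
            origin=tuple(sc["origin"]),
            seed=seed * 1000 + i,
        )
        fixes = simulate.observe_argos(
            truth,
            obs_rate_per_day=float(sc["obs_rate_per_day"]),
            seed=seed * 1000 + 500 + i,
            ptt=f"SIM{i + 1:03d}",
        )
        truths.append(truth)
        all_fixes.extend(fixes)
    argos.write_argos_csv(out / "argos.csv", all_fixes)
    pd.concat(
        [simulate.truth_to_frame(t).assign(ptt=f"SIM{i + 1:03d}") for i, t in enumerate(truths)],
        ignore_index=True,
    ).to_csv(out / "truth.csv", index=False)

    g = sc["scene"]["grid"]
    grid = grids.GridSpec(**g)
    scene = simulate.simulate_scene(
        grid,
        front=simulate.FrontSpec(lon=sc["scene"]["front_lon"], width_deg=sc["scene"]["front_width_deg"]),
        depth=simulate.DepthSpec(),
        lanes=[
            simulate.LaneSpec(
                points=[tuple(p) for p in sc["scene"]["lane"]],
                width_deg=sc["scene"]["lane_width_deg"],
                value=int(sc["scene"]["lane_value"]),
            )
        ],
        n_days=int(sc["scene"]["n_days"]),
        seed=seed + 77,
    )
    grids.write_grid(out / "depth.txt", scene.depth, grid)
    grids.write_grid(out / "traffic.txt", scene.traffic, grid)
    grids.write_grid(out / "chla_day0.txt", scene.chla[0], grid)
    state["scene"] = scene
    state["truths"] = truths


def _stage_ingest(cfg, seed, out, state):
    ic = cfg["ingest"]
    src = ic.get("argos_csv") or out / "argos.csv"
    fixes = argos.read_argos_table(src)
    report = argos.prepare_segments(
        fixes,
        gap_threshold_days=float(ic["gap_threshold_days"]),
        min_duration_days=float(ic["min_duration_days"]),
        min_fixes=int(ic["min_fixes"]),
    )
    argos.write_segments_csv(out / "segments.csv", report.kept)
    argos.write_segments_geojson(out / "segments.geojson", report.kept)
    (out / "exclusions.json").write_text(
        json.dumps({"excluded": [{"ptt": p, "reason": r} for p, r in report.excluded]}, indent=1)
    )
    state["segments"] = report.kept


def _stage_fit(cfg, seed, out, state):
    fc = cfg["fit"]
    segments = state.get("segments")
    if segments is None:
        raise ValueError("fit requires the ingest stage")
    regs = [ssm.regularise(s, step_hours=float(fc["step_hours"])) for s in segments]
    mcmc = MCMCConfig(seed=seed, **{k: int(v) for k, v in fc["mcmc"].items()})
    fit = fit_hssm(regs, mcmc=mcmc)
    fit.summary().to_csv(out / "posterior_params.csv", index=False)
    (out / "diagnostics.json").write_text(json.dumps(fit.diagnostics, indent=1))
    rows = []
    for sp, bhat, xmean in zip(fit.segments, fit.behaviour_means(), fit.location_means()):
        times = sp.origin + pd.to_timedelta(sp.state_times, unit="h")
        lo = np.quantile(sp.x_samples, 0.05, axis=(0, 1))
        hi = np.quantile(sp.x_samples, 0.95, axis=(0, 1))
        rows.append(
            pd.DataFrame(
                {
                    "ptt": sp.ptt,
                    "segment": sp.segment_label,
                    "time": times,
                    "lon": xmean[:, 0],
                    "lat": xmean[:, 1],
                    "lon_q5": lo[:, 0],
                    "lon_q95": hi[:, 0],
                    "lat_q5": lo[:, 1],
                    "lat_q95": hi[:, 1],
                    "b_hat": bhat,
                }
            )
        )
    pd.concat(rows, ignore_index=True).to_csv(out / "states.csv", index=False)
    state["fit"] = fit
    state["seg_durations"] = {
        (s.ptt, s.segment_label): s.duration_days for s in segments
    }


def _stage_classify(cfg, seed, out, state):
    cc = cfg["classify"]
    fit = state.get("fit")
    if fit is None:
        raise ValueError("classify requires the fit stage")
    cutoffs = tuple(cc["cutoffs"])
    series_list = []
    reports = []
    for sp, bhat in zip(fit.segments, fit.behaviour_means()):
        series = classify.classify_series(sp.ptt, sp.segment_label, bhat, cutoffs)
        series_list.append(series)
        days = state.get("seg_durations", {}).get((sp.ptt, sp.segment_label), np.nan)
        reports.append(classify.summarise_track(series, days_of_transmission=days))
    classify.reports_to_frame(reports).to_csv(out / "track_report.csv", index=False)
    pooled = classify.pooled_label_fractions(series_list)
    (out / "pooled_behaviour.json").write_text(json.dumps(pooled, indent=1))
    state["series_list"] = series_list


def _stage_homerange(cfg, seed, out, state):
    hc = cfg["homerange"]
    df = pd.read_csv(out / "states.csv", parse_dates=["time"])
    lonlat = df[["lon", "lat"]].to_numpy()
    xy, proj = homerange.project_positions(lonlat)
    mbg = homerange.minimum_bounding_geometry(xy)
    ud = homerange.kde_ud(xy)
    hr = homerange.home_ranges(ud, float(hc["core_level"]), float(hc["total_level"]))
    grids.write_grid(out / "ud.txt", ud.density, ud.grid)
    summary = {
        "projection_center": [proj.lon0, proj.lat0],
        "bandwidth_km": list(ud.bandwidth_km),
        "chr_area_km2": hr.chr_area_km2,
        "thr_area_km2": hr.thr_area_km2,
        "chr_mass": hr.chr_mass,
        "thr_mass": hr.thr_mass,
        "mbg_area_km2": mbg.area,
    }
    (out / "homerange.json").write_text(json.dumps(summary, indent=1))
    state.update({"ud": ud, "home": hr, "mbg": mbg, "proj": proj, "positions": df})


def _stage_habitat(cfg, seed, out, state):
    hc = cfg["habitat"]
    scene = state.get("scene")
    if scene is None:
        raise ValueError("habitat requires the simulate stage's scene")
    df = state.get("positions")
    if df is None:
        df = pd.read_csv(out / "states.csv", parse_dates=["time"])
    day0 = pd.to_datetime(df["time"]).dt.date.min()
    days = [(pd.Timestamp(day0) + pd.Timedelta(days=i)).date() for i in range(scene.chla.shape[0])]
    stack = habitat.build_habitat_stack(
        scene.chla, scene.depth, scene.grid, days, sea=~scene.land
    )
    daily = habitat.daily_positions(df)
    daily = daily[daily["day"].isin(days)]
    prox = habitat.distance_to_habitat(daily, stack, threshold_km=float(hc["threshold_km"]))
    daily.assign(distance_km=prox.distances_km.to_numpy()).to_csv(
        out / "habitat_proximity.csv", index=False
    )
    summary = {
        "threshold_km": prox.threshold_km,
        "fraction_within": prox.fraction_within,
        "n_positions": int(len(daily)),
        "n_excluded_empty_days": prox.n_excluded_empty_days,
    }
    (out / "habitat_summary.json").write_text(json.dumps(summary, indent=1))
    freq = habitat.habitat_frequency(stack, days)
    grids.write_grid(out / "habitat_frequency.txt", freq, scene.grid)
    state["habitat_stack"] = stack


def _stage_overlap(cfg, seed, out, state):
    oc = cfg["overlap"]
    scene = state.get("scene")
    ud = state.get("ud")
    home = state.get("home")
    mbg = state.get("mbg")
    proj = state.get("proj")
    if any(v is None for v in (scene, ud, home, mbg, proj)):
        raise ValueError("overlap requires the simulate and homerange stages")
    # resample the lon/lat traffic raster onto the UD's equal-area grid
    X, Y = np.meshgrid(ud.grid.x_centers, ud.grid.y_centers)
    lonlat = proj.inverse(np.column_stack([X.ravel(), Y.ravel()]))
    cols = np.floor((lonlat[:, 0] - scene.grid.lon0) / scene.grid.dlon).astype(int)
    rows = np.floor((lonlat[:, 1] - scene.grid.lat0) / scene.grid.dlat).astype(int)
    ok = (cols >= 0) & (cols < scene.grid.nx) & (rows >= 0) & (rows < scene.grid.ny)
    vals = np.zeros(len(lonlat), dtype=np.int64)
    vals[ok] = scene.traffic[rows[ok], cols[ok]]
    raster = traffic.TrafficRaster(grid=ud.grid, values=vals.reshape(ud.grid.shape))
    polys, mask, rule = traffic.extract_high_traffic(raster, mbg, percentile=float(oc["percentile"]))
    report = traffic.overlap_percentages(home, polys, mbg, rule)
    (out / "overlap.json").write_text(json.dumps(report.to_dict(), indent=1))


def _stage_report(cfg, seed, out, state):
    text = report(out)
    (out / "report.txt").write_text(text)


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "ingest": _stage_ingest,
    "fit": _stage_fit,
    "classify": _stage_classify,
    "homerange": _stage_homerange,
    "habitat": _stage_habitat,
    "overlap": _stage_overlap,
    "report": _stage_report,
}


# ---------------------------------------------------------------------------
# reporting


def duration_stats(durations) -> tuple[float, float | None]:
    """Mean and sample (n−1) SD of tag durations; SD is None for n < 2."""
    arr = np.asarray(list(durations), dtype=float)
    if arr.size == 0:
        raise ValueError("no durations")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if arr.size > 1 else None
    return mean, sd


def report(run_dir: str | Path, tag_types: dict[str, str] | None = None) -> str:
    """Human-readable run summary assembled from stage outputs.

    Emits per-segment behaviour rows, the pooled label percentages, mean/SD
    of tracking durations by tag type (sample SD; 'n/a' for a single tag),
    and the proximity / overlap summaries when those stages ran. Missing
    stage outputs are listed as absent, not fatal. Idempotent.
    """
    run_dir = Path(run_dir)
    lines = ["Movement-analysis run summary", "=" * 31]

    track_csv = run_dir / "track_report.csv"
    if track_csv.exists():
        df = pd.read_csv(track_csv)
        lines.append("\nPer-track behavioural classification (% of locations):")
        lines.append(df.to_string(index=False))
        tag_types = tag_types or {}
        per_tag = df.groupby("ptt")["days_of_transmission"].max()
        groups: dict[str, list[float]] = {}
        for ptt, days in per_tag.items():
            groups.setdefault(tag_types.get(str(ptt), "all tags"), []).append(float(days))
        lines.append("\nTracking durations by tag type:")
        for tag, days in sorted(groups.items()):
            mean, sd = duration_stats(days)
            sd_txt = f"{sd:.1f}" if sd is not None else "n/a"
            lines.append(f"  {tag}: n={len(days)} mean={mean:.1f} d SD={sd_txt}")
    else:
        lines.append("\n[track report absent]")

    pooled_json = run_dir / "pooled_behaviour.json"
    if pooled_json.exists():
        pooled = json.loads(pooled_json.read_text())
        lines.append(
            "\nPooled behaviour: "
            + ", ".join(f"{k} {v:.1f}%" for k, v in pooled.items())
        )
    else:
        lines.append("\n[pooled behaviour absent]")

    for name, label in [
        ("homerange.json", "Home ranges"),
        ("habitat_summary.json", "Habitat proximity"),
        ("overlap.json", "Traffic overlap"),
    ]:
        p = run_dir / name
        if p.exists():
            lines.append(f"\n{label}: {json.dumps(json.loads(p.read_text()))}")
        else:
            lines.append(f"\n[{label} absent]")
    return "\n".join(lines) + "\n"
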