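"""End-to-end orchestration: simulate -> render -> register -> measure.

Condition presets encode the study conditions: basal scanning in control and
kainate-activated tissue (mean tip speed 2.38 vs 2.46 μm/min, territory
median 4.18 vs 5.38 μm), the coordinated collective wave toward an agonist
pipette (front speed 1.30 vs 2.68 μm/min over a ~78 μm span), the rapid
uncoordinated convergence onto a laser lesion (3.75 vs 4.16 μm/min within a
35.8 μm response radius), and the severity-graded morphology batch.  Every
run is reproducible from (preset, seed); reports echo the parameters used at
every stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import morphometry, motility, registration, rings, stats, synthetic
from .series import save_tiff

# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

#: Fully resolved condition presets (all physical units in the field names).
CONDITION_PRESETS: dict[str, dict] = {
    "ctrl-basal": {
        "scenario": "basal",
        "morphology": "control",
        "n_cells": 10,
        "speed_mean_um_min": 2.38,
        "territory_scale_um": 4.18,
        "duration_s": 480.0,
        "dt_s": 45.0,
        "dx_nm": 200.0,
    },
    "ka-basal": {
        "scenario": "basal",
        "morphology": "intermediate",
        "n_cells": 10,
        "speed_mean_um_min": 2.46,
        "territory_scale_um": 5.38,
        "duration_s": 480.0,
        "dt_s": 45.0,
        "dx_nm": 200.0,
    },
    "ctrl-agonist": {
        "scenario": "agonist",
        "front_speed_um_min": 1.30,
        "far_distance_um": 77.7,  # farthest responder; (77.7 - 2) / 1.30 ~ 58 min
        "near_distance_um": 25.0,
        "n_tips": 24,
        "coordination": True,
        "speed_cv": 0.02,
        "abort_fraction": 0.15,
        "abort_min_radius_um": 33.0,
        "response_radius_um": 120.0,
        "duration_s": 3900.0,
        "dt_s": 30.0,
        "dx_nm": 300.0,
        "ring_r0_um": 10.0,
        "ring_spacing_um": 5.0,
        "ring_width_um": 2.0,
        "ring_n": 5,
    },
    "ka-agonist": {
        "scenario": "agonist",
        "front_speed_um_min": 2.68,
        "far_distance_um": 77.7,  # (77.7 - 2) / 2.68 ~ 28 min
        "near_distance_um": 25.0,
        "n_tips": 24,
        "coordination": True,
        "speed_cv": 0.02,
        "abort_fraction": 0.15,
        "abort_min_radius_um": 33.0,
        "response_radius_um": 120.0,
        "duration_s": 2400.0,
        "dt_s": 30.0,
        "dx_nm": 300.0,
        "ring_r0_um": 10.0,
        "ring_spacing_um": 5.0,
        "ring_width_um": 2.0,
        "ring_n": 5,
    },
    "ctrl-lesion": {
        "scenario": "lesion",
        "front_speed_um_min": 3.75,
        "dist_mean_um": 26.0,  # responder start distances, clipped normal
        "dist_sd_um": 5.0,
        "dist_lo_um": 17.0,
        "dist_hi_um": 35.5,
        "n_tips": 20,
        "coordination": False,
        "speed_cv": 0.10,
        "abort_fraction": 0.05,
        "abort_beyond_um": 20.8,
        "abort_min_radius_um": 16.5,
        "response_radius_um": 35.8,
        "duration_s": 720.0,
        "dt_s": 25.0,
        "dx_nm": 200.0,
        "ring_r0_um": 5.0,
        "ring_spacing_um": 5.0,
        "ring_width_um": 2.0,
        "ring_n": 3,
    },
    "ka-lesion": {
        "scenario": "lesion",
        "front_speed_um_min": 4.16,
        "dist_mean_um": 26.0,
        "dist_sd_um": 5.0,
        "dist_lo_um": 17.0,
        "dist_hi_um": 35.5,
        "n_tips": 20,
        "coordination": False,
        "speed_cv": 0.10,
        "abort_fraction": 0.05,
        "abort_beyond_um": 20.8,
        "abort_min_radius_um": 16.5,
        "response_radius_um": 35.8,
        "duration_s": 660.0,
        "dt_s": 25.0,
        "dx_nm": 200.0,
        "ring_r0_um": 5.0,
        "ring_spacing_um": 5.0,
        "ring_width_um": 2.0,
        "ring_n": 3,
    },
    "morphology-gradient": {
        "scenario": "morphology",
        "levels": ["control", "intermediate", "intense", "severe"],
        "n_cells_per_level": 90,
        "dx_nm": 200.0,
    },
}

ARRIVAL_RADIUS_UM = 2.0
THETA_UM_MIN = 0.5  # stationary threshold for step classification


def _subseed(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *key]))


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------


def field_config_for_cells(
    cells,
    dx_nm: float,
    dt_s: float,
    margin_um: float = 18.0,
    nz: int = 9,
    **cfg_kwargs,
) -> synthetic.RenderConfig:
    """Render config whose field encloses the cells plus a motion margin."""
    pts = np.vstack([c.all_points() for c in cells])
    lo = pts[:, :2].min(axis=0) - margin_um
    hi = pts[:, :2].max(axis=0) + margin_um
    px = dx_nm / 1000.0
    nx = int(np.ceil((hi[0] - lo[0]) / px)) + 1
    ny = int(np.ceil((hi[1] - lo[1]) / px)) + 1
    z_mid = float(pts[:, 2].mean())
    origin = (float(lo[0]), float(lo[1]), z_mid - (nz - 1) / 2.0)
    return synthetic.RenderConfig(
        shape=(nz, ny, nx), dx_nm=dx_nm, dt_s=dt_s, origin_um=origin, **cfg_kwargs
    )


# ---------------------------------------------------------------------------
# basal experiments
# ---------------------------------------------------------------------------


def run_basal_experiment(
    preset: str,
    seed: int,
    n_cells: int | None = None,
    render_images: bool = True,
    duration_s: float | None = None,
    dt_s: float | None = None,
    drift_amp_px: float = 1.5,
) -> dict:
    """One basal-motility batch: simulate, optionally render/register/track.

    Returns a report with the batch mean tip velocity, territory median, the
    per-tip tables, and (when rendering) the tracked counterparts recovered
    from the registered image series.
    """
    p = dict(CONDITION_PRESETS[preset])
    if p["scenario"] != "basal":
        raise ValueError(f"{preset!r} is not a basal preset")
    n_cells = n_cells or p["n_cells"]
    duration = duration_s or p["duration_s"]
    dt = dt_s or p["dt_s"]

    report: dict = {"preset": preset, "seed": seed, "params": {**p, "n_cells": n_cells,
                    "duration_s": duration, "dt_s": dt, "theta_um_min": THETA_UM_MIN}}
    true_speeds, true_terrs = [], []
    meas_speeds, meas_terrs = [], []
    all_steps = []

    for ci in range(n_cells):
        rng = _subseed(seed, 101, ci)
        cell = synthetic.build_cell(p["morphology"], rng, cell_id=f"cell{ci}")
        gt = synthetic.simulate_basal(
            cell,
            speed_mean=p["speed_mean_um_min"],
            territory_scale=p["territory_scale_um"],
            duration=duration,
            dt=dt,
            rng_seed=rng,
        )
        trajs_true = motility.from_ground_truth(gt)
        for tip, traj in zip(gt.tips, trajs_true):
            true_speeds.append(tip.true_mean_speed)
            true_terrs.append(motility.territory(traj))

        if not render_images:
            for traj in trajs_true:
                meas_speeds.append(motility.mean_tip_velocity(traj))
                meas_terrs.append(motility.territory(traj))
                all_steps.extend(motility.step_kinematics(traj, theta_um_min=THETA_UM_MIN))
            continue

        n_frames = len(gt.tips[0].t_s)
        t = np.arange(n_frames)
        drift = drift_amp_px * np.column_stack(
            [np.sin(2 * np.pi * t / max(n_frames - 1, 1)), t / max(n_frames - 1, 1)]
        )
        drift[0] = 0.0
        cfg = field_config_for_cells(
            [cell], dx_nm=p["dx_nm"], dt_s=dt, drift_px=drift
        )
        series = synthetic.render(cell, gt, cfg, rng_seed=rng)
        trace = registration.estimate_drift(series)
        registered = registration.apply_drift(series, trace)
        proj = registration.mip(registered)

        origin = np.asarray(cfg.origin_um[:2])
        seeds = [
            (tip.tip_id, tip.pos_um[0, 0] - origin[0], tip.pos_um[0, 1] - origin[1])
            for tip in gt.tips
        ]
        tracks = motility.track_tips(proj, seeds, search_radius_um=3.5)
        for tip, track in zip(gt.tips, tracks):
            if len(track) < max(4, n_frames // 2):
                continue  # lost early; exclude from batch statistics
            meas_speeds.append(motility.mean_tip_velocity(track))
            ref = motility.ReferencePoint(
                "parent_origin", tuple(np.asarray(tip.ref_um[:2]) - origin)
            )
            meas_terrs.append(motility.territory(track, ref))
            all_steps.extend(
                motility.step_kinematics(track, reference=ref, theta_um_min=THETA_UM_MIN)
            )

    report["n_tips_true"] = len(true_speeds)
    report["n_tips_measured"] = len(meas_speeds)
    report["true"] = {
        "mean_tip_velocity_um_min": stats.summarize(true_speeds, "mean_sem"),
        "territory_um": stats.summarize(true_terrs, "median_quartiles"),
    }
    report["measured"] = {
        "mean_tip_velocity_um_min": stats.summarize(meas_speeds, "mean_sem"),
        "territory_um": stats.summarize(meas_terrs, "median_quartiles"),
    }
    labels = [s.label for s in all_steps]
    report["steps"] = {
        "n": len(labels),
        "elongation": labels.count("elongation"),
        "retraction": labels.count("retraction"),
        "stationary": labels.count("stationary"),
    }
    report["_tip_tables"] = {
        "true_speeds": true_speeds,
        "true_territories": true_terrs,
        "measured_speeds": meas_speeds,
        "measured_territories": meas_terrs,
    }
    return report


# ---------------------------------------------------------------------------
# directed experiments
# ---------------------------------------------------------------------------


def _directed_distances(p: dict, rng: np.random.Generator) -> np.ndarray:
    if p["scenario"] == "agonist":
        d = rng.uniform(p["near_distance_um"], p["far_distance_um"] - 5.0, p["n_tips"] - 1)
        far = rng.normal(p["far_distance_um"], 2.5)
        return np.r_[d, far]
    d = rng.normal(p["dist_mean_um"], p["dist_sd_um"], p["n_tips"])
    return np.clip(d, p["dist_lo_um"], p["dist_hi_um"])


def run_directed_experiment(
    preset: str,
    seed: int,
    render_images: bool = True,
) -> dict:
    """One directed run: simulate the response, render, estimate ring velocity,
    time-to-target and response extent."""
    p = dict(CONDITION_PRESETS[preset])
    if p["scenario"] not in ("agonist", "lesion"):
        raise ValueError(f"{preset!r} is not a directed preset")
    rng = _subseed(seed, 202)
    target = np.zeros(3)
    distances = _directed_distances(p, rng)
    cells = synthetic.build_target_field(target, distances, rng)
    gt = synthetic.simulate_directed(
        cells,
        target,
        scenario=p["scenario"],
        front_speed=p["front_speed_um_min"],
        response_radius=p["response_radius_um"],
        coordination=p["coordination"],
        duration=p["duration_s"],
        dt=p["dt_s"],
        rng_seed=rng,
        speed_cv=p["speed_cv"],
        abort_fraction=p["abort_fraction"],
        abort_beyond_um=p.get("abort_beyond_um"),
        abort_min_radius_um=p.get("abort_min_radius_um"),
        arrival_radius=ARRIVAL_RADIUS_UM,
    )
    trajs = motility.from_ground_truth(gt)
    report: dict = {"preset": preset, "seed": seed, "params": p}

    t_arr = motility.time_to_target(trajs, target[:2], ARRIVAL_RADIUS_UM)
    extent = motility.response_extent(trajs, target[:2], arrival_radius_um=ARRIVAL_RADIUS_UM)
    elong = []
    for tip, traj in zip(gt.tips, trajs):
        if not tip.responded:
            continue
        v_el = [
            abs(s.radial_velocity_um_min)
            for s in motility.step_kinematics(traj, theta_um_min=THETA_UM_MIN)
            if s.label == "elongation"
        ]
        if v_el:
            elong.append(float(np.mean(v_el)))
    report["time_to_target_min"] = t_arr
    report["max_responding_um"] = extent.max_responding_um
    report["max_arriving_um"] = extent.max_arriving_um
    report["mean_elongation_velocity_um_min"] = float(np.mean(elong)) if elong else None

    if render_images:
        half = float(distances.max() + 14.0 + np.sqrt(30.0 / np.pi))
        px = p["dx_nm"] / 1000.0
        n = int(np.ceil(2 * half / px)) + 1
        cfg = synthetic.RenderConfig(
            shape=(1, n, n),
            dx_nm=p["dx_nm"],
            dt_s=p["dt_s"],
            origin_um=(-half, -half, 0.0),
        )
        series = synthetic.render(cells, gt, cfg, rng_seed=rng)
        proj = registration.mip(series)
        center = (target[0] + half, target[1] + half)
        ringset = rings.build_rings(
            center,
            r0_um=p["ring_r0_um"],
            spacing_um=p["ring_spacing_um"],
            width_um=p["ring_width_um"],
            n=p["ring_n"],
        )
        traces = rings.ring_traces(proj, ringset)
        est = rings.global_velocity(list(reversed(traces)), p["ring_spacing_um"])
        report["global_velocity"] = est.to_dict()
    return report


# ---------------------------------------------------------------------------
# morphology batch
# ---------------------------------------------------------------------------


def run_morphology_batch(
    seed: int,
    levels: list[str] | None = None,
    n_cells_per_level: int | None = None,
) -> pd.DataFrame:
    """Render and measure a severity-graded batch; one record per cell."""
    p = CONDITION_PRESETS["morphology-gradient"]
    levels = levels or p["levels"]
    n_per = n_cells_per_level or p["n_cells_per_level"]
    records = []
    for li, level in enumerate(levels):
        for ci in range(n_per):
            rng = _subseed(seed, 303, li, ci)
            cell = synthetic.build_cell(level, rng, cell_id=f"{level}{ci}")
            cfg = field_config_for_cells(
                [cell], dx_nm=p["dx_nm"], dt_s=45.0, margin_um=4.0,
                amp_tube=900.0, amp_tip=2500.0,
            )
            stack = synthetic.render(cell, None, cfg, rng_seed=rng).data[0]
            vox = _subseed_voxel(cell, cfg)
            rec = morphometry.measure_cell(
                stack,
                vox,
                px_um=cfg.px_um,
                pz_um=cfg.pz_um,
                cell_id=cell.cell_id,
                crisis=morphometry.CRISIS_LEVELS[level],
                animal_id=f"A{li}_{ci % 5}",
                slice_id=f"S{li}_{ci % 10}",
            )
            d = rec.__dict__ | {
                "level": level,
                "true_soma_area_um2": cell.soma_area,
                "true_n_primary": cell.n_primary,
                "true_longest_um": cell.longest_process_xy(),
            }
            records.append(d)
    return pd.DataFrame(records)


def _subseed_voxel(cell, cfg) -> tuple[int, int]:
    """Soma seed pixel (y, x) on the MIP grid from the cell's true soma center."""
    o = np.asarray(cfg.origin_um)
    y = int(round((cell.soma_center[1] - o[1]) / cfg.px_um))
    x = int(round((cell.soma_center[0] - o[0]) / cfg.px_um))
    return (y, x)


def run_coupling_batch(seed: int, n_experiments: int = 12) -> pd.DataFrame:
    """Per-experiment median soma size vs median territory, coupled presets.

    Emulates the observed association between microglial cell-body size and
    the territory scanned by single processes: experiments span the
    activation gradient, and the basal territory scale rises with the
    experiment's soma size (power-law coupling with lognormal scatter).
    Returns one row per experiment with the two medians.
    """
    rows = []
    levels = ["control", "mild", "intermediate", "intense", "severe"]
    for ei in range(n_experiments):
        rng = _subseed(seed, 505, ei)
        level = levels[ei % len(levels)]
        cells = [synthetic.build_cell(level, rng, cell_id=f"e{ei}c{ci}") for ci in range(4)]
        somas = [c.soma_area for c in cells]
        # couple the experiment's territory scale to its realized soma size
        scale = 4.18 * (float(np.median(somas)) / 40.0) ** 0.7 * float(
            np.exp(rng.normal(0.0, 0.15))
        )
        terrs = []
        for cell in cells:
            gt = synthetic.simulate_basal(
                cell, speed_mean=2.4, territory_scale=scale,
                duration=1800.0, dt=30.0, rng_seed=rng,
            )
            terrs.extend(t.true_territory for t in gt.tips)
        rows.append(
            {
                "experiment": ei,
                "level": level,
                "median_soma_um2": float(np.median(somas)),
                "median_territory_um": float(np.median(terrs)),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# config-driven runs and fixtures
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Config for a preset run; loadable from YAML."""

    preset: str
    seed: int
    output_dir: str | None = None
    theta_um_min: float = THETA_UM_MIN
    arrival_radius_um: float = ARRIVAL_RADIUS_UM
    overrides: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.preset not in CONDITION_PRESETS:
            raise ValueError(
                f"unknown preset {self.preset!r}; known: {sorted(CONDITION_PRESETS)}"
            )
        if self.seed is None:
            raise ValueError("a seed is mandatory for simulation runs")
        if self.theta_um_min < 0:
            raise ValueError("theta_um_min must be >= 0")
        if self.arrival_radius_um <= 0:
            raise ValueError("arrival_radius_um must be positive")
        unknown = set(self.overrides) - set(CONDITION_PRESETS[self.preset])
        if unknown:
            raise ValueError(f"unknown override keys for {self.preset!r}: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def run(config: RunConfig) -> dict:
    """Execute one preset run and return (and optionally write) the report."""
    preset = config.preset
    base = CONDITION_PRESETS[preset]
    if config.overrides:
        CONDITION_PRESETS[preset] = {**base, **config.overrides}
    try:
        if base["scenario"] == "basal":
            report = run_basal_experiment(preset, config.seed)
            report.pop("_tip_tables")
        elif base["scenario"] in ("agonist", "lesion"):
            report = run_directed_experiment(preset, config.seed)
        else:
            df = run_morphology_batch(config.seed)
            summary = df.groupby("level")[["soma_area_um2", "n_primary", "longest_process_um"]].median()
            report = {
                "preset": preset,
                "seed": config.seed,
                "params": base,
                "medians_by_level": summary.to_dict(orient="index"),
                "n_cells": int(len(df)),
            }
    finally:
        CONDITION_PRESETS[preset] = base
    report["provenance"] = {
        "preset": preset,
        "seed": config.seed,
        "theta_um_min": config.theta_um_min,
        "arrival_radius_um": config.arrival_radius_um,
    }
    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / f"report_{preset}_seed{config.seed}.json", "w") as fh:
            json.dump(report, fh, indent=2, default=float)
    return report


def make_fixtures(out_dir, size: str = "tiny", seed: int = 0) -> dict:
    """Write small seeded TIFF/CSV fixtures (drift series, agonist, lesion)."""
    if size not in ("tiny", "standard"):
        raise ValueError("size must be 'tiny' or 'standard'")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    n_cells = 1 if size == "tiny" else 3
    paths = {}

    rng = _subseed(seed, 404)
    cell = synthetic.build_cell("control", rng, cell_id="fix0")
    gt = synthetic.simulate_basal(cell, duration=225.0, dt=45.0, rng_seed=rng)
    n_frames = len(gt.tips[0].t_s)
    drift = np.zeros((n_frames, 2))
    drift[2] = (3.0, -2.0)  # known injected shift for registration tests
    if n_frames > 3:
        drift[3:] = (1.0, 1.0)
    cfg = field_config_for_cells([cell], dx_nm=200.0, dt_s=45.0, drift_px=drift)
    series = synthetic.render(cell, gt, cfg, rng_seed=rng)
    paths["basal_drift_tiff"] = str(out / "basal_drift.tiff")
    save_tiff(paths["basal_drift_tiff"], series)
    gt.to_frame().to_csv(out / "basal_drift_truth.csv", index=False)
    paths["basal_drift_truth"] = str(out / "basal_drift_truth.csv")

    for scen, preset in (("agonist", "ctrl-agonist"), ("lesion", "ctrl-lesion")):
        p = dict(CONDITION_PRESETS[preset])
        rng = _subseed(seed, 405 if scen == "agonist" else 406)
        target = np.zeros(3)
        if scen == "agonist":
            dist = np.linspace(18.0, 30.0, 4)
            p.update(duration_s=1500.0)
        else:
            dist = np.linspace(12.0, 20.0, 4)
        cells = synthetic.build_target_field(target, dist, rng)
        gtd = synthetic.simulate_directed(
            cells, target, scenario=scen, front_speed=p["front_speed_um_min"],
            response_radius=p["response_radius_um"], coordination=p["coordination"],
            duration=p["duration_s"], dt=p["dt_s"], rng_seed=rng,
            speed_cv=p["speed_cv"], abort_fraction=0.0,
        )
        half = float(dist.max() + 14.0 + 4.0)
        n = int(np.ceil(2 * half / (p["dx_nm"] / 1000.0))) + 1
        cfg = synthetic.RenderConfig(
            shape=(1, n, n), dx_nm=p["dx_nm"], dt_s=p["dt_s"], origin_um=(-half, -half, 0.0)
        )
        ser = synthetic.render(cells, gtd, cfg, rng_seed=rng)
        paths[f"{scen}_tiff"] = str(out / f"{scen}.tiff")
        save_tiff(paths[f"{scen}_tiff"], ser)
        gtd.to_frame().to_csv(out / f"{scen}_truth.csv", index=False)
        paths[f"{scen}_truth"] = str(out / f"{scen}_truth.csv")
    return paths
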