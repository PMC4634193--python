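"""Tip tracking and process-motility statistics.

All kinematics live on the 2D maximal-intensity projection, in physical units
(μm, μm/min).  Each inter-frame movement of a tip is classified as elongation,
retraction or stationary from its radial velocity relative to a fixed
reference point: for basal motility the reference is where the process emerges
from its parent, and elongation means growing away from it; for a directed
stimulus (pipette tip or lesion site) elongation means approaching the target.
The territory explored is the max-minus-min radial distance from the
reference, irrespective of the direction of movement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from skimage.feature import peak_local_max

from .series import ImageSeries
from .synthetic import MotilityGroundTruth

REFERENCE_KINDS = ("parent_origin", "pipette_tip", "lesion_site")


@dataclass(frozen=True)
class ReferencePoint:
    kind: str  # parent_origin | pipette_tip | lesion_site
    position_um: tuple[float, float]

    def __post_init__(self):
        if self.kind not in REFERENCE_KINDS:
            raise ValueError(f"unknown reference kind {self.kind!r}")
        if not np.all(np.isfinite(self.position_um)):
            raise ValueError("reference position must be finite")

    @property
    def is_target(self) -> bool:
        return self.kind in ("pipette_tip", "lesion_site")


@dataclass
class TipTrajectory:
    """Time-ordered 2D tip positions in μm, with equal frame spacing."""

    tip_id: str
    t_s: np.ndarray  # (N,)
    xy_um: np.ndarray  # (N, 2)
    reference: ReferencePoint | None = None
    scenario: str = ""
    flags: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.t_s = np.asarray(self.t_s, float)
        self.xy_um = np.asarray(self.xy_um, float)
        if len(self.t_s) != len(self.xy_um):
            raise ValueError("t_s and xy_um must have equal length")
        dt = np.diff(self.t_s)
        if len(dt) and np.any(dt <= 0):
            raise ValueError("time must be strictly increasing")
        if len(dt) > 1 and not np.allclose(dt, dt[0]):
            self.flags.append("missing_frames")

    def __len__(self) -> int:
        return len(self.t_s)

    def radial_um(self, reference: ReferencePoint | None = None) -> np.ndarray:
        ref = reference or self.reference
        if ref is None:
            raise ValueError("no reference point available")
        return np.linalg.norm(self.xy_um - np.asarray(ref.position_um), axis=1)


@dataclass(frozen=True)
class MovementStep:
    tip_id: str
    t0_s: float
    t1_s: float
    displacement_um: float  # euclidean step length, >= 0
    radial_velocity_um_min: float  # signed d r / dt
    label: str  # elongation | retraction | stationary


def from_ground_truth(gt: MotilityGroundTruth) -> list[TipTrajectory]:
    """Project simulator ground truth onto the 2D analysis representation."""
    out = []
    for tip in gt.tips:
        if gt.scenario == "basal":
            ref = ReferencePoint("parent_origin", tuple(tip.ref_um[:2]))
        else:
            kind = "pipette_tip" if gt.scenario == "agonist" else "lesion_site"
            ref = ReferencePoint(kind, tuple(gt.target_um[:2]))
        out.append(
            TipTrajectory(
                tip_id=tip.tip_id,
                t_s=tip.t_s.copy(),
                xy_um=tip.pos_um[:, :2].copy(),
                reference=ref,
                scenario=gt.scenario,
            )
        )
    return out


# ---------------------------------------------------------------------------
# tracking
# ---------------------------------------------------------------------------


def track_tips(
    mip_series: ImageSeries,
    seed_points_um,
    search_radius_um: float = 3.0,
    smooth_sigma_px: float = 1.0,
) -> list[TipTrajectory]:
    """Link seeded tips frame-to-frame to the nearest local intensity maximum.

    ``seed_points_um`` is a sequence of (tip_id, x_um, y_um) giving tip
    positions on frame 0.  In each subsequent frame, candidate positions are
    the local maxima of the lightly smoothed MIP; each live tip claims the
    nearest candidate within ``search_radius_um`` (global greedy assignment by
    distance, so a contested candidate goes to the closer tip and the loser's
    track is terminated).  Tracks are terminated, never extrapolated, when no
    candidate exists.
    """
    frames = mip_series.frames2d()
    px = mip_series.px_um
    seeds = [(str(tid), float(x), float(y)) for tid, x, y in seed_points_um]
    positions: dict[str, list[np.ndarray]] = {
        tid: [np.array([x, y])] for tid, x, y in seeds
    }
    alive = {tid: True for tid, _, _ in seeds}
    term_flags: dict[str, str] = {}

    for k in range(1, len(frames)):
        img = ndi.gaussian_filter(frames[k].astype(float), smooth_sigma_px)
        thr = float(np.median(img) + 2.0 * img.std())
        peaks_px = peak_local_max(img, min_distance=1, threshold_abs=thr)
        cand = peaks_px[:, ::-1].astype(float) * px  # (x_um, y_um)
        live = [tid for tid in positions if alive[tid]]
        if len(cand) == 0:
            for tid in live:
                alive[tid] = False
                term_flags[tid] = "no_candidates"
            continue
        # greedy global assignment by distance
        pairs = []
        for tid in live:
            d = np.linalg.norm(cand - positions[tid][-1], axis=1)
            for j in np.where(d <= search_radius_um)[0]:
                pairs.append((d[j], tid, j))
        pairs.sort()
        taken_tip, taken_cand = set(), set()
        for d, tid, j in pairs:
            if tid in taken_tip or j in taken_cand:
                continue
            taken_tip.add(tid)
            taken_cand.add(j)
            positions[tid].append(cand[j])
        for tid in live:
            if tid not in taken_tip:
                alive[tid] = False
                term_flags[tid] = "lost"

    dt = mip_series.dt_s
    out = []
    for tid, _, _ in seeds:
        pts = np.asarray(positions[tid])
        traj = TipTrajectory(
            tip_id=tid, t_s=np.arange(len(pts)) * dt, xy_um=pts, scenario="tracked"
        )
        if tid in term_flags:
            traj.flags.append(f"terminated:{term_flags[tid]}")
        out.append(traj)
    return out


# ---------------------------------------------------------------------------
# kinematics
# ---------------------------------------------------------------------------


def step_kinematics(
    traj: TipTrajectory,
    reference: ReferencePoint | None = None,
    theta_um_min: float = 0.5,
) -> list[MovementStep]:
    """Classify each inter-frame step as elongation / retraction / stationary.

    θ (``theta_um_min``) is the stationary threshold on |radial velocity|;
    ties (|Δr/Δt| == θ) are stationary.  For a parent-origin reference,
    elongation is growth away from the origin; for a target reference
    (pipette or lesion), elongation is approach toward it.  Steps spanning
    missing frames are excluded.
    """
    if theta_um_min < 0:
        raise ValueError("theta must be >= 0")
    ref = reference or traj.reference
    if ref is None:
        raise ValueError("a reference point is required")
    if len(traj) < 2:
        raise ValueError("trajectory needs at least two points")
    r = traj.radial_um(ref)
    dt_nominal = np.min(np.diff(traj.t_s))
    steps = []
    for i in range(len(r) - 1):
        dt_s = traj.t_s[i + 1] - traj.t_s[i]
        if not np.isclose(dt_s, dt_nominal):
            continue  # gap: excluded from step statistics
        dt_min = dt_s / 60.0
        v_rad = (r[i + 1] - r[i]) / dt_min
        disp = float(np.linalg.norm(traj.xy_um[i + 1] - traj.xy_um[i]))
        if abs(v_rad) <= theta_um_min:
            label = "stationary"
        elif (v_rad > 0) != ref.is_target:
            label = "elongation"  # away from origin, or toward the target
        else:
            label = "retraction"
        steps.append(
            MovementStep(
                tip_id=traj.tip_id,
                t0_s=float(traj.t_s[i]),
                t1_s=float(traj.t_s[i + 1]),
                displacement_um=disp,
                radial_velocity_um_min=float(v_rad),
                label=label,
            )
        )
    return steps


def steps_frame(steps: list[MovementStep]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in steps])


def mean_tip_velocity(traj: TipTrajectory) -> float:
    """Mean absolute tip speed over intervals, μm/min (|displacement| / Δt)."""
    if len(traj) < 2:
        raise ValueError("trajectory needs at least two points")
    d = np.linalg.norm(np.diff(traj.xy_um, axis=0), axis=1)
    dt_min = np.diff(traj.t_s) / 60.0
    return float(np.mean(d / dt_min))


def territory(traj: TipTrajectory, reference: ReferencePoint | None = None) -> float:
    """Territory explored: max minus min radial distance from the reference, μm."""
    if len(traj) < 2:
        raise ValueError("trajectory needs at least two points")
    r = traj.radial_um(reference)
    return float(r.max() - r.min())


def time_to_target(
    trajectories: list[TipTrajectory],
    target_um,
    arrival_radius_um: float = 2.0,
) -> float | None:
    """First time any tip enters the arrival disk, in minutes; None if censored."""
    if arrival_radius_um <= 0:
        raise ValueError("arrival_radius must be positive")
    target = np.asarray(target_um, float)
    best = None
    for traj in trajectories:
        d = np.linalg.norm(traj.xy_um - target, axis=1)
        inside = np.where(d <= arrival_radius_um)[0]
        if len(inside):
            t = traj.t_s[inside[0]] / 60.0
            best = t if best is None else min(best, t)
    return best


def _is_responder(r: np.ndarray, delta_um: float, k_steps: int) -> bool:
    """Net approach >= delta over a run of >= k consecutive approaching steps."""
    dr = np.diff(r)
    run_len, run_sum = 0, 0.0
    for step in dr:
        if step < 0:
            run_len += 1
            run_sum += -step
            if run_len >= k_steps and run_sum >= delta_um:
                return True
        else:
            run_len, run_sum = 0, 0.0
    return False


@dataclass
class ResponseExtent:
    max_responding_um: float | None
    max_arriving_um: float | None
    n_responding: int
    n_arriving: int


def response_extent(
    trajectories: list[TipTrajectory],
    target_um,
    delta_um: float = 2.0,
    k_steps: int = 3,
    arrival_radius_um: float = 2.0,
) -> ResponseExtent:
    """Initial distance of the farthest responding and farthest arriving tip.

    A tip responds if it sustains a net approach of at least ``delta_um`` over
    ``k_steps`` or more consecutive approaching intervals; it arrives if it
    enters the arrival disk.  Arriving tips are responders by construction of
    the movement, but the two classes are assessed independently.
    """
    target = np.asarray(target_um, float)
    responding, arriving = [], []
    for traj in trajectories:
        r = np.linalg.norm(traj.xy_um - target, axis=1)
        d0 = float(r[0])
        if _is_responder(r, delta_um, k_steps):
            responding.append(d0)
        if np.any(r <= arrival_radius_um):
            arriving.append(d0)
    if not responding:
        warnings.warn("no responding processes found")
    return ResponseExtent(
        max_responding_um=max(responding) if responding else None,
        max_arriving_um=max(arriving) if arriving else None,
        n_responding=len(responding),
        n_arriving=len(arriving),
    )
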