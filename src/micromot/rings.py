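"""Concentric-ring ("global velocity") front-speed estimator.

Fluorescence is averaged per frame in concentric annuli around the target.
As the process front advances inward, outer rings peak before inner ones; the
front speed is the ring spacing divided by the time between the fluorescence
maxima of consecutive rings.  An experiment is valid only when at least three
rings show a clearly identifiable peak — i.e. at least two pairwise
velocities — and the mean of the pairwise velocities is the representative
value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import peak_prominences

from .series import ImageSeries


@dataclass(frozen=True)
class RingSet:
    """Concentric annuli: centers at r0 + i*spacing, half-open width w."""

    center_um: tuple[float, float]  # (x, y)
    r0_um: float
    spacing_um: float
    width_um: float
    n: int

    def __post_init__(self):
        if min(self.r0_um, self.spacing_um, self.width_um) <= 0 or self.n < 1:
            raise ValueError("ring parameters must be positive and n >= 1")
        if self.width_um > self.spacing_um:
            raise ValueError("rings overlap: width must not exceed spacing")

    def radii_um(self) -> np.ndarray:
        return self.r0_um + self.spacing_um * np.arange(self.n)

    def bounds_um(self) -> list[tuple[float, float]]:
        return [(r - self.width_um / 2, r + self.width_um / 2) for r in self.radii_um()]


def build_rings(
    center_um,
    r0_um: float = 2.0,
    spacing_um: float = 5.0,
    width_um: float = 2.0,
    n: int = 5,
    field_um: tuple[float, float] | None = None,
) -> RingSet:
    """Validated ring geometry; optionally checked against the field extent."""
    rings = RingSet(tuple(map(float, center_um)), r0_um, spacing_um, width_um, n)
    if field_um is not None:
        fx, fy = field_um
        cx, cy = rings.center_um
        outer = rings.radii_um()[-1] + width_um / 2
        margin = min(cx, cy, fx - cx, fy - cy)
        if outer > margin:
            raise ValueError(
                f"ring {n - 1} (outer radius {outer:.1f} μm) extends beyond the field "
                f"(margin {margin:.1f} μm from center)"
            )
    return rings


@dataclass
class RingTrace:
    """Background-subtracted mean fluorescence of one annulus over time."""

    ring_index: int
    radius_um: float
    t_s: np.ndarray
    trace: np.ndarray  # background-subtracted raw
    smoothed: np.ndarray
    peak_frame: int
    peak_time_s: float
    valid: bool
    flags: list[str] = field(default_factory=list)


def _smooth3(x: np.ndarray) -> np.ndarray:
    """Centered moving average, window 3, edges averaged over available frames."""
    out = np.empty_like(x, dtype=float)
    for i in range(len(x)):
        lo, hi = max(0, i - 1), min(len(x), i + 2)
        out[i] = x[lo:hi].mean()
    return out


def ring_traces(
    mip_series: ImageSeries,
    rings: RingSet,
    n_baseline_frames: int = 1,
    prominence_frac: float = 0.2,
) -> list[RingTrace]:
    """Per-ring fluorescence-vs-time with peak detection.

    Background is the mean over the pre-stimulus frames (default: frame 0)
    and is subtracted per ring.  The trace is smoothed by a centered 3-frame
    moving average; the peak is the earliest frame attaining the smoothed
    maximum.  A peak is valid when its prominence is at least
    ``prominence_frac`` of the trace's dynamic range and it is not pinned to
    the first or last frame (flat or still-rising traces are invalid).
    """
    frames = mip_series.frames2d().astype(float)
    px = mip_series.px_um
    ny, nx = frames.shape[1:]
    yy, xx = np.mgrid[:ny, :nx]
    cx, cy = rings.center_um
    r_map = np.hypot(xx * px - cx, yy * px - cy)

    t_s = mip_series.times_s()
    out = []
    for i, (lo, hi) in enumerate(rings.bounds_um()):
        mask = (r_map >= lo) & (r_map < hi)
        if not mask.any():
            raise ValueError(f"ring {i} ([{lo:.1f}, {hi:.1f}) μm) covers no pixels")
        raw = frames[:, mask].mean(axis=1)
        baseline = raw[: max(1, n_baseline_frames)].mean()
        trace = raw - baseline
        sm = _smooth3(trace)
        peak = int(np.argmax(sm))  # argmax returns the earliest tie
        flags = []
        rng_dyn = float(sm.max() - sm.min())
        valid = True
        if rng_dyn <= 0:
            valid, flags = False, ["flat_trace"]
        elif peak in (0, len(sm) - 1):
            valid, flags = False, ["peak_at_boundary"]
        else:
            prom = float(peak_prominences(sm, [peak])[0][0])
            if prom < prominence_frac * rng_dyn:
                valid, flags = False, ["low_prominence"]
        out.append(
            RingTrace(
                ring_index=i,
                radius_um=float(rings.radii_um()[i]),
                t_s=t_s,
                trace=trace,
                smoothed=sm,
                peak_frame=peak,
                peak_time_s=float(t_s[peak]),
                valid=valid,
                flags=flags,
            )
        )
    return out


def traces_frame(traces: list[RingTrace]) -> pd.DataFrame:
    rows = []
    for tr in traces:
        for t, f, fs in zip(tr.t_s, tr.trace, tr.smoothed):
            rows.append(
                {"ring": tr.ring_index, "t_s": t, "F": f, "F_smoothed": fs, "valid": tr.valid}
            )
    return pd.DataFrame(rows)


@dataclass
class GlobalVelocityEstimate:
    pairwise_um_min: list[float]
    mean_um_min: float | None
    n_valid_peaks: int
    valid: bool
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "pairwise_velocities_um_min": self.pairwise_um_min,
            "mean_velocity_um_min": self.mean_um_min,
            "n_valid_peaks": self.n_valid_peaks,
            "valid": self.valid,
            "flags": self.flags,
        }


def global_velocity(traces: list[RingTrace], spacing_um: float) -> GlobalVelocityEstimate:
    """Front speed from peak-time gaps of consecutive valid rings, μm/min.

    Traces must be ordered outer to inner (the front advances toward the
    target, so outer rings peak first).  A pair whose peak times are
    non-monotonic (inner before outer) is dropped with a warning.  The
    estimate is valid only with >= 3 valid peaks.
    """
    valid_traces = [tr for tr in traces if tr.valid]
    flags: list[str] = []
    pairwise: list[float] = []
    for a, b in zip(valid_traces[:-1], valid_traces[1:]):
        gap_rings = abs(a.ring_index - b.ring_index)
        dt_s = b.peak_time_s - a.peak_time_s
        if dt_s <= 0:
            flags.append(f"non_monotonic_pair:{a.ring_index}-{b.ring_index}")
            warnings.warn(
                f"inner ring {b.ring_index} peaked before outer ring {a.ring_index}; pair dropped"
            )
            continue
        pairwise.append(spacing_um * gap_rings / (dt_s / 60.0))
    n_valid = len(valid_traces)
    valid = n_valid >= 3 and len(pairwise) >= 1
    mean = float(np.mean(pairwise)) if (valid and pairwise) else None
    return GlobalVelocityEstimate(
        pairwise_um_min=pairwise,
        mean_um_min=mean,
        n_valid_peaks=n_valid,
        valid=valid,
        flags=flags,
    )
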