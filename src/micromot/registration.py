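"""Lateral drift compensation and maximal-intensity projection.

Live-slice time series drift slowly in x-y; all tip tracking and ring
measurements assume a stationary field, so frames are registered to the first
frame by pure 2D translation estimated with phase cross-correlation on the
per-frame maximal-intensity projections.  Axial drift is not corrected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from skimage.registration import phase_cross_correlation

from .series import ImageSeries


@dataclass
class DriftTrace:
    """Per-frame translation (y, x) of each frame relative to the reference."""

    shifts_px: np.ndarray  # (T, 2), subpixel allowed
    reference_frame: int = 0
    flagged: list[int] = field(default_factory=list)  # frames where estimation failed

    def __post_init__(self):
        self.shifts_px = np.asarray(self.shifts_px, float)
        if self.shifts_px.ndim != 2 or self.shifts_px.shape[1] != 2:
            raise ValueError("shifts_px must be (T, 2)")
        ref = self.shifts_px[self.reference_frame]
        if not np.allclose(ref, 0.0, atol=1e-9):
            raise ValueError("shift at the reference frame must be (0, 0)")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": np.arange(len(self.shifts_px)),
                "shift_y_px": self.shifts_px[:, 0],
                "shift_x_px": self.shifts_px[:, 1],
            }
        )


def mip(series: ImageSeries) -> ImageSeries:
    """Per-frame maximum over z; calibration carried over (z collapsed to 1)."""
    return ImageSeries(
        data=series.data.max(axis=1, keepdims=True),
        dx_nm=series.dx_nm,
        dy_nm=series.dy_nm,
        dz_nm=series.dz_nm,
        dt_s=series.dt_s,
        meta=dict(series.meta, mip=True),
    )


def estimate_drift(series: ImageSeries, upsample_factor: int = 20) -> DriftTrace:
    """Estimate per-frame (y, x) translation against the first frame.

    Works on the MIP of each frame.  A frame with no signal (all-zero) has an
    undefined shift; it is flagged and its shift linearly interpolated from
    neighbours.
    """
    if series.n_frames < 2:
        raise ValueError("need at least two frames to estimate drift")
    mips = series.data.max(axis=1)
    ref = mips[0]
    shifts = np.zeros((series.n_frames, 2))
    flagged: list[int] = []
    # plain cross-correlation (normalization=None): the correlation peak is
    # weighted by the bright static structures (soma, arbor), so the moving
    # tips barely bias it — more robust here than whitened phase correlation
    for k in range(1, series.n_frames):
        frame = mips[k]
        if not np.any(frame) or not np.any(ref):
            flagged.append(k)
            shifts[k] = np.nan
            continue
        # returned shift registers `frame` onto `ref`; the frame's displacement
        # relative to the reference is the negation
        shift, _, _ = phase_cross_correlation(
            ref, frame, upsample_factor=upsample_factor, normalization=None
        )
        shifts[k] = -shift
    if flagged:
        warnings.warn(f"shift undefined for frames {flagged}; interpolated from neighbours")
        good = ~np.isnan(shifts[:, 0])
        idx = np.arange(series.n_frames)
        for c in range(2):
            shifts[~good, c] = np.interp(idx[~good], idx[good], shifts[good, c])
    return DriftTrace(shifts_px=shifts, reference_frame=0, flagged=flagged)


def apply_drift(series: ImageSeries, trace: DriftTrace) -> ImageSeries:
    """Resample each frame by the negated estimated shift (linear interpolation).

    Pixels shifted in from outside the field are filled with a robust
    background estimate (per-frame median).
    """
    if len(trace.shifts_px) != series.n_frames:
        raise ValueError(
            f"trace length {len(trace.shifts_px)} != frame count {series.n_frames}"
        )
    out = np.empty_like(series.data, dtype=float)
    for k in range(series.n_frames):
        sy, sx = trace.shifts_px[k]
        if sy == 0 and sx == 0:
            out[k] = series.data[k]
            continue
        bg = float(np.median(series.data[k]))
        out[k] = ndi.shift(
            series.data[k].astype(float), (0.0, -sy, -sx), order=1, mode="constant", cval=bg
        )
    return ImageSeries(
        data=np.clip(out, 0.0, None),
        dx_nm=series.dx_nm,
        dy_nm=series.dy_nm,
        dz_nm=series.dz_nm,
        dt_s=series.dt_s,
        meta=dict(series.meta, registered=True),
    )
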