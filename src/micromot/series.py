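"""Calibrated 4D image series: the in-memory container and TIFF round-trip.

An :class:`ImageSeries` holds a (t, z, y, x) intensity grid together with the
physical voxel size (nm) and the frame interval (s).  Two-photon time-lapse
stacks of GFP-labeled microglia are anisotropic: the axial step (dz, typically
1000 nm) is several times the lateral pixel (dx = dy, 200-300 nm), and frames
arrive every 25-60 s.  All downstream measurements convert to μm and μm/min
through the calibration stored here, never through hard-coded constants.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import tifffile


@dataclass
class ImageSeries:
    """A (t, z, y, x) fluorescence stack with physical calibration.

    Parameters
    ----------
    data:
        4D array indexed (t, z, y, x).  Non-negative.
    dx_nm, dy_nm, dz_nm:
        Voxel edge lengths in nanometres; dx must equal dy (square pixels)
        and dz >= dx (anisotropic axial sampling).
    dt_s:
        Interval between consecutive frames, seconds.
    meta:
        Free-form provenance (condition, animal, slice, injected drift, ...).
    """

    data: np.ndarray
    dx_nm: float
    dy_nm: float
    dz_nm: float
    dt_s: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"expected (t, z, y, x) data, got ndim={self.data.ndim}")
        if any(s < 1 for s in self.data.shape):
            raise ValueError(f"all dimensions must be >= 1, got shape {self.data.shape}")
        if not (self.dx_nm == self.dy_nm > 0):
            raise ValueError("square pixels required: dx_nm == dy_nm > 0")
        if self.dz_nm < self.dx_nm:
            raise ValueError("dz_nm must be >= dx_nm (axial step coarser than lateral)")
        if self.dt_s <= 0:
            raise ValueError("dt_s must be positive")
        if self.data.size and float(self.data.min()) < 0:
            raise ValueError("intensities must be non-negative")

    # -- convenience ---------------------------------------------------

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_z(self) -> int:
        return self.data.shape[1]

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.data.shape

    @property
    def px_um(self) -> float:
        """Lateral pixel size in μm."""
        return self.dx_nm / 1000.0

    def frames2d(self) -> np.ndarray:
        """(t, y, x) view for series that are already projections (z == 1)."""
        if self.n_z != 1:
            raise ValueError("frames2d requires z == 1; take a MIP first")
        return self.data[:, 0]

    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) * float(self.dt_s)


def save_tiff(path, series: ImageSeries) -> None:
    """Write a multi-page TIFF with the calibration embedded as JSON metadata."""
    meta = {
        "axes": "TZYX",
        "dx_nm": series.dx_nm,
        "dy_nm": series.dy_nm,
        "dz_nm": series.dz_nm,
        "dt_s": series.dt_s,
        "micromot_meta": json.dumps(series.meta, default=str),
    }
    data = series.data
    if data.dtype.kind == "f":
        data = data.astype(np.float32)
    tifffile.imwrite(path, data, metadata=meta)


def load_tiff(path) -> ImageSeries:
    """Read a series written by :func:`save_tiff` (calibration restored)."""
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        md = tif.shaped_metadata[0] if tif.shaped_metadata else {}
    if data.ndim == 3:  # single z-plane collapsed by tifffile
        data = data[:, None, :, :]
    meta = json.loads(md.get("micromot_meta", "{}"))
    return ImageSeries(
        data=data,
        dx_nm=float(md.get("dx_nm", 200.0)),
        dy_nm=float(md.get("dy_nm", md.get("dx_nm", 200.0))),
        dz_nm=float(md.get("dz_nm", 1000.0)),
        dt_s=float(md.get("dt_s", 45.0)),
        meta=meta,
    )
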