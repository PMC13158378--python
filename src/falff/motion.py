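"""Framewise displacement, outlier-frame flagging and subject exclusion.

FD follows the bounding-box control-point method: six control points are
placed at the face centers of a box around the brain (default
140 x 180 x 115 mm), each frame's rigid-body transform is applied to the
points, and FD(t) is the largest Euclidean displacement of any point
between frames t-1 and t. Rotations are taken about the box center, so FD
depends only on the box dimensions, not its placement. Rotation
convention: intrinsic rotations about x, then y, then z (composite
R = Rx @ Ry @ Rz on column vectors).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Default bounding-box dimensions (mm) around the brain.
DEFAULT_BOX_DIMS = (140.0, 180.0, 115.0)

MOTION_COLUMNS = ("trans_x_mm", "trans_y_mm", "trans_z_mm",
                  "rot_x_rad", "rot_y_rad", "rot_z_rad")


@dataclass
class QcResult:
    """Per-run motion QC summary."""

    fd: np.ndarray
    outlier_mask: np.ndarray
    outlier_fraction: float
    excluded: bool
    mean_fd: float

    def to_frame(self, global_z: np.ndarray | None = None) -> pd.DataFrame:
        n = len(self.fd)
        return pd.DataFrame({
            "frame": np.arange(n),
            "fd_mm": self.fd,
            "global_z": np.zeros(n) if global_z is None else global_z,
            "outlier": self.outlier_mask.astype(int),
        })


def motion_params(trace) -> np.ndarray:
    """Coerce a motion trace (DataFrame or array) to an (n, 6) float array."""
    if isinstance(trace, pd.DataFrame):
        arr = trace[list(MOTION_COLUMNS)].to_numpy(dtype=np.float64)
    else:
        arr = np.asarray(trace, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[1] != 6:
        raise ValueError(f"motion trace must be (n_frames, 6), got {arr.shape}")
    return arr


def rotation_matrix(rx: float, ry: float, rz: float) -> np.ndarray:
    """Intrinsic x-y-z rotation matrix (R = Rx @ Ry @ Rz)."""
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    rx_m = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry_m = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz_m = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rx_m @ ry_m @ rz_m


def control_points(box_dims_mm=DEFAULT_BOX_DIMS) -> np.ndarray:
    """Six face-center control points, relative to the box center (mm)."""
    hx, hy, hz = (d / 2.0 for d in box_dims_mm)
    return np.array([
        [+hx, 0, 0], [-hx, 0, 0],
        [0, +hy, 0], [0, -hy, 0],
        [0, 0, +hz], [0, 0, -hz],
    ], dtype=np.float64)


def framewise_displacement(
    trace,
    box_dims_mm=DEFAULT_BOX_DIMS,
    box_center=None,
) -> np.ndarray:
    """FD series (mm) from rigid-body parameters; FD(0) = 0.

    ``box_center`` is accepted for interface symmetry but does not affect
    the result: control points are defined relative to the center and
    rotations are taken about it.
    """
    params = motion_params(trace)
    if params.shape[0] < 2:
        raise ValueError("need at least 2 frames to compute FD")
    bad = ~np.isfinite(params).all(axis=1)
    if bad.any():
        raise ValueError(f"non-finite motion parameters at frame {int(np.where(bad)[0][0])}")
    pts = control_points(box_dims_mm)  # (6, 3)
    n = params.shape[0]
    positions = np.empty((n, 6, 3))
    for t in range(n):
        r = rotation_matrix(*params[t, 3:])
        positions[t] = pts @ r.T + params[t, :3]
    disp = np.linalg.norm(np.diff(positions, axis=0), axis=2)  # (n-1, 6)
    fd = np.zeros(n)
    fd[1:] = disp.max(axis=1)
    return fd


def global_signal_z(global_signal: np.ndarray) -> np.ndarray:
    """Z-scored frame-to-frame change of the global signal (first frame 0).

    A constant signal yields all-zero z-scores rather than an error.
    """
    gs = np.asarray(global_signal, dtype=np.float64)
    dz = np.zeros(len(gs))
    d = np.diff(gs)
    sd = d.std()
    if sd > 0:
        dz[1:] = (d - d.mean()) / sd
    return dz


def flag_outlier_frames(
    fd: np.ndarray,
    global_signal: np.ndarray | None = None,
    fd_thresh_mm: float = 0.5,
    z_thresh: float = 3.0,
) -> np.ndarray:
    """Union of the FD and global-signal-change outlier criteria."""
    fd = np.asarray(fd, dtype=np.float64)
    flags = fd > fd_thresh_mm
    if global_signal is not None:
        gs = np.asarray(global_signal, dtype=np.float64)
        if len(gs) != len(fd):
            raise ValueError(f"series lengths differ: fd {len(fd)}, global {len(gs)}")
        flags = flags | (np.abs(global_signal_z(gs)) > z_thresh)
    return flags


def subject_exclusion(outlier_mask: np.ndarray, max_fraction: float = 0.10) -> bool:
    """Excluded iff the flagged fraction strictly exceeds ``max_fraction``."""
    mask = np.asarray(outlier_mask, dtype=bool)
    if mask.size == 0:
        raise ValueError("empty outlier mask")
    return bool(mask.mean() > max_fraction)


def qc_run(
    trace,
    global_signal: np.ndarray | None = None,
    fd_thresh_mm: float = 0.5,
    z_thresh: float = 3.0,
    max_fraction: float = 0.10,
    box_dims_mm=DEFAULT_BOX_DIMS,
) -> QcResult:
    """Full per-run QC: FD, outlier flags, exclusion decision."""
    fd = framewise_displacement(trace, box_dims_mm=box_dims_mm)
    flags = flag_outlier_frames(fd, global_signal, fd_thresh_mm, z_thresh)
    frac = float(flags.mean())
    return QcResult(
        fd=fd,
        outlier_mask=flags,
        outlier_fraction=frac,
        excluded=frac > max_fraction,
        mean_fd=float(fd.mean()),
    )
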