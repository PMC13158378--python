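"""NIfTI and table I/O with strict shape/affine validation.

All images are NIfTI-1 (gzip allowed). Data are float32 on disk and float64
in memory. Voxel and frame indices are 0-based; time intervals half-open.
No resampling is performed anywhere: spatial operations must preserve the
affine, and shape mismatches raise instead of being coerced.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Metric names an AmplitudeMap may carry.
METRICS = ("ALFF", "fALFF", "tSNR", "gbold_beta", "gm_prob", "fc_z", "tstat")


@dataclass
class BoldRun:
    """A 4D BOLD run: (x, y, z, t) array, repetition time and brain mask."""

    data: np.ndarray
    tr: float
    affine: np.ndarray
    brain_mask: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError(f"BOLD data must be 4D, got shape {self.data.shape}")
        if self.data.shape[3] < 2:
            raise ValueError(f"need at least 2 frames, got {self.data.shape[3]}")
        if self.tr <= 0:
            raise ValueError(f"TR must be positive, got {self.tr}")
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.affine.shape != (4, 4):
            raise ValueError(f"affine must be 4x4, got {self.affine.shape}")
        self.brain_mask = np.asarray(self.brain_mask).astype(bool)
        if self.brain_mask.shape != self.data.shape[:3]:
            raise ValueError(
                f"mask shape {self.brain_mask.shape} does not match "
                f"spatial shape {self.data.shape[:3]}"
            )

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]


@dataclass
class LabelAtlas:
    """Integer label image; label 0 is background, labels 1..K are ROIs."""

    labels: np.ndarray
    names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("atlas labels must be integer-valued")
        present = set(np.unique(self.labels).tolist())
        for lab in self.names:
            if lab != 0 and lab not in present:
                raise ValueError(f"named label {lab} absent from label image")

    @property
    def roi_labels(self) -> list[int]:
        labs = np.unique(self.labels)
        return [int(v) for v in labs if v != 0]

    def roi_mask(self, label: int) -> np.ndarray:
        return self.labels == label


@dataclass
class AmplitudeMap:
    """A 3D voxelwise metric map with provenance."""

    values: np.ndarray
    metric: str
    normalized: bool = False
    source: str | None = None
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(f"map must be 3D, got shape {self.values.shape}")
        if self.metric not in METRICS:
            raise ValueError(f"unknown metric {self.metric!r}; one of {METRICS}")


def load_run(
    path_bold: str | Path,
    path_mask: str | Path,
    tr_override: float | None = None,
) -> BoldRun:
    """Load a 4D run and its brain mask, validating shapes and TR.

    TR is taken from the NIfTI header (pixdim[4]) unless ``tr_override``
    is given, in which case the override wins and a warning is logged.
    """
    img = nib.load(str(path_bold))
    data = np.asanyarray(img.dataobj).astype(np.float64)
    if data.ndim != 4:
        raise ValueError(f"{path_bold}: expected a 4D image, got {data.ndim}D")
    mask_img = nib.load(str(path_mask))
    mask = np.asanyarray(mask_img.dataobj)
    if mask.shape != data.shape[:3]:
        raise ValueError(
            f"mask shape {mask.shape} does not match run spatial shape "
            f"{data.shape[:3]}"
        )
    header_tr = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 0.0
    if tr_override is not None:
        if header_tr > 0 and abs(header_tr - tr_override) > 1e-9:
            logger.warning(
                "TR override %.4g s replaces header TR %.4g s for %s",
                tr_override, header_tr, path_bold,
            )
        tr = float(tr_override)
    else:
        tr = header_tr
    if tr <= 0:
        raise ValueError(f"{path_bold}: nonpositive TR {tr}; pass tr_override")
    return BoldRun(data=data, tr=tr, affine=img.affine, brain_mask=mask > 0)


def save_run(run: BoldRun, path: str | Path) -> None:
    """Write a 4D run as float32 NIfTI-1 with TR in the header."""
    img = nib.Nifti1Image(run.data.astype(np.float32), run.affine)
    img.header.set_zooms(tuple(img.header.get_zooms()[:3]) + (run.tr,))
    nib.save(img, str(path))


def save_mask(mask: np.ndarray, affine: np.ndarray, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(mask.astype(np.uint8), affine), str(path))


def save_atlas(atlas: LabelAtlas, affine: np.ndarray, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(atlas.labels.astype(np.int16), affine), str(path))


def load_atlas(path: str | Path, names: dict[int, str] | None = None) -> LabelAtlas:
    img = nib.load(str(path))
    labels = np.asanyarray(img.dataobj).astype(np.int64)
    return LabelAtlas(labels=labels, names=names or {})


def save_map(
    amap: AmplitudeMap,
    path: str | Path,
    affine: np.ndarray | None = None,
    mask: np.ndarray | None = None,
) -> None:
    """Write an AmplitudeMap as float32 NIfTI-1.

    NaN is permitted outside the mask; NaN inside the mask raises. The
    metric name (and normalization flag) is stored in the header descrip
    field.
    """
    if affine is None:
        affine = amap.affine
    if affine is None:
        raise ValueError("no affine available: pass one or set it on the map")
    if mask is not None:
        inside = amap.values[np.asarray(mask, dtype=bool)]
        if not np.all(np.isfinite(inside)):
            raise ValueError(f"non-finite values inside mask for metric {amap.metric}")
    img = nib.Nifti1Image(amap.values.astype(np.float32), np.asarray(affine))
    tag = amap.metric + (":normalized" if amap.normalized else "")
    img.header["descrip"] = tag.encode()[:79]
    nib.save(img, str(path))


def load_map(path: str | Path) -> AmplitudeMap:
    img = nib.load(str(path))
    descrip = bytes(img.header["descrip"].tobytes()).rstrip(b"\x00").decode()
    metric, _, flag = descrip.partition(":")
    if metric not in METRICS:
        raise ValueError(f"{path}: unrecognized metric tag {descrip!r}")
    return AmplitudeMap(
        values=np.asanyarray(img.dataobj).astype(np.float64),
        metric=metric,
        normalized=(flag == "normalized"),
        affine=img.affine,
        source=str(path),
    )


def truncate_run(run: BoldRun, n_keep: int, n_discard_initial: int = 0) -> BoldRun:
    """Keep frames [n_discard_initial, n_discard_initial + n_keep).

    Motion and confound tables must be truncated identically by the
    caller; this function only slices the image data.
    """
    if n_discard_initial < 0 or n_keep < 2:
        raise ValueError("n_discard_initial must be >= 0 and n_keep >= 2")
    available = run.n_frames - n_discard_initial
    if n_keep > available:
        raise ValueError(
            f"cannot keep {n_keep} frames: only {available} available after "
            f"discarding {n_discard_initial} of {run.n_frames}"
        )
    sl = slice(n_discard_initial, n_discard_initial + n_keep)
    return replace(run, data=run.data[..., sl])


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
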