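"""ROI summarization, test-retest ICC and Bland-Altman agreement.

The ICC is the Shrout-Fleiss two-way random, absolute-agreement,
single-measure form, ICC(2,1):

    ICC = (MS_R - MS_E) / (MS_R + (k-1) MS_E + k (MS_C - MS_E) / n)

with n units, k sessions, MS_R the between-unit, MS_C the between-session
and MS_E the residual mean square of the two-way ANOVA. It can be
computed per ROI across subjects (reliability of a region) or per subject
across ROIs (repeatability of a subject's whole regional profile); the
mode is recorded on the result.

Bland-Altman differences follow the session2 - session1 sign convention,
with limits of agreement bias +/- 1.96 SD(differences, ddof=1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import AmplitudeMap, LabelAtlas

logger = logging.getLogger(__name__)


def roi_summarize(
    amap: AmplitudeMap,
    atlas: LabelAtlas,
    mask: np.ndarray | None = None,
) -> dict[int, float]:
    """Mean map value over in-ROI, in-mask, finite voxels per label.

    Infinite sentinel voxels (e.g. zero-variance tSNR) are excluded. An
    empty ROI yields NaN with a warning.
    """
    if atlas.labels.shape != amap.values.shape:
        raise ValueError(
            f"atlas shape {atlas.labels.shape} != map shape {amap.values.shape}"
        )
    select = atlas.labels > 0
    if mask is not None:
        select &= np.asarray(mask, dtype=bool)
    if not select.any():
        raise ValueError("no overlap between atlas and mask")
    out: dict[int, float] = {}
    for lab in atlas.roi_labels:
        vals = amap.values[(atlas.labels == lab) & select]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            logger.warning("ROI %d has no finite in-mask voxels", lab)
            out[lab] = float("nan")
        else:
            out[lab] = float(vals.mean())
    return out


def build_roi_table(rows: list[dict]) -> pd.DataFrame:
    """Assemble per-(subject, session) ROI means into a tidy table."""
    df = pd.DataFrame(rows)
    dup = df.duplicated(subset=["subject", "session"])
    if dup.any():
        raise ValueError("duplicate (subject, session) rows in ROI table")
    return df


@dataclass
class IccResult:
    unit: str
    icc: float
    ms_rows: float
    ms_cols: float
    ms_error: float
    mode: str
    undefined: bool = False


def icc(paired_values: np.ndarray, mode: str = "per_roi_across_subjects",
        unit: str = "") -> IccResult:
    """ICC(2,1) for an (n_units, k_sessions) matrix via two-way ANOVA."""
    y = np.asarray(paired_values, dtype=np.float64)
    if y.ndim != 2 or y.shape[1] != 2:
        raise ValueError(f"expected (n_units, 2) matrix, got {y.shape}")
    n, k = y.shape
    if n < 3:
        raise ValueError(f"need at least 3 units, got {n}")
    grand = y.mean()
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((y - grand) ** 2).sum()
    ss_error = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_cols = ss_cols / (k - 1)
    ms_error = ss_error / ((n - 1) * (k - 1))
    denom = ms_rows + (k - 1) * ms_error + k * (ms_cols - ms_error) / n
    if ss_total <= 0 or denom == 0:
        return IccResult(unit, float("nan"), ms_rows, ms_cols, ms_error, mode, undefined=True)
    value = (ms_rows - ms_error) / denom
    return IccResult(unit, float(value), ms_rows, ms_cols, ms_error, mode)


def icc_per_roi(table: pd.DataFrame, roi_columns: list[str]) -> list[IccResult]:
    """ICC(2,1) per ROI across subjects (sessions as raters)."""
    out = []
    for col in roi_columns:
        wide = table.pivot(index="subject", columns="session", values=col).to_numpy()
        out.append(icc(wide, mode="per_roi_across_subjects", unit=str(col)))
    return out


def icc_per_subject(table: pd.DataFrame, roi_columns: list[str]) -> list[IccResult]:
    """ICC(2,1) per subject across ROIs (whole-profile repeatability)."""
    out = []
    for subj, sub in table.groupby("subject"):
        wide = sub.sort_values("session")[roi_columns].to_numpy().T  # (rois, sessions)
        out.append(icc(wide, mode="per_subject_across_rois", unit=str(subj)))
    return out


@dataclass
class BlandAltmanResult:
    means: np.ndarray
    differences: np.ndarray
    bias: float
    lower_limit: float
    upper_limit: float


def bland_altman(s1: np.ndarray, s2: np.ndarray) -> BlandAltmanResult:
    """Agreement of paired sessions; differences are s2 - s1."""
    a = np.asarray(s1, dtype=np.float64)
    b = np.asarray(s2, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need two paired 1D arrays of equal length >= 2")
    d = b - a
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(
        means=(a + b) / 2.0,
        differences=d,
        bias=bias,
        lower_limit=bias - 1.96 * sd,
        upper_limit=bias + 1.96 * sd,
    )


def fraction_above(icc_values, cutoff: float = 0.8) -> float:
    """Proportion of defined ICC values >= cutoff (inclusive)."""
    vals = np.asarray([v for v in icc_values if np.isfinite(v)], dtype=np.float64)
    if vals.size == 0:
        raise ValueError("no defined ICC values after filtering")
    return float((vals >= cutoff).mean())
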