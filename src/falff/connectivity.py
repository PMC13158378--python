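"""Seed-based functional connectivity and the per-ROI mixed-effects model.

The seed series is the mean denoised signal over the seed cluster (the
largest suprathreshold fALFF cluster upstream). Voxelwise Pearson
correlations with the seed are Fisher z-transformed (atanh, with |r|
clamped just below 1), smoothed with a 6-mm FWHM mask-aware Gaussian
kernel, and averaged within each target ROI. Per ROI, connectivity is
modeled as

    fc ~ 1 + group + sex + mFD + session + (1 | subject)

fitted by REML, with Benjamini-Yekutieli FDR across ROIs on the group
effect. Positive group beta means the second group has higher
connectivity. Session enters as a categorical effect (session 1
reference); reference levels for group and sex are the first group and
male. Wald p-values use a residual-df t approximation
(df = nobs - n_fixed - 1).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests

from .io import AmplitudeMap, BoldRun, LabelAtlas

logger = logging.getLogger(__name__)

_R_CLAMP = 1.0 - 1e-7
FIXED_EFFECTS = ("group", "sex", "mfd", "session")


def extract_seed_series(run: BoldRun, seed: np.ndarray) -> np.ndarray:
    """Mean series over the (nonempty, in-mask) seed voxels."""
    seed = np.asarray(seed, dtype=bool) & run.brain_mask
    if not seed.any():
        raise ValueError("seed mask is empty within the brain mask")
    return run.data[seed].mean(axis=0)


def seed_correlation_map(run: BoldRun, seed_series: np.ndarray) -> AmplitudeMap:
    """Voxelwise Fisher z of the Pearson correlation with the seed series.

    |r| >= 1 - 1e-7 is clamped before atanh (a warning is logged).
    """
    s = np.asarray(seed_series, dtype=np.float64)
    sd = s - s.mean()
    s_norm = np.sqrt(sd @ sd)
    if s_norm == 0:
        raise ValueError("constant seed series; correlation undefined")
    series = run.data[run.brain_mask]
    yd = series - series.mean(axis=-1, keepdims=True)
    y_norm = np.sqrt((yd ** 2).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (yd @ sd) / np.where(y_norm > 0, y_norm * s_norm, 1.0)
    r = np.where(y_norm > 0, r, 0.0)
    n_clamped = int((np.abs(r) >= _R_CLAMP).sum())
    if n_clamped:
        logger.warning("clamped %d voxel correlations at |r| = %g", n_clamped, _R_CLAMP)
    z = np.arctanh(np.clip(r, -_R_CLAMP, _R_CLAMP))
    out = np.full(run.spatial_shape, np.nan)
    out[run.brain_mask] = z
    return AmplitudeMap(out, metric="fc_z", affine=run.affine)


def smooth_map(
    values: np.ndarray,
    fwhm_mm: float = 6.0,
    voxel_size_mm: float | tuple[float, float, float] = 2.0,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Mask-aware Gaussian smoothing (sigma = FWHM / (2 sqrt(2 ln 2))).

    Each in-mask voxel's value is spread with a kernel normalized over the
    in-mask kernel mass reachable from it, so the in-mask sum (hence mean)
    is conserved exactly. fwhm 0 is the identity.
    """
    if fwhm_mm < 0:
        raise ValueError("FWHM must be >= 0")
    vals = np.asarray(values, dtype=np.float64)
    if fwhm_mm == 0:
        return vals.copy()
    vox = np.broadcast_to(np.asarray(voxel_size_mm, dtype=float), (3,))
    sigma_vox = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / vox
    m = np.ones(vals.shape) if mask is None else np.asarray(mask, dtype=np.float64)
    reach = ndimage.gaussian_filter(m, sigma_vox, mode="constant")
    with np.errstate(invalid="ignore", divide="ignore"):
        src = np.where(m > 0, np.nan_to_num(vals) * m / np.maximum(reach, 1e-12), 0.0)
    sm = ndimage.gaussian_filter(src, sigma_vox, mode="constant")
    out = np.where(m > 0, sm, np.nan)
    return out


def roi_fc(
    zmap: AmplitudeMap,
    atlas: LabelAtlas,
    exclude_labels: tuple[int, ...] = (),
) -> dict[int, float]:
    """Mean Fisher z per target ROI; the seed's own ROI is excluded."""
    if atlas.labels.shape != zmap.values.shape:
        raise ValueError("atlas not aligned to z map")
    out: dict[int, float] = {}
    for lab in atlas.roi_labels:
        if lab in exclude_labels:
            continue
        vals = zmap.values[atlas.labels == lab]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            logger.warning("target ROI %d empty; fc missing", lab)
            out[lab] = float("nan")
        else:
            out[lab] = float(vals.mean())
    return out


@dataclass
class MixedModelFit:
    """Fixed-effect estimates of the per-ROI connectivity model."""

    roi: int
    beta: dict[str, float]
    se: dict[str, float]
    tvalue: dict[str, float]
    pvalue: dict[str, float]
    random_intercept_var: float
    residual_var: float
    fallback_ols: bool = False


def _design_frame(table: pd.DataFrame) -> pd.DataFrame:
    df = table.copy()
    df["group_c"] = (df["group"].astype(str) != sorted(df["group"].astype(str).unique())[0]).astype(float)
    df["sex_c"] = (df["sex"].astype(str) == "F").astype(float)
    sessions = sorted(df["session"].unique())
    df["session_c"] = (df["session"] != sessions[0]).astype(float)
    return df


def fit_fc_mixed_model(table: pd.DataFrame, roi: int) -> MixedModelFit:
    """Random-intercept mixed model of FC for one ROI, fitted by REML.

    ``table`` has columns fc, group, sex, mfd, session, subject (rows =
    subject x session for this ROI). On a singular fit the model falls
    back to OLS and the result is flagged.
    """
    sub = table[table["roi"] == roi] if "roi" in table.columns else table
    if sub["subject"].nunique() < 10:
        raise ValueError("need at least 10 subjects for the mixed model")
    df = _design_frame(sub)
    exog = df[["group_c", "sex_c", "mfd", "session_c"]].to_numpy()
    exog = np.column_stack([np.ones(len(df)), exog])
    names = ["intercept", "group", "sex", "mfd", "session"]
    endog = df["fc"].to_numpy(dtype=np.float64)
    groups = df["subject"].to_numpy()
    n_fixed = exog.shape[1]
    resid_df = len(df) - n_fixed - 1
    fallback = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = MixedLM(endog, exog, groups=groups)
            fit = model.fit(reml=True)
        if not np.all(np.isfinite(fit.bse_fe)):
            raise np.linalg.LinAlgError("non-finite fixed-effect SEs")
        beta = dict(zip(names, fit.fe_params))
        se = dict(zip(names, fit.bse_fe))
        re_var = float(fit.cov_re.iloc[0, 0]) if hasattr(fit.cov_re, "iloc") else float(fit.cov_re[0, 0])
        resid_var = float(fit.scale)
    except (np.linalg.LinAlgError, ValueError) as err:
        logger.warning("singular mixed fit for ROI %s (%s); falling back to OLS", roi, err)
        fallback = True
        coef, *_ = np.linalg.lstsq(exog, endog, rcond=None)
        resid = endog - exog @ coef
        sigma2 = resid @ resid / (len(df) - n_fixed)
        cov = sigma2 * np.linalg.inv(exog.T @ exog)
        beta = dict(zip(names, coef))
        se = dict(zip(names, np.sqrt(np.diag(cov))))
        re_var = 0.0
        resid_var = float(sigma2)
    tval = {k: beta[k] / se[k] if se[k] > 0 else float("nan") for k in names}
    pval = {
        k: float(np.clip(2.0 * stats.t.sf(abs(tval[k]), resid_df), np.finfo(float).tiny, 1.0))
        for k in names
    }
    return MixedModelFit(
        roi=roi, beta=beta, se=se, tvalue=tval, pvalue=pval,
        random_intercept_var=re_var, residual_var=resid_var, fallback_ols=fallback,
    )


def fdr_adjust(pvalues, method: str = "by") -> np.ndarray:
    """Step-up FDR-adjusted p-values (BH or BY)."""
    p = np.asarray(list(pvalues), dtype=np.float64)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    key = {"bh": "fdr_bh", "by": "fdr_by"}.get(method.lower())
    if key is None:
        raise ValueError(f"unknown FDR method {method!r}; use 'bh' or 'by'")
    _, adjusted, *_ = multipletests(p, alpha=0.05, method=key)
    return adjusted


def report_significant_rois(
    fits: list[MixedModelFit],
    q: float = 0.001,
    method: str = "by",
) -> pd.DataFrame:
    """Per-ROI fixed-effect report filtered on the adjusted group p-value.

    Mirrors a per-effect table (beta, SE, T, p, p-FDR), sorted by the
    adjusted group p ascending; FDR is applied across ROIs to the group
    effect's p-values.
    """
    group_p = [f.pvalue["group"] for f in fits]
    adjusted = fdr_adjust(group_p, method=method)
    rows = []
    for fit, p_adj in zip(fits, adjusted):
        if p_adj < q:
            for eff in FIXED_EFFECTS:
                rows.append({
                    "roi": fit.roi,
                    "effect": eff,
                    "beta": fit.beta[eff],
                    "se": fit.se[eff],
                    "t": fit.tvalue[eff],
                    "p": fit.pvalue[eff],
                    "p_fdr": p_adj if eff == "group" else float("nan"),
                    "group_p_fdr": p_adj,
                })
    report = pd.DataFrame(
        rows, columns=["roi", "effect", "beta", "se", "t", "p", "p_fdr", "group_p_fdr"],
    )
    if len(report):
        report = report.sort_values(
            ["group_p_fdr", "roi"], kind="stable"
        ).drop(columns=["group_p_fdr"]).reset_index(drop=True)
    else:
        report = report.drop(columns=["group_p_fdr"])
    return report
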