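"""Confound regression and the ALFF / fALFF / tSNR / gBOLD-beta maps.

Amplitude metrics are defined on the RMS scale (square root of mean band
power): for a demeaned series x with DFT X,

    ALFF  = sqrt( sum over band bins of w_k |X_k|^2 / n^2 )
    fALFF = sqrt( band power sum / total positive-frequency power sum )

with w_k = 2 for interior positive bins and 1 for the Nyquist bin, so the
band power sum equals the time-domain mean square of the ideally
band-filtered signal (Parseval). The DC bin is excluded from both sums.
Band edges are inclusive (low <= f <= high). A ``power_scale="power"``
switch returns mean power instead of its square root; the whole-brain
normalization makes group contrasts insensitive to this monotone choice,
but the scale is fixed and recorded on the map.

Confound regression projects out a principal-component basis of the
candidate nuisance columns (6 motion parameters + CSF + WM mean series)
plus an intercept; no polynomial detrending is performed (detrending
biases amplitude metrics), and the voxel mean is re-added so tSNR remains
defined on denoised data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import AmplitudeMap, BoldRun
from .motion import motion_params

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BandSpec:
    """A frequency band in Hz; defaults to the 0.008-0.1 Hz low band."""

    low: float = 0.008
    high: float = 0.1

    def validate(self, tr: float) -> None:
        nyquist = 1.0 / (2.0 * tr)
        if not (0 < self.low < self.high <= nyquist + 1e-12):
            raise ValueError(
                f"invalid band [{self.low}, {self.high}] Hz for TR {tr} s "
                f"(Nyquist {nyquist:.4g} Hz)"
            )


@dataclass
class ConfoundMatrix:
    """Orthogonal principal-component confound regressors (mean-centered)."""

    components: np.ndarray  # (n_frames, n_components)
    explained_variance: np.ndarray

    @property
    def n_components(self) -> int:
        return self.components.shape[1]


def build_confound_matrix(
    motion,
    csf: np.ndarray,
    wm: np.ndarray,
    n_components: int = 6,
) -> ConfoundMatrix:
    """PCA of the centered, variance-scaled candidate nuisance columns.

    Candidates are the 6 motion parameters plus the CSF and WM mean
    series (8 columns). If the candidate rank is below ``n_components``,
    the rank is kept and a warning logged.
    """
    cols = [motion_params(motion)] if motion is not None else []
    for s in (csf, wm):
        if s is not None:
            cols.append(np.asarray(s, dtype=np.float64).reshape(-1, 1))
    if not cols:
        return ConfoundMatrix(components=np.empty((0, 0)), explained_variance=np.empty(0))
    x = np.hstack(cols)
    n = x.shape[0]
    if any(c.shape[0] != n for c in cols):
        raise ValueError("confound candidate columns have unequal lengths")
    x = x - x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    keep = sd > 0
    x = x[:, keep] / sd[keep]
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    tol = s.max(initial=0.0) * max(x.shape) * np.finfo(float).eps
    rank = int((s > tol).sum())
    k = min(n_components, rank)
    if k < n_components:
        logger.warning("confound rank %d below requested %d components", rank, n_components)
    scores = u[:, :k] * s[:k]
    var = s[:k] ** 2 / (n - 1)
    return ConfoundMatrix(components=scores, explained_variance=var)


def regress_confounds(run: BoldRun, confounds: ConfoundMatrix) -> BoldRun:
    """OLS residual per voxel after projecting out confounds + intercept.

    The voxel temporal mean is re-added to the residual. With zero
    components this is the identity transform.
    """
    if confounds.n_components == 0:
        return BoldRun(run.data.copy(), run.tr, run.affine, run.brain_mask)
    c = confounds.components
    if c.shape[0] != run.n_frames:
        raise ValueError(
            f"confound rows {c.shape[0]} != run frames {run.n_frames}"
        )
    x = np.column_stack([np.ones(c.shape[0]), c])
    shape = run.data.shape
    y = run.data.reshape(-1, shape[3]).T  # (t, voxels)
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    resid += y.mean(axis=0, keepdims=True)
    return BoldRun(resid.T.reshape(shape), run.tr, run.affine, run.brain_mask)


def _spectral_weights(n: int) -> np.ndarray:
    """Parseval weights for rfft bins: DC 0, interior 2, Nyquist (even n) 1."""
    n_bins = n // 2 + 1
    w = np.full(n_bins, 2.0)
    w[0] = 0.0
    if n % 2 == 0:
        w[-1] = 1.0
    return w


def band_power(series_2d: np.ndarray, tr: float, band: BandSpec | None):
    """Band and total mean-square power per series (rows = series).

    Returns (band_power, total_power) where total is over all positive
    frequencies and band over bins with band.low <= f <= band.high
    (or the full positive spectrum when band is None).
    """
    x = np.asarray(series_2d, dtype=np.float64)
    n = x.shape[-1]
    xd = x - x.mean(axis=-1, keepdims=True)
    spec = np.fft.rfft(xd, axis=-1)
    power = (spec.real ** 2 + spec.imag ** 2) * _spectral_weights(n) / n ** 2
    freqs = np.fft.rfftfreq(n, tr)
    total = power.sum(axis=-1)
    if band is None:
        return total, total
    in_band = (freqs >= band.low - 1e-12) & (freqs <= band.high + 1e-12)
    if not in_band.any():
        raise ValueError(
            f"band [{band.low}, {band.high}] Hz contains 0 of {len(freqs)} "
            f"frequency bins at n={n}, TR={tr}"
        )
    return power[..., in_band].sum(axis=-1), total


def _masked_series(run: BoldRun) -> tuple[np.ndarray, np.ndarray]:
    mask = run.brain_mask
    return run.data[mask], mask


def alff_map(run: BoldRun, band: BandSpec = BandSpec(), power_scale: str = "amplitude") -> AmplitudeMap:
    """Voxelwise ALFF: RMS amplitude within the low-frequency band."""
    band.validate(run.tr)
    series, mask = _masked_series(run)
    p_band, _ = band_power(series, run.tr, band)
    vals = np.sqrt(p_band) if power_scale == "amplitude" else p_band
    out = np.full(run.spatial_shape, np.nan)
    out[mask] = vals
    return AmplitudeMap(out, metric="ALFF", affine=run.affine)


def falff_map(run: BoldRun, band: BandSpec = BandSpec(), power_scale: str = "amplitude") -> AmplitudeMap:
    """Voxelwise fALFF: band amplitude as a fraction of full-spectrum amplitude.

    Bounded in [0, 1] before normalization; zero-variance voxels map to 0.
    """
    band.validate(run.tr)
    series, mask = _masked_series(run)
    p_band, p_total = band_power(series, run.tr, band)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(p_total > 0, p_band / np.maximum(p_total, 1e-300), 0.0)
    ratio = np.clip(ratio, 0.0, 1.0)
    vals = np.sqrt(ratio) if power_scale == "amplitude" else ratio
    out = np.full(run.spatial_shape, np.nan)
    out[mask] = vals
    return AmplitudeMap(out, metric="fALFF", affine=run.affine)


def tsnr_map(run: BoldRun) -> AmplitudeMap:
    """Temporal mean / temporal SD (ddof=1); zero variance -> +inf sentinel."""
    series, mask = _masked_series(run)
    mean = series.mean(axis=-1)
    sd = series.std(axis=-1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        tsnr = np.where(sd > 0, mean / np.where(sd > 0, sd, 1.0), np.inf)
    out = np.full(run.spatial_shape, np.nan)
    out[mask] = tsnr
    return AmplitudeMap(out, metric="tSNR", affine=run.affine)


def normalize_map(amap: AmplitudeMap, global_mask: np.ndarray) -> AmplitudeMap:
    """Divide by the mean over finite in-mask voxels; post-mean is 1."""
    mask = np.asarray(global_mask, dtype=bool)
    vals = amap.values[mask]
    finite = np.isfinite(vals)
    if not finite.any():
        raise ValueError("no finite in-mask voxels to normalize over")
    mean = vals[finite].mean()
    if mean <= 0:
        raise ValueError(f"nonpositive in-mask mean {mean}; cannot normalize")
    return AmplitudeMap(
        amap.values / mean,
        metric=amap.metric,
        normalized=True,
        source=amap.source,
        affine=amap.affine,
    )


def global_series(run: BoldRun) -> np.ndarray:
    """gBOLD: the mean series over the brain mask."""
    return run.data[run.brain_mask].mean(axis=0)


def gbold_beta_map(run: BoldRun, region_mask: np.ndarray | None = None) -> AmplitudeMap:
    """Voxelwise OLS slope of the voxel series on the global BOLD series.

    Both series are demeaned; the map is restricted to ``region_mask``
    (default: whole brain mask).
    """
    g = global_series(run)
    gd = g - g.mean()
    denom = gd @ gd
    if denom <= 0:
        raise ValueError("constant global signal; gBOLD beta undefined")
    mask = run.brain_mask if region_mask is None else np.asarray(region_mask, dtype=bool)
    series = run.data[mask]
    yd = series - series.mean(axis=-1, keepdims=True)
    beta = yd @ gd / denom
    out = np.full(run.spatial_shape, np.nan)
    out[mask] = beta
    return AmplitudeMap(out, metric="gbold_beta", affine=run.affine)
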