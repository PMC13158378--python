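"""Voxelwise two-group inference with permutation FWE control.

The group model at each voxel is an OLS fit

    value ~ intercept + group + covariates

with the t-statistic of the group coefficient as the test statistic
(a two-group t-test with covariate adjustment). Family-wise error is
controlled by the permutation of group labels with the maximum-statistic
method: the height threshold is the (1 - alpha) quantile of the max-|t|
permutation null over the mask. Suprathreshold voxels are grouped into
connected components (26-neighborhood by default, 6/18 available) and
components below the minimum extent are discarded.

Scalar covariates (e.g. mean FD) are shared across voxels; voxelwise
covariates (e.g. gBOLD beta, gray-matter probability maps) are sampled at
each voxel. Permutations require the scalar-covariate design (voxelwise
covariates would need per-voxel refits per permutation).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

logger = logging.getLogger(__name__)

_STRUCTURES = {6: 1, 18: 2, 26: 3}


@dataclass
class GroupDesign:
    """Per-subject maps, group labels and covariates for voxelwise tests.

    ``maps`` is (n_subjects, n_voxels) with voxels flattened over the
    analysis mask; ``mask`` is the 3D boolean mask used to unflatten
    statistic maps. Group is coded 0 (reference) / 1.
    """

    maps: np.ndarray
    group: np.ndarray
    mask: np.ndarray
    covariates: np.ndarray | None = None
    covariate_names: list[str] = field(default_factory=list)
    voxelwise_covariates: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=np.float64)
        self.group = np.asarray(self.group)
        n = self.maps.shape[0]
        if self.group.shape != (n,):
            raise ValueError("one group label per subject map required")
        if sorted(np.unique(self.group).tolist()) != [0, 1]:
            raise ValueError("group must contain exactly the labels 0 and 1")
        if min((self.group == 0).sum(), (self.group == 1).sum()) < 2:
            raise ValueError("need at least 2 subjects per group")
        if self.covariates is not None:
            self.covariates = np.atleast_2d(np.asarray(self.covariates, dtype=np.float64))
            if self.covariates.shape[0] != n:
                self.covariates = self.covariates.T
            if self.covariates.shape[0] != n:
                raise ValueError("covariate rows do not align with subjects")
            if not self.covariate_names:
                self.covariate_names = [f"cov{i}" for i in range(self.covariates.shape[1])]
        for name, vc in self.voxelwise_covariates.items():
            if np.asarray(vc).shape != self.maps.shape:
                raise ValueError(f"voxelwise covariate {name!r} shape mismatch")

    @property
    def n_subjects(self) -> int:
        return self.maps.shape[0]

    def unflatten(self, flat: np.ndarray) -> np.ndarray:
        out = np.full(self.mask.shape, np.nan)
        out[self.mask] = flat
        return out


@dataclass
class StatMap:
    """Voxelwise t-statistics with degrees of freedom and direction."""

    t: np.ndarray           # 3D, NaN outside mask
    df: int
    direction: str
    mask: np.ndarray


@dataclass
class ClusterSet:
    labels: np.ndarray      # 3D integer cluster labels (0 = none)
    sizes: list[int]
    peak_t: list[float]
    peak_coord: list[tuple[int, int, int]]

    @property
    def n_clusters(self) -> int:
        return len(self.sizes)

    def largest_mask(self) -> np.ndarray:
        if not self.sizes:
            raise ValueError("empty cluster set")
        idx = int(np.argmax(self.sizes)) + 1
        return self.labels == idx


def _check_rank(x: np.ndarray, names: list[str]) -> None:
    # residual-based detection: catches near-collinearity (e.g. a covariate
    # constant to machine precision) that matrix_rank's tolerance can miss
    collinear = []
    for j in range(x.shape[1]):
        others = np.delete(x, j, axis=1)
        resid = x[:, j] - others @ np.linalg.lstsq(others, x[:, j], rcond=None)[0]
        if np.linalg.norm(resid) < 1e-8 * max(np.linalg.norm(x[:, j]), 1.0):
            collinear.append(names[j])
    if collinear:
        raise ValueError(f"rank-deficient design; collinear columns: {collinear}")


class _GroupGLM:
    """Vectorized group-coefficient t-statistics with a shared design.

    Precomputes the covariate-dependent pieces so that recomputing t for
    a permuted group vector costs one (n x V) product.
    """

    def __init__(self, maps: np.ndarray, covariates: np.ndarray | None):
        self.y = maps
        self.n = maps.shape[0]
        self.covs = covariates
        self.fixed = [np.ones(self.n)]
        if covariates is not None:
            self.fixed.extend(covariates.T)
        self.fixed_xty = np.stack([c @ maps for c in self.fixed])  # (p_fixed, V)
        self.ssy = (maps ** 2).sum(axis=0)
        self.p = len(self.fixed) + 1
        self.df = self.n - self.p

    def t_for(self, group: np.ndarray) -> np.ndarray:
        g = group.astype(np.float64)
        cols = [self.fixed[0], g] + self.fixed[1:]
        x = np.column_stack(cols)
        xtx = x.T @ x
        h = np.linalg.inv(xtx)
        xty = np.vstack([self.fixed_xty[0], g @ self.y, self.fixed_xty[1:]])
        beta = h @ xty
        ss_res = self.ssy - np.einsum("pv,pv->v", beta, xty)
        ss_res = np.maximum(ss_res, 0.0)
        sigma2 = ss_res / self.df
        with np.errstate(invalid="ignore", divide="ignore"):
            t = beta[1] / np.sqrt(np.maximum(sigma2 * h[1, 1], 1e-300))
        return t


def _voxelwise_glm_t(design: GroupDesign) -> tuple[np.ndarray, int]:
    """Per-voxel designs (voxelwise covariates present): batched OLS."""
    n, v = design.maps.shape
    p_scalar = 2 + (0 if design.covariates is None else design.covariates.shape[1])
    p = p_scalar + len(design.voxelwise_covariates)
    x = np.empty((v, n, p))
    x[:, :, 0] = 1.0
    x[:, :, 1] = design.group.astype(float)
    col = 2
    if design.covariates is not None:
        for j in range(design.covariates.shape[1]):
            x[:, :, col] = design.covariates[:, j]
            col += 1
    for vc in design.voxelwise_covariates.values():
        x[:, :, col] = np.asarray(vc, dtype=np.float64).T
        col += 1
    xtx = np.einsum("vnp,vnq->vpq", x, x)
    xty = np.einsum("vnp,vn->vp", x, design.maps.T)
    beta = np.linalg.solve(xtx, xty[..., None])[..., 0]
    resid = design.maps.T - np.einsum("vnp,vp->vn", x, beta)
    df = n - p
    sigma2 = (resid ** 2).sum(axis=1) / df
    h11 = np.linalg.inv(xtx)[:, 1, 1]
    with np.errstate(invalid="ignore", divide="ignore"):
        t = beta[:, 1] / np.sqrt(np.maximum(sigma2 * h11, 1e-300))
    return t, df


def voxelwise_group_ttest(design: GroupDesign, direction: str = "group2>group1") -> StatMap:
    """Voxelwise covariate-adjusted two-group t-test.

    ``direction`` orients the sign: "group2>group1" keeps the group-1
    (coded) coefficient's sign, "group1>group2" negates it, "two-sided"
    keeps the raw signed statistic.
    """
    names = ["intercept", "group"] + design.covariate_names + list(design.voxelwise_covariates)
    x_scalar = np.column_stack(
        [np.ones(design.n_subjects), design.group.astype(float)]
        + ([] if design.covariates is None else [design.covariates])
    )
    _check_rank(x_scalar, ["intercept", "group"] + design.covariate_names)
    if design.voxelwise_covariates:
        t, df = _voxelwise_glm_t(design)
    else:
        glm = _GroupGLM(design.maps, design.covariates)
        t, df = glm.t_for(design.group), glm.df
    if direction == "group1>group2":
        t = -t
    elif direction not in ("group2>group1", "two-sided"):
        raise ValueError(f"unknown direction {direction!r}")
    return StatMap(t=design.unflatten(t), df=df, direction=direction, mask=design.mask)


def fwe_threshold(
    design: GroupDesign,
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[float, np.ndarray]:
    """Permutation max-|t| height threshold controlling FWE at ``alpha``.

    Returns (threshold, null max-|t| distribution). If fewer than
    ``n_perm`` distinct group relabelings exist, all are enumerated.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if design.voxelwise_covariates:
        raise ValueError("permutation FWE requires a scalar-covariate design")
    glm = _GroupGLM(design.maps, design.covariates)
    n = design.n_subjects
    n1 = int(design.group.sum())
    total = math.comb(n, n1)
    rng = np.random.default_rng(seed)
    max_t = np.empty(min(n_perm, total))
    if total <= n_perm:
        logger.warning(
            "only %d distinct permutations available (< %d); enumerating exhaustively",
            total, n_perm,
        )
        for i, ones in enumerate(itertools.combinations(range(n), n1)):
            g = np.zeros(n)
            g[list(ones)] = 1.0
            max_t[i] = np.nanmax(np.abs(glm.t_for(g)))
    else:
        for i in range(n_perm):
            g = rng.permutation(design.group).astype(float)
            max_t[i] = np.nanmax(np.abs(glm.t_for(g)))
    threshold = float(np.quantile(max_t, 1.0 - alpha, method="higher"))
    return threshold, max_t


def extract_clusters(
    stat: StatMap,
    height: float,
    min_extent: int = 10,
    connectivity: int = 26,
) -> ClusterSet:
    """Connected suprathreshold components of at least ``min_extent`` voxels.

    Thresholding is one-sided on the (direction-oriented) t map:
    voxels with t > height.
    """
    if not np.isfinite(height):
        raise ValueError("height threshold must be finite")
    if connectivity not in _STRUCTURES:
        raise ValueError(f"connectivity must be one of {sorted(_STRUCTURES)}")
    supra = np.nan_to_num(stat.t, nan=-np.inf) > height
    structure = ndimage.generate_binary_structure(3, _STRUCTURES[connectivity])
    labeled, n_found = ndimage.label(supra, structure=structure)
    out = np.zeros_like(labeled)
    sizes, peaks, coords = [], [], []
    next_label = 0
    for lab in range(1, n_found + 1):
        comp = labeled == lab
        size = int(comp.sum())
        if size < min_extent:
            continue
        next_label += 1
        out[comp] = next_label
        tvals = np.where(comp, stat.t, -np.inf)
        peak = np.unravel_index(np.nanargmax(np.nan_to_num(tvals, nan=-np.inf)), tvals.shape)
        sizes.append(size)
        peaks.append(float(stat.t[peak]))
        coords.append(tuple(int(c) for c in peak))
    return ClusterSet(labels=out, sizes=sizes, peak_t=peaks, peak_coord=coords)


def cohens_d_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> float:
    """Standardized mean difference with the pooled SD."""
    if sd1 <= 0 or sd2 <= 0 or n1 < 2 or n2 < 2:
        raise ValueError("need positive SDs and n >= 2 per group")
    pooled = math.sqrt(((n1 - 1) * sd1 ** 2 + (n2 - 1) * sd2 ** 2) / (n1 + n2 - 2))
    return (mean1 - mean2) / pooled


def summary_ci(mean: float, sd: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Normal-quantile confidence interval mean +/- z * sd / sqrt(n)."""
    if n < 2 or sd < 0:
        raise ValueError("need n >= 2 and sd >= 0")
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * sd / math.sqrt(n)
    return (mean - half, mean + half)


def binarize_map(stat: StatMap, p_uncorrected: float = 0.05) -> np.ndarray:
    """One-sided uncorrected threshold: voxels with p < p_uncorrected."""
    t_crit = stats.t.ppf(1.0 - p_uncorrected, stat.df)
    return np.nan_to_num(stat.t, nan=-np.inf) > t_crit


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|a&b| / (|a|+|b|); 0 (with warning) if both empty."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    total = int(a.sum()) + int(b.sum())
    if total == 0:
        logger.warning("both masks empty; dice defined as 0")
        return 0.0
    return 2.0 * int((a & b).sum()) / total


def _two_sample_t_power(n: int, d: float, alpha: float, tails: int) -> float:
    df = 2 * n - 2
    ncp = d * math.sqrt(n / 2.0)
    t_crit = stats.t.ppf(1.0 - alpha / tails, df)
    power = stats.nct.sf(t_crit, df, ncp)
    if tails == 2:
        power += stats.nct.cdf(-t_crit, df, ncp)
    return float(power)


def required_sample_size(
    d: float, power: float = 0.8, alpha: float = 0.05, tails: int = 2
) -> int:
    """Smallest per-group n whose exact two-sample t-test power >= target.

    Starts from the normal approximation 2 (z_{1-alpha/tails} + z_power)^2
    / d^2 and refines by exact noncentral-t search.
    """
    if d <= 0 or not 0 < power < 1:
        raise ValueError("need d > 0 and 0 < power < 1")
    z_a = stats.norm.ppf(1.0 - alpha / tails)
    z_b = stats.norm.ppf(power)
    n = max(2, math.ceil(2.0 * (z_a + z_b) ** 2 / d ** 2) - 5)
    while _two_sample_t_power(n, d, alpha, tails) < power:
        n += 1
    while n > 2 and _two_sample_t_power(n - 1, d, alpha, tails) >= power:
        n -= 1
    return n
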