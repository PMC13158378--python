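"""Calibration and recovery experiments on synthetic data.

These experiments quantify, under known ground truth, the operating
characteristics the pipeline relies on: family-wise error control of the
permutation threshold under the null, recovery of a planted band-amplitude
effect as a surviving cluster, and recovery of a planted group effect by
the per-ROI mixed model under FDR control. They are used by the test
suite and by the reproduction script; all randomness is seed-driven.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .connectivity import fdr_adjust, fit_fc_mixed_model
from .inference import (
    GroupDesign,
    dice,
    extract_clusters,
    fwe_threshold,
    voxelwise_group_ttest,
)
from .repeatability import icc
from .spectral import (
    build_confound_matrix,
    falff_map,
    normalize_map,
    regress_confounds,
)
from .synthetic import CohortSpec, generate_cohort


def _ellipsoid_mask(shape):
    from .synthetic import _ellipsoid_mask as impl

    return impl(shape)


def fwe_null_calibration(
    n_cohorts: int = 200,
    n_per_group: int = 10,
    grid_shape=(16, 16, 16),
    n_perm: int = 500,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Family-wise false-positive rate of the max-|t| permutation threshold.

    Each replicate is a null cohort of exchangeable subject amplitude maps
    (iid Gaussian over an ellipsoidal brain mask, no group effect); a
    replicate counts as a family-wise false positive if any voxel of its
    observed |t| map exceeds the permutation threshold.
    """
    mask = _ellipsoid_mask(grid_shape)
    n_vox = int(mask.sum())
    rng = np.random.default_rng(np.random.SeedSequence([seed, 50]))
    group = np.repeat([0, 1], n_per_group)
    false_positives = 0
    for i in range(n_cohorts):
        maps = rng.standard_normal((2 * n_per_group, n_vox))
        design = GroupDesign(maps=maps, group=group, mask=mask)
        stat = voxelwise_group_ttest(design, "two-sided")
        threshold, _ = fwe_threshold(
            design, alpha, n_perm, seed=np.random.SeedSequence([seed, 51, i])
        )
        if np.nanmax(np.abs(stat.t[mask])) > threshold:
            false_positives += 1
    return {
        "rate": false_positives / n_cohorts,
        "n_false_positives": false_positives,
        "n_cohorts": n_cohorts,
    }


def cohort_falff_design(spec: CohortSpec, n_components: int = 6):
    """Generate a cohort and assemble its session-averaged fALFF GroupDesign.

    Returns (design, dataset) where maps are whole-brain-normalized fALFF
    averaged over the two sessions per subject.
    """
    dataset, _truth = generate_cohort(spec)
    mask = dataset.brain_mask
    per_subject: dict[str, list[np.ndarray]] = {}
    groups: dict[str, int] = {}
    for rec, run, conf, trace in dataset.iter_runs():
        cm = build_confound_matrix(
            trace, conf["csf"].to_numpy(), conf["wm"].to_numpy(), n_components
        )
        denoised = regress_confounds(run, cm)
        fa = normalize_map(falff_map(denoised), mask)
        per_subject.setdefault(rec.subject, []).append(fa.values[mask])
        groups[rec.subject] = rec.group
    subjects = sorted(per_subject)
    design = GroupDesign(
        maps=np.stack([np.mean(per_subject[s], axis=0) for s in subjects]),
        group=np.array([groups[s] for s in subjects]),
        mask=mask,
    )
    return design, dataset


def amplitude_recovery(
    n_seeds: int = 20,
    n_per_group: int = 20,
    effect_band_amp: float = 1.2,
    grid_shape=(16, 16, 16),
    n_frames: int = 480,
    n_perm: int = 500,
    alpha: float = 0.05,
    min_extent: int = 10,
    min_dice: float = 0.3,
    seed: int = 0,
) -> dict:
    """Recovery of a planted band-amplitude increase as a surviving cluster.

    Couplings are group-equal so the only planted group difference is the
    amplitude effect in the seed ROI. A replicate is a hit if the largest
    surviving fALFF cluster overlaps the true ROI with dice > ``min_dice``.
    """
    hits, dices = 0, []
    for i in range(n_seeds):
        spec = CohortSpec(
            n_per_group=n_per_group,
            n_frames=n_frames,
            grid_shape=grid_shape,
            atlas_rois=6,
            effect_band_amp=effect_band_amp,
            fc_coupling_by_group=(0.3, 0.3),
            rng_seed=int(np.random.SeedSequence([seed, 60, i]).generate_state(1)[0] % 2**31),
        )
        design, dataset = cohort_falff_design(spec)
        stat = voxelwise_group_ttest(design, "group2>group1")
        threshold, _ = fwe_threshold(
            design, alpha, n_perm, seed=np.random.SeedSequence([seed, 61, i])
        )
        clusters = extract_clusters(stat, threshold, min_extent)
        true_roi = dataset.atlas.roi_mask(spec.seed_roi_id)
        d = dice(clusters.largest_mask(), true_roi) if clusters.n_clusters else 0.0
        dices.append(d)
        hits += d > min_dice
    return {
        "hit_rate": hits / n_seeds,
        "mean_dice": float(np.mean(dices)),
        "n_seeds": n_seeds,
    }


def simulate_fc_table(
    rng: np.random.Generator,
    n_per_group: int = 30,
    n_rois: int = 8,
    planted_roi: int = 1,
    effect: float = 0.4,
    subject_sd: float = 0.2,
    resid_sd: float = 0.1,
) -> pd.DataFrame:
    """Two-session FC tables with a group effect planted in one ROI."""
    rows = []
    for g in (0, 1):
        for i in range(n_per_group):
            subj = f"sub-{g}{i:02d}"
            u = rng.normal(0, subject_sd, size=n_rois)
            sex = "F" if i % 2 == 0 else "M"
            mfd = rng.uniform(0.05, 0.15)
            for ses in (1, 2):
                for roi in range(1, n_rois + 1):
                    fc = u[roi - 1] + rng.normal(0, resid_sd)
                    if g == 1 and roi == planted_roi:
                        fc += effect
                    rows.append({
                        "subject": subj, "group": f"group{g + 1}", "sex": sex,
                        "mfd": mfd, "session": ses, "roi": roi, "fc": fc,
                    })
    return pd.DataFrame(rows)


def mixed_model_recovery(
    n_seeds: int = 100,
    n_per_group: int = 30,
    n_rois: int = 8,
    effect: float = 0.4,
    subject_sd: float = 0.2,
    resid_sd: float = 0.1,
    beta_tolerance: float = 0.1,
    q: float = 0.001,
    seed: int = 0,
) -> dict:
    """Recovery of a planted FC group effect by the mixed model + BY FDR.

    A replicate succeeds if the planted ROI's group beta is within
    ``beta_tolerance`` of the truth and its BY-adjusted p is below ``q``.
    """
    successes, betas = 0, []
    for i in range(n_seeds):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 70, i]))
        table = simulate_fc_table(
            rng, n_per_group=n_per_group, n_rois=n_rois, planted_roi=1,
            effect=effect, subject_sd=subject_sd, resid_sd=resid_sd,
        )
        fits = [fit_fc_mixed_model(table, roi=r) for r in range(1, n_rois + 1)]
        adjusted = fdr_adjust([f.pvalue["group"] for f in fits], method="by")
        beta = fits[0].beta["group"]
        betas.append(beta)
        if abs(beta - effect) <= beta_tolerance and adjusted[0] < q:
            successes += 1
    return {
        "success_rate": successes / n_seeds,
        "mean_beta": float(np.mean(betas)),
        "n_seeds": n_seeds,
    }


def repeatability_demo(spec: CohortSpec | None = None, seed: int = 0) -> dict:
    """Per-ROI fALFF ICC on a default cohort (high subject heterogeneity)."""
    if spec is None:
        spec = CohortSpec(n_per_group=10, n_frames=320, grid_shape=(12, 12, 12),
                          atlas_rois=5, subject_amp_sd=0.2, rng_seed=seed)
    else:
        spec = dataclasses.replace(spec, rng_seed=seed)
    dataset, _ = generate_cohort(spec)
    mask = dataset.brain_mask
    rows = []
    for rec, run, conf, trace in dataset.iter_runs():
        cm = build_confound_matrix(trace, conf["csf"].to_numpy(), conf["wm"].to_numpy(), 6)
        fa = normalize_map(falff_map(regress_confounds(run, cm)), mask)
        row = {"subject": rec.subject, "session": rec.session + 1}
        for lab in dataset.atlas.roi_labels:
            row[f"roi{lab:02d}"] = float(np.nanmean(fa.values[dataset.atlas.labels == lab]))
        rows.append(row)
    table = pd.DataFrame(rows)
    iccs = []
    for lab in dataset.atlas.roi_labels:
        wide = table.pivot(index="subject", columns="session", values=f"roi{lab:02d}")
        iccs.append(icc(wide.to_numpy()).icc)
    return {"median_icc": float(np.median(iccs)), "n_rois": len(iccs)}
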