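"""End-to-end orchestration: simulate -> QC -> metrics -> repeatability ->
group inference -> seed connectivity -> mixed model, with a manifest.

Stages run in a fixed order and each writes its reports under the output
directory. Subjects excluded by motion QC (outlier fraction above the
threshold in any session) are absent from every downstream table. The
single pipeline seed is expanded per stage with
``numpy.random.SeedSequence([seed, stage_index])`` so stages are
individually reproducible.

Group-model covariates are the subject's mean FD and mean gBOLD coupling
(both scalar; the permutation scheme exchanges group labels against a
shared covariate design). The group maps under test are the two sessions'
normalized metric maps averaged per subject.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .connectivity import (
    extract_seed_series,
    fdr_adjust,
    fit_fc_mixed_model,
    report_significant_rois,
    roi_fc,
    seed_correlation_map,
    smooth_map,
)
from .inference import (
    GroupDesign,
    binarize_map,
    dice,
    extract_clusters,
    fwe_threshold,
    voxelwise_group_ttest,
)
from .io import AmplitudeMap, save_map, write_tsv
from .motion import qc_run
from .repeatability import bland_altman, icc_per_roi, icc_per_subject
from .spectral import (
    BandSpec,
    alff_map,
    build_confound_matrix,
    falff_map,
    gbold_beta_map,
    global_series,
    normalize_map,
    regress_confounds,
    tsnr_map,
)
from .synthetic import CohortSpec, generate_cohort

logger = logging.getLogger(__name__)

STAGES = ("simulate", "qc", "metrics", "repeatability", "group", "connectivity")


@dataclass
class PipelineConfig:
    """All pipeline thresholds and switches; serialized with every run."""

    cohort: CohortSpec = field(default_factory=CohortSpec)
    out_root: str = "falff_out"
    band_low: float = 0.008
    band_high: float = 0.1
    fd_thresh_mm: float = 0.5
    gs_z_thresh: float = 3.0
    exclusion_fraction: float = 0.10
    n_confound_components: int = 6
    normalize: bool = True
    alpha: float = 0.05
    n_perm: int = 500
    min_extent: int = 10
    connectivity: int = 26
    fwhm_mm: float = 6.0
    fdr_q: float = 0.001
    fdr_method: str = "by"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.band_low < self.band_high:
            raise ValueError("need 0 < band_low < band_high")
        if not 0 < self.alpha < 1 or not 0 < self.fdr_q <= 1:
            raise ValueError("alpha and fdr_q must lie in (0, 1)")
        if self.fd_thresh_mm <= 0 or not 0 <= self.exclusion_fraction <= 1:
            raise ValueError("invalid QC thresholds")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")

    @property
    def band(self) -> BandSpec:
        return BandSpec(self.band_low, self.band_high)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        cohort = d.pop("cohort", None)
        cfg = cls(**d)
        if cohort is not None:
            for key in ("tr_by_group", "grid_shape", "effect_rois", "fc_target_rois",
                        "fc_coupling_by_group"):
                if cohort.get(key) is not None:
                    cohort[key] = tuple(cohort[key])
            cfg.cohort = CohortSpec(**cohort)
        return cfg


@dataclass
class RunManifest:
    config: dict
    seed: int
    version: str
    stages_run: list[str]
    output_hashes: dict[str, str]
    timestamp: float

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class PipelineError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


def run_pipeline(
    config: PipelineConfig,
    out_dir: str | Path | None = None,
    until: str = "connectivity",
) -> RunManifest:
    """Execute the pipeline through stage ``until`` and write reports."""
    if until not in STAGES:
        raise ValueError(f"unknown stage {until!r}; one of {STAGES}")
    last = STAGES.index(until)
    out = Path(out_dir if out_dir is not None else config.out_root)
    out.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []
    stages_run: list[str] = []
    t0 = time.time()

    spec = dataclasses.replace(config.cohort, rng_seed=config.rng_seed)
    band = config.band

    # --- simulate -----------------------------------------------------
    try:
        dataset, truth = generate_cohort(spec)
    except Exception as err:  # noqa: BLE001 - halt with stage context
        raise PipelineError("simulate", str(err)) from err
    stages_run.append("simulate")
    parts = dataset.participants()
    write_tsv(parts, out / "participants.tsv")
    truth.to_json(out / "ground_truth.json")
    config.to_yaml(out / "pipeline_config.yaml")
    outputs += [out / "participants.tsv", out / "ground_truth.json", out / "pipeline_config.yaml"]
    if last == 0:
        return _manifest(config, stages_run, outputs, out, t0)

    # --- qc -----------------------------------------------------------
    qc_rows, qc_by_run = [], {}
    for rec in dataset.records:
        try:
            run, _conf, trace, _spikes = dataset.realize(rec)
            gs = global_series(run)
            qc = qc_run(trace, gs, config.fd_thresh_mm, config.gs_z_thresh,
                        config.exclusion_fraction)
        except Exception as err:  # noqa: BLE001
            raise PipelineError("qc", f"{rec.subject} ses-{rec.session + 1}: {err}") from err
        qc_by_run[(rec.subject, rec.session)] = qc
        qc_rows.append({
            "subject": rec.subject, "session": rec.session + 1,
            "group": f"group{rec.group + 1}", "mean_fd": qc.mean_fd,
            "outlier_fraction": qc.outlier_fraction, "excluded": int(qc.excluded),
        })
    qc_table = pd.DataFrame(qc_rows)
    excluded_subjects = sorted(qc_table.loc[qc_table["excluded"] == 1, "subject"].unique())
    retained = [r for r in dataset.records if r.subject not in excluded_subjects]
    write_tsv(qc_table, out / "qc.tsv")
    (out / "exclusions.json").write_text(json.dumps({"excluded_subjects": excluded_subjects}))
    outputs += [out / "qc.tsv", out / "exclusions.json"]
    stages_run.append("qc")
    if len({r.subject for r in retained}) < 4:
        raise PipelineError("qc", "fewer than 4 subjects retained after exclusion")
    if last == 1:
        return _manifest(config, stages_run, outputs, out, t0)

    # --- metrics --------------------------------------------------------
    mask = dataset.brain_mask
    metric_maps: dict[tuple[str, int], dict[str, np.ndarray]] = {}
    roi_rows = {"ALFF": [], "fALFF": []}
    for rec in retained:
        try:
            run, conf, trace, _ = dataset.realize(rec)
            confounds = build_confound_matrix(
                trace, conf["csf"].to_numpy(), conf["wm"].to_numpy(),
                config.n_confound_components,
            )
            denoised = regress_confounds(run, confounds)
            maps = {
                "ALFF": alff_map(denoised, band),
                "fALFF": falff_map(denoised, band),
                "tSNR": tsnr_map(denoised),
                "gbold_beta": gbold_beta_map(denoised),
            }
            if config.normalize:
                for key in ("ALFF", "fALFF"):
                    maps[key] = normalize_map(maps[key], mask)
        except Exception as err:  # noqa: BLE001
            raise PipelineError("metrics", f"{rec.subject} ses-{rec.session + 1}: {err}") from err
        entry = {k: m.values[mask] for k, m in maps.items()}
        metric_maps[(rec.subject, rec.session)] = entry
        for key in ("ALFF", "fALFF"):
            row = {"subject": rec.subject, "session": rec.session + 1,
                   "group": f"group{rec.group + 1}"}
            flat_labels = dataset.atlas.labels[mask]
            vals = entry[key]
            for lab in dataset.atlas.roi_labels:
                sel = vals[flat_labels == lab]
                sel = sel[np.isfinite(sel)]
                row[f"roi{lab:02d}"] = float(sel.mean()) if sel.size else float("nan")
            roi_rows[key].append(row)
    roi_tables = {k: pd.DataFrame(v) for k, v in roi_rows.items()}
    for key, table in roi_tables.items():
        write_tsv(table, out / f"roi_{key.lower()}.tsv")
        outputs.append(out / f"roi_{key.lower()}.tsv")
    stages_run.append("metrics")
    if last == 2:
        return _manifest(config, stages_run, outputs, out, t0)

    # --- repeatability --------------------------------------------------
    roi_cols = [f"roi{lab:02d}" for lab in dataset.atlas.roi_labels]
    rep_rows, ba_summary = [], {}
    for key, table in roi_tables.items():
        for res in icc_per_roi(table, roi_cols):
            rep_rows.append({"metric": key, "mode": res.mode, "unit": res.unit,
                             "icc": res.icc})
        for res in icc_per_subject(table, roi_cols):
            rep_rows.append({"metric": key, "mode": res.mode, "unit": res.unit,
                             "icc": res.icc})
        whole = table.assign(mean_value=table[roi_cols].mean(axis=1))
        for grp, sub in whole.groupby("group"):
            wide = sub.pivot(index="subject", columns="session", values="mean_value")
            ba = bland_altman(wide[1].to_numpy(), wide[2].to_numpy())
            ba_summary[f"{key}_{grp}"] = {
                "mean": float(wide.to_numpy().mean()), "bias": ba.bias,
                "lower_limit": ba.lower_limit, "upper_limit": ba.upper_limit,
            }
    write_tsv(pd.DataFrame(rep_rows), out / "icc.tsv")
    (out / "bland_altman.json").write_text(json.dumps(ba_summary, indent=2, sort_keys=True))
    outputs += [out / "icc.tsv", out / "bland_altman.json"]
    stages_run.append("repeatability")
    if last == 3:
        return _manifest(config, stages_run, outputs, out, t0)

    # --- group inference --------------------------------------------------
    subjects = sorted({r.subject for r in retained})
    group_of = {r.subject: r.group for r in retained}
    mfd = qc_table.groupby("subject")["mean_fd"].mean()
    stat_maps, cluster_sets = {}, {}
    affine = dataset.affine
    seed_mask = None

    def _session_mean(subject: str, key: str) -> np.ndarray:
        stack = [metric_maps[(subject, ses)][key] for ses in range(spec.n_sessions)]
        return np.mean(stack, axis=0)

    group_vec = np.array([group_of[s] for s in subjects])
    mfd_vec = mfd.loc[subjects].to_numpy()
    for key in ("fALFF", "ALFF", "tSNR", "gbold_beta"):
        maps = np.stack([_session_mean(s, key) for s in subjects])
        maps[~np.isfinite(maps)] = np.nan  # tSNR sentinel voxels drop out
        design = GroupDesign(
            maps=maps, group=group_vec, mask=mask,
            covariates=mfd_vec[:, None], covariate_names=["mean_fd"],
        )
        try:
            stat = voxelwise_group_ttest(design, direction="group2>group1")
            thresh, _null = fwe_threshold(
                design, config.alpha, config.n_perm,
                seed=np.random.SeedSequence([config.rng_seed, 4]),
            )
            clusters = extract_clusters(stat, thresh, config.min_extent, config.connectivity)
        except Exception as err:  # noqa: BLE001
            raise PipelineError("group", f"{key}: {err}") from err
        stat_maps[key], cluster_sets[key] = stat, clusters
        save_map(AmplitudeMap(stat.t, metric="tstat", affine=affine),
                 out / f"group_{key.lower()}_tmap.nii.gz")
        outputs.append(out / f"group_{key.lower()}_tmap.nii.gz")
        cluster_df = pd.DataFrame({
            "cluster": np.arange(1, clusters.n_clusters + 1),
            "size_vox": clusters.sizes,
            "peak_t": clusters.peak_t,
            "peak_xyz_vox": [str(c) for c in clusters.peak_coord],
        })
        cluster_df["fwe_threshold"] = thresh
        write_tsv(cluster_df, out / f"clusters_{key.lower()}.tsv")
        outputs.append(out / f"clusters_{key.lower()}.tsv")
    # control analysis: overlap of the physiology-proxy (gBOLD) group map
    # with the amplitude group maps, on uncorrected-binarized masks
    control = {}
    gbold_bin = binarize_map(stat_maps["gbold_beta"], 0.05)
    for key in ("ALFF", "fALFF"):
        control[f"dice_gbold_{key.lower()}"] = dice(
            binarize_map(stat_maps[key], 0.05), gbold_bin
        )
    (out / "control_dice.json").write_text(json.dumps(control, indent=2, sort_keys=True))
    outputs.append(out / "control_dice.json")
    if cluster_sets["fALFF"].n_clusters:
        seed_mask = cluster_sets["fALFF"].largest_mask()
    stages_run.append("group")
    if last == 4:
        return _manifest(config, stages_run, outputs, out, t0)

    # --- connectivity ----------------------------------------------------
    if seed_mask is None:
        logger.warning("no surviving fALFF cluster; seeding from the designated atlas ROI")
        seed_mask = dataset.atlas.roi_mask(spec.seed_roi_id)
    seed_peak = cluster_sets["fALFF"].peak_coord[
        int(np.argmax(cluster_sets["fALFF"].sizes))
    ] if cluster_sets["fALFF"].n_clusters else None
    seed_label = (int(dataset.atlas.labels[seed_peak]) if seed_peak
                  else spec.seed_roi_id)
    fc_rows = []
    vox = tuple(float(v) for v in np.abs(np.diag(affine))[:3])
    for rec in retained:
        try:
            run, conf, trace, _ = dataset.realize(rec)
            confounds = build_confound_matrix(
                trace, conf["csf"].to_numpy(), conf["wm"].to_numpy(),
                config.n_confound_components,
            )
            denoised = regress_confounds(run, confounds)
            series = extract_seed_series(denoised, seed_mask)
            zmap = seed_correlation_map(denoised, series)
            smoothed = smooth_map(zmap.values, config.fwhm_mm, vox, mask)
            zmap_s = AmplitudeMap(smoothed, metric="fc_z", affine=affine)
            fc = roi_fc(zmap_s, dataset.atlas, exclude_labels=(seed_label,))
        except Exception as err:  # noqa: BLE001
            raise PipelineError("connectivity",
                                f"{rec.subject} ses-{rec.session + 1}: {err}") from err
        for lab, value in fc.items():
            fc_rows.append({
                "subject": rec.subject, "session": rec.session + 1,
                "group": f"group{rec.group + 1}", "sex": rec.sex,
                "mfd": qc_by_run[(rec.subject, rec.session)].mean_fd,
                "roi": lab, "fc": value,
            })
    fc_table = pd.DataFrame(fc_rows)
    write_tsv(fc_table, out / "fc_table.tsv")
    outputs.append(out / "fc_table.tsv")
    fits = []
    for lab in sorted(fc_table["roi"].unique()):
        try:
            fits.append(fit_fc_mixed_model(fc_table, lab))
        except Exception as err:  # noqa: BLE001
            raise PipelineError("connectivity", f"mixed model roi {lab}: {err}") from err
    report = report_significant_rois(fits, q=config.fdr_q, method=config.fdr_method)
    write_tsv(report, out / "fc_report.tsv")
    all_rows = pd.DataFrame([
        {"roi": f.roi, "beta_group": f.beta["group"], "se_group": f.se["group"],
         "t_group": f.tvalue["group"], "p_group": f.pvalue["group"],
         "fallback_ols": int(f.fallback_ols)}
        for f in fits
    ])
    all_rows["p_fdr_group"] = (
        list(fdr_adjust(all_rows["p_group"], method=config.fdr_method))
        if len(all_rows) else []
    )
    write_tsv(all_rows, out / "fc_model_all_rois.tsv")
    outputs += [out / "fc_report.tsv", out / "fc_model_all_rois.tsv"]
    stages_run.append("connectivity")
    return _manifest(config, stages_run, outputs, out, t0)


def _manifest(
    config: PipelineConfig,
    stages_run: list[str],
    outputs: list[Path],
    out: Path,
    t0: float,
) -> RunManifest:
    manifest = RunManifest(
        config=dataclasses.asdict(config),
        seed=config.rng_seed,
        version=__version__,
        stages_run=stages_run,
        output_hashes={p.name: _sha256(p) for p in sorted(set(outputs))},
        timestamp=t0,
    )
    manifest.to_json(out / "manifest.json")
    return manifest
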