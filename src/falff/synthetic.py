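"""Synthetic two-group, two-session BOLD cohorts with known ground truth.

Each voxel time-series is a sum of interpretable components:

* a band-limited (0.008-0.1 Hz) "neural" fluctuation whose RMS amplitude
  is scaled per ROI and group (the planted amplitude effect),
* a shared band-limited latent signal coupled into the seed ROI and into
  designated target ROIs with group-dependent strength (the planted
  seed-connectivity effect),
* sinusoidal respiratory (0.3 Hz) and cardiac (1.1 Hz) components; at
  TR 0.72/0.8 s the cardiac term aliases into the sampled spectrum,
* a global component multiplied by a per-voxel coupling beta,
* white noise, whose above-band (> 0.1 Hz) content can be scaled per
  group (lower high-frequency noise also raises fALFF),
* an optional slow drift below 0.008 Hz (amplitude metrics must tolerate
  it because no detrending is applied downstream),
* motion-spike artifacts at the frames spiked in the motion trace,
* a constant baseline.

Band-limited components are normalized to exact unit RMS before scaling,
so the generated band amplitude equals the requested one by construction.
Everything is driven by ``numpy.random.SeedSequence`` keyed on the cohort
seed plus (group, subject, session), so identical (spec, seed) give
bit-identical cohorts and any single run can be re-materialized on demand
without holding the whole cohort in memory.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
import yaml

from .io import BoldRun, LabelAtlas, save_atlas, save_mask, save_run, write_tsv
from .motion import MOTION_COLUMNS

_TRANS_JITTER_MM = 0.02     # uniform half-width of translation jitter
_ROT_JITTER_RAD = 2e-4      # uniform half-width of rotation jitter
_SPIKE_ARTIFACT_GAIN = 3.0  # BOLD offset per mm of motion spike


@dataclass
class CohortSpec:
    """Study-design parameters for a synthetic cohort.

    Defaults emulate the acquisition being modeled: two groups scanned in
    two sessions on separate days, TR 0.72 s (group 1) / 0.8 s (group 2),
    ~6.5 min runs, a 20% low-frequency amplitude increase for group 2 in
    the seed ROI, and stronger seed-cortex coupling in group 2.
    """

    n_per_group: int = 10
    n_sessions: int = 2
    tr_by_group: tuple[float, float] = (0.72, 0.8)
    n_frames: int = 480
    grid_shape: tuple[int, int, int] = (16, 16, 16)
    voxel_size: float = 2.0
    atlas_rois: int = 6
    seed_roi_id: int = 1
    effect_rois: tuple[int, ...] | None = None   # default: (seed_roi_id,)
    effect_band_amp: float = 1.2
    effect_highfreq_amp: float = 1.0
    highfreq_cut: float = 0.1
    fc_coupling: dict[int, tuple[float, float]] | None = None
    fc_target_rois: tuple[int, ...] | None = None
    fc_coupling_by_group: tuple[float, float] = (0.3, 0.6)
    resp_freq: float = 0.3
    card_freq: float = 1.1
    resp_amp: float = 0.5
    card_amp: float = 0.5
    global_amp: float = 0.5
    global_coupling_sd: float = 0.3
    drift_amp: float = 0.2
    drift_freq: float = 0.003
    neural_amp: float = 1.0
    noise_sd: float = 1.0
    subject_amp_sd: float = 0.1
    baseline: float = 1000.0
    motion_spike_prob: float = 0.02
    spike_mag_mm: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_per_group", "n_sessions", "n_frames", "atlas_rois"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("effect_band_amp", "effect_highfreq_amp", "resp_freq",
                     "card_freq", "neural_amp", "voxel_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 <= self.motion_spike_prob <= 1:
            raise ValueError("motion_spike_prob must be in [0, 1]")
        if self.effect_rois is None:
            self.effect_rois = (self.seed_roi_id,)
        if self.fc_target_rois is None:
            # last two labels by default (disjoint from the usual seed label 1)
            k = self.atlas_rois
            self.fc_target_rois = tuple(lab for lab in (k - 1, k) if lab != self.seed_roi_id and lab >= 1)

    def resolved_fc_coupling(self) -> np.ndarray:
        """(n_rois, 2) coupling of the shared latent signal, per group."""
        coupling = np.zeros((self.atlas_rois, 2))
        coupling[self.seed_roi_id - 1, :] = 1.0
        for lab in self.fc_target_rois:
            coupling[lab - 1, :] = self.fc_coupling_by_group
        if self.fc_coupling:
            for lab, (g1, g2) in self.fc_coupling.items():
                coupling[lab - 1, :] = (g1, g2)
        return coupling

    def resolved_band_amp(self) -> np.ndarray:
        """(n_rois, 2) neural band RMS amplitude per ROI and group."""
        amp = np.full((self.atlas_rois, 2), self.neural_amp)
        for lab in self.effect_rois:
            amp[lab - 1, 1] = self.neural_amp * self.effect_band_amp
        return amp

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortSpec":
        d = yaml.safe_load(Path(path).read_text())
        for key in ("tr_by_group", "grid_shape", "effect_rois", "fc_target_rois",
                    "fc_coupling_by_group"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        if d.get("fc_coupling"):
            d["fc_coupling"] = {int(k): tuple(v) for k, v in d["fc_coupling"].items()}
        return cls(**d)


@dataclass
class GroundTruth:
    """Planted effects of a generated cohort; determined by (spec, seed)."""

    roi_labels: list[int]
    band_amp_by_group: np.ndarray       # (n_rois, 2)
    seed_coupling_by_group: np.ndarray  # (n_rois, 2)
    seed_roi_id: int
    effect_rois: list[int]
    spike_indices: dict[str, list[int]]
    global_beta: np.ndarray             # 3D per-voxel coupling

    def to_json(self, path: str | Path) -> None:
        d = {
            "roi_labels": self.roi_labels,
            "band_amp_by_group": self.band_amp_by_group.tolist(),
            "seed_coupling_by_group": self.seed_coupling_by_group.tolist(),
            "seed_roi_id": self.seed_roi_id,
            "effect_rois": self.effect_rois,
            "spike_indices": self.spike_indices,
            "global_beta_shape": list(self.global_beta.shape),
            "global_beta": self.global_beta.ravel().tolist(),
        }
        Path(path).write_text(json.dumps(d))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            roi_labels=[int(v) for v in d["roi_labels"]],
            band_amp_by_group=np.asarray(d["band_amp_by_group"]),
            seed_coupling_by_group=np.asarray(d["seed_coupling_by_group"]),
            seed_roi_id=int(d["seed_roi_id"]),
            effect_rois=[int(v) for v in d["effect_rois"]],
            spike_indices={k: [int(i) for i in v] for k, v in d["spike_indices"].items()},
            global_beta=np.asarray(d["global_beta"]).reshape(d["global_beta_shape"]),
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, GroundTruth):
            return NotImplemented
        return (
            self.roi_labels == other.roi_labels
            and np.array_equal(self.band_amp_by_group, other.band_amp_by_group)
            and np.array_equal(self.seed_coupling_by_group, other.seed_coupling_by_group)
            and self.seed_roi_id == other.seed_roi_id
            and self.effect_rois == other.effect_rois
            and self.spike_indices == other.spike_indices
            and np.array_equal(self.global_beta, other.global_beta)
        )


@dataclass(frozen=True)
class RunRecord:
    """Metadata identifying one run of the cohort; enough to regenerate it."""

    subject: str
    group: int          # 0 or 1 (group index; "group 2" of the design is 1)
    sex: str            # "F" / "M"
    session: int        # 0-based


@dataclass
class CohortDataset:
    """A generated cohort: metadata plus on-demand run materialization."""

    spec: CohortSpec
    atlas: LabelAtlas
    brain_mask: np.ndarray
    affine: np.ndarray
    global_beta: np.ndarray
    subject_scales: dict[str, float]
    records: list[RunRecord]

    def participants(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"subject": r.subject, "group": f"group{r.group + 1}",
              "sex": r.sex, "session": r.session + 1} for r in self.records]
        )

    def realize(self, record: RunRecord):
        """Regenerate (BoldRun, confounds, motion trace, spikes) for a record."""
        return generate_subject_run(
            self.spec, record.group, record.session, self.atlas,
            seed=_run_seed(self.spec, record),
            global_beta=self.global_beta,
            subject_scale=self.subject_scales[record.subject],
        )

    def iter_runs(self) -> Iterator[tuple[RunRecord, BoldRun, pd.DataFrame, pd.DataFrame]]:
        for rec in self.records:
            run, conf, trace, _ = self.realize(rec)
            yield rec, run, conf, trace


def _run_seed(spec: CohortSpec, record: RunRecord) -> np.random.SeedSequence:
    subj_idx = int(record.subject.split("-")[1])
    return np.random.SeedSequence([spec.rng_seed, 1 + record.group, subj_idx, record.session])


def _ellipsoid_mask(shape: tuple[int, int, int]) -> np.ndarray:
    grids = np.indices(shape).astype(float)
    mask = np.zeros(shape, dtype=bool)
    dist = np.zeros(shape)
    for ax, g in enumerate(grids):
        c = (shape[ax] - 1) / 2.0
        r = max(shape[ax] * 0.45, 1.0)
        dist += ((g - c) / r) ** 2
    mask[dist <= 1.0] = True
    return mask


def generate_atlas(spec: CohortSpec) -> LabelAtlas:
    """Compact Voronoi parcellation of an ellipsoidal brain mask.

    Labels 1..K partition the mask (nearest-seed assignment in voxel
    space); label 0 is background. Deterministic in spec.rng_seed.
    """
    mask = _ellipsoid_mask(spec.grid_shape)
    coords = np.argwhere(mask)
    if spec.atlas_rois > len(coords):
        raise ValueError(
            f"requested {spec.atlas_rois} ROIs but the brain mask holds only "
            f"{len(coords)} voxels"
        )
    rng = np.random.default_rng(np.random.SeedSequence([spec.rng_seed, 7]))
    centers = coords[rng.choice(len(coords), size=spec.atlas_rois, replace=False)]
    d2 = ((coords[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    assign = d2.argmin(axis=1) + 1
    labels = np.zeros(spec.grid_shape, dtype=np.int16)
    labels[tuple(coords.T)] = assign
    names = {i: f"roi{i:02d}" for i in range(1, spec.atlas_rois + 1)}
    names[spec.seed_roi_id] = f"roi{spec.seed_roi_id:02d}_seed"
    return LabelAtlas(labels=labels, names=names)


def generate_motion_trace(
    n_frames: int,
    spike_prob: float,
    spike_mag_mm: float = 1.0,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[pd.DataFrame, list[int]]:
    """Rigid-body parameter trace with small jitter and optional spikes.

    Spikes displace trans_x by at least ``spike_mag_mm`` with alternating
    sign, so every spiked frame produces an FD excursion of that size.
    Returns the 6-column trace and the spiked frame indices.
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    rng = np.random.default_rng(seed)
    trans = rng.uniform(-_TRANS_JITTER_MM, _TRANS_JITTER_MM, (n_frames, 3))
    rot = rng.uniform(-_ROT_JITTER_RAD, _ROT_JITTER_RAD, (n_frames, 3))
    spiked = np.zeros(n_frames, dtype=bool)
    if spike_prob > 0:
        spiked[1:] = rng.random(n_frames - 1) < spike_prob
    sign = 1.0
    for t in np.where(spiked)[0]:
        trans[t, 0] += sign * spike_mag_mm * (1.1 + 0.2 * rng.random())
        sign = -sign
    df = pd.DataFrame(np.hstack([trans, rot]), columns=list(MOTION_COLUMNS))
    return df, [int(t) for t in np.where(spiked)[0]]


def _band_noise(
    rng: np.random.Generator, n_series: int, n: int, tr: float,
    low: float, high: float,
) -> np.ndarray:
    """Unit-RMS noise with support only on bins low <= f <= high."""
    freqs = np.fft.rfftfreq(n, tr)
    sel = (freqs >= low) & (freqs <= high) & (freqs > 0)
    if not sel.any():
        raise ValueError(f"no frequency bins in [{low}, {high}] Hz at n={n}, TR={tr}")
    spec = np.zeros((n_series, len(freqs)), dtype=complex)
    spec[:, sel] = rng.standard_normal((n_series, sel.sum())) + 1j * rng.standard_normal((n_series, sel.sum()))
    if n % 2 == 0 and sel[-1]:
        spec[:, -1] = spec[:, -1].real
    x = np.fft.irfft(spec, n=n, axis=-1)
    rms = np.sqrt((x ** 2).mean(axis=-1, keepdims=True))
    return x / rms


def generate_subject_run(
    spec: CohortSpec,
    group: int,
    session: int,
    atlas: LabelAtlas,
    seed: int | np.random.SeedSequence = 0,
    global_beta: np.ndarray | None = None,
    subject_scale: float = 1.0,
) -> tuple[BoldRun, pd.DataFrame, pd.DataFrame, list[int]]:
    """One synthetic run: (BoldRun, confound table, motion trace, spikes)."""
    if group not in (0, 1):
        raise ValueError(f"group must be 0 or 1, got {group}")
    if not 0 <= session < spec.n_sessions:
        raise ValueError(f"session {session} out of range [0, {spec.n_sessions})")
    tr = spec.tr_by_group[group]
    n = spec.n_frames
    rng = np.random.default_rng(seed)
    # drawn first so spike indices are recoverable without building the 4D data
    motion_seed = int(rng.integers(2 ** 31))
    mask = atlas.labels != 0  # brain mask is the union of labels
    labels_flat = atlas.labels[mask]
    n_vox = int(mask.sum())
    t_sec = np.arange(n) * tr

    if global_beta is None:
        beta_rng = np.random.default_rng(np.random.SeedSequence([spec.rng_seed, 999]))
        global_beta = 1.0 + spec.global_coupling_sd * beta_rng.standard_normal(spec.grid_shape)
    beta_flat = np.asarray(global_beta)[mask]

    band_amp = spec.resolved_band_amp()[:, group]       # per ROI
    coupling = spec.resolved_fc_coupling()[:, group]
    amp_vox = band_amp[labels_flat - 1] * subject_scale
    # coupling is relative to the voxel's neural amplitude, so a planted
    # band-amplitude factor scales the ROI's entire low-frequency content
    coup_vox = coupling[labels_flat - 1] * amp_vox

    neural = _band_noise(rng, n_vox, n, tr, 0.008, 0.1) * amp_vox[:, None]
    latent = _band_noise(rng, 1, n, tr, 0.008, 0.1)[0]

    phase = rng.uniform(0, 2 * np.pi, size=3)
    resp = spec.resp_amp * np.sin(2 * np.pi * spec.resp_freq * t_sec + phase[0])
    card = spec.card_amp * np.sin(2 * np.pi * spec.card_freq * t_sec + phase[1])
    physio = resp + card

    global_sig = spec.global_amp * _band_noise(rng, 1, n, tr, 0.01, 0.2)[0]

    noise = rng.standard_normal((n_vox, n)) * spec.noise_sd
    if group == 1 and spec.effect_highfreq_amp != 1.0:
        freqs = np.fft.rfftfreq(n, tr)
        spec_n = np.fft.rfft(noise, axis=-1)
        spec_n[:, freqs > spec.highfreq_cut] *= spec.effect_highfreq_amp
        noise = np.fft.irfft(spec_n, n=n, axis=-1)

    drift = np.zeros(n)
    if spec.drift_amp > 0:
        drift = spec.drift_amp * np.sin(2 * np.pi * spec.drift_freq * t_sec + phase[2])

    trace, spikes = generate_motion_trace(
        n, spec.motion_spike_prob, spec.spike_mag_mm, seed=motion_seed,
    )
    artifact = np.zeros(n)
    sign = 1.0
    for tdx in spikes:
        artifact[tdx] += sign * _SPIKE_ARTIFACT_GAIN * spec.spike_mag_mm * spec.noise_sd
        sign = -sign

    series = (
        spec.baseline
        + neural
        + coup_vox[:, None] * latent[None, :]
        + physio[None, :]
        + beta_flat[:, None] * global_sig[None, :]
        + noise
        + drift[None, :]
        + artifact[None, :]
    )
    data = np.zeros(spec.grid_shape + (n,))
    data[mask] = series

    affine = np.diag([spec.voxel_size] * 3 + [1.0])
    run = BoldRun(data=data, tr=tr, affine=affine, brain_mask=mask)

    confounds = pd.DataFrame({
        "csf": physio + 0.2 * rng.standard_normal(n),
        "wm": 0.5 * global_sig + 0.2 * rng.standard_normal(n),
    })
    return run, confounds, trace, spikes


def generate_cohort(
    spec: CohortSpec,
    out_dir: str | Path | None = None,
) -> tuple[CohortDataset, GroundTruth]:
    """Generate the full cohort (and optionally write it to disk).

    Runs are n_per_group x 2 groups x n_sessions; sexes are balanced
    within group. Writing refuses to overwrite an existing cohort
    directory. The returned dataset materializes runs lazily.
    """
    atlas = generate_atlas(spec)
    mask = atlas.labels != 0
    affine = np.diag([spec.voxel_size] * 3 + [1.0])
    beta_rng = np.random.default_rng(np.random.SeedSequence([spec.rng_seed, 999]))
    global_beta = 1.0 + spec.global_coupling_sd * beta_rng.standard_normal(spec.grid_shape)

    records: list[RunRecord] = []
    subject_scales: dict[str, float] = {}
    scale_rng = np.random.default_rng(np.random.SeedSequence([spec.rng_seed, 1001]))
    for group in (0, 1):
        for i in range(spec.n_per_group):
            subj_idx = group * spec.n_per_group + i
            subject = f"sub-{subj_idx:03d}"
            subject_scales[subject] = float(np.exp(
                spec.subject_amp_sd * scale_rng.standard_normal()
            ))
            sex = "F" if i % 2 == 0 else "M"
            for session in range(spec.n_sessions):
                records.append(RunRecord(subject=subject, group=group, sex=sex, session=session))

    dataset = CohortDataset(
        spec=spec, atlas=atlas, brain_mask=mask, affine=affine,
        global_beta=global_beta, subject_scales=subject_scales, records=records,
    )

    def _spikes_only(rec: RunRecord) -> list[int]:
        run_rng = np.random.default_rng(_run_seed(spec, rec))
        motion_seed = int(run_rng.integers(2 ** 31))
        _, spikes = generate_motion_trace(
            spec.n_frames, spec.motion_spike_prob, spec.spike_mag_mm, seed=motion_seed,
        )
        return spikes

    spike_indices: dict[str, list[int]] = {}
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        if out.exists() and any(out.iterdir()):
            raise FileExistsError(f"output directory {out} exists and is not empty")
        out.mkdir(parents=True, exist_ok=True)
        save_atlas(atlas, affine, out / "atlas.nii.gz")
        save_mask(mask, affine, out / "brain_mask.nii.gz")
        write_tsv(dataset.participants(), out / "participants.tsv")
        spec.to_yaml(out / "cohort_spec.yaml")

    for rec in records:
        key = f"{rec.subject}_ses-{rec.session + 1}"
        if out is not None:
            run, confounds, trace, spikes = dataset.realize(rec)
            spike_indices[key] = spikes
            stem = out / key
            save_run(run, f"{stem}_bold.nii.gz")
            write_tsv(trace, f"{stem}_motion.tsv")
            write_tsv(confounds, f"{stem}_confounds.tsv")
        else:
            spike_indices[key] = _spikes_only(rec)

    truth = GroundTruth(
        roi_labels=atlas.roi_labels,
        band_amp_by_group=spec.resolved_band_amp(),
        seed_coupling_by_group=spec.resolved_fc_coupling(),
        seed_roi_id=spec.seed_roi_id,
        effect_rois=list(spec.effect_rois),
        spike_indices=spike_indices,
        global_beta=global_beta,
    )
    if out is not None:
        truth.to_json(out / "ground_truth.json")
    return dataset, truth
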