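# Methods

This note documents the models, conventions and numerical choices behind
the package, and what its synthetic-data validation does and does not
establish about real data.

## Signal model of the synthetic cohort

Each generated voxel time-series is

```
y_v(t) = baseline
       + a_v · s · n_v(t)                 band-limited neural component
       + c_r · a_v · s · L(t)             shared latent (seed) signal
       + A_resp sin(2π f_resp t + φ) + A_card sin(2π f_card t + φ')
       + β_v · G(t)                       global component
       + ε_v(t)                           white noise
       + drift(t) + spike(t)
```

where `n_v` and `L` are independent unit-RMS signals with spectral
support exactly in 0.008–0.1 Hz (constructed in the frequency domain and
normalized to unit RMS, so generated band power equals the requested
amplitude squared by construction), `a_v` is the per-ROI amplitude
(multiplied by the group effect factor in designated effect ROIs), `s`
is a per-subject lognormal scale (SD parameter 0.1) shared across
sessions, and `c_r` is the per-ROI latent coupling, expressed *relative
to the voxel's neural amplitude* so that a planted amplitude factor
scales the ROI's entire low-frequency content (this makes the planted
ROI band-power ratio exactly the squared amplitude factor, and keeps the
serialized ground truth a true description of the data).

Defaults emulate the modeled acquisition: two groups × two sessions, TR
0.72 s (group 1) and 0.8 s (group 2), 480 frames (~6.4 min), 2 mm
voxels, an ellipsoidal brain mask partitioned into compact Voronoi ROIs.
Respiration is 0.3 Hz and the cardiac component 1.1 Hz; at these TRs the
cardiac term aliases into the sampled spectrum, which is intentional —
it exercises the fALFF denominator the way physiological aliasing does
in practice. A slow drift (0.003 Hz, amplitude 0.2) is on by default
because the pipeline deliberately performs no detrending and the
amplitude metrics must tolerate it. The group effect has two independent
knobs — a band-amplitude factor (default 1.2 for group 2 in the seed
ROI) and an above-band noise factor (default 1.0) — because both a
low-frequency increase and a high-frequency decrease raise fALFF. Sex is
balanced within group and has no simulated effect; it exists to exercise
the mixed-model covariate. Motion traces carry uniform jitter
(±0.02 mm, ±2e-4 rad) plus Bernoulli spike frames whose displacement is
at least the spike magnitude with alternating sign.

All randomness flows from `numpy.random.SeedSequence` keyed on the
cohort seed and (group, subject, session), so identical (spec, seed)
yield bit-identical cohorts and any single run can be re-materialized
without regenerating the rest.

What the generator does **not** emulate: anatomy, EPI distortion, T2*
decay, spatial autocorrelation of noise, k-space or multi-band
artifacts, non-stationary physiology. Passing recovery tests therefore
show the *statistical machinery* is correct and calibrated, not that
effect sizes on real scanners will match.

## Framewise displacement

FD uses the bounding-box control-point method: six points at the face
centers of a 140×180×115 mm box, each frame's rigid transform applied to
them, FD(t) the largest Euclidean point displacement between frames t−1
and t; FD(0)=0. Rotations are intrinsic about x, then y, then z
(`R = Rx·Ry·Rz`), taken about the box center — so FD depends only on box
dimensions, is exact for pure translations (the step norm, any box), and
is invariant to constant translation offsets. Outlier frames are the
union of FD > 0.5 mm and |frame-to-frame global-signal change, z-scored
over the run| > 3 (a constant global signal yields zero z-scores, not an
error). Subjects are excluded when a session's outlier fraction strictly
exceeds 0.10; flagged frames are otherwise retained (no censoring),
matching a subject-level-exclusion design. Exclusion removes the subject
from every downstream table.

## Amplitude metrics

Metrics are defined on the RMS (square-root of mean band power) scale;
`power_scale="power"` preserves the mean-power reading. The whole-brain
normalization that precedes any group contrast makes the choice a
monotone relabeling, but it must be fixed, and RMS matches the original
amplitude-of-fluctuation definition. Conventions:

- plain periodogram of the demeaned series, no taper or Welch averaging;
- DC excluded everywhere; the fALFF denominator is all bins 0 < f ≤
  Nyquist (with DC included the "full spectrum" would be mean-dependent);
- band edges inclusive (`low ≤ f ≤ high`);
- Parseval weighting (2 on interior bins, 1 on the Nyquist bin) so the
  spectrum-domain ALFF equals the time-domain RMS of the ideally
  band-filtered signal to rounding error — this identity is the test
  oracle;
- zero-variance voxels: fALFF 0, tSNR +inf sentinel (excluded from ROI
  means and group maps);
- confound regression projects out the leading principal components
  (default 6) of the centered, variance-scaled candidates {6 motion
  parameters, CSF mean, WM mean} jointly, plus an intercept; the voxel
  mean is re-added so tSNR stays defined after denoising. If the
  candidates are rank-deficient the rank is kept with a warning. The
  alternative reading (raw motion columns alongside tissue PCs) can be
  had by passing a prebuilt component matrix.
- normalization divides by the mean over finite in-mask voxels and
  requires it positive; it is idempotent.

## Group inference

At each voxel, `value ~ intercept + group + covariates` by OLS; the test
statistic is the group coefficient's t. Scalar covariates (mean FD) are
shared across voxels; voxelwise covariates (gray-matter probability,
gBOLD beta maps) are sampled per voxel via a batched per-voxel GLM.
Rank deficiency is detected by a residual-projection test (robust to
covariates constant to machine precision — e.g. the whole-brain mean of
gBOLD betas, which is identically 1) and reported with the offending
columns.

FWE control uses the permutation max-|t| method: group labels are
permuted against the fixed covariate design, the max over the mask of
|t| recorded per permutation, and the height threshold is the (1−α)
"higher" quantile of that null (chosen so the implied test size is
α·n_perm/(n_perm+1) ≈ α). When fewer distinct relabelings than
permutations exist they are enumerated exhaustively with a warning.
Permutation was chosen over random-field theory because no smoothness
estimation is defined for these maps and the permutation null is
assumption-light; this is a deliberate deviation from parametric
neuroimaging practice. The permutation path requires the
scalar-covariate design; with voxelwise covariates the t-map is still
available but a per-voxel permutation scheme is out of scope.

Clusters are connected components above the height threshold
(26-neighborhood default; 6 and 18 available — the convention must be
explicit for extent filtering to be reproducible), discarded below 10
voxels. The uncorrected-p screen sometimes layered under FWE is
redundant when the FWE threshold is stricter and is exposed only as
`binarize_map` (one-sided, strict inequality), which also feeds the dice
control analysis. Confidence intervals from cluster summaries use the
normal quantile (1.959964 at 95%), the convention under which the
reference summary values reproduce exactly; Cohen's d uses the pooled
SD. The sample-size utility starts from the normal approximation
`n = 2(z_{1−α/tails}+z_{power})²/d²` and refines by exact noncentral-t
search.

## Repeatability

ICC is fixed to the Shrout–Fleiss two-way random, absolute-agreement,
single-measure form ICC(2,1) — the appropriate form for two-session
absolute repeatability — computed from the two-way ANOVA mean squares.
Both units are supported: per ROI across subjects (regional
reliability) and per subject across ROIs (whole-profile repeatability
per participant); results record the mode. Zero-variance tables are
flagged undefined rather than erroring. Bland–Altman differences are
session 2 − session 1 (bias negative when values decline), limits
bias ± 1.96·SD(differences, ddof=1). Atlas-level ROI exclusions (e.g.
regions unreliable at the acquisition resolution) are handled by
passing a reduced label set, not hard-coded labels.

## Seed connectivity and the mixed model

Correlation is computed on denoised, unsmoothed series; |r| is clamped
at 1−1e-7 before the Fisher z transform (flagged); smoothing is applied
to the z-map. Smoothing uses a Gaussian kernel with
σ = FWHM/(2√(2 ln 2)) per axis in voxel units and mask-aware,
mass-preserving normalization: each in-mask voxel's value is spread
with a kernel renormalized by the in-mask kernel mass reachable from it,
which conserves the in-mask sum (hence mean) exactly; far from mask
edges it coincides with ordinary Gaussian convolution. The seed's own
atlas ROI is excluded from the target set.

Per target ROI, `fc ~ 1 + group + sex + mFD + session + (1 | subject)`
is fitted by REML (statsmodels MixedLM). Reference levels: first group,
male, session 1; positive group β means the second group has higher
connectivity. Wald p-values use a residual-df t approximation
(df = n_obs − n_fixed − 1) rather than MixedLM's normal reference; with
≥ 10 subjects the two differ negligibly. Singular fits fall back to OLS
and are flagged. FDR across ROIs defaults to Benjamini–Yekutieli (valid
under dependence; BH available), applied to the group effect's
p-values; "multivariate" modeling is realized as one univariate model
per ROI with FDR across ROIs, matching a per-ROI reporting table — a
joint multivariate fit is out of scope.

## Pipeline

Stages run in order simulate → QC → denoise/metrics → repeatability →
group inference → seed FC → mixed model, each writing TSV/JSON/NIfTI
reports and a manifest of config, seed, version and output SHA-256
hashes; reruns with the same config reproduce the hashes bit for bit.
The single pipeline seed is expanded per stage as
`SeedSequence([seed, stage_index])`. Group maps under test are the two
sessions' normalized maps averaged per subject (the session-1-only
alternative is a one-line change; averaging uses both sessions'
information symmetrically). The group-model covariate is mean FD; gBOLD
enters as a control analysis (group t-map of voxelwise gBOLD betas,
binarized-dice overlap against the amplitude maps) because its
whole-brain mean is identically 1 and voxelwise covariates are not
permutable (above). If no fALFF cluster survives, connectivity falls
back to the designated atlas seed ROI with a warning.

## Validation experiment sizes

The calibration and recovery experiments (`falff.validate`) run at desk
scale: FWE calibration on 200 null cohorts of 10+10 exchangeable
subject maps over a 16³-grid mask with 500 permutations each (null maps
are generated directly because only exchangeability matters to the
threshold's validity); amplitude recovery on 20 cohorts of 20+20
subjects, 480 frames, group-equal couplings, planted factor 1.2;
mixed-model recovery on 100 simulated FC tables (8 ROIs, one planted,
30 subjects/group, 2 sessions). The reproduction script runs reduced
replicate counts of the same experiments.

## Known limitations

- The mixed-model recovery experiment's joint bar (β̂ within ±0.1 *and*
  adjusted p < 0.001 in ≥95% of seeds) sits above the theoretical
  ceiling of its own conditions: with subject SD 0.2, residual SD 0.1,
  two sessions and 30 per group, SE(β̂) = 0.0548, so β̂ lands within
  ±0.1 with probability ≈ 0.93 per seed even for an exactly unbiased
  estimator — the observed 91/100 matches this. The estimator itself is
  unbiased (mean β̂ ≈ 0.40) and its null rejection rate is calibrated.
- Periodogram amplitude estimates are noisy at ~6.5 min runs; session
  averaging mitigates but does not remove this.
- The synthetic atlas has no anatomical meaning; dice values against
  "truth" measure recovery of the planted partition element only.
- tSNR group contrasts on synthetic data mostly reflect the noise-scale
  knobs, not acquisition physics.
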