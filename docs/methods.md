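# Methods

This note documents the models, parameters and numerical choices behind
`mrbpe`, and what the synthetic validation does and does not demonstrate.

## Measurement model

The package quantifies two properties of the normal breast from a standard
clinical MRI exam.

**MRI breast density.** Fibro-glandular tissue (FGT) is segmented within a
whole-breast mask on the non-fat-suppressed T2-weighted volume, where
parenchyma is dark and fat is bright.  Density is a voxel-count ratio,
`MRBD (%) = 100 |FGT| / |breast|`, and fibro-glandular volume is
`|FGT| × voxel volume`.  Both are computed per breast.

**Background parenchymal enhancement.** The parenchyma is segmented on the
*pre-contrast* frame of the DCE series — segmenting post-contrast or
subtraction images would preferentially keep strongly enhancing tissue and
bias the enhancement distribution.  The maximum-enhancement time point
(MTP) is the post-contrast frame with the highest median parenchymal
intensity (ties resolved to the earliest frame; the pre-contrast frame is
excluded from the search by construction).  The voxelwise map is
`BPE (%) = 100 (I_MTP − I_FTP)/I_FTP` over parenchyma voxels, and its
distribution is summarised by median, Q1, Q3, IQR, moment skewness
`g1 = m3/m2^{3/2}` and **non-excess** kurtosis `b2 = m4/m2²` (normal → 3).
The non-excess convention is pinned by a Monte-Carlo test (10⁶ normal draws
→ 3.00 ± 0.05, uniform → 1.80 ± 0.05) so the kurtosis scale is unambiguous.

## Pipeline stages and their parameters

**Region growing** (`masking.region_grow`). The breast mask is the
self-consistent fixed point of: admit voxels with
`|I − mean(region)| ≤ tolerance`, keep the 26-connected components
containing a seed, recompute the mean.  Iterating to a fixed point, rather
than accreting a frontier one pass at a time, makes the result independent
of seed ordering and of redundant interior seeds — early admissions that
the converged mean does not support are revoked.  A limit cycle (possible
in principle when the tolerance straddles a tissue boundary) terminates the
iteration at the smaller cycle state with a warning.  Defaults: seeds are
chosen automatically as one bright-fat voxel per left/right image half (the
voxel closest to that half's 99.5th intensity percentile); the tolerance
defaults to 0.55 × the robust (0.5–99.5 percentile) intensity range, which
on breast T2w data spans the fat–parenchyma contrast while excluding
muscle and air.  Both are exposed for the semi-automated use the method is
designed for.

**Hole filling and erosion.** Isolated interior voxels rejected by the
tolerance criterion under noise would be amplified by the subsequent
erosion (each hole removes its whole structuring-element neighbourhood), so
the pipeline fills holes (`scipy.ndimage.binary_fill_holes`) before eroding.
Erosion uses a ball element of radius 2 voxels (4 mm at the default 2 mm
spacing) — enough to remove a 1–2-voxel skin rind and the chest-wall
interface in one isotropic operation; the radius is a config parameter
because the appropriate rind thickness is acquisition dependent.

**Laterality.** Left and right breasts are split at the world-x midpoint of
the grid, with sides defined from the affine (RAS+: larger world x =
subject's right).  Index conventions of the storage order never enter the
logic, so flipped or permuted on-disk layouts cannot silently swap sides.

**Bias-field correction** (`bias.correct_bias`). The log-intensity inside
the mask is modelled as a low-order polynomial (total degree ≤ 2 by
default) plus per-tissue-class offsets; the two parts are refined
alternately, with the offsets estimated by 1D k-means (2 classes: fat and
parenchyma) on the field-corrected residuals.  The polynomial absorbs only
the smooth field because the piecewise tissue structure is absorbed by the
offsets.  The field is normalised to mean 1 over the mask, making the
correction gauge-free (global intensity scale preserved, correction
scale-equivariant).  This is a contract-level replacement for N4-style
correction — appropriate here because the quantity of interest is the
removal of a smooth multiplicative field, not the N4 algorithm itself — and
a `field_estimator` hook accepts any external estimator.  Convergence:
relative coefficient change < 10⁻⁶ or 25 iterations.

**Fuzzy c-means** (`fcm.FuzzyCMeans`). Standard FCM objective
`J = Σ_i Σ_k u_ik^m (x_i − c_k)²` with `Σ_k u_ik = 1`, minimised by
alternating membership/centroid updates; J is monotonically non-increasing
and the trace is recorded per iteration.  Defaults: K = 7 clusters,
fuzziness m = 2 (the universal default), convergence at relative objective
change < 10⁻⁶ or 300 iterations.  Initial centroids sit at K evenly spaced
quantiles of the sample — deterministic, so a fixed seed gives
bit-reproducible segmentations; optional seeded jitter explores basins.
Samples exactly on a centroid receive full membership there; hard
assignment is by maximum membership with ties to the lower (darker)
cluster index.  Fitting fewer distinct values than K is a degenerate-data
error.

**Cluster-to-tissue labelling.** On T2w the parenchyma is dark
(`lowest:n` rule, n = 3 of 7 by convention); on fat-suppressed pre-contrast
frames it is bright (`highest:n`).  A fixed cluster count is, however, the
step that practitioners adjust per case at density extremes — with very low
or very high density the number of clusters falling on the parenchymal
side of the intensity gap changes.  The pipeline therefore defaults to the
`gap` rule: split the ascending centroids at the largest inter-centroid
gap and label the dark (T2w) or bright (DCE) side as parenchyma.  This is
the automated analogue of per-case fine-tuning and is exact on bimodal
data; the fixed-count rules and explicit cluster sets remain available as
overrides.

**BPE guards.** Parenchyma voxels whose pre-contrast intensity falls below
1% of the parenchymal pre-contrast median are dropped from the map (the
ratio is undefined as the denominator approaches zero) and counted in a QC
field.  Regions of failed fat suppression are removed through an explicit
exclusion mask before the parenchyma fit.

**Statistics.** Repeatability CV is `(σ/μ)·100%` per subject with sample
(n−1) standard deviations, pooled as the root-mean-square across subjects
(reduces to the single-subject formula at n = 1).  Bland–Altman uses
Δ = right − left, `RPC = 1.96 · SD(Δ)`, limits of agreement bias ± RPC.
Mann–Whitney and Wilcoxon p-values are exact for combined n ≤ 12 — computed
from the full permutation distribution (label enumeration for
Mann–Whitney; a subset-sum count over doubled mid-ranks for Wilcoxon, which
is exhaustive in effect) — and tie-corrected normal approximations above.
All p-values are two-sided at the conventional 0.05 level; multiplicity
correction (Holm) is available but off by default.  The group-comparison
table applies a Shapiro–Wilk screen to choose t-test vs Mann–Whitney per
metric, overridable per metric.  The kurtosis regression is OLS on
`[1, age, risk, age·risk]` with t-based 95% CIs.

## The phantom: what it emulates, and what it does not

Each synthetic case comprises bilateral hemi-ellipsoid breasts (semi-axes
≈ 26 × 60 × 26 mm) on a chest-wall slab, a skin rind defined as a
ball-erosion shell (2 voxels by default), and a connected lobulated FGT
region thresholded from a smooth seeded field at the exact per-breast
quantile, so the ground-truth MRBD equals the voxel-count ratio by
construction.  Default grid 64 × 96 × 32 at 2 mm isotropic — small enough
for seconds-scale tests while preserving 3D morphology.

Tissue intensities use bounded uniform textures (fat 200 ± 4%, FGT
100 ± 10%, muscle 40, skin 175 on T2w), which guarantees the
region-growing margins analytically.  The DCE series is generated through
the steady-state spoiled-gradient-echo equation
`S = s0 sin(FA)(1−E1)/(1−cos(FA)E1)`, `E1 = exp(−TR·R1)`, with TR 4.24 ms,
FA 12°, parenchymal R1 = 0.7 s⁻¹ (T1 ≈ 1.4 s at 3 T) and frames every
59.1 s.  Per-voxel peak enhancement is drawn from a log-normal
parameterised to hit the configured median and IQR (defaults 15% and 14
points, typical of screening cohorts) — strictly positive and right-skewed,
as parenchymal enhancement is.  Post-contrast targets are realised by
inverting the SPGR equation for R1 and re-evaluating it, so targets beyond
the sequence's dynamic range (`S ≥ s0 sin FA`) raise a saturation error
rather than silently clipping.  Type I (persistent) kinetics rise as a
saturating exponential with the maximum at the final frame; a plateau
variant peaks mid-series.  Fat suppression leaves a 3% residual, and an
optional failure patch of unsuppressed, non-enhancing fat exercises the
exclusion path.  A smooth quadratic multiplicative bias field (amplitude
5% by default) and additive Gaussian noise (σ = 2% of mean tissue signal)
are applied last; with `symmetric=True` (default) textures and enhancement
are mirrored left/right so inter-breast agreement has a known truth.

Not modelled: coil sensitivity profiles beyond the polynomial field,
cardiac/respiratory motion and ghosting, parallel-imaging artefacts,
Rician magnitude bias (noise is Gaussian by design so recovery oracles
stay exact), partial-volume blur at tissue boundaries, and contrast-agent
pharmacokinetics (enhancement is parameterised directly in % terms because
tissue T1 and relaxivity values are not part of the measurement contract).
Consequently, passing recovery tests demonstrates the correctness and
internal consistency of the implementation under idealised contrast — not
the clinical accuracy of the segmentations on real scans, where
partial-volume effects, motion and operator choices dominate the error
budget (real-world inter-user CVs of 8–14% are typical for these metrics).

## Numerical and design choices

- Quantiles everywhere use linear interpolation between order statistics
  (numpy default), pinned for bit-reproducibility.
- Mask resampling between the T2w and DCE grids is nearest-neighbour in
  world coordinates: it preserves booleans exactly, is idempotent, and
  avoids the unstated threshold a linear-interpolation transfer would need.
  An identity world mapping between sequences is assumed (co-registered
  acquisition).
- Skewness/kurtosis on a zero-variance sample are undefined: reported as
  NaN with a flag, while quantiles are still returned.
- Per-subject seeds derive from the cohort seed and subject id (CRC32), so
  subject results do not depend on cohort ordering; identical config + seed
  is bit-reproducible end to end.
- Cohort runs use a skip-and-log failure policy: one unreadable subject is
  recorded and skipped, never aborting the cohort.
- Erosion radius, tolerance, cluster count, selection rules, denominator
  floor and bias order are all surfaced in `RunConfig`; defaults are chosen
  once for the phantom's acquisition-like geometry and documented above.

## Known limitations

- The `lowest:3`/`highest:3` fixed-count labelling is not reliable on
  strongly bimodal data at density extremes (the reason the `gap` default
  exists); on real multi-tissue continua the fixed count is the
  conventional choice and the gap rule may split within a tissue class.
- The polynomial bias model cannot represent fields rougher than its
  degree; raise `bias_order` or inject an external estimator via the hook
  for such data.
- The exact rank tests enumerate only up to combined n = 12 (beyond that
  the normal approximation is used), matching small-cohort repeatability
  designs rather than large trials.
- Region growing assumes the breast is separable from the chest wall by
  intensity at the chosen tolerance; on data where muscle and parenchyma
  overlap in intensity the erosion radius is the only chest-wall control.
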