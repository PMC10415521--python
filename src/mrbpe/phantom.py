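"""Digital breast phantoms: paired T2w-like and DCE datasets with ground truth.

The phantom emulates the structure the analysis pipeline assumes, at a
desk-test scale:

* bilateral hemi-ellipsoid breasts on an anterior chest-wall slab, with a
  thin skin rind (a ``ball(skin_vox)``-erosion shell of the full breast);
* a connected, lobulated central fibro-glandular (FGT) region hitting a
  configurable volume fraction of the breast;
* T2w contrast with FGT darker than fat, and a fat-suppressed DCE series
  (1 pre-contrast + ``n_post`` post-contrast frames at ``dt_s`` spacing,
  59.1 s by default) in which only the parenchyma enhances;
* type I (persistent) enhancement kinetics, realised voxelwise through the
  spoiled-gradient-echo (SPGR) signal equation so that signal saturation of
  the sequence's dynamic range is part of the model;
* a smooth low-order polynomial multiplicative bias field and additive
  Gaussian noise, both applied last.

Every generated case carries a :class:`PhantomGroundTruth` with the true
masks, bias field and per-voxel enhancement, enabling parameter-recovery
tests of the whole pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage.morphology import ball

from .grids import DceSeries, VolumeGrid

# Tissue intensity model (arbitrary units, T2w non-fat-suppressed).
# Textures are uniform (bounded), so region-growing margins are guaranteed.
T2_FAT, T2_FGT, T2_MUSCLE, T2_SKIN = 200.0, 100.0, 40.0, 175.0
TEX_FAT, TEX_FGT, TEX_MUSCLE, TEX_SKIN = 0.04, 0.10, 0.10, 0.04
# DCE pre-contrast model: fat suppression leaves a small residual signal.
DCE_FAT_RESIDUAL = 0.03   # of parenchymal signal
DCE_MUSCLE_LEVEL = 0.10
DCE_FAILURE_LEVEL = 1.5   # unsuppressed fat, relative to parenchymal signal
DCE_TEX_FGT, DCE_TEX_OTHER = 0.05, 0.04
R1_PARENCHYMA_PER_S = 0.7  # ~T1 of 1.4 s at 3 T
SPGR_S0 = 1000.0

_Z75 = 0.6744897501960817  # 75th percentile of the standard normal


class GeometryError(ValueError):
    """The requested tissue layout cannot be realised on this grid."""


class SaturationError(ValueError):
    """A target signal exceeds the SPGR dynamic range (S >= s0*sin FA)."""


# ---------------------------------------------------------------------------
# SPGR signal model


@dataclass(frozen=True)
class SpgrParams:
    """Spoiled gradient-echo steady-state parameters."""

    tr_ms: float = 4.24
    fa_deg: float = 12.0
    r1_per_s: float = R1_PARENCHYMA_PER_S
    s0: float = SPGR_S0

    def __post_init__(self) -> None:
        if self.tr_ms <= 0:
            raise ValueError("tr_ms must be > 0")
        if not (0 < self.fa_deg < 90):
            raise ValueError("fa_deg must lie in (0, 90)")


def spgr_signal(p: SpgrParams):
    """Steady-state SPGR signal S = s0 sin(FA) (1 - E1) / (1 - cos(FA) E1).

    ``E1 = exp(-TR * R1)``.  The signal is zero at R1 = 0, strictly
    increasing in R1, and saturates at ``s0 sin(FA)``.
    """
    r1 = np.asarray(p.r1_per_s, dtype=float)
    fa = math.radians(p.fa_deg)
    e1 = np.exp(-(p.tr_ms / 1000.0) * r1)
    out = p.s0 * math.sin(fa) * (1.0 - e1) / (1.0 - math.cos(fa) * e1)
    return float(out) if np.isscalar(p.r1_per_s) else out


def spgr_r1_for_signal(signal, tr_ms: float, fa_deg: float, s0: float):
    """Invert the SPGR equation for R1 (1/s) given a target signal.

    Raises
    ------
    SaturationError
        If any target is at or beyond the saturation plateau
        ``s0 sin(FA)`` — i.e. outside the sequence's dynamic range.
    """
    fa = math.radians(fa_deg)
    g = np.asarray(signal, dtype=float) / (s0 * math.sin(fa))
    if np.any(g < 0):
        raise ValueError("signal must be >= 0")
    if np.any(g >= 1.0):
        raise SaturationError(
            "target signal saturates the SPGR dynamic range "
            f"(max {float(np.max(g)) * 100:.1f}% of s0*sin FA)"
        )
    e1 = (1.0 - g) / (1.0 - g * math.cos(fa))
    r1 = -np.log(e1) / (tr_ms / 1000.0)
    return float(r1) if np.isscalar(signal) else r1


# ---------------------------------------------------------------------------
# Enhancement kinetics


def kinetic_curve(shape: str, t_index: int, n_post: int, peak_fraction: float = 1.0):
    """Fraction of peak enhancement reached at a dynamic frame.

    ``t_index`` counts frames (0 = pre-contrast, ``n_post`` = final frame).

    ``type1_persistent`` rises monotonically through the whole series
    (saturating-exponential uptake, maximum at the final frame);
    ``plateau`` ramps linearly to its peak at the mid-series frame and stays
    flat thereafter.
    """
    if not (0 <= t_index <= n_post):
        raise ValueError(f"t_index {t_index} outside [0, {n_post}]")
    if n_post < 1:
        raise ValueError("n_post must be >= 1")
    t = t_index / n_post
    if shape == "type1_persistent":
        base = (1.0 - math.exp(-3.0 * t)) / (1.0 - math.exp(-3.0))
    elif shape == "plateau":
        t_peak = math.ceil(n_post / 2) / n_post
        base = min(1.0, t / t_peak)
    else:
        raise ValueError(f"unknown kinetic shape {shape!r}")
    return peak_fraction * base


# ---------------------------------------------------------------------------
# Configuration and ground truth


@dataclass(frozen=True)
class PhantomConfig:
    """Generative parameters of one synthetic case.

    Defaults describe a plausible screening subject: breast density near the
    cohort medians (~12%), a small smooth bias field, mild noise, and
    persistent (type I) enhancement with a median of 15% and an
    inter-quartile spread of 14 percentage points at the final frame.
    """

    grid_shape: tuple[int, int, int] = (64, 96, 32)
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    fgt_fraction: float = 0.125
    bias_amplitude: float = 0.05
    noise_sigma: float = 0.02
    enhancement_median_pct: float = 15.0
    enhancement_spread_pct: float = 14.0
    kinetic_shape: str = "type1_persistent"
    n_post: int = 6
    dt_s: float = 59.1
    fat_sup_failure_fraction: float = 0.0
    rng_seed: int = 0
    # geometry knobs
    skin_vox: int = 2
    symmetric: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.fgt_fraction < 1):
            raise ValueError("fgt_fraction must lie in (0, 1)")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.n_post < 1:
            raise ValueError("n_post must be >= 1")
        if self.dt_s <= 0:
            raise ValueError("dt_s must be > 0")
        if self.enhancement_median_pct <= 0:
            raise ValueError("enhancement_median_pct must be > 0")
        if self.enhancement_spread_pct < 0:
            raise ValueError("enhancement_spread_pct must be >= 0")


@dataclass
class PhantomGroundTruth:
    """Generative truth emitted with every phantom."""

    breast_mask_left: np.ndarray
    breast_mask_right: np.ndarray
    fgt_mask: np.ndarray
    skin_mask: np.ndarray
    fat_sup_failure_mask: np.ndarray
    true_bias_field: np.ndarray
    true_voxel_enhancement_pct: np.ndarray
    true_fgt_volume_cc: float
    true_mrbd_pct: float
    affine: np.ndarray
    config: PhantomConfig

    @property
    def breast_mask(self) -> np.ndarray:
        return self.breast_mask_left | self.breast_mask_right


def _affine(cfg: PhantomConfig) -> np.ndarray:
    """RAS+ affine with the left-right (x) and z axes centred on the grid."""
    dx, dy, dz = cfg.voxel_size_mm
    nx, _, nz = cfg.grid_shape
    a = np.eye(4)
    a[0, 0], a[1, 1], a[2, 2] = dx, dy, dz
    a[0, 3] = -dx * (nx - 1) / 2.0
    a[2, 3] = -dz * (nz - 1) / 2.0
    return a


def _world_grids(cfg: PhantomConfig, affine: np.ndarray):
    idx = [np.arange(n, dtype=float) for n in cfg.grid_shape]
    ii, jj, kk = np.meshgrid(*idx, indexing="ij")
    x = affine[0, 0] * ii + affine[0, 3]
    y = affine[1, 1] * jj + affine[1, 3]
    z = affine[2, 2] * kk + affine[2, 3]
    return x, y, z


def _mirror_x(a: np.ndarray) -> np.ndarray:
    return a[::-1, ...].copy()


def lognormal_for_median_iqr(median: float, iqr: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with the given median and inter-quartile
    range: sigma = asinh(IQR / 2 median) / z_{0.75}."""
    if median <= 0:
        raise ValueError("median must be > 0")
    sigma = math.asinh(iqr / (2.0 * median)) / _Z75 if iqr > 0 else 0.0
    return math.log(median), sigma


def generate_phantom(
    cfg: PhantomConfig,
) -> tuple[VolumeGrid, DceSeries, PhantomGroundTruth]:
    """Generate one synthetic case: (T2w volume, DCE series, ground truth).

    Identical config (including ``rng_seed``) gives bit-identical output.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    affine = _affine(cfg)
    x, y, z = _world_grids(cfg, affine)
    shape = cfg.grid_shape
    voxvol = float(np.prod(cfg.voxel_size_mm))

    # ---- geometry (right breast, then mirror) -----------------------------
    extent_x = cfg.voxel_size_mm[0] * shape[0]
    cx = extent_x / 4.0                       # right-breast centre (world x>0)
    ax_ = 0.40 * extent_x / 2.0               # semi-axes, mm
    ay_ = 60.0
    az_ = min(26.0, 0.80 * cfg.voxel_size_mm[2] * shape[2] / 2.0)
    y_slab = 20.0                             # chest-wall slab: y < y_slab

    rho2 = ((x - cx) / ax_) ** 2 + ((y - y_slab) / ay_) ** 2 + (z / az_) ** 2
    full_r = (rho2 <= 1.0) & (y >= y_slab)
    if not full_r.any():
        raise GeometryError("breast ellipsoid does not intersect the grid")
    interior_r = ndimage.binary_erosion(full_r, structure=ball(cfg.skin_vox))
    if not interior_r.any():
        raise GeometryError("skin erosion annihilated the breast interior")
    skin_r = full_r & ~interior_r

    # lobulated FGT field: ellipsoidal distance from the breast core plus a
    # smooth seeded perturbation; threshold at the exact per-breast quantile
    phases = rng.uniform(0, 2 * np.pi, size=3)
    lam = 25.0  # lobulation wavelength, mm
    pert = (
        np.cos(2 * np.pi * np.abs(x - cx) / lam + phases[0])
        + np.cos(2 * np.pi * y / lam + phases[1])
        + np.cos(2 * np.pi * z / lam + phases[2])
    ) / 3.0
    gfield = np.sqrt(
        ((x - cx) / (0.8 * ax_)) ** 2
        + ((y - (y_slab + 0.45 * ay_)) / (0.8 * ay_)) ** 2
        + (z / (0.8 * az_)) ** 2
    ) + 0.35 * pert

    n_int = int(interior_r.sum())
    k_fgt = int(round(cfg.fgt_fraction * n_int))
    if k_fgt < 1:
        raise GeometryError(
            f"fgt_fraction {cfg.fgt_fraction} yields no voxels in a breast "
            f"of {n_int} voxels"
        )
    gv = gfield[interior_r]
    order = np.argsort(gv, kind="stable")
    sel = np.zeros(n_int, dtype=bool)
    sel[order[:k_fgt]] = True
    fgt_r = np.zeros(shape, dtype=bool)
    fgt_r[interior_r] = sel

    # fat-suppression failure patch: k nearest fat voxels to a sub-surface site
    fail_r = np.zeros(shape, dtype=bool)
    if cfg.fat_sup_failure_fraction > 0:
        k_fail = int(round(cfg.fat_sup_failure_fraction * n_int))
        fat_r = interior_r & ~fgt_r
        if k_fail > int(fat_r.sum()):
            raise GeometryError("fat_sup_failure_fraction exceeds the fat volume")
        if k_fail >= 1:
            d2 = (x - cx) ** 2 + (y - (y_slab + 0.8 * ay_)) ** 2 + z**2
            dv = np.where(fat_r, d2, np.inf).ravel()
            idx = np.argsort(dv, kind="stable")[:k_fail]
            fail_r.ravel()[idx] = True

    # ---- per-voxel random fields (drawn once, mirrored for symmetry) ------
    tex_t2 = rng.uniform(-1.0, 1.0, size=shape)
    tex_dce = rng.uniform(-1.0, 1.0, size=shape)
    mu_e, sig_e = lognormal_for_median_iqr(
        cfg.enhancement_median_pct, cfg.enhancement_spread_pct
    )
    enh_field = np.exp(rng.normal(mu_e, sig_e, size=shape))

    if cfg.symmetric:
        tex_t2_l, tex_dce_l, enh_l = (
            _mirror_x(tex_t2), _mirror_x(tex_dce), _mirror_x(enh_field))
        interior_l, skin_l, fgt_l, fail_l = (
            _mirror_x(interior_r), _mirror_x(skin_r),
            _mirror_x(fgt_r), _mirror_x(fail_r))
    else:
        tex_t2_l = rng.uniform(-1.0, 1.0, size=shape)
        tex_dce_l = rng.uniform(-1.0, 1.0, size=shape)
        enh_l = np.exp(rng.normal(mu_e, sig_e, size=shape))
        interior_l, skin_l, fgt_l, fail_l = (
            _mirror_x(interior_r), _mirror_x(skin_r),
            _mirror_x(fgt_r), _mirror_x(fail_r))

    left_half = x < 0
    tex_t2 = np.where(left_half, tex_t2_l, tex_t2)
    tex_dce = np.where(left_half, tex_dce_l, tex_dce)
    enh_field = np.where(left_half, enh_l, enh_field)
    interior = interior_r | interior_l
    skin = skin_r | skin_l
    fgt = fgt_r | fgt_l
    fail = fail_r | fail_l
    slab = y < y_slab
    fat = interior & ~fgt

    # ---- T2w (non-fat-suppressed): FGT darker than fat --------------------
    t2w = np.zeros(shape)
    t2w[slab] = T2_MUSCLE * (1 + TEX_MUSCLE * tex_t2[slab])
    t2w[fat] = T2_FAT * (1 + TEX_FAT * tex_t2[fat])
    t2w[fgt] = T2_FGT * (1 + TEX_FGT * tex_t2[fgt])
    t2w[skin] = T2_SKIN * (1 + TEX_SKIN * tex_t2[skin])

    # ---- DCE series through the SPGR model --------------------------------
    s_par = spgr_signal(SpgrParams())           # parenchymal pre-contrast level
    pre = np.zeros(shape)
    pre[slab] = DCE_MUSCLE_LEVEL * s_par * (1 + DCE_TEX_OTHER * tex_dce[slab])
    pre[fat | skin] = DCE_FAT_RESIDUAL * s_par * (
        1 + DCE_TEX_OTHER * tex_dce[fat | skin])
    pre[fgt] = s_par * (1 + DCE_TEX_FGT * tex_dce[fgt])
    pre[fail] = DCE_FAILURE_LEVEL * s_par * (1 + DCE_TEX_OTHER * tex_dce[fail])

    enh_pct = np.where(fgt, enh_field, 0.0)
    n_frames = cfg.n_post + 1
    frames = np.empty(shape + (n_frames,))
    frames[..., 0] = pre
    s0_fgt = pre[fgt]
    for t in range(1, n_frames):
        k_t = kinetic_curve(cfg.kinetic_shape, t, cfg.n_post)
        target = s0_fgt * (1.0 + enh_pct[fgt] / 100.0 * k_t)
        # realise the target through the SPGR signal equation (round trip
        # enforces the sequence's dynamic range)
        r1 = spgr_r1_for_signal(target, 4.24, 12.0, SPGR_S0)
        vol = pre.copy()
        vol[fgt] = spgr_signal(replace(SpgrParams(), r1_per_s=r1))
        frames[..., t] = vol

    # ---- bias field and noise, applied last -------------------------------
    nxyz = [(c - c.mean()) / (np.ptp(c) / 2 + 1e-12) for c in (x, y, z)]
    coeffs = rng.normal(size=9)
    q = (coeffs[0] * nxyz[0] + coeffs[1] * nxyz[1] + coeffs[2] * nxyz[2]
         + coeffs[3] * nxyz[0] * nxyz[1] + coeffs[4] * nxyz[0] * nxyz[2]
         + coeffs[5] * nxyz[1] * nxyz[2]
         + coeffs[6] * nxyz[0] ** 2 + coeffs[7] * nxyz[1] ** 2
         + coeffs[8] * nxyz[2] ** 2)
    breast_all = interior | skin
    q -= q[breast_all].mean()
    peak = np.max(np.abs(q[breast_all]))
    bias = 1.0 + (cfg.bias_amplitude * q / peak if peak > 0 else 0.0)

    t2w *= bias
    frames *= bias[..., None]
    if cfg.noise_sigma > 0:
        t2w += rng.normal(size=shape) * cfg.noise_sigma * t2w[breast_all | slab].mean()
        dce_scale = cfg.noise_sigma * frames[..., 0][interior].mean()
        frames += rng.normal(size=frames.shape) * dce_scale

    times = np.arange(n_frames, dtype=float) * cfg.dt_s
    truth = PhantomGroundTruth(
        breast_mask_left=interior_l,
        breast_mask_right=interior_r,
        fgt_mask=fgt,
        skin_mask=skin,
        fat_sup_failure_mask=fail,
        true_bias_field=bias,
        true_voxel_enhancement_pct=enh_pct,
        true_fgt_volume_cc=float(fgt.sum()) * voxvol / 1000.0,
        true_mrbd_pct=100.0 * float(fgt.sum()) / float(interior.sum()),
        affine=affine,
        config=cfg,
    )
    return (
        VolumeGrid(t2w, affine.copy()),
        DceSeries(frames, affine.copy(), times),
        truth,
    )


def save_phantom_case(out_dir, t2w: VolumeGrid, dce: DceSeries,
                      truth: PhantomGroundTruth) -> dict:
    """Write one phantom case to a directory (NIfTI + JSON sidecar).

    Emits the T2w volume, the 4D DCE series with a frame-times sidecar,
    uint8 truth masks, the true bias field, and a JSON sidecar with the
    config and the scalar truths.  Returns the path map.
    """
    import json
    from pathlib import Path

    from .grids import write_mask_volume, write_series, write_volume

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "t2w": out / "t2w.nii.gz",
        "dce": out / "dce.nii.gz",
        "times": out / "dce_times.json",
        "breast_mask_left": out / "truth_breast_left.nii.gz",
        "breast_mask_right": out / "truth_breast_right.nii.gz",
        "fgt_mask": out / "truth_fgt.nii.gz",
        "fat_sup_failure_mask": out / "truth_fat_sup_failure.nii.gz",
        "true_bias_field": out / "truth_bias.nii.gz",
        "true_enhancement": out / "truth_enhancement_pct.nii.gz",
        "sidecar": out / "truth.json",
    }
    write_volume(t2w, paths["t2w"])
    write_series(dce, paths["dce"], paths["times"])
    aff = truth.affine
    write_mask_volume(truth.breast_mask_left, aff, paths["breast_mask_left"])
    write_mask_volume(truth.breast_mask_right, aff, paths["breast_mask_right"])
    write_mask_volume(truth.fgt_mask, aff, paths["fgt_mask"])
    write_mask_volume(truth.fat_sup_failure_mask, aff,
                      paths["fat_sup_failure_mask"])
    write_volume(VolumeGrid(truth.true_bias_field, aff.copy()),
                 paths["true_bias_field"])
    write_volume(VolumeGrid(truth.true_voxel_enhancement_pct, aff.copy()),
                 paths["true_enhancement"])
    cfg = truth.config
    sidecar = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in cfg.__dict__.items()},
        "true_fgt_volume_cc": truth.true_fgt_volume_cc,
        "true_mrbd_pct": truth.true_mrbd_pct,
    }
    with open(paths["sidecar"], "w") as fh:
        json.dump(sidecar, fh, indent=2)
    return {k: str(v) for k, v in paths.items()}
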