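# mrbpe — quantitative breast density and background parenchymal enhancement from MRI

`mrbpe` is a Python toolkit for quantitative analysis of standard clinical
breast MRI exams: a non-fat-suppressed T2-weighted volume plus a dynamic
contrast-enhanced (DCE) T1-weighted series (one pre-contrast and several
post-contrast frames).  It is aimed at researchers studying imaging
biomarkers of breast-cancer risk, where two quantities are of central
interest:

* **MRBD (MRI breast density)** — the percentage of the whole-breast volume
  occupied by fibro-glandular tissue (FGT):
  `MRBD (%) = 100 · |FGT| / |breast|`, with the fibro-glandular volume
  `V_FGT = |FGT| · v` (voxel volume `v`).
* **BPE (background parenchymal enhancement)** — the post-contrast signal
  increase of normal parenchyma, quantified voxelwise as

  ```
  BPE (%) = 100 · (I_MTP − I_FTP) / I_FTP
  ```

  where `I_FTP` is the intensity on the first (pre-contrast) time point and
  `I_MTP` on the maximum-enhancement time point — the post-contrast frame
  with the highest median intensity over the segmented parenchyma.  The BPE
  distribution over one breast is summarised by its median, quartiles,
  skewness `g1 = m3 / m2^(3/2)` and (non-excess) kurtosis `b2 = m4 / m2²`.

The processing chain is semi-automatic and mirrors standard practice:

1. **Whole-breast masking** — seeded 3D region growing on the T2w volume
   (26-connectivity, self-consistent region-mean criterion), hole filling,
   and ball erosion to strip the skin rind and chest-wall interface;
   left/right split at the mid-sagittal world plane from the affine.
2. **Bias-field correction** — removal of a smooth multiplicative
   (coil-sensitivity) field, modelled as a low-order log-domain polynomial
   with per-tissue intensity offsets.
3. **FGT segmentation** — fuzzy c-means clustering of the masked
   intensities into K = 7 clusters per breast, with a cluster-to-tissue
   labelling rule (dark clusters on T2w; bright clusters on fat-suppressed
   pre-contrast frames), then density metrics.
4. **BPE mapping** — parenchyma segmentation on the *pre-contrast* DCE
   frame (no enhancement presumed), MTP selection, the voxelwise map and
   its distribution summary.
5. **Statistics** — repeatability coefficients of variation `(σ/μ)·100%`,
   Bland–Altman right/left agreement (`RPC = 1.96 · SD(Δ)`), exact
   small-sample rank tests, Spearman correlation, and a multivariable OLS
   of BPE kurtosis on age, risk group and their interaction.

Because clinical cohorts cannot be redistributed, the package ships a
**digital phantom generator**: bilateral hemi-ellipsoid breasts with skin
and chest wall, a configurable FGT fraction, type I (persistent)
enhancement kinetics realised through the spoiled-gradient-echo signal
equation (TR 4.24 ms, FA 12°, frame spacing 59.1 s), a polynomial bias
field and Gaussian noise — all with exported ground truth, so every stage
can be validated by parameter recovery.

## Worked example

```python
from mrbpe import PhantomConfig, generate_phantom
from mrbpe.pipeline import RunConfig, analyse_subject_volumes

cfg = PhantomConfig(fgt_fraction=0.2, enhancement_median_pct=18.0, rng_seed=42)
t2w, dce, truth = generate_phantom(cfg)

records = analyse_subject_volumes(t2w, dce, RunConfig(), "demo")
right = next(r for r in records if r["laterality"] == "right")
for key in ("mrbd_pct", "fgt_volume_cc", "bpe_median_pct", "bpe_kurtosis",
            "mtp_index"):
    print(key, "=", right[key])
```

prints

```
mrbd_pct = 20.0
fgt_volume_cc = 10.368
bpe_median_pct = 18.96797...
bpe_kurtosis = 9.23834...
mtp_index = 6
```

The phantom was built with a 20% FGT fraction and the pipeline recovers
`mrbd_pct = 20.0` exactly; the recovered BPE median (18.97%) sits within
0.1 points of the generative truth for this seed (18.90%), and the MTP is
the final frame, as persistent (type I) kinetics require.  `fgt_volume_cc`
is the fibro-glandular volume of the right breast in cc; the kurtosis
reflects the right-skewed log-normal enhancement distribution the phantom
draws.

The same chain is available from the shell:

```bash
mrbpe phantom --seed 42 --out case/
mrbpe mask --t2w case/t2w.nii.gz --out masks/
mrbpe bias-correct --in case/t2w.nii.gz --mask masks/breast_bilateral.nii.gz --out bias/
mrbpe segment-fgt --in bias/corrected.nii.gz --mask masks/breast_right.nii.gz \
      --laterality right --select gap --out seg/
mrbpe bpe --dce case/dce.nii.gz --times case/dce_times.json \
      --breast-mask masks/breast_right.nii.gz --laterality right \
      --select gap-high --out bpe/
mrbpe run-all --manifest manifest.json --seed 0 --out cohort/   # whole cohorts
mrbpe stats --results cohort/results.csv --out stats/
```

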