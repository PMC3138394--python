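# subvolreg

Subvolume-based rigid registration of repeat prostate MR series, with a
center-of-mass precision analysis and a synthetic pelvic phantom for
validation.

## The problem

In image-guided radiotherapy of localized prostate cancer, repeat MR
imaging is used for patient set-up and treatment-response assessment.
Rigid registration of the whole pelvis aligns the bony anatomy and body
contour — but the prostate moves relative to the bone (dominantly in the
anterior-posterior direction, driven by rectum and bladder filling), so
whole-volume registration leaves the *target* misaligned by several
millimetres. A non-invasive alternative to implanted fiducial markers is
to restrict the registration metric to a subvolume around the prostate, so
that the recovered rigid transform — directly interpretable as a couch
shift — aligns the gland itself.

This package implements that protocol and the analysis used to choose the
subvolume size:

* **Registration volumes.** The delineated prostate gland `RV0` and its
  isotropic 3D margin expansions `RV1`/`RV2`/`RV3` (1/2/3 cm by default,
  computed with a spacing-aware Euclidean distance transform), plus the
  full image grid.
* **Masked rigid registration.** Mean-square intensity metric evaluated
  only at mask voxels,

  $$M(T) = \frac{1}{N}\sum_{x \in \mathrm{RV}} \bigl[\,m(x) - f(T(x))\,\bigr]^2,$$

  where the moving image $m$ is the reference (pre-treatment) series
  carrying the delineation, $f$ is a follow-up series, and $T$ is a rigid
  transform parametrized by a versor (unit quaternion vector part
  $v_1,v_2,v_3$) and translation $(t_x,t_y,t_z)$ about the mask's center
  of mass. Optimization is regular-step gradient descent with an exact
  analytic gradient: a fixed step against the scale-weighted gradient,
  step halved whenever the gradient direction reverses, convergence when
  the step underflows.
* **Precision analysis.** For each registered pair, the residual
  $\Delta = \mathrm{COM}(\text{target prostate}) -
  T(\mathrm{COM}(\text{reference prostate}))$ resolved along right-left /
  anterior-posterior / cranio-caudal axes; per-volume sample SDs of the
  signed components and the norm, one-sided F-tests of variance reduction,
  per-pair norm improvements over full-volume registration, and the
  fraction of pairs for which each volume is most precise.
* **Synthetic phantom.** An analytic pelvic phantom (body, bone shells,
  bladder, rectum, textured prostate) with exactly known rigid prostate
  motion, variable rectum/bladder appearance and Rician MR noise, so the
  whole pipeline is testable against ground truth.

## Worked example

```python
import subvolreg as sv

config = sv.StudyConfig(n_patients=2, seed=7)
report = sv.run_study(config)
print(report.per_axis_stats[("sd",)].round(2))
print("best volume:", report.best_volume_frequency)
```

prints

```
                     d_rl_mm  d_ap_mm  d_cc_mm  norm_mm
registration_volume
RV0                     0.50     0.33     0.27     0.13
RV1                     0.36     1.76     2.13     2.09
RV2                     0.95     2.76     2.78     2.52
RV3                     0.83     3.49     3.56     3.11
full                    0.81     5.06     2.49     2.63
best volume: {'RV0': 0.83, 'RV1': 0.17, 'RV2': 0.0, 'RV3': 0.0, 'full': 0.0}
```

Read: full-volume registration leaves an anterior-posterior residual SD of
5.1 mm — it tracked the static bone, so the residual is simply the
injected prostate motion (AP SD 4 mm, plus rotation leverage) — while
prostate-only registration reduces it to 0.3 mm; the margin volumes fall
in between, degrading as the mask admits more of the changing rectum and
bladder, and `RV0` is the most precise volume for 83 % of the image pairs.

The same pipeline runs from the shell:

```bash
subvolreg study run --synthetic --patients 10 --seed 7 --out results/
subvolreg phantom generate --patients 1 --seed 4 --out phantoms/
subvolreg masks expand --margin-mm 10 phantoms/P00/prostate_00.nii.gz rv1.nii.gz
subvolreg register --fixed f.nii.gz --moving m.nii.gz --mask rv0.nii.gz --out reg.json
```

A study writes `report.json`, `distances.csv`, `table1.csv` (norm
improvements and variance-test p-values per volume), `figure2.png`
(per-axis mean ± SD bars) and per-registration transform JSONs.

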