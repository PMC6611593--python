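# cstpm — compressed-sensing tissue phase mapping

`cstpm` reconstructs and analyses accelerated cardiac **tissue phase
mapping** (TPM) MRI: cine phase-contrast imaging in which every myocardial
pixel carries a velocity measurement in the phase of the complex signal.
Fully sampled TPM of a small-animal heart takes 10–20 minutes per slice;
this package implements the compressed-sensing route to cutting that time
by 2–16×, plus the machinery to quantify what the acceleration costs in
measured velocity and strain.

It is aimed at preclinical/cardiac MRI researchers who want a transparent,
fully testable reference implementation of the whole chain:

* **Mask design** — centre-weighted random phase-encode undersampling with
  a guaranteed fully-sampled centre block (a quarter of acquired lines)
  and incoherence screening by the sidelobe-to-peak ratio of the mask PSF.
* **Reconstruction** — per-coil, per-encoding iterative soft-thresholding
  solving `min ‖Tx‖₁ s.t. ‖Rx − k‖₂ ≤ ε` with a pixelwise temporal
  Fourier sparsifying transform `T`, data-consistency reinsertion each
  iteration, and a residual-plateau stopping rule
  (`|r_i − r_{i−1}| ≤ 0.01·|r_1 − r_2|`, between 15 and 50 iterations).
* **Velocity decoding** — least-squares inversion of
  `φ_e = φ₀ + (π/venc)·M_e·v` for any full-rank multipoint encoding
  scheme (two-point, balanced four-point and nine-point shipped), with
  magnitude-weighted coil combination and polynomial background-phase
  correction.
* **Kinematics** — global and 6-segment radial/longitudinal velocities and
  circumferential strain from RK2 Lagrangian tracking of a midwall
  contour, in cm/s and %strain.
* **Validation** — retrospective undersampling at factors {2, 4, 8, 16}
  with nonparametric Bland-Altman agreement (median bias, 2.5/97.5
  percentile limits of agreement) and Wilcoxon rank-sum group comparison
  with Bonferroni correction.
* **Phantom** — a synthetic contracting annulus with closed-form motion
  (`s(t) = 1 − a·sin²(πt/T)`, peak strain exactly −100·a %strain),
  forward-encoded into multi-coil, multi-encoding k-space, so the entire
  pipeline is testable without any scanner data.

See `docs/methods.md` for the full model description and numerical
choices.

## Worked example

Simulate a phantom acquisition, undersample it 4×, reconstruct and
compare:

```python
import numpy as np
from cstpm import (PhantomSpec, ReconConfig, render_kspace, make_mask_set,
                   retrospective_undersample, cs_reconstruct,
                   magnitude_nrmse, retrospective_experiment)
from cstpm.evaluation import kinematics_from_images

data = render_kspace(PhantomSpec(matrix=64, n_frames=16, seed=1))
masks = make_mask_set(n_ky=64, us_factor=4, n_frames=16, n_encodings=4, seed=11)
und = retrospective_undersample(data.kspace, masks)
images, report = cs_reconstruct(und, masks, ReconConfig(lam=0.01))
ref = data.kspace.to_images()
print(f"iterations: {report.iterations_run} (converged={report.converged})")
print(f"NRMSE  CS: {magnitude_nrmse(images.data, ref.data):.4f}"
      f"   zero-filled: {magnitude_nrmse(und.to_images().data, ref.data):.4f}")

seg = data.segmentation()
res, _ = kinematics_from_images(images, data.spec.scheme, seg, data.contour_seeds)
print(f"peak global strain: {res.strain_circ_global.min():.2f} %strain")
```

prints

```
iterations: 42 (converged=True)
NRMSE  CS: 0.0367   zero-filled: 0.5495
peak global strain: -14.57 %strain
```

i.e. the 4× compressed-sensing reconstruction reduces the magnitude-image
error fifteen-fold relative to naive zero-filling, and the strain derived
from one quarter of the data lands close to the phantom's analytic
−15 %strain. A full agreement table across factors is one call
(`retrospective_experiment`) or one command away:

```bash
cstpm simulate --matrix 64 --frames 16 --seed 1 -o p.h5 --truth t.h5
cstpm evaluate p.h5 --truth t.h5 --factors 2,4,8,16 --seed 3 -o agreement.csv
```

`agreement.csv` holds bias and 95% limits of agreement for global and
regional radial velocity, longitudinal velocity and circumferential
strain at each factor; limits widen monotonically with acceleration while
biases stay small through 4×.

The CLI also provides `mask` (standalone mask sets), `recon`
(reconstruct a container, with per-iteration residual logging) and
`analyze` (kinematics CSV from a reconstructed container); all commands
write a `.provenance.json` next to their output.

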