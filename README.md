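# sipspect

Desk-scale simulation and evaluation of **sparse-view ^177^Lu SPECT with
synthetic intermediate projections (SIPs)**, carried through to kidney and
bone-marrow dosimetry.

Quantitative SPECT/CT after ^177^Lu therapy (DOTATATE, PSMA) needs several
imaging time points, and a 120-view acquisition takes 15–40 min per field of
view.  Acquiring only 30 views cuts that time by four but raises noise —
worst at late time points, and worst for bone-marrow dosimetry, where uptake
is low.  One remedy is to *inpaint* the missing views: train a convolutional
network to synthesise the three intermediate projections in each angular gap
of the sparse acquisition, then reconstruct the re-completed 120-view set.

`sipspect` provides every stage of that pipeline as a library plus CLI, with
synthetic digital phantoms standing in for patient data, so the whole chain
is reproducible from a seed:

| stage | module | what it does |
|---|---|---|
| phantoms | `sipspect.phantom` | abdominal phantoms: activity (Bq/ml), 208 keV µ-map, organ masks, biexponential organ kinetics C(t) = A₁e^(−λ₁t) + A₂e^(−λ₂t) |
| projector | `sipspect.projector` | rotation-based attenuated forward/back projection with depth-dependent Gaussian PSF (exact adjoint pair), Poisson noise, optional photon-sampling Monte Carlo mode |
| inpainting | `sipspect.sip` | 120→30 down-sampling (views 1, 5, …, 117), per-offset U-net-shaped networks (numpy, seeded, L1/L2 losses) and an angle-linear interpolation baseline, 30+90 reassembly |
| reconstruction | `sipspect.recon` | OSEM (default 10 iterations × 6 subsets; subsets=1 gives MLEM), calibration to Bq/ml |
| image quality | `sipspect.metrics` | NRMSE, NMAE, PSNR = 20·log₁₀(MAX/RMSE), global-moment SSIM |
| dosimetry | `sipspect.dosimetry` | recovery coefficients from a uniformly filled kidney VOI, 4-ml marrow sphere VOIs, vertebra→red-marrow scaling (÷0.57), biexponential fits, TIA = A₁/λ₁ + A₂/λ₂, local electron energy deposition (×0.65 marrow absorbed fraction) |
| statistics | `sipspect.evaluation` | Bland–Altman (pairwise-mean relative differences, 1.96·SD limits), OLS R², paired t-tests with Bonferroni (0.05/4 = 0.0125), repeated-measures ANOVA, and the end-to-end experiment driver |

## Worked example

```python
import numpy as np
import sipspect as sp
from sipspect.sip import downsample_projections, interpolation_sips, assemble_cusip_set
from sipspect.metrics import quality_report

phantom = sp.make_phantom(sp.PhantomConfig(shape=(48, 48, 32), kidney_volume_ml=80), seed=1)
geom = sp.AcquisitionGeometry(n_projections=120, matrix=(48, 32))

pt = sp.phantom_at_time(phantom, sp.DEFAULT_KINETICS, 168.0)   # day-7 count level
full = sp.add_poisson_noise(sp.forward_project(pt.activity, pt.mu_map, geom), seed=42)

sparse = downsample_projections(full)                           # 30 views
cusip = assemble_cusip_set(sparse, interpolation_sips(sparse))  # 30 + 90 inpainted

rec120 = sp.osem_reconstruct(full,   pt.mu_map, geom, 10, 6).values
rec30  = sp.osem_reconstruct(sparse, pt.mu_map, geom, 10, 6).values
reccu  = sp.osem_reconstruct(cusip,  pt.mu_map, geom, 10, 6).values

print("30P  :", quality_report(rec30, rec120))
print("CUSIP:", quality_report(reccu, rec120))
```

prints (day-7, the noisiest time point):

```
30P  : {'nrmse': 0.9409, 'nmae': 0.4344, 'psnr_db': 31.6185, 'ssim': 0.9296}
CUSIP: {'nrmse': 0.8311, 'nmae': 0.3933, 'psnr_db': 32.0659, 'ssim': 0.9421}
```

i.e. against the full-view reconstruction as reference, the inpainted
reconstruction has ~12 % lower NRMSE and clearly higher structural
similarity than the plain sparse-view reconstruction, even with the
training-free interpolation baseline.  The trained networks (see
`sipspect.evaluation.run_experiment`) improve on this baseline and carry the
advantage across all four measures and all four time points.

A command-line umbrella mirrors the library:

```bash
sipspect simulate --config cfg.yaml --seed 1 --out phantom/
sipspect project --phantom phantom/ --time-point 24 --noise-seed 3 --out proj.npz
sipspect sip train --projections proj.npz ... --loss L2 --epochs 20 --out model.npz
sipspect reconstruct --projections proj.npz --mu phantom/mu_map.nii --out rec.nii
sipspect dose --recons rec_d0.nii ... --phantom phantom/ --rc 0.87 --out doses.csv
sipspect experiment --seed 1 --out bundle/
```

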