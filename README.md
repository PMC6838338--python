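# questmri

Quench-assisted MRI (QUEST MRI) detects excessive free-radical production
*in vivo* as a supra-normal spin-lattice relaxation rate R1 (= 1/T1) that
returns to baseline after acute anti-oxidant administration.  This package
implements the full analysis for a noise-induced cochlear oxidative-stress
study in the rat: variable-TR spin-echo R1 mapping of the cochlea, the
three-group quench comparison (normal hearing NH, noise exposed NE, noise
exposed + anti-oxidants NE+AO, each with a silicone-protected and an
unprotected ear), ABR hearing-threshold calling, and the companion
histology readouts (cytocochleogram of missing hair cells, HO-1
immunofluorescence intensity).  A synthetic-data generator with known
ground truth drives every stage, so the whole pipeline is testable without
any animal data.

It is intended for MRI/auditory researchers who want a reference
implementation of the QUEST analysis chain, and for method developers who
need a fully simulated test bed for relaxometry pipelines.

## The model

Saturation-recovery signal at repetition time TR for a pixel with
equilibrium signal S0 and relaxation rate R1:

    S(TR) = S0 (1 - exp(-TR * R1))

The acquisition collects 23 single-spin-echo images at 8 TRs (0.15 s x6,
0.25 x5, 0.35 x4, 0.50 x3, 1.00 x2, 1.90, 2.70, 3.50 x1; 192x192 over
20x20 mm^2, 104 um in-plane).  The analysis chain is

1. rigid (translation) registration of same-TR repeats, then averaging
   to one image per TR,
2. registration across TRs to the longest-TR image,
3. three passes of a 3x3 Gaussian on the 0.15 s image to estimate the
   receive-coil (B1) profile,
4. division of the other seven TR images by that smoothed reference, and
5. a pixel-wise three-parameter fit `intensity = a + b exp(-c TR)` to the
   seven normalized images, with `c = R1` in 1/s.

Because the reference division is a per-pixel constant across TRs, any
smooth multiplicative coil field cancels exactly and leaves the fitted
rate unchanged.  The quench readout compares ROI-mean R1 across groups
with a treatment x ear two-way ANOVA (Type II) and Scheffé post hoc
contrasts; HO-1 percent changes use a mixed-factor ANOVA with random rat
intercepts and ear-specific residual variances (REML) and least-squares
means.

## Worked example

```python
import numpy as np
from questmri import (AcquisitionProtocol, CoilFieldSpec, NoiseSpec,
                      compute_r1_map, generate_series, roi_mean_r1,
                      RoiMask, two_region_phantom)

phantom = two_region_phantom((96, 96), r1_left=0.2, r1_right=0.4)
protocol = AcquisitionProtocol(matrix=(96, 96))
series, truth = generate_series(
    phantom, protocol,
    CoilFieldSpec("gaussian-bump", (0.8, 1.2), 60.0),
    NoiseSpec(sigma=0.03, jitter_sigma=0.5, seed=1))
r1map = compute_r1_map(series)
for name, mask in phantom.roi_masks.items():
    mean, n, sd = roi_mean_r1(r1map, RoiMask(name, mask))
    print(f"{name}: R1 = {mean:.3f} 1/s over {n} px (sd {sd:.3f})")
```

prints

```
left: R1 = 0.195 1/s over 2280 px (sd 0.116)
right: R1 = 0.394 1/s over 2357 px (sd 0.119)
```

i.e. the fitted rate map recovers the two simulated tissue rates (0.2 and
0.4 1/s) from 23 noisy, jittered, coil-shaded images; the per-pixel
spread reflects the Rician noise at ROI SNR ~ 20 plus residual
interpolation error near the region boundary after motion correction.

The full pipeline (simulate -> R1 map -> quench statistics -> ABR ->
histology) runs from a YAML config:

```
questmri run-all --config run.yaml --seed 1 --out results/
questmri report --out results/
```

The report summarizes group R1 by ear, the ANOVA and post hoc contrasts,
the QUEST decision (elevated / quenched), ABR threshold shifts by cochlear
region, the cytocochleogram, and the HO-1 mixed-model least-squares means.

## Conventions

Pixel coordinates are 0-based and row-major.  Image series are exchanged
as NIfTI plus a JSON sidecar of per-volume TR seconds; tables as CSV;
histology fields as multi-page TIFF; configs as YAML.
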