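# f19mri

Sensitivity characterization for fluorine-19 MRI: noise-bias-corrected SNR
estimation, double-angle B1+ flip-angle mapping, ¹⁹F-spins-per-voxel
detection-limit calibration, scan-time accounting, and a seeded synthetic
phantom simulator that ties the stages into a reproducible two-coil
benchmark.

¹⁹F MRI is background-free — tissue contains essentially no endogenous
fluorine — which makes it attractive for tracking perfluorocarbon-labeled
inflammatory cells, but the available signal is tiny, so every SNR claim
has to be made carefully.  This package is for MR physicists and
preclinical imaging groups who need to (a) quote unbiased SNR from
magnitude images, (b) characterize the transmit field of transceive
surface probes, and (c) express coil sensitivity as a detection limit in
fluorine atoms per voxel.

## The statistics at the core

**Corrected SNR.** Magnitude voxels follow a Rician law (single channel)
or a noncentral-chi law with 4 degrees of freedom (two-channel quadrature,
root-sum-of-squares).  Both bias weak signals upward and shrink the
background std to c_σ·σ (c_σ ≈ 0.655 Rician, ≈ 0.682–0.687 chi).  The
estimator forms σ = σ_m/c_σ from the background std σ_m and solves the
distribution's mean equation E[M | S, σ] = S_m for the true signal S by
monotone root finding, reporting SNR = S/σ; measurements at the noise
floor are flagged and reported as zero instead of being extrapolated.

**Double-angle B1+ mapping.** From two fully relaxed scans at nominal
angles α and 2α, the local flip angle is FA = acos(SI_2α / 2·SI_α),
independent of any receive profile; maps are also normalized to a nominal
90° (×90/α).

**Sensitivity calibration.** Atoms per voxel is
N = c·V_voxel·n_F·N_A (n_F = 20 for perfluoro-15-crown-5-ether); SNR is
modeled as strictly proportional, SNR = k·N, fitted on the log scale with
unit exponent.  Slope ratios give the SNR gain of one coil over another;
cutoff/k gives the detection limit (cutoff 2 by default).  Depth profiles
of two coils are compared by their pointwise ratio: peak gain, its depth,
and the crossover depth where the gain falls to 1.

**Scan time.** TA = TR × ceil(phase steps / ETL) × averages for Cartesian
RARE/FLASH protocols, with console-style rendering ("36 s", "1 h 25 min").

## Worked example

```python
import numpy as np
from f19mri import (NoiseModel, correct_snr, FluorineSample, VoxelGeometry,
                    atoms_per_voxel, fit_sensitivity, detection_limit)

# corrected SNR from a weak two-channel measurement
model = NoiseModel(channels=2)          # quadrature probe, c_sigma = 0.687
est = correct_snr(s_m=2.1, sigma_m=0.7, model=model)
print(f"corrected SNR = {est.snr:.2f} "
      f"(naive ratio would be {2.1/(0.7/model.c_sigma):.2f})")

# dilution-series calibration
voxel = VoxelGeometry(0.104, 0.104, 1.2)
points = []
for conc, snr in [(200, 4.1), (400, 8.6), (600, 12.4), (1200, 25.3)]:
    n = atoms_per_voxel(FluorineSample(conc), voxel)
    points.append((n, snr))
    print(f"{conc:5d} mM -> {n:.2e} atoms/voxel, SNR {snr}")
fit = fit_sensitivity(points)
print(f"slope k = {fit.slope_k:.2e} SNR per atom")
print(f"detection limit at SNR=2: {detection_limit(fit, 2.0):.2e} atoms/voxel")
```

prints

```
corrected SNR = 0.89 (naive ratio would be 2.06)
  200 mM -> 3.13e+16 atoms/voxel, SNR 4.1
  400 mM -> 6.25e+16 atoms/voxel, SNR 8.6
  600 mM -> 9.38e+16 atoms/voxel, SNR 12.4
 1200 mM -> 1.88e+17 atoms/voxel, SNR 25.3
slope k = 1.34e-16 SNR per atom
detection limit at SNR=2: 1.49e+16 atoms/voxel
```

The first line shows why the correction matters: a measurement barely
above the two-channel noise floor (naive ratio 2.06) corresponds to a true
SNR below 1.  The calibration lines convert a tube series into a single
sensitivity slope and a detection limit in fluorine atoms per voxel — the
hardware-independent currency for comparing coils.

## Command line

A thin `f19` CLI wraps the library:

```bash
f19 snr --image img.nii.gz --bg bg.nii.gz --channels 2 --roi tube.nii.gz
f19 famap --alpha a60.nii.gz --double a120.nii.gz --nominal 60
f19 profile --in famap.nii.gz --axis depth --out profile.csv
f19 calibrate --table tubes.csv --cutoff 2
f19 compare --a crp_profile.csv --b rt_profile.csv
f19 scantime --protocol rare3d.yaml
f19 simulate --scenario scenario.yaml --out sim/
f19 benchmark --config run.yaml
```

`f19 benchmark` runs the whole chain — simulate two coil setups on a
dilution-series phantom, estimate per-tube corrected SNR through a central
circular ROI, fit slopes, report gain, detection limits and depth-profile
metrics — writing `report.json`, per-tube CSV tables and a log with all
seeds.

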