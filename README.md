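# carotidcs

Compressed-sensing (CS) accelerated multi-contrast carotid vessel-wall
imaging, simulated end to end on digital phantoms.

High-resolution black-blood MRI of the carotid artery wall is a standard
way to assess atherosclerotic plaque, but 3-D multi-contrast protocols are
slow; CS undersampling shortens them.  Before an accelerated protocol can
replace the standard one, two things must be shown: that morphological
measurements (lumen area, wall area, wall thickness) remain *repeatable*
across scan sessions and readers, and that acceleration does not
systematically *shift* them.  Real scan-rescan cohorts are expensive and
not redistributable, so this package rebuilds the whole validation chain
on synthetic ground truth — for methods developers who want to study how
acceleration, noise, repositioning and reader variability propagate into
morphometry and its repeatability statistics.

## What it implements

* **phantom** — a bifurcating vessel (CCA splitting into ICA/ECA analogs)
  with black-blood contrast (lumen < background < wall), rendered with
  exact analytic partial-volume coverage; scan-session jitter and a
  simulated-reader contour model.
* **kspace** — multi-coil orthonormal Fourier encoding; variable-density
  Gaussian pseudo-random undersampling with an exactly `round(N/R)` sample
  budget and a fully sampled 32×32 centre; uniform parallel-imaging combs;
  complex Gaussian noise.
* **recon** — the iterative reconstruction

  minimise ‖Ψm‖₁ subject to ‖F m̂ − y‖₂² ≤ ε,

  with Ψ the nearest-neighbour finite-difference transform of the complex
  image m, solved by 15 proximal-gradient iterations with hard data
  consistency (acquired k-space substituted back each iteration, ε = 0);
  then a GRAPPA-style autocalibrated fill of uniform-comb gaps and
  sum-of-squares coil combination √(Σ_c |m_c|²).
* **morphometry** — axial reformat to 0.2×0.2×0.3 mm, sub-pixel half-max
  contours, shoelace areas, equivalent-circle radii r = √(area/π), wall
  thickness r_outer − r_lumen, wall–lumen sharpness 1/d₂₀₋₈₀ (reciprocal
  20–80 % edge distance), plaque flags at thickness ≥ 1.5 mm.
* **stats** — CoV = 100·sd(x₁ᵢ−x₂ᵢ) / (Σ(x₁ᵢ+x₂ᵢ)/2 / n), ICC(2,1) with
  95 % CI (Shrout–Fleiss), Bland–Altman limits, two-tailed paired t-test,
  agreement categories (>0.75 excellent, 0.40–0.75 good, <0.40 poor).
* **experiment** — seeded, bit-reproducible study designs: scan-rescan
  repeatability, sharpness vs CS factor, intra/inter-observer
  reproducibility, and the CS-vs-non-CS thickness comparison.

## Worked example

```python
import numpy as np
from carotidcs.phantom import PhantomSpec, build_phantom
from carotidcs.kspace import encode, make_cs_mask, apply_mask
from carotidcs.recon import reconstruct, zero_fill_recon, sos_combine, nrmse
from carotidcs.morphometry import reformat_axial, measure_vessel

spec = PhantomSpec()                       # 3 mm lumen, 1 mm wall
images, geometry, sens = build_phantom(spec)
k = encode(images["t1w"], sens, noise_sd=0.05, seed=7)
mask = make_cs_mask(spec.grid_shape[1:], R=2.0, seed=1)   # CS factor 2
ku = apply_mask(k, mask)

ref = sos_combine(sens.maps * images["t1w"][None])
print(f"zero-fill NRMSE: {nrmse(sos_combine(zero_fill_recon(ku)), ref):.4f}")
res = reconstruct(ku)
print(f"CS NRMSE:        {nrmse(res.combined, ref):.4f}")

ax = reformat_axial(res.combined, spec.voxel_mm,
                    x_range_mm=(-12, 12), y_range_mm=(-8, 8),
                    z_range_mm=(spec.bifurcation_z_mm - 8, spec.bifurcation_z_mm + 8))
df = measure_vessel(ax, geometry).per_slice
print(df.groupby("segment")[["lumen_area", "wall_area", "wall_thickness"]].mean().round(2))
```

prints

```
zero-fill NRMSE: 0.1352
CS NRMSE:        0.1271
         lumen_area  wall_area  wall_thickness
segment
CCA           28.11      20.08            0.93
ECA           13.20      16.46            1.02
ICA           19.82      19.12            1.01
```

The CS reconstruction beats plain zero-filling at twice acceleration, and
the measured wall thickness recovers the 1 mm ground truth (lumen areas
near π·3² ≈ 28.3 mm² for the CCA, smaller for the branches) to better
than a tenth of a millimetre on this noisy single R = 2 acquisition; the
noiseless fully sampled pipeline recovers it to a few hundredths.

The full study drivers live under `analysis/` and write their tables to
`results/`:

```bash
python analysis/01_scan_rescan_repeatability.py --seed 0 --subjects 6
python analysis/02_sharpness_vs_cs_factor.py   --seed 0
python analysis/03_observer_reproducibility.py --seed 0
python analysis/04_thickness_cs_comparison.py  --seed 0
```

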