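# grinsim

Synthetic two-photon calcium imaging through GRIN-lens microendoscopes,
with ground truth attached.

Long gradient-index (GRIN) rod lenses relay a two-photon focal plane into
deep brain structures, but their intrinsic aberrations enlarge the
excitation point-spread function (PSF) away from the optical axis: lateral
cells get dim and blurry, signals from neighbouring somata mix, and the
usable field of view (FOV) shrinks. Printed aspherical corrective lenses
fix much of this. Evaluating how much they help *for population calcium
analysis* requires data where the true sources are known — which is what
this package provides. It forward-simulates calcium imaging t-series
through configurable optics models of corrected and uncorrected probes
(6.4 mm and 8.8 mm), and evaluates the rendered movies against their own
ground truth.

The pipeline, end to end:

1. **tissue** — spherical somata (radius ~ N(10, 3) µm) with dark nuclei
   (half-width ~ N(5, 1) µm), packed without overlap in a
   400 x 400 x 170 µm³ volume on a 0.8 x 0.8 x 1 µm voxel grid.
2. **activity** — each neuron is an independent Poisson process plus
   shared Poisson processes from a random pairing graph (pair probability
   0.05), summed rate 0.3 Hz per neuron, 5 min at 1 ms steps; spikes are
   turned into fluorescence by a fast-indicator kernel. The shared rate is
   calibrated (0.0124 Hz) so the mean all-pairs Pearson correlation of
   ground-truth traces is 0.041.
3. **optics** — asphere sag Z(r) = c r²/(1 + √(1 − (1+k)c²r²)) + Σ αₙ r²ⁿ,
   curved focal surfaces (5th-order polynomial for corrected probes, two
   spherical shells for uncorrected astigmatism), quartic radial models of
   PSF FWHM f(r) = a r⁴ + b r² + c, FOV distortion
   g(x) = d x⁴ + e x² + f x + h, and a radial excitation-intensity
   profile.
4. **render** — a binary excitation ellipsoid (semi-axes = FWHM/2) scanned
   along the focal surface(s), orthogonal to them, collapses into a static
   pixel x neuron mixing matrix; movies at 30 Hz add the three fitted
   pixel-noise regimes (edge dark noise, background, neuron-voxel noise).
5. **extract** — per-frame [80th, 95th] percentile-band ROI traces inside
   detected boxes, background subtraction, sliding-20th-percentile
   ΔF/F₀ (10 s window), peak SNR = max(ΔF/F₀)/SD(sub-25th-percentile
   values), distortion-calibrated centroids.
6. **metrics / stats** — adjacent-pair correlations against an expected
   (ground-truth) threshold, a GLM purity index
   maxⱼ(aⱼ²)/Σⱼ aⱼ², first-source correlations, radial regressions with
   permutation tests.

## Worked example

Simulate one corrected-probe FOV and look at what was detected:

```python
from grinsim import pipeline as pl

cfg = pl.ExperimentConfig(probe_type="corrected-6.4", n_fovs=1,
                          duration=60.0, n_px=256, seed=11)
res = pl.run_experiment(cfg)
df = res.roi_table()
print(len(df), round(res.gt_corr_mean, 3), round(res.expected_threshold, 3))
```

prints `284 0.106 0.248` — 284 ROIs were extracted, the ground-truth
sources of this 60 s FOV correlate 0.106 on average (the population value
is 0.041; a single short FOV carries only a handful of shared spikes, so
per-FOV means scatter widely), and an adjacent ROI pair is called
contaminated when its trace correlation exceeds 0.248 (mean plus three
SDs of the ground-truth pair correlations).

The numbered drivers under `analysis/` run the full study at reduced
scale and write tables under `results/`:

```text
01_calibrate_shared_rate.py    calibrate the shared Poisson rate -> 0.041
02_ground_truth_correlation.py the headline correlation statistic
03_effective_fov.py            effective-FOV radii and fold changes
04_bead_phantom_recovery.py    optics -> charfit self-consistency loop
05_compare_probes.py           corrected vs uncorrected, all four metrics
```

`python analysis/03_effective_fov.py` prints

```text
6.4 mm probe: effective FOV radius 46 -> 100 µm, radius fold 2.17, area fold 4.7
8.8 mm probe: effective FOV radius 34 -> 52 µm, radius fold 1.53, area fold 2.3
```

i.e. the radius where the axial resolution quartic crosses the 10 µm
threshold grows 2.17-fold (6.4 mm probe) and 1.53-fold (8.8 mm probe)
under correction, enlarging the effective FOV area 4.7x and 2.3x.

`python analysis/05_compare_probes.py` (5 FOVs per condition, 60 s,
256 x 256 px, ~6 min) reports the four comparisons: corrected probes
yield more ROIs at every peak-SNR cutoff, a smaller fraction of adjacent
ROI pairs correlated above the expected threshold, a purity-vs-radius
slope several times shallower than uncorrected probes (permutation
p < 0.05 for the difference), and a higher median correlation of
extracted traces with their best ground-truth source.

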