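# Methods

`grinsim` is a forward model of two-photon calcium imaging through
GRIN-lens microendoscopes, together with the ground-truth-aware evaluation
pipeline used to quantify what aberration correction buys: more
high-SNR cells, less cross-contamination between neighbours, and purer
source demixing across the field of view (FOV). This note records the
model, its assumptions, the parameters that matter, and the design choices
made where the design was genuinely open.

## Tissue model

Neurons are spheres with radius ~ N(10, 3) µm and a concentric dark
(non-expressing) nuclear region of half-width ~ N(5, 1) µm; only the shell
between nucleus and soma boundary fluoresces. The soma radius is drawn
unconditionally (redrawn only if non-positive) and the nucleus half-width
is then redrawn until it fits strictly inside the soma, which keeps the
soma-radius distribution unbiased; a soma too small for any plausible
nucleus clips the half-width to 0.95 r. Somata are placed by random
sequential addition with a hard non-overlap constraint (centre distance at
least the sum of radii), uniformly in the volume, with centres inside the
volume but somata free to protrude through its faces. Placement stops at a
target density or after a configurable run of consecutive rejected
insertions (default 10^4), because the literature density of
26.8 x 10^4 cells/mm^3 lies above the jamming density of non-overlapping
spheres of this size and can never be realised.

The experiment pipeline instead targets 5.12 x 10^4 cells/mm^3
(~1392 neurons in a 400 x 400 x 170 µm^3 volume, i.e. ~9.7 x 10^5
ground-truth source pairs), the realised density implied by the reference
synthetic dataset this package emulates. Volumes are
400 x 400 x 170 µm^3 for the 6.4 mm probes and 360 x 360 x 200 µm^3 for
the 8.8 mm probes; the voxel grid is 0.8 x 0.8 x 1.0 µm. Membership is
tested at voxel centres with no partial-volume weighting.

## Activity model

Spiking runs for 5 simulated minutes at 1 ms steps. Each unordered neuron
pair is linked with probability 0.05 and each neuron fires as an
independent Poisson process plus one shared Poisson process per activity
group, with the summed rate fixed at 0.3 Hz for every neuron (the
independent rate absorbs the remainder, clamped at zero with a warning).

Two group conventions are implemented. In the default `components`
convention, groups are the connected components of the pairing graph; at
p = 0.05 and populations of hundreds the graph is almost surely one
component, so every neuron carries a single common shared process and the
expected all-pairs fluorescence correlation is exactly
shared_rate / total_rate, independent of population size and of radial
position. The `pairs` convention treats every sampled edge as its own
group of two (the common-shock model); its paired-count correlation is
also shared_rate / total_rate, but splitting each neuron's 0.3 Hz across
its ~p·n groups caps the all-pairs mean near 1/n, far below the reference
statistic. The `components` convention is the default precisely because it
is the one whose mean pairwise correlation can be calibrated to the
reference value of 0.041; the calibrated default shared rate is 0.0124 Hz
(`analysis/01_calibrate_shared_rate.py`, bisection on simulations,
consistent with the analytic 0.041 x 0.3 Hz).

Spikes drive a difference-of-exponentials sensor kernel (rise constant
2 ms, decay constant 101 ms = 70 ms half-decay, unit peak), scaled by a
unitary amplitude of 0.4 dF/F per spike on a resting brightness of 3000
intensity units, with an optional Hill saturation (off by default). These
sensor numbers are a configurable stand-in for a fast GCaMP-family
indicator, not measured values; the brightness was chosen once so that
somata are ~3x brighter than the background neuropil level of the noise
model (as in real indicator-expressing tissue) and the extracted peak-SNR
distribution spans the analysis' threshold sweep. Fluorescence is
evaluated by exact sparse kernel placement at spike events (identical to
convolving the binned trains) and bin-averaged onto the 30 Hz frame grid;
because 1 ms bins do not divide 33.3 ms frames, frames alternate between
33 and 34 bins using time-edge binning.

## Optics models

All optics are rotationally symmetric functions of radial distance r.

* **Focal surface.** Corrected probes use a fifth-order polynomial sag
  rotated about the axis; uncorrected probes use one or two spherical
  shells (astigmatism), with the published curvature radii 273 & 2000 µm
  (6.4 mm) and 992 & 2000 µm (8.8 mm). A `center_depth` anchors the
  surface in the volume and a sign convention (default: margins curve
  toward the probe) orients it; the corrected 8.8 mm surface is anchored
  deeper than its uncorrected counterpart, so the two conditions sample
  different neurons, as in the reference data.
* **PSF size.** Lateral and axial excitation FWHM follow even quartics
  f(r) = a r^4 + b r^2 + c. The default coefficients are reconstructions
  anchored to an on-axis axial FWHM of 5 µm and to the published
  effective-FOV radii at the 10 µm axial threshold (corrected/uncorrected:
  100/46 µm at 6.4 mm, 52/34 µm at 8.8 mm); they are not published fits.
  Because a quartic diverges outside its fitted range, evaluation is
  capped (40 µm axial for corrected probes; 100 µm for uncorrected probes,
  whose off-axis aberrations made beads unmeasurable beyond ~75 µm;
  10 µm lateral for both).
* **Distortion.** The local magnification factor is an even quartic of
  nominal radius and the real-to-nominal distance calibration g is a
  quartic with a linear term, inverted numerically (monotone bisection,
  clamped at the radius where an extrapolated quartic turns over). Pixel
  centres are laid out on the nominal grid and mapped radially through
  g^-1 into sample space, giving the non-uniform sampling of a distorted
  FOV; ROI centroids are calibrated back through the same inverse.
* **Radial intensity.** Relative excitation efficiency is a clipped even
  polynomial equal to 1 on axis, decaying strongly for uncorrected probes
  (zero beyond ~135 µm) and mildly for corrected ones — a qualitative
  stand-in for the fluorescent-film measurements.

## Rendering

The excitation volume at each pixel is a binary ellipsoid with semi-axes
half the lateral/lateral/axial FWHM at that pixel's radius, centred on the
focal surface and tilted along the local surface normal (a
Gaussian-weighted profile is used for the bead phantoms). Every tissue
voxel whose centre falls inside the ellipsoid contributes: shell voxels
the neuron's fluorescence, nucleus voxels zero signal, empty voxels a
static background level. Because the geometry is static, this collapses
into a pixel x neuron mixing matrix (weight = in-shell voxel fraction of
the ellipsoid) plus per-pixel noise aggregates; rendering a frame is a
sparse product plus Gaussian draws, and a dense per-frame voxel render is
used as the equivalence oracle in the tests. For two-shell (astigmatic)
probes the two passes are averaged with equal weight by default.

Pixel noise uses the three fitted regimes of the reference recordings
verbatim: FOV-edge dark noise (two-component Gaussian mixture for the
mean: 0.35/137.48/48.96 and 0.65/126.83/5.02, SD = clamp(-175.39 +
1.57 mean, 0)); empty-centre background (lognormal mean, log-space
parameters 6.54/0.78 by default with a linear-space switch, SD = 29.91 +
7.75 sqrt(mean)); and neuron-voxel noise (zero-mean, SD = 322.18 +
0.98 sqrt(voxel mean), nucleus voxels at mean 0). Voxel noise averaged
over an excitation volume is aggregated analytically
(sqrt(sum SD^2)/n_vox), which is exactly equivalent to drawing per voxel.

The radial intensity profile multiplies the neural signal only:
detector/background noise does not scale with excitation efficiency, so
SNR genuinely falls toward the margins. (Full-pixel modulation is
available behind a switch, but it makes dF/F0 and peak SNR exactly
gain-invariant, which would erase the radial SNR degradation the study
quantifies.) Pixels with zero excitation efficiency, and pixels whose
ellipsoid contains no neuron, fall back to the background regime; pixels
outside the circular FOV carry unmodulated dark noise. Movies are float32;
16-bit quantisation is available at export.

## Extraction

ROI boxes default to the ground-truth projection detector: the bounding
rectangle of each neuron's nonzero mixing-matrix footprint. This replaces
the trained network detector of the reference analysis with a
deterministic, download-free stand-in, and all cross-condition comparisons
use the same detector; a simple median-projection blob detector and
externally supplied box lists are also accepted. Per frame, the ROI inside
a box is the set of pixels in the closed [80th, 95th] percentile band of
the box's intensities (linear-interpolation percentiles; a constant box
degenerates to the whole box), and the trace is the ROI mean minus a
per-frame background: the mean of pixels outside every box whose value
exceeds the frame's mean corner level (pixels beyond the circular FOV) and
stays below the frame's maximum inside boxes, carried forward when the
candidate set is empty. dF/F0 uses a 20th-percentile baseline in a 10 s
window centred on each frame and truncated at the ends; a non-positive
baseline anywhere flags the ROI out of all SNR statistics. Peak SNR is
max(dF/F0) over the SD of the values below the trace's 25th percentile
(degenerate lower tails flag the ROI as infinite and excluded).

## Evaluation

Contributing sources of a box are the neurons whose footprint overlaps it
by at least one pixel. The purity of an extracted trace is
max_j(a_j^2) / sum_j(a_j^2) from a least-squares fit (intercept included;
minimum-norm under collinearity, cross-checked against a statsmodels GLM
with identity link in the tests) of the trace on its contributing
ground-truth traces. Note the index is deliberately scale-sensitive — all
sources enter on the common ground-truth trace scale. Adjacent ROI pairs
(calibrated centroid distance <= 25 µm, alternative 30 µm) are called
contaminated when their dF/F0 correlation exceeds the expected pair
correlation: the across-FOV mean of all-pairs ground-truth correlations
plus three SDs of the pooled pair correlations. The first-source
correlation of an ROI (peak SNR > 10) is its maximum Pearson correlation
over contributing sources. Radial trends are ordinary least squares with a
Wald slope test when the residuals pass the normality gate (Shapiro-Wilk
below n = 50, D'Agostino-Pearson above) and a pairings permutation test
otherwise; condition comparisons permute condition labels. Permutation
tests use 10^4 permutations below n = 500 and 10^5 above, sampled with
replacement, with an add-one correction so p > 0.

## Problem sizes and defaults

The packaged experiment scale is 5 FOVs per condition, 60 s movies at
256 x 256 pixels (reference scale: 13–15 FOVs of 300 s), which runs the
full two-condition comparison in a few minutes on one core; the headline
correlation statistic uses 200 neurons for 300 s averaged over
30–150 repeats. At these sizes the four qualitative contrasts between
corrected and uncorrected probes (ROI counts, contaminated-pair fraction,
purity slope, first-source correlation) are stable in sign; their absolute
values are not comparable to the reference figures because the detector,
sensor brightness and reconstructed optics coefficients differ.

## What the generator does and does not emulate

The simulator reproduces: ground-truth-linked source geometry and
activity with calibrated pairwise correlation; radially varying PSF,
focal-surface curvature and astigmatism; FOV distortion; radial intensity
loss; and empirically fitted pixel-noise statistics. It does not emulate
motion artifacts, photobleaching, intra-frame scan timing, shot-noise
statistics beyond the fitted Gaussian models, non-spherical morphology or
neuropil structure, or a trained cell detector's failure modes. Passing
tests therefore demonstrate correctness of the pipeline and the direction
and mechanism of the aberration-correction effects, not quantitative
agreement with any particular in vivo recording.

## Numerical choices

Percentiles interpolate linearly between order statistics throughout.
Ellipsoid membership and voxel/neuron membership are tested at centres;
ties at degenerate percentile bands include the whole box. The sensor
kernel is truncated where it falls below 1e-6 of its peak. Seeds expand
through `numpy.random.SeedSequence` substreams per FOV and per stage, so
every stage is independently reproducible and identical configurations
produce byte-identical outputs.
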