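# Methods

## The measurement problem

A photoconvertible calcium integrator targeted to synapses turns from
green- to red-emitting in proportion to local calcium at the moment of a
violet-light pulse. Imaging a field of dendrite before (G0, R0) and after
(G1, R1) conversion therefore encodes, synapse by synapse, how strongly
each synapse was activated. Extracting that signal at scale requires
detecting thousands of puncta in 3D, holding their identity across
timepoints despite tissue deformation, rejecting autofluorescent debris
that mimics converted synapses, and reducing four fluorescence values per
synapse to one activity metric. `punctapipe` implements that workflow and
validates every stage against a synthetic phantom with full ground truth.

## Photoconversion metric

Raw per-synapse intensities are the maximum voxel value of the ROI in the
raw median-filtered volume of each channel/timepoint. Green values are
normalized by the population mean of G0 and red values by the population
mean of R0, computed over kept (non-rejected, valid) ROIs; normalized
values are written g0, g1, r0, r1. The activity metric is

    pc = ΔR / (g0 + g1),   ΔR = r1 − r0.

Dividing by total green removes the correlation with synapse size that raw
ΔR carries (baseline green is a proxy for postsynaptic scaffold size), and
using both timepoints makes the denominator robust to conversion-induced
green dimming. Because the normalizations enter numerator and denominator
once each, pc is invariant to global gain changes in either channel and to
any per-synapse factor (sub-voxel sampling, PSF attenuation) that
multiplies all four values of a synapse equally — the property the test
suite checks directly.

## Pipeline stages and numerical choices

1. **Median filter** (radius 1 voxel, cube footprint). The filtered copy
   is the only input to intensity extraction; the API accepts a
   `ProcessedPair` so the deconvolved member cannot be quantified by
   accident.
2. **Richardson–Lucy deconvolution** with the microscope's Gaussian PSF
   (FWHM 0.35 × 0.35 × 1.5 µm x/y/z by default), applied by separable
   Gaussian filtering; default 20 iterations (10 in the pipeline presets),
   early stop when the mean relative update falls below 1e-4. The RL
   multiplicative update preserves non-negativity and total flux (±1%,
   tested). Deconvolved data feed registration and detection only.
3. **Registration.** Chromatic/beam offset between the red and green
   acquisition wavelengths is a pure translation estimated by sub-voxel
   phase cross-correlation, using broad-spectrum (dual-channel) objects as
   the signal. Timepoint re-alignment ("unwarping") runs four stages —
   translation, rotation, affine, B-spline (8 µm control spacing, two
   resolution levels) — with a normalized cross-correlation metric on the
   green channel only, deterministic regular sampling (1% of voxels), and
   a fixed iteration budget. A stage that fails to improve the metric is
   kept as an identity stage, so similarity is monotone along the chain.
   The chain is applied unchanged to every channel; resampling before
   max-intensity extraction uses cubic B-spline interpolation because
   linear interpolation systematically attenuates peak amplitudes, which
   would bias the metric low where conversion is weak.
4. **Background subtraction.** The voxelwise median of each volume (puncta
   are sparse, so the median sits on the background plateau) is subtracted
   before extraction. Without it the DC offset inflates the population
   mean of the dim baseline-red channel and deflates pc by tens of
   percent.
5. **Detection.** Per voxel, 12 rotation-invariant features: the
   scale-normalized (γ = 2) Laplacian of Gaussian and the three
   eigenvalues of the scale-normalized Hessian, each at three scales
   (pipeline preset 1, 2, 4 µm; the finer 0.3/0.6/1.2 µm default suits
   sub-µm sampling). Second derivatives are textbook central differences
   on the Gaussian-smoothed volume; eigenvalues come from the closed-form
   trigonometric solution for symmetric 3×3 matrices. A random forest (30
   trees, depth ≤ 12, fixed seed, held-out accuracy reported) classifies
   spot vs background; classifier-positive voxels are grouped under
   26-connectivity (corner-touching voxels merge); components outside
   4–2000 voxels are discarded; each component is wrapped in an
   axis-aligned enclosing ellipsoid (semi-axes √3·max|deviation| per axis
   plus half a voxel, centered on the centroid) and stored as the ROI.
6. **Autofluorescence rejection.** Spots with elevated baseline red are
   flagged: threshold = median + k·1.4826·MAD of the per-spot R0 maxima
   (k = 3), falling back to Otsu's split when the MAD is zero. The scaled
   MAD keeps the threshold robust against the heavy right tail the debris
   itself creates. Rejected spots are flagged, never deleted, and excluded
   from population means.
7. **Analysis.** Active synapses: pc above mean + 3σ of the kept
   population (robust median+3·1.4826·MAD variant available). Distance
   analysis: synapses binned into contiguous 20 µm concentric rings by 3D
   Euclidean distance from the soma (dendritic path length is not
   traced); per-ring median and IQR; weighted (by ring count) nonlinear
   least squares of A·exp(−d/λ) at ring centers, multistart from a
   log-linear seed (×0.5, ×1, ×2), tolerance 1e-8. Turnover:
   A·exp(−t/τ) + C fitted to the population pc trace; a constant model is
   fitted alongside and the winner chosen by small-sample AIC (with an
   SSE floor at the float64 noise of the data scale so exact ties go to
   the simpler model). Enrichment: per-structure
   (target_compartment/target_shaft)/(filler_compartment/filler_shaft),
   summarized by the median; zero-shaft pairs flagged.

## The phantom

The generator renders amplitude-parameterized isotropic Gaussian puncta
(σ = radius/2) on a 3D grid, convolves with the anisotropic Gaussian PSF,
applies tissue warp (a smooth random displacement field, capped below half
its smoothness scale so it stays invertible) and the chromatic offset at
the point level before rasterizing timepoint-1/red scenes, then adds
Poisson photon noise and Gaussian read noise. Per-synapse conversion c_i
is defined on the metric scale: the red increment carries the factor
(2 − dimming·min(c_i, 1)) coupling it to green dimming, so in the
noiseless limit the pipeline's pc equals c_i exactly — a property the test
suite asserts to 1e-5. Green dimming is linear in c_i, capped at 1 (a
stand-in exposed as `dimming_factor`; the literature gives no quantitative
dimming-to-conversion ratio).

Default study conditions (chosen once, as a bright, well-averaged
acquisition): 1 µm isotropic voxels, synapse radii 1.2–2.0 µm, ≥5 µm
center separation, density 1.6×10⁻³ µm⁻³, brightness lognormal
(log-σ 0.28) around 1, baseline red 0.4× green, background 0.02,
photon scale 1000 (≈ hundreds of photons at a peak), read noise 0.01.
Conversion distributions are lognormal; the graded-stimulation presets fix
the median at 0.139 / 0.327 / 0.984 with log-σ 0.58 / 0.66 / 0.88 chosen
to reproduce the corresponding measured mean/median ratios. The
distance-decay preset uses A = 2, λ = 105 µm with log-σ 0.5 scatter on a
~207 µm field (soma in a corner, radial placement so all 20 µm rings are
occupied); the turnover preset decays c_i with τ = 29.4 min over 13
timepoints spanning an hour; the spine-calcium table uses λ = 106 µm with
log-σ 0.38 scatter calibrated so the 55-point fit's R² lands near 0.66.

Autofluorescent clutter granules are bright in both channels at all
timepoints. Their median radius grows weakly with the occupied volume
fraction f (1.65 µm at f = 0.4%, ∝ f^0.138, floored at 1.4 µm, lognormal
log-σ 0.2) — emulating larger lipofuscin bodies in older tissue — with
brightness 5× the median synapse (log-σ 0.25) and centers excluded from
synapse neighborhoods (solid bodies do not interpenetrate). Under these
conditions the baseline-red filter rejects essentially all granules,
<1–2% of synapses, and 10–30% of all detected spots across f = 0.4–4%.

Classifier training labels emulate a user's brush strokes on the phantom:
spot strokes inside object cores (0.6× radius), background strokes both in
the shell just outside the object (1.0–1.6× radius) and in empty regions.
Without the peri-object strokes the forest labels spot halos as spot and
neighboring puncta merge into single components at realistic densities.

### What the phantom does not emulate

No dendritic shafts or neuropil texture (detection is easier than on real
tissue); no bleaching, focus drift, or z-dependent attenuation; voxels are
coarser (1 µm) than real two-photon sampling because the distance fit
needs a >200 µm field at desk scale, so puncta span only a few voxels;
warp fields are smooth and single-scale; conversion noise is lognormal
and independent of position given distance. Passing recovery tests
therefore demonstrates correctness of the algorithms under controlled
conditions, not segmentation performance on real neuropil.

## Problem sizes used by the validation runs

The distance-constant study runs the full pipeline (render, 2 µm warp,
4-stage registration, detection, rejection, extraction, rings, fit) on
28×208×208-voxel stacks with 1860 synapses, averaged over 10 seeds; the
turnover study uses 138 synapses × 13 timepoints (10 seeds); the
metric-fidelity studies use ~2587/472/356 synapses (5 seeds each); the
spine-calcium table uses 55 spines (20 seeds). These sizes keep every
ring/timepoint populated at the stated densities while each seed completes
in seconds to tens of seconds on one CPU.

## Known limitations

- Euclidean distance from the soma underestimates dendritic path length;
  fitted λ is therefore interpretable only in the same convention.
- The ROI ellipsoid is an enclosing, not minimum-volume, axis-aligned
  ellipsoid; it is a bookkeeping region, not a segmentation.
- The rejection threshold assumes clutter is a minority (<~35%) of
  detected spots; beyond that the robust statistics it uses break down.
- Registration quality is tuned for smooth, few-µm deformations typical of
  slice-culture timepoints; it is not a motion-correction tool.
- pc is reported per ROI; merged puncta (closer than ~2 object radii)
  yield one record dominated by the brighter synapse.
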