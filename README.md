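# punctapipe

Detection and ratiometric photoconversion quantification of synaptic
puncta in two-channel 3D fluorescence stacks.

## What this is for

Photoconvertible, synaptically targeted calcium integrators mark active
synapses by turning from green- to red-emitting under violet light, in
proportion to local calcium. One experiment yields 3D image stacks of a
green and a red channel before (G0, R0) and after (G1, R1)
photoconversion, containing thousands of diffraction-limited puncta
(spine heads, boutons). Turning those stacks into per-synapse activity
calls for a pipeline: deconvolution, non-rigid re-alignment of timepoints
("unwarping"), trainable spot detection, rejection of autofluorescent
debris, intensity extraction and normalization, and downstream analyses
(active-synapse classification, distance-from-soma decay fits, turnover
kinetics, compartment enrichment). `punctapipe` implements that pipeline
for analysts working with this class of sensor, together with a phantom
generator that renders fully ground-truthed synthetic experiments so every
stage is testable without microscope data.

## The metric at the core

Per ROI, raw intensities are maxima over member voxels of the raw
median-filtered stacks. Green values are normalized to the population
mean of G0 and red values to the population mean of R0 (kept spots only),
giving g0, g1, r0, r1. Photoconversion is quantified as

    pc = ΔR / (g0 + g1),    ΔR = r1 − r0

which, unlike raw ΔR, is uncorrelated with synapse size (baseline green
is a size proxy) and invariant to per-channel gain. Synapses with
pc > mean + 3σ of the population are classified active. Spatial structure
is summarized by 20 µm concentric Sholl rings around the soma with
weighted exponential fits A·exp(−d/λ), and turnover by A·exp(−t/τ) + C
against a constant-model control.

## Worked example

Render a ~400-synapse phantom with 1% autofluorescent clutter, run the
full pipeline (median filter, deconvolution, detection with a random
forest trained on phantom-truth strokes, baseline-red rejection,
extraction, normalization), and classify active synapses:

```python
from punctapipe import PhantomSpec, ConversionModel, generate_phantom
from punctapipe.pipeline import PipelineConfig, run_pipeline
from punctapipe.analyze import classify_active

spec = PhantomSpec(
    volume_shape=(28, 128, 128),          # 27 x 127 x 127 um field
    n_synapses=400,
    conversion_model=ConversionModel(kind="constant", median=0.33,
                                     dispersion=0.66),
    autofluorescence_volume_fraction=0.01,
    seed=0,
)
stacks, truth = generate_phantom(spec)
result = run_pipeline(stacks, PipelineConfig(seed=0), truth=truth)

rec = result.records
kept = rec[rec["pc_valid"] & ~rec["autofluorescent"] & ~rec["invalid"]]
flagged, threshold = classify_active(kept)

print(f"detected spots:        {len(result.rois)}")
print(f"rejected (high R0):    {result.rejection.n_rejected} "
      f"({100 * result.rejection.fraction_rejected:.1f}%)")
print(f"kept synapse records:  {len(kept)}")
print(f"median pc:             {kept['pc'].median():.3f}   "
      f"(true median {truth.synapses['conversion'].median():.3f})")
print(f"active threshold:      {threshold:.3f}")
print(f"active synapses:       {int(flagged['active'].sum())}")
```

Output:

```
detected spots:        502
rejected (high R0):    110 (21.9%)
kept synapse records:  392
median pc:             0.309   (true median 0.309)
active threshold:      1.268
active synapses:       7
```

502 spots are detected (400 synapses plus autofluorescent granules and a
few split/merged components); the dynamic baseline-red filter removes
21.9% of them — the debris, which is bright in both channels at baseline.
The recovered population median of pc matches the generating median, and
the 3σ rule flags the upper tail of the right-skewed conversion
distribution as active.

A command-line surface wraps the same functions:

```
punctapipe simulate --config spec.yaml --seed 3 --out phantom/
punctapipe register --fixed g0.tif --moving g1.tif --apply r1.tif --out-dir reg/
punctapipe analyze rings --records records.csv --out rings.csv
```

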