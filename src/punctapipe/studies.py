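"""Preset phantom studies: canned generator conditions plus the recovery
analyses run on them.

Each function builds a phantom whose generating parameters are the study
conditions (distance constant, decay constant, conversion medians, clutter
load), runs the relevant portion of the pipeline, and returns the recovered
quantity next to the generating one.  These are the entry points used by
the acceptance script and the validation suite; they are also convenient
starting points for exploring the pipeline's operating range.
"""

from __future__ import annotations

import numpy as np

from .analyze import (FitResult, fit_exponential_curve,
                      fit_exponential_decay, fit_exponential_distance,
                      ring_analysis)
from .detect import rois_from_truth
from .phantom import (ConversionModel, PhantomSpec, WarpSpec,
                      generate_phantom, render_timeseries,
                      simulate_spine_amplitude_table)
from .pipeline import PipelineConfig, run_pipeline
from .preprocess import median_filter_3d
from .quantify import reject_autofluorescent

#: Conversion-distribution conditions for graded somatic spike trains:
#: (median, lognormal log-sigma, n_synapses).  The log-sigma values set the
#: distribution mean/median ratio of measured conversion histograms.
CONVERSION_CONDITIONS: dict[str, tuple[float, float, int]] = {
    "0bAP": (0.139, 0.575, 356),
    "3bAP": (0.327, 0.658, 472),
    "50bAP": (0.984, 0.88, 2587),
}

#: Default distance constant (µm) of the conversion-vs-distance phantom.
DISTANCE_LAMBDA_UM = 105.0
#: Default decay constant (min) of the turnover phantom.
TURNOVER_TAU_MIN = 29.4
#: Default distance constant (µm) of the spine calcium-amplitude table.
CALCIUM_LAMBDA_UM = 106.0


def _square_shape_for(n_synapses: int, density_per_um3: float,
                      nz: int = 28, voxel=(1.0, 1.0, 1.0)):
    """Smallest (nz, n, n) grid holding n_synapses at the given density."""
    target_volume = n_synapses / density_per_um3
    z_extent = (nz - 1) * voxel[0]
    nxy = int(np.ceil(np.sqrt(target_volume / z_extent) / voxel[1])) + 1
    return (nz, nxy, nxy)


# ------------------------------------------------------ distance-decay study

def distance_study_spec(
    seed: int,
    n_synapses: int = 1860,
    lambda_um: float = DISTANCE_LAMBDA_UM,
    amplitude: float = 2.0,
    dispersion: float = 0.5,
    warp_um: float = 2.0,
    clutter_fraction: float = 0.01,
    volume_shape=(28, 208, 208),
) -> PhantomSpec:
    """Phantom of one neuron's dendritic field: conversion falls off
    exponentially with Euclidean distance from a corner soma."""
    return PhantomSpec(
        volume_shape=volume_shape,
        voxel_size=(1.0, 1.0, 1.0),
        n_synapses=n_synapses,
        placement="radial",
        distance_range=(5.0, 240.0),
        conversion_model=ConversionModel(
            kind="exponential_distance", amplitude=amplitude,
            lambda_um=lambda_um, dispersion=dispersion),
        autofluorescence_volume_fraction=clutter_fraction,
        warp=WarpSpec(max_displacement_um=warp_um, smoothness_um=25.0),
        seed=seed,
    )


def recover_distance_constant(
    seed: int,
    n_synapses: int = 1860,
    lambda_um: float = DISTANCE_LAMBDA_UM,
    register: bool = True,
    ring_width_um: float = 20.0,
) -> dict:
    """Full-pipeline recovery of the distance constant λ.

    Render -> (register) -> detect -> reject -> extract -> rings -> fit.
    Returns the fitted λ, fit R², ring table and record count.
    """
    spec = distance_study_spec(seed, n_synapses=n_synapses, lambda_um=lambda_um,
                               warp_um=2.0 if register else 0.0)
    stacks, truth = generate_phantom(spec)
    config = PipelineConfig(register=register, seed=seed)
    result = run_pipeline(stacks, config, truth=truth)
    rec = result.records
    rec = rec[rec["pc_valid"] & ~rec["autofluorescent"] & ~rec["invalid"]]
    rings = ring_analysis(rec, ring_width_um=ring_width_um,
                          max_distance_um=spec.distance_range[1])
    fit = fit_exponential_distance(rings)
    return {
        "lambda_um": fit.params.get("lambda_um", float("nan")),
        "r_squared": fit.r_squared,
        "converged": fit.converged,
        "rings": rings,
        "n_records": int(len(rec)),
        "fit": fit,
    }


# -------------------------------------------------- conversion-median study

def conversion_study_spec(
    condition: str,
    seed: int,
    n_synapses: int | None = None,
    density_per_um3: float = 1.6e-3,
    clutter_fraction: float = 0.01,
) -> PhantomSpec:
    """Two-timepoint phantom whose true conversion distribution matches one
    of the graded spike-train conditions (right-skewed, fixed median)."""
    median, log_sigma, n_default = CONVERSION_CONDITIONS[condition]
    n = n_synapses if n_synapses is not None else n_default
    shape = _square_shape_for(n, density_per_um3)
    return PhantomSpec(
        volume_shape=shape,
        voxel_size=(1.0, 1.0, 1.0),
        n_synapses=n,
        placement="uniform",
        conversion_model=ConversionModel(kind="constant", median=median,
                                         dispersion=log_sigma),
        autofluorescence_volume_fraction=clutter_fraction,
        seed=seed,
    )


def recover_conversion_median(condition: str, seed: int,
                              n_synapses: int | None = None) -> dict:
    """Pipeline-recovered population median of pc for one condition."""
    spec = conversion_study_spec(condition, seed, n_synapses)
    stacks, truth = generate_phantom(spec)
    result = run_pipeline(stacks, PipelineConfig(seed=seed), truth=truth)
    rec = result.records
    kept = rec[rec["pc_valid"] & ~rec["autofluorescent"] & ~rec["invalid"]]
    return {
        "median_pc": float(kept["pc"].median()),
        "true_median": float(truth.synapses["conversion"].median()),
        "n_kept": int(len(kept)),
        "fraction_rejected": result.rejection.fraction_rejected,
    }


# ----------------------------------------------------------- turnover study

def turnover_study(
    seed: int,
    tau_min: float = TURNOVER_TAU_MIN,
    n_synapses: int = 138,
    timepoints_min: tuple[float, ...] = (0, 5, 10, 15, 20, 25, 30, 35, 40, 45, 50, 55, 60),
    conversion_median: float = 1.5,
    dispersion: float = 0.4,
    null_control: bool = True,
) -> dict:
    """Red-signal turnover: photoconvert, then image every ~5 min for an hour.

    The phantom's red increment decays with the generating τ; the pipeline
    detects synapses at baseline, extracts every timepoint, and fits
    A·exp(-t/τ)+C to the population-mean pc trace.  A null phantom
    (outside the illuminated region: zero conversion) checks that the
    constant model is selected in the absence of decay.
    """
    def run(median: float) -> tuple[np.ndarray, FitResult]:
        shape = _square_shape_for(n_synapses, 1.6e-3)
        spec = PhantomSpec(
            volume_shape=shape, voxel_size=(1.0, 1.0, 1.0),
            n_synapses=n_synapses, placement="uniform",
            conversion_model=ConversionModel(kind="constant", median=median,
                                             dispersion=dispersion),
            seed=seed,
        )
        baseline, series, truth = render_timeseries(spec, tau_min,
                                                    list(timepoints_min))
        stacks = {"G0": baseline["G0"], "R0": baseline["R0"]}
        for k, frame in enumerate(series, start=1):
            stacks[f"G{k}"] = frame["G"]
            stacks[f"R{k}"] = frame["R"]
        result = run_pipeline(stacks, PipelineConfig(seed=seed), truth=truth)
        rec = result.records
        kept = rec[~rec["autofluorescent"] & ~rec["invalid"]].copy()
        trace = []
        for k in range(1, len(series) + 1):
            denom = kept["g0"] + kept[f"g{k}"]
            pc_k = (kept[f"r{k}"] - kept["r0"]) / denom.where(denom > 0)
            trace.append(float(pc_k.mean()))
        t = np.asarray(timepoints_min, float)
        return np.asarray(trace), fit_exponential_decay(t, np.asarray(trace))

    trace, fit = run(conversion_median)
    out = {
        "tau_min": fit.params.get("tau_min", float("nan")),
        "r_squared": fit.r_squared,
        "selected_model": fit.selected_model,
        "trace": trace,
        "fit": fit,
    }
    if null_control:
        _, control = run(0.0)
        out["control_selected_model"] = control.selected_model
    return out


# --------------------------------------------- spine calcium-amplitude study

def calcium_distance_study(
    seed: int,
    n_spines: int = 55,
    lambda_um: float = CALCIUM_LAMBDA_UM,
    noise_log_sigma: float = 0.38,
) -> dict:
    """Fit of spine calcium-transient amplitudes vs distance (table-level).

    Emulates single-spine ΔF/F amplitude measurements along the dendritic
    tree during somatic spike trains; returns the fitted distance constant.
    """
    table = simulate_spine_amplitude_table(
        n_spines=n_spines, lambda_um=lambda_um,
        noise_log_sigma=noise_log_sigma, seed=seed)
    fit = fit_exponential_curve(table["distance_um"].to_numpy(),
                                table["amplitude"].to_numpy())
    return {"lambda_um": fit.params.get("lambda_um", float("nan")),
            "r_squared": fit.r_squared, "table": table, "fit": fit}


# ----------------------------------------------------------- rejection study

def rejection_study(
    clutter_volume_fraction: float,
    seed: int,
    volume_shape=(28, 130, 130),
    density_per_um3: float = 1.6e-3,
) -> dict:
    """Baseline-red rejection performance at a given clutter load.

    Uses ground-truth ROIs for both synapses and clutter so the filter is
    measured in isolation from the detector.  Returns per-class rejection
    fractions and the overall rejected fraction of detected spots.
    """
    extent = [(s - 1) * v for s, v in zip(volume_shape, (1.0, 1.0, 1.0))]
    n_syn = int(round(density_per_um3 * float(np.prod(extent))))
    spec = PhantomSpec(
        volume_shape=volume_shape, voxel_size=(1.0, 1.0, 1.0),
        n_synapses=n_syn, placement="uniform",
        conversion_model=ConversionModel(kind="constant", median=0.5,
                                         dispersion=0.5),
        autofluorescence_volume_fraction=clutter_volume_fraction,
        seed=seed,
    )
    stacks, truth = generate_phantom(spec)
    rois = rois_from_truth(truth, include_clutter=True)
    r0_med = median_filter_3d(stacks["R0"], 1)
    kept, report = reject_autofluorescent(rois, r0_med)
    n_clutter = len(truth.clutter)
    clutter_ids = set(range(n_syn, n_syn + n_clutter))
    rejected = set(report.rejected_ids)
    return {
        "fraction_rejected": report.fraction_rejected,
        "clutter_rejected_fraction": len(rejected & clutter_ids) / max(n_clutter, 1),
        "synapse_rejected_fraction": len(rejected - clutter_ids) / max(n_syn, 1),
        "n_synapses": n_syn,
        "n_clutter": n_clutter,
        "threshold": report.threshold,
    }
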